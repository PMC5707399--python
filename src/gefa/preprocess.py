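"""Preprocessing: anomalies, area averages, EOF truncation, seasonal pooling.

Raw monthly fields become estimator inputs in four steps:

1. the mean seasonal cycle (per-calendar-month climatology) is removed;
2. a least-squares linear trend is removed from the anomalies;
3. gridded forcing fields are reduced either to cos-latitude-weighted area
   averages over fixed region boxes, or to leading EOF principal components
   (truncation suppresses sampling error from highly correlated grid cells);
4. for seasonal analyses, three consecutive calendar months are pooled so
   the effective sample is 3 x the number of years, with each pooled month
   paired to its lag-tau partner month (which may precede the season).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import GEFAError, calendar_months, parse_season


# ---------------------------------------------------------------------------
# gridded containers

@dataclass
class RegionBox:
    """A lat/lon box; boundary cells whose centers fall inside are included."""

    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self):
        if not self.lat_min < self.lat_max:
            raise GEFAError(f"box {self.name}: lat_min must be < lat_max")


#: the three North African ecoregions used for terrestrial forcings
SAHEL = RegionBox("sahel", 12.0, 17.0, -20.0, 40.0)
WAM = RegionBox("wam", 5.0, 12.0, -20.0, 30.0)
HOA = RegionBox("hoa", -5.0, 10.0, 30.0, 52.0)


def _normalize_lon(lon):
    """Map longitudes into the -180..180 convention."""
    lon = np.asarray(lon, dtype=float)
    return np.where(lon > 180.0, lon - 360.0, lon)


@dataclass
class GriddedField:
    """A monthly lat/lon field with area weights and a missing-data mask.

    values: (time, nlat, nlon); mask True marks missing cells; area_weights
    default to cos(latitude) per row. `months` carries the calendar month
    index (January = 0) of each time step.
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    start_month: int = 0
    mask: np.ndarray | None = None
    area_weights: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = _normalize_lon(self.lon)
        d = np.diff(self.lat)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise GEFAError("lat must be strictly monotonic")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        if self.area_weights is None:
            w = np.cos(np.deg2rad(self.lat))
            self.area_weights = np.broadcast_to(w[:, None], self.values.shape[1:]).copy()
        if np.any(self.area_weights < 0) or not np.all(np.isfinite(self.area_weights)):
            raise GEFAError("area_weights must be nonnegative and finite")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def months(self) -> np.ndarray:
        return calendar_months(self.n_time, self.start_month)

    def box_indices(self, box: RegionBox) -> tuple[np.ndarray, np.ndarray]:
        ilat = np.where((self.lat >= box.lat_min) & (self.lat <= box.lat_max))[0]
        ilon = np.where((self.lon >= box.lon_min) & (self.lon <= box.lon_max))[0]
        if ilat.size == 0 or ilon.size == 0:
            raise GEFAError(f"box {box.name} does not overlap the grid")
        return ilat, ilon


@dataclass
class EOFBasis:
    """Area-weighted EOF decomposition of a boxed anomaly field.

    modes: (n_modes, n_space) spatial patterns in the raw (unweighted) field
    units; pcs: (time, n_modes) projections; explained_fraction sums to <= 1.
    Reconstruction: field ~= pcs @ modes (on the retained cells).
    """

    modes: np.ndarray
    pcs: np.ndarray
    explained_fraction: np.ndarray
    cell_weights: np.ndarray = field(repr=False, default=None)
    cell_index: tuple = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# series operations

def remove_seasonal_cycle(series: np.ndarray, start_month: int = 0) -> np.ndarray:
    """Subtract the per-calendar-month mean climatology.

    Works on 1-D (time,) or 2-D (time, k) monthly series; NaNs are ignored
    in the climatology and preserved in the output. Output per-month means
    are zero to machine precision.
    """
    x = np.asarray(series, dtype=float)
    one_d = x.ndim == 1
    x = x[:, None] if one_d else x.copy()
    if x.shape[0] < 24:
        raise GEFAError("need at least 24 months to estimate a seasonal cycle")
    months = calendar_months(x.shape[0], start_month)
    out = x.astype(float).copy()
    for m in range(12):
        sel = months == m
        if not sel.any():
            raise GEFAError(f"calendar month {m} never observed")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            clim = np.nanmean(x[sel], axis=0)
        out[sel] = x[sel] - clim
    return out[:, 0] if one_d else out


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend over the whole record.

    NaNs are excluded from the fit and preserved in the output.
    """
    x = np.asarray(series, dtype=float)
    one_d = x.ndim == 1
    x = x[:, None] if one_d else x.copy()
    n = x.shape[0]
    if n < 3:
        raise GEFAError("need at least 3 points to detrend")
    t = np.arange(n, dtype=float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ok = np.isfinite(x[:, j])
        if ok.sum() < 3:
            raise GEFAError(f"series {j}: fewer than 3 finite values")
        coef = np.polyfit(t[ok], x[ok, j], 1)
        out[:, j] = x[:, j] - np.polyval(coef, t)
    return out[:, 0] if one_d else out


def to_anomalies(series: np.ndarray, start_month: int = 0) -> np.ndarray:
    """Remove the seasonal cycle and the linear trend jointly.

    A joint least-squares fit on the 12 calendar-month indicators plus a
    linear term removes both components exactly (sequential application of
    `remove_seasonal_cycle` then `detrend_linear` leaves a small trend x
    calendar cross-term); the residual has zero per-month means and zero
    correlation with the time index simultaneously.
    """
    x = np.asarray(series, dtype=float)
    one_d = x.ndim == 1
    x = x[:, None] if one_d else x
    n = x.shape[0]
    if n < 24:
        raise GEFAError("need at least 24 months to estimate a seasonal cycle")
    months = calendar_months(n, start_month)
    D = np.zeros((n, 13))
    D[np.arange(n), months] = 1.0
    D[:, 12] = np.arange(n) - (n - 1) / 2.0
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ok = np.isfinite(x[:, j])
        if ok.sum() < 15:
            raise GEFAError(f"series {j}: too few finite values")
        coef, *_ = np.linalg.lstsq(D[ok], x[ok, j], rcond=None)
        out[:, j] = x[:, j] - D @ coef
    return out[:, 0] if one_d else out


def area_average(field: GriddedField, box: RegionBox) -> np.ndarray:
    """Cos-latitude-weighted mean over unmasked box cells, per time step.

    A time step whose box cells are all masked yields NaN, which downstream
    pairing drops.
    """
    ilat, ilon = field.box_indices(box)
    vals = field.values[np.ix_(np.arange(field.n_time), ilat, ilon)]
    msk = field.mask[np.ix_(np.arange(field.n_time), ilat, ilon)]
    w = field.area_weights[np.ix_(ilat, ilon)]
    wt = np.where(msk, 0.0, w[None, :, :])
    denom = wt.sum(axis=(1, 2))
    num = np.where(msk, 0.0, np.nan_to_num(vals)) * wt
    with np.errstate(invalid="ignore"):
        out = num.sum(axis=(1, 2)) / denom
    out[denom == 0] = np.nan
    return out


def compute_eof(field: GriddedField, box: RegionBox, n_modes: int) -> EOFBasis:
    """Area-weighted EOF decomposition of the box anomalies.

    Cells masked at any time are dropped; anomalies are time-demeaned, scaled
    by sqrt(cos lat), and decomposed by SVD. Modes are orthonormal under the
    area weighting and signed so each pattern's largest-|.| element is
    positive; pcs carry the variance (pcs = U * s in weighted units).
    """
    ilat, ilon = field.box_indices(box)
    sub = field.values[np.ix_(np.arange(field.n_time), ilat, ilon)]
    msk = field.mask[np.ix_(np.arange(field.n_time), ilat, ilon)]
    w2d = field.area_weights[np.ix_(ilat, ilon)]
    keep = ~msk.any(axis=0)
    X = sub[:, keep]
    w = w2d[keep]
    n_time, n_space = X.shape
    if n_modes > min(n_time, n_space):
        raise GEFAError(f"n_modes={n_modes} exceeds min(time, space)={min(n_time, n_space)}")
    Xc = X - X.mean(axis=0)
    sw = np.sqrt(w)
    U, s, Vt = np.linalg.svd(Xc * sw, full_matrices=False)
    lam = s**2
    total = lam.sum()
    if total == 0:
        raise GEFAError("field has zero variance in the box")
    lead = lam[: min(n_modes + 1, lam.size)]
    if lead.size >= 2 and np.any(np.isclose(lead[:-1], lead[1:], rtol=1e-9, atol=0)):
        warnings.warn("degenerate (tied) leading eigenvalues; mode order tie-broken by SVD order")
    modes_w = Vt[:n_modes]                       # orthonormal in weighted space
    modes = modes_w / sw                          # raw-units patterns
    pcs = U[:, :n_modes] * s[:n_modes]
    # sign convention: largest-|.| element of each raw pattern positive
    for k in range(n_modes):
        i = np.argmax(np.abs(modes[k]))
        if modes[k, i] < 0:
            modes[k] = -modes[k]
            pcs[:, k] = -pcs[:, k]
    return EOFBasis(
        modes=modes,
        pcs=pcs,
        explained_fraction=lam[:n_modes] / total,
        cell_weights=w,
        cell_index=(ilat, ilon, keep),
    )


# ---------------------------------------------------------------------------
# seasonal pooling

@dataclass
class SeasonPooling:
    """Index pairing for a 3-month seasonal pool at lag tau.

    targets[i] is the time index of pooled month i; partners[i] = targets[i]
    - tau is its lag partner, which for a season's first month falls in the
    preceding calendar month outside the season. Pairs whose partner precedes
    the record start are dropped and counted in n_dropped.
    """

    targets: np.ndarray
    partners: np.ndarray
    tau: int
    n_dropped: int

    @property
    def n_pairs(self) -> int:
        return len(self.targets)

    def pooled(self, series: np.ndarray) -> np.ndarray:
        return np.asarray(series)[self.targets]

    def lagged(self, series: np.ndarray) -> np.ndarray:
        return np.asarray(series)[self.partners]


def pool_season(n_months: int, season, tau: int, start_month: int = 0) -> SeasonPooling:
    """Build the (target, lag partner) index pairs for a pooled season.

    For a 30-year record and a 3-month season this yields 90 pooled months
    (minus any first-year pairs whose lag partner precedes the record).
    """
    months_in_season = parse_season(season)
    if tau < 0:
        raise GEFAError("tau must be nonnegative")
    months = calendar_months(n_months, start_month)
    in_season = np.isin(months, months_in_season)
    targets_all = np.where(in_season)[0]
    if n_months < 24:
        raise GEFAError("record must cover at least 2 years")
    partners_all = targets_all - tau
    ok = partners_all >= 0
    return SeasonPooling(
        targets=targets_all[ok],
        partners=partners_all[ok],
        tau=tau,
        n_dropped=int((~ok).sum()),
    )


def full_record_pooling(n_months: int, tau: int) -> SeasonPooling:
    """Pairing over the whole (unpooled) record at lag tau."""
    targets = np.arange(tau, n_months)
    return SeasonPooling(targets=targets, partners=targets - tau, tau=tau, n_dropped=tau)
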