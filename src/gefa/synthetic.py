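"""Synthetic land-ocean-atmosphere generator with known ground truth.

The generator realizes the stochastic picture the estimator assumes: slow
forcings O(t) (SST modes, vegetation indices) evolve as a cross-correlated
vector AR(1) process, and each fast atmospheric response follows

    A(t) = B_true . O(t) + N(t)  (+ seasonal cycle + linear trend),

with N(t) white Gaussian by default (the fast-weather limit; an AR(1) noise
option exists to probe robustness). Because B_true, the noise levels and
the forcing autocorrelations are known, every downstream stage - anomaly
preprocessing, stepwise selection, feedback estimation, variance
decomposition, multi-dataset combination - can be tested for parameter
recovery without any external data.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from ._util import GEFAError, child_seed
from .dust import DEFAULT_DAYTIME_WINDOW, DUST_CODES, StationRecord


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic scenario.

    Parameters
    ----------
    B_true
        Feedback matrix, shape (n_responses, n_forcings), response units per
        unit-variance forcing.
    forcing_ar1
        Lag-1 autocorrelation of each forcing, each in [0, 1).
    forcing_crosscov
        Target stationary covariance of the forcings (symmetric PSD).
    noise_sd
        Standard deviation of the atmospheric internal noise per response.
    seasonal_amplitude, seasonal_phase, trend_slope
        Deterministic components injected per response so that the
        climatology/trend removal steps have something real to remove.
        Amplitude in response units, phase in radians, slope in units/month.
    noise_ar1
        Lag-1 autocorrelation of N(t); 0 (white) by default.
    seed
        Base RNG seed; all sub-generators derive child seeds from it.
    """

    B_true: np.ndarray
    forcing_ar1: np.ndarray
    forcing_crosscov: np.ndarray
    noise_sd: np.ndarray
    seasonal_amplitude: np.ndarray | None = None
    seasonal_phase: np.ndarray | None = None
    trend_slope: np.ndarray | None = None
    noise_ar1: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.B_true = np.atleast_2d(np.asarray(self.B_true, dtype=float))
        self.forcing_ar1 = np.atleast_1d(np.asarray(self.forcing_ar1, dtype=float))
        self.forcing_crosscov = np.atleast_2d(np.asarray(self.forcing_crosscov, dtype=float))
        self.noise_sd = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        n_resp, n_forc = self.B_true.shape
        for name in ("seasonal_amplitude", "seasonal_phase", "trend_slope"):
            v = getattr(self, name)
            v = np.zeros(n_resp) if v is None else np.broadcast_to(np.atleast_1d(np.asarray(v, dtype=float)), (n_resp,)).copy()
            setattr(self, name, v)
        self.validate()

    @property
    def n_forcings(self) -> int:
        return self.B_true.shape[1]

    @property
    def n_responses(self) -> int:
        return self.B_true.shape[0]

    def validate(self) -> None:
        k = self.n_forcings
        if self.forcing_ar1.shape != (k,):
            raise GEFAError(f"forcing_ar1 must have length {k}, got {self.forcing_ar1.shape}")
        if self.forcing_crosscov.shape != (k, k):
            raise GEFAError(f"forcing_crosscov must be {k}x{k}")
        if not np.allclose(self.forcing_crosscov, self.forcing_crosscov.T, atol=1e-12):
            raise GEFAError("forcing_crosscov must be symmetric")
        eig = np.linalg.eigvalsh(self.forcing_crosscov)
        if eig.min() < -1e-10:
            raise GEFAError(f"forcing_crosscov is not PSD: smallest eigenvalue {eig.min():.3e}")
        if np.any(self.forcing_ar1 < 0) or np.any(self.forcing_ar1 >= 1):
            raise GEFAError("forcing_ar1 entries must lie in [0, 1)")
        if np.any(self.noise_sd < 0):
            raise GEFAError("noise_sd must be nonnegative")
        if self.noise_sd.shape != (self.n_responses,):
            raise GEFAError("noise_sd must have one entry per response")
        if not 0 <= self.noise_ar1 < 1:
            raise GEFAError("noise_ar1 must lie in [0, 1)")


def generate_forcings(truth: SyntheticTruth, n_months: int) -> np.ndarray:
    """Simulate the slow forcings as a stationary vector AR(1) process.

    x_t = diag(phi) x_{t-1} + e_t with innovation covariance solved from the
    discrete Lyapunov relation Q_ij = S_ij (1 - phi_i phi_j), so the
    stationary covariance equals ``truth.forcing_crosscov`` exactly.
    Returns an array of shape (n_months, n_forcings).
    """
    truth.validate()
    if n_months < 24:
        raise GEFAError("need at least 24 months of forcing data")
    phi = truth.forcing_ar1
    S = truth.forcing_crosscov
    Q = S * (1.0 - np.outer(phi, phi))
    eig = np.linalg.eigvalsh(Q)
    if eig.min() < -1e-10:
        raise GEFAError(
            f"no stationary AR(1) with this crosscov/ar1 combination: innovation "
            f"covariance eigenvalue {eig.min():.3e} < 0"
        )
    rng = np.random.default_rng(child_seed(truth.seed, "forcings"))
    k = truth.n_forcings
    # matrix square roots via eigen-decomposition (PSD-safe)
    def _sqrtm(M):
        w, V = np.linalg.eigh(M)
        return V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T

    x = np.empty((n_months, k))
    x[0] = _sqrtm(S) @ rng.standard_normal(k)
    Lq = _sqrtm(Q)
    innov = rng.standard_normal((n_months - 1, k)) @ Lq.T
    for t in range(1, n_months):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return x


def generate_atmosphere(
    truth: SyntheticTruth, forcings: np.ndarray, start_month: int = 0
) -> np.ndarray:
    """Build the fast responses A(t) = B_true . O(t) + N(t) + cycle + trend.

    Returns an array of shape (n_months, n_responses). The seasonal cycle is
    a single 12-month sinusoid per response and the trend is linear in the
    month index; both exist so preprocessing has real structure to remove.
    """
    forcings = np.asarray(forcings, dtype=float)
    if forcings.ndim != 2 or forcings.shape[1] != truth.n_forcings:
        raise GEFAError(
            f"forcings have {forcings.shape[-1] if forcings.ndim == 2 else '?'} columns, "
            f"B_true expects {truth.n_forcings}"
        )
    n = forcings.shape[0]
    rng = np.random.default_rng(child_seed(truth.seed, "atmosphere"))
    signal = forcings @ truth.B_true.T
    eps = rng.standard_normal((n, truth.n_responses)) * truth.noise_sd
    if truth.noise_ar1 > 0:
        a = truth.noise_ar1
        noise = np.empty_like(eps)
        noise[0] = eps[0] / np.sqrt(1 - a**2)
        for t in range(1, n):
            noise[t] = a * noise[t - 1] + eps[t]
    else:
        noise = eps
    t_idx = np.arange(n)[:, None]
    months = (t_idx + start_month) % 12
    cycle = truth.seasonal_amplitude * np.sin(2 * np.pi * months / 12.0 + truth.seasonal_phase)
    trend = truth.trend_slope * t_idx
    return signal + noise + cycle + trend


def generate_dataset_replicates(
    base: np.ndarray, n_datasets: int, error_sds, seed: int = 0
) -> list[np.ndarray]:
    """Emulate multiple observational datasets measuring the same truth.

    Replicate k = base + independent Gaussian measurement error with
    sd ``error_sds[k]``; index 0 is the most reliable (smallest error).
    """
    base = np.asarray(base, dtype=float)
    error_sds = np.asarray(error_sds, dtype=float)
    if n_datasets < 2:
        raise GEFAError("need at least 2 dataset replicates")
    if error_sds.shape != (n_datasets,):
        raise GEFAError("error_sds must have one entry per dataset")
    if np.any(error_sds < 0):
        raise GEFAError("error_sds must be nonnegative")
    if np.any(np.diff(error_sds) < 0):
        raise GEFAError("error_sds must be nondecreasing (index 0 = most reliable)")
    out = []
    for k in range(n_datasets):
        rng = np.random.default_rng(child_seed(seed, f"replicate-{k}"))
        out.append(base + rng.standard_normal(base.shape) * error_sds[k])
    return out


@dataclass
class DustScenario:
    """Random or scripted station-weather scenario.

    ``code_probs`` draws each observation's code independently;
    ``scripted`` overrides whole station-days with explicit
    (station index, day index) -> list of (hour, code) entries.
    """

    code_probs: dict = field(default_factory=lambda: {"none": 0.9, "dust_suspension": 0.08, "dust_storm": 0.015, "severe_dust_storm": 0.005})
    obs_hours: tuple = tuple(range(0, 24, 3))
    daytime_window: tuple[float, float] = DEFAULT_DAYTIME_WINDOW
    start_date: _dt.date = _dt.date(2000, 1, 1)
    scripted: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.daytime_window
        if not lo < hi:
            raise GEFAError("daytime window is empty")
        bad = set(self.code_probs) - set(DUST_CODES)
        if bad:
            raise GEFAError(f"unknown weather codes in scenario: {bad}")


def generate_station_weather(
    n_stations: int, n_days: int, scenario: DustScenario | None = None, seed: int = 0
) -> list[StationRecord]:
    """Generate hourly station weather records on a known 0.5 deg grid.

    Stations are laid out along a Sahel-like transect (lat 14N, lon spaced
    0.5 deg from 10W). Scripted scenario entries are reproduced exactly;
    otherwise codes are iid draws from ``scenario.code_probs``.
    """
    scenario = scenario or DustScenario()
    rng = np.random.default_rng(child_seed(seed, "station-weather"))
    codes = list(scenario.code_probs)
    probs = np.array([scenario.code_probs[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    stations = []
    for s in range(n_stations):
        lat, lon = 14.0, -10.0 + 0.5 * s
        obs = []
        for d in range(n_days):
            day = scenario.start_date + _dt.timedelta(days=d)
            if (s, d) in scenario.scripted:
                for hour, code in scenario.scripted[(s, d)]:
                    h = int(hour)
                    minute = int(round((hour - h) * 60))
                    obs.append((_dt.datetime.combine(day, _dt.time(h, minute)), code))
            else:
                drawn = rng.choice(len(codes), size=len(scenario.obs_hours), p=probs)
                for hour, ci in zip(scenario.obs_hours, drawn):
                    obs.append((_dt.datetime.combine(day, _dt.time(int(hour))), codes[ci]))
        stations.append(StationRecord(f"ST{s:03d}", lat, lon, obs))
    return stations


def sahel_scenario_truth(seed: int = 0, ar1: float = 0.85) -> SyntheticTruth:
    """The bundled attribution scenario: 17 ocean-like + 3 land-like candidates.

    Three forcings are truly coupled to the single response (two oceanic and
    one terrestrial); the rest are null. Signal fractions are 0.30 for the
    ocean group and 0.15 for the land group, with total response variance 1,
    moderate forcing persistence, and weak cross-correlation among candidates.
    """
    n_forc = 20
    b = np.zeros((1, n_forc))
    b[0, 0] = np.sqrt(0.15)   # ocean forcing 1
    b[0, 1] = np.sqrt(0.15)   # ocean forcing 2
    b[0, 17] = np.sqrt(0.15)  # land forcing
    noise_sd = np.sqrt(1.0 - 0.45)
    crosscov = np.full((n_forc, n_forc), 0.0)
    np.fill_diagonal(crosscov, 1.0)
    return SyntheticTruth(
        B_true=b,
        forcing_ar1=np.full(n_forc, ar1),
        forcing_crosscov=crosscov,
        noise_sd=[noise_sd],
        seasonal_amplitude=[1.0],
        trend_slope=[0.002],
        seed=seed,
    )


#: forcing names and oceanic/terrestrial group tags for `sahel_scenario_truth`
SAHEL_SCENARIO_NAMES = (
    [f"sst_basin{b}_eof{m}" for b in range(1, 9) for m in (1, 2)]
    + ["sst_mediterranean"]
    + ["ndvi_sahel", "ndvi_wam", "ndvi_hoa"]
)
SAHEL_SCENARIO_GROUPS = ["oceanic"] * 17 + ["terrestrial"] * 3
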