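"""Feedback estimation from lagged covariances, with bootstrap significance.

At time scales beyond the atmospheric memory a fast variable A(t) is modeled
as a linear response to slow forcings plus internal noise,

    A(t) = B . O(t) + N(t).

Right-multiplying by O^T(t - tau) and using that later noise cannot force
the slow variables (C_NO(tau) = 0 for tau > 0) gives the estimator

    B = C_AO(tau) . C_OO(tau)^-1,
    C_AO(tau) = (1/L) A(t) O^T(t-tau),   C_OO(tau) = (1/L) O(t) O^T(t-tau).

The lag defaults to one month: in theory B is lag-independent, but sampling
error grows with tau, and at tau = 0 the noise-independence argument fails
for real data (tau = 0 is kept for oracle/testing use, where it reduces to
ordinary multiple regression). Significance comes from a Monte Carlo
bootstrap that scrambles the response series and re-estimates B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import GEFAError
from .preprocess import SeasonPooling, full_record_pooling

#: relative condition number above which C_OO is treated as singular
CONDITION_LIMIT = 1e8

#: significance level used for flagging throughout
P_SIGNIFICANT = 0.1


@dataclass
class ForcingMatrix:
    """Stacked slow-forcing series O(t), one standardized column per forcing.

    Columns are standardized to zero mean and unit variance so feedback
    coefficients read as response units per one standard deviation of the
    forcing. Each column carries a name and an 'oceanic'/'terrestrial' tag.
    """

    values: np.ndarray
    names: list[str]
    group: list[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names) or len(self.names) != len(self.group):
            raise GEFAError("values, names and group must agree in column count")
        if len(set(self.names)) != len(self.names):
            raise GEFAError("duplicate forcing names")

    @classmethod
    def from_series(cls, columns: dict[str, np.ndarray], group: dict[str, str] | str = "oceanic",
                    standardize: bool = True) -> "ForcingMatrix":
        names = list(columns)
        vals = np.column_stack([np.asarray(columns[n], dtype=float) for n in names])
        if standardize:
            mu = np.nanmean(vals, axis=0)
            sd = np.nanstd(vals, axis=0)
            if np.any(sd == 0):
                bad = [n for n, s in zip(names, sd) if s == 0]
                raise GEFAError(f"constant forcing column(s): {bad}")
            vals = (vals - mu) / sd
        groups = [group] * len(names) if isinstance(group, str) else [group[n] for n in names]
        return cls(vals, names, groups)

    @property
    def n_forcings(self) -> int:
        return self.values.shape[1]

    def subset(self, names: list[str]) -> "ForcingMatrix":
        idx = [self.names.index(n) for n in names]
        return ForcingMatrix(self.values[:, idx], [self.names[i] for i in idx],
                             [self.group[i] for i in idx])

    def group_subset(self, tag: str) -> "ForcingMatrix":
        names = [n for n, g in zip(self.names, self.group) if g == tag]
        return self.subset(names)


@dataclass
class FeedbackMatrix:
    """Estimated feedback coefficients with bootstrap p-values.

    B has shape (n_responses, n_forcings) in response units per forcing
    standard deviation; p_values is the same shape (NaN until the bootstrap
    has run); L_effective is the retained pair count.
    """

    B: np.ndarray
    tau: int
    L_effective: int
    forcing_names: list[str]
    response_names: list[str] = field(default_factory=list)
    p_values: np.ndarray | None = None

    def __post_init__(self):
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if not np.all(np.isfinite(self.B)):
            raise GEFAError("feedback matrix contains non-finite entries")
        if self.p_values is not None:
            self.p_values = np.atleast_2d(np.asarray(self.p_values, dtype=float))

    def significant(self, alpha: float = P_SIGNIFICANT) -> np.ndarray:
        if self.p_values is None:
            raise GEFAError("run bootstrap_significance first")
        return self.p_values < alpha


def _paired(A: np.ndarray, O: ForcingMatrix, tau: int, pooling: SeasonPooling | None):
    """Extract aligned (target, partner) samples, dropping pairs with NaNs."""
    A = np.asarray(A, dtype=float)
    A2 = A[:, None] if A.ndim == 1 else A
    if pooling is None:
        pooling = full_record_pooling(A2.shape[0], tau)
    elif pooling.tau != tau:
        raise GEFAError(f"pooling was built for tau={pooling.tau}, estimator got tau={tau}")
    At = A2[pooling.targets]
    Ot = O.values[pooling.targets]
    Op = O.values[pooling.partners]
    ok = np.isfinite(At).all(axis=1) & np.isfinite(Ot).all(axis=1) & np.isfinite(Op).all(axis=1)
    return At[ok], Ot[ok], Op[ok]


def lagged_covariance(A: np.ndarray, O: ForcingMatrix, tau: int,
                      pooling: SeasonPooling | None = None):
    """Sample lagged covariances C_AO(tau) and C_OO(tau) with 1/L scaling.

    Note C_OO at tau > 0 is in general not symmetric. Pairs with any missing
    member are dropped; L is the retained pair count.
    """
    At, Ot, Op = _paired(A, O, tau, pooling)
    L = At.shape[0]
    if L < O.n_forcings + 5:
        raise GEFAError(
            f"only {L} retained pairs at tau={tau} for {O.n_forcings} forcings; "
            f"need at least {O.n_forcings + 5}"
        )
    C_AO = At.T @ Op / L
    C_OO = Ot.T @ Op / L
    return C_AO, C_OO, L


def estimate_feedback(A: np.ndarray, O: ForcingMatrix, tau: int = 1,
                      pooling: SeasonPooling | None = None,
                      response_names: list[str] | None = None) -> FeedbackMatrix:
    """Estimate B = C_AO(tau) . C_OO(tau)^-1.

    Raises when C_OO is ill-conditioned (relative condition number above
    1e8); the intended remedy is EOF truncation of the forcing fields and
    stepwise selection, not regularization.
    """
    C_AO, C_OO, L = lagged_covariance(A, O, tau, pooling)
    sv = np.linalg.svd(C_OO, compute_uv=False)
    cond = np.inf if sv[-1] == 0 else sv[0] / sv[-1]
    if cond > CONDITION_LIMIT:
        raise GEFAError(
            f"C_OO(tau={tau}) is ill-conditioned (cond={cond:.2e}); reduce the "
            f"forcing set (EOF truncation / stepwise selection) before estimating"
        )
    B = C_AO @ np.linalg.inv(C_OO)
    A2 = np.asarray(A, dtype=float)
    n_resp = 1 if A2.ndim == 1 else A2.shape[1]
    return FeedbackMatrix(
        B=B,
        tau=tau,
        L_effective=L,
        forcing_names=list(O.names),
        response_names=response_names or [f"response{i}" for i in range(n_resp)],
    )


def bootstrap_significance(A: np.ndarray, O: ForcingMatrix, tau: int = 1,
                           n_iter: int = 1000, seed: int = 0,
                           pooling: SeasonPooling | None = None,
                           block: int | None = None) -> FeedbackMatrix:
    """Attach Monte Carlo scrambling p-values to the feedback estimate.

    The pooled response vector is randomly permuted n_iter times (destroying
    the forcing-response alignment while preserving the response's marginal
    distribution exactly), B is re-estimated each time, and each coefficient
    gets a two-sided p-value: the fraction of scrambled |B| at least as large
    as the observed |B|. `block` permutes contiguous blocks instead, for
    strongly autocorrelated responses (off by default).
    """
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} gives coarse p-value resolution")
    fb = estimate_feedback(A, O, tau, pooling)
    At, _, Op = _paired(A, O, tau, pooling)
    _, C_OO, L = lagged_covariance(A, O, tau, pooling)
    Minv = np.linalg.inv(C_OO)
    rng = np.random.default_rng(seed)
    n_resp = At.shape[1]
    exceed = np.zeros_like(fb.B)
    absB = np.abs(fb.B)
    for _ in range(n_iter):
        if block:
            n_blocks = int(np.ceil(L / block))
            order = rng.permutation(n_blocks)
            idx = np.concatenate([np.arange(b * block, min((b + 1) * block, L)) for b in order])
        else:
            idx = rng.permutation(L)
        B_s = (At[idx].T @ Op / L) @ Minv
        exceed += np.abs(B_s) >= absB
    fb.p_values = exceed / n_iter
    return fb
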