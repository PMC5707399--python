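"""Backward stepwise forcing selection under AIC.

Short records cannot support feedback estimation against ~20 candidate
forcings at once, so negligible forcings are eliminated first. Each
candidate model is scored with

    AIC = 2 N_f - 2 ln(Lhat),
    ln(Lhat) = -(L/2) ln( sum_t (Ahat(t) - A(t))^2 / L ),
    Ahat(t) = B . O(t),

where N_f is the number of forcings, B the lagged-covariance feedback fit,
and the Gaussian-likelihood constant is dropped (only AIC differences
matter). Each round all single-forcing removals are tried and the one
yielding the lowest AIC is accepted as long as AIC does not increase;
selection stops when every removal increases AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import GEFAError
from .core import ForcingMatrix, estimate_feedback
from .preprocess import SeasonPooling, full_record_pooling


@dataclass
class SelectionTrace:
    """Record of accepted removals: (removed name, AIC before, AIC after)."""

    steps: list[tuple[str, float, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["removed", "aic_before", "aic_after"])


def aic_score(A: np.ndarray, O: ForcingMatrix | None, tau: int = 1,
              pooling: SeasonPooling | None = None) -> float:
    """AIC of the feedback model with forcing set O (None or empty = noise-only).

    A perfect fit (zero residual sum of squares) returns -inf with a warning.
    """
    A1 = np.asarray(A, dtype=float)
    if A1.ndim != 1:
        raise GEFAError("aic_score expects a single response series")
    if pooling is None:
        pooling = full_record_pooling(A1.shape[0], tau)
    At = pooling.pooled(A1)
    ok = np.isfinite(At)
    if O is None or O.n_forcings == 0:
        resid = At[ok]
        L = ok.sum()
        n_f = 0
    else:
        fb = estimate_feedback(A1, O, tau, pooling)
        Ot = pooling.pooled(O.values)
        ok = ok & np.isfinite(Ot).all(axis=1)
        resid = At[ok] - Ot[ok] @ fb.B[0]
        L = int(ok.sum())
        n_f = O.n_forcings
    rss = float(resid @ resid)
    if rss == 0.0:
        warnings.warn("perfect fit: zero residual sum of squares; AIC = -inf")
        return -np.inf
    log_lik = -(L / 2.0) * np.log(rss / L)
    return 2.0 * n_f - 2.0 * log_lik


def backward_select(A: np.ndarray, O: ForcingMatrix, tau: int = 1,
                    pooling: SeasonPooling | None = None) -> tuple[SelectionTrace, ForcingMatrix]:
    """Greedy backward elimination of forcings under AIC.

    Removals that leave AIC unchanged (to 1e-9) are accepted; ties between
    candidate removals are broken toward the column with the smaller current
    |coefficient|. May empty the forcing set entirely when all candidates are
    negligible.
    """
    if O.n_forcings < 1:
        raise GEFAError("backward_select needs at least one forcing")
    trace = SelectionTrace()
    current = O
    aic_now = aic_score(A, current, tau, pooling)
    while current.n_forcings > 0:
        coef = np.abs(estimate_feedback(A, current, tau, pooling).B[0])
        candidates = []
        for j, name in enumerate(current.names):
            reduced = current.subset([n for n in current.names if n != name])
            aic_j = aic_score(A, reduced if reduced.n_forcings else None, tau, pooling)
            candidates.append((aic_j, coef[j], name, reduced))
        aic_best, _, name_best, reduced_best = min(candidates, key=lambda c: (c[0], c[1]))
        if aic_best <= aic_now + 1e-9:
            trace.steps.append((name_best, aic_now, aic_best))
            current = reduced_best
            aic_now = aic_best
        else:
            break
    trace.retained = list(current.names)
    return trace, current
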