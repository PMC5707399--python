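"""Reliability-weighted combination of per-dataset feedback results.

Each observational dataset yields its own feedback/response estimate; the
multi-dataset summary is built by a Monte Carlo bootstrap: per iteration,
one uniform(0,1) weight per dataset is drawn, the weights are sorted
descending and assigned in order of regional reliability (largest weight to
the most reliable dataset), normalized to sum to one, and the weighted
average formed. The mean and the 10th/90th percentiles of the resulting
distribution of weighted averages give the multi-dataset estimate and its
uncertainty band.

The rule for declaring the multi-dataset mean significant is an artifact
construction (the source method reports per-dataset bootstrap p-values
only): the mean is flagged when at least half the datasets are individually
significant and every individually significant dataset agrees in sign with
the weighted mean. Any callable with the same signature can replace it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import GEFAError
from .core import P_SIGNIFICANT

DEFAULT_N_ITER = 1000


@dataclass
class DatasetEnsemble:
    """Per-dataset result arrays plus their reliability ordering.

    responses: list of same-shape arrays (scalars allowed); reliability_rank
    lists dataset indices from most to least reliable.
    """

    responses: list[np.ndarray]
    reliability_rank: list[int]
    n_iter: int = DEFAULT_N_ITER

    def __post_init__(self):
        self.responses = [np.asarray(r, dtype=float) for r in self.responses]
        shapes = {r.shape for r in self.responses}
        if len(shapes) != 1:
            raise GEFAError(f"dataset result arrays differ in shape: {shapes}")
        if sorted(self.reliability_rank) != list(range(len(self.responses))):
            raise GEFAError("reliability_rank must be a permutation of dataset indices")


@dataclass
class MultiDatasetSummary:
    mean: np.ndarray
    p10: np.ndarray
    p90: np.ndarray
    samples: np.ndarray = field(repr=False, default=None)


def weighted_bootstrap(ensemble: DatasetEnsemble, seed: int = 0,
                       sort_weights: bool = True) -> MultiDatasetSummary:
    """Monte Carlo distribution of reliability-weighted dataset averages.

    With ``sort_weights=False`` the weights are left unsorted (all datasets
    exchangeable), so the expected combination approaches the plain mean -
    useful as a sensitivity check on the reliability ordering.
    """
    K = len(ensemble.responses)
    if K < 1:
        raise GEFAError("empty ensemble")
    stack = np.stack(ensemble.responses)       # (K, ...)
    if K == 1:
        warnings.warn("single dataset: degenerate multi-dataset summary")
        return MultiDatasetSummary(stack[0], stack[0], stack[0], stack[None, 0])
    rng = np.random.default_rng(seed)
    w = rng.uniform(size=(ensemble.n_iter, K))
    if sort_weights:
        w = np.sort(w, axis=1)[:, ::-1]        # descending: col 0 = largest
        weights = np.empty_like(w)
        weights[:, ensemble.reliability_rank] = w
    else:
        weights = w
    weights = weights / weights.sum(axis=1, keepdims=True)
    flat = stack.reshape(K, -1)
    samples = weights @ flat                   # (n_iter, n_elements)
    shape = stack.shape[1:]
    mean = samples.mean(axis=0).reshape(shape)
    p10 = np.percentile(samples, 10, axis=0).reshape(shape)
    p90 = np.percentile(samples, 90, axis=0).reshape(shape)
    return MultiDatasetSummary(mean, p10, p90, samples.reshape((ensemble.n_iter,) + shape))


def significance_of_mean(ensemble: DatasetEnsemble, p_values: list[np.ndarray],
                         summary: MultiDatasetSummary | None = None,
                         alpha: float = P_SIGNIFICANT,
                         rule=None) -> np.ndarray:
    """Combine per-dataset p-values into a significance mask for the mean.

    Default rule: significant where >= half the datasets have p < alpha and
    every such dataset's response shares the weighted mean's sign. Pass
    ``rule(stack, pstack, mean, alpha) -> mask`` to substitute another rule.
    """
    stack = np.stack(ensemble.responses)
    pstack = np.stack([np.asarray(p, dtype=float) for p in p_values])
    if pstack.shape != stack.shape:
        raise GEFAError("p-values must align with responses")
    if summary is None:
        summary = weighted_bootstrap(ensemble)
    if rule is not None:
        return rule(stack, pstack, summary.mean, alpha)
    sig = pstack < alpha
    enough = sig.sum(axis=0) >= stack.shape[0] / 2.0
    mean_sign = np.sign(summary.mean)
    agrees = np.where(sig, np.sign(stack) == mean_sign, True).all(axis=0)
    return enough & agrees
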