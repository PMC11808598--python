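"""Cumulative sum scaling (CSS) normalization.

CSS corrects for library-size variation by scaling each sample with the
cumulative count of its lower-abundance taxa up to a chosen quantile,
rather than the total sum, which makes the factor robust to a handful of
dominant taxa. For sample ``j`` with quantile ``l``:

    q_j = l-th quantile of the sample's nonzero counts
    s_j = sum of nonzero counts c_ij with c_ij <= q_j
    value_ij = c_ij * N / s_j

with scale constant ``N`` (default 1000; any positive N rescales all
features uniformly and cannot affect tree-based classifiers). The quantile
is taken over nonzero counts only — zeros carry no depth information in
sparse profiles — and the cumulative sum is inclusive at ties.

Normalization is always fit per dataset / per data split: scaling factors
from one split are never applied to another.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

DEFAULT_QUANTILE = 0.5
DEFAULT_SCALE = 1000.0


def css_scaling_factors(matrix: CountMatrix, quantile: float = DEFAULT_QUANTILE) -> np.ndarray:
    """Per-sample CSS scaling factors s_j.

    An all-zero sample carries no depth information; its factor is set to 1
    with a logged warning so the zero column passes through unchanged.
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must lie in (0, 1), got {quantile}")
    counts = matrix.counts
    factors = np.ones(matrix.n_samples, dtype=float)
    for j in range(matrix.n_samples):
        nz = counts[:, j][counts[:, j] > 0]
        if nz.size == 0:
            logger.warning(
                "sample %r has no nonzero counts; scaling factor set to 1",
                matrix.samples[j],
            )
            continue
        q = np.quantile(nz, quantile)  # linear-interpolation convention
        factors[j] = float(nz[nz <= q].sum())
    return factors


def css_normalize(
    matrix: CountMatrix,
    quantile: float = DEFAULT_QUANTILE,
    scale_constant: float = DEFAULT_SCALE,
    log_transform: bool = False,
) -> NormalizedMatrix:
    """CSS-normalize a count matrix, recording factors, quantile and scale.

    ``log_transform`` applies log1p after scaling; off by default.
    """
    if scale_constant <= 0:
        raise ValueError("scale_constant must be positive")
    factors = css_scaling_factors(matrix, quantile)
    values = matrix.counts.astype(float) * (scale_constant / factors)[None, :]
    if log_transform:
        values = np.log1p(values)
    return NormalizedMatrix(
        features=list(matrix.features),
        samples=list(matrix.samples),
        values=values,
        scaling_factors=factors,
        quantile_used=quantile,
        scale_constant=scale_constant,
        log_transformed=log_transform,
    )


def select_quantile_adaptive(
    matrix: CountMatrix,
    candidates: np.ndarray | None = None,
    instability_threshold: float = 0.1,
    floor: float = 0.5,
) -> float:
    """Data-driven choice of the CSS quantile.

    Scans candidate quantiles l in {0.01, ..., 0.99}; at each l computes
    the median across samples of ``|q_j^l - ref^l|`` where ``ref^l`` is the
    l-th quantile of the across-sample median count profile. Returns the
    smallest l at which this deviation's relative increase over the
    previous candidate exceeds ``instability_threshold``, floored at 0.5.
    This approximates the adaptive quantile search of reference CSS
    implementations; degenerate matrices (all samples identical, or no
    instability point) fall back to the floor.
    """
    if matrix.n_samples < 2:
        raise ValueError("adaptive quantile selection needs at least 2 samples")
    if candidates is None:
        candidates = np.round(np.arange(0.01, 1.00, 0.01), 2)
    counts = matrix.counts
    median_profile = np.median(counts, axis=1)
    ref_nz = median_profile[median_profile > 0]
    per_sample_nz = [counts[:, j][counts[:, j] > 0] for j in range(matrix.n_samples)]
    if ref_nz.size == 0 or all(nz.size == 0 for nz in per_sample_nz):
        return floor

    deviations = np.empty(candidates.size)
    for k, l in enumerate(candidates):
        ref_q = np.quantile(ref_nz, l)
        qs = np.array([np.quantile(nz, l) if nz.size else 0.0 for nz in per_sample_nz])
        deviations[k] = np.median(np.abs(qs - ref_q))

    for k in range(1, candidates.size):
        prev, cur = deviations[k - 1], deviations[k]
        if prev == 0.0:
            unstable = cur > 0.0
        else:
            unstable = (cur - prev) / prev > instability_threshold
        if unstable:
            return float(max(candidates[k], floor))
    return floor
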