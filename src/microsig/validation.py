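"""Cross-dataset transfer testing against a shuffled-label null.

Models trained on one cohort are scored, iteration by iteration, on an
independently CSS-normalized external cohort whose features are aligned
(zero-filled) onto the training universe. The chance distribution comes
from null models retrained after uniform random permutation of the tissue
labels — retrained per shuffled labelling, not score-permuted. A signature
is "preserved" in the external cohort when the true models beat the null
significantly (rank-sum on AUROC and AUPR, true medians higher) and
additionally clear the detection thresholds (external mean AUROC >= 0.70,
mean relative AUPR >= 1.4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .containers import CountMatrix, SampleMetadata
from .io import align_features
from .models import (
    DEFAULT_AUROC_MIN,
    DEFAULT_REL_AUPR_MIN,
    MetricsRecord,
    ModelSpec,
    SignatureResults,
    TissueSignatureModel,
    evaluate,
)
from .normalize import DEFAULT_QUANTILE, DEFAULT_SCALE, css_normalize


def _external_design(
    external_counts: CountMatrix,
    external_meta: SampleMetadata,
    target_tissue: str,
    feature_universe,
    quantile: float,
    scale_constant: float,
):
    """Independently CSS-normalize the external cohort and align it onto
    the training feature universe; returns (X, y)."""
    if not external_meta.aligned_with(external_counts):
        raise ValueError("external metadata must align with external counts")
    y = (external_meta.tissue_labels() == target_tissue).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(
            f"external cohort lacks positives or negatives for {target_tissue!r}"
        )
    nm = css_normalize(external_counts, quantile=quantile, scale_constant=scale_constant)
    aligned, _ = align_features(nm, feature_universe)
    return aligned.values.T, y


def transfer_test(
    trained: SignatureResults,
    external_counts: CountMatrix,
    external_meta: SampleMetadata,
    feature_universe=None,
    quantile: float = DEFAULT_QUANTILE,
    scale_constant: float = DEFAULT_SCALE,
) -> list[MetricsRecord]:
    """Score every stored training iteration on the external cohort.

    Normalization of the external data is fit on the external data alone;
    no training-split scaling factor ever crosses over.
    """
    if not trained.models:
        raise ValueError(
            "no stored iteration models; rerun the signature experiment with store_models=True"
        )
    records = []
    for itmodel in trained.models:
        universe = feature_universe if feature_universe is not None else itmodel.feature_universe
        X, y = _external_design(
            external_counts, external_meta, trained.tissue, universe, quantile, scale_constant
        )
        records.append(evaluate(itmodel.fitted, X, y))
    return records


def random_label_null(
    counts: CountMatrix,
    metadata: SampleMetadata,
    target_tissue: str,
    feature_universe,
    spec: ModelSpec | None = None,
    quantile: float = DEFAULT_QUANTILE,
    scale_constant: float = DEFAULT_SCALE,
) -> SignatureResults:
    """Retrain the signature experiment with tissue labels permuted
    uniformly at random (a fresh seeded permutation per iteration); stored
    models provide the chance distribution for external scoring."""
    spec = spec or ModelSpec()
    model = TissueSignatureModel(
        counts,
        metadata,
        target_tissue,
        feature_universe,
        spec,
        quantile=quantile,
        scale_constant=scale_constant,
        store_models=True,
        label_permutation_seed=spec.master_seed + 1_000_003,
    )
    return model.fit()


@dataclass
class TransferReport:
    """External-cohort performance of true models versus the label-shuffled
    null, with the preservation verdict."""

    tissue: str
    true_metrics: list[MetricsRecord]
    null_metrics: list[MetricsRecord]
    p_auroc: float
    p_aupr: float
    preserved: bool

    @property
    def mean_auroc(self) -> float:
        return float(np.mean([r.auroc for r in self.true_metrics]))

    @property
    def mean_relative_aupr(self) -> float:
        return float(np.mean([r.relative_aupr for r in self.true_metrics]))

    @property
    def null_mean_auroc(self) -> float:
        return float(np.mean([r.auroc for r in self.null_metrics]))

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "mean_auroc": self.mean_auroc,
            "mean_relative_aupr": self.mean_relative_aupr,
            "null_mean_auroc": self.null_mean_auroc,
            "p_auroc": self.p_auroc,
            "p_aupr": self.p_aupr,
            "preserved": self.preserved,
            "true_iterations": [r.to_dict() for r in self.true_metrics],
            "null_iterations": [r.to_dict() for r in self.null_metrics],
        }

    def summary(self) -> str:
        return (
            f"Transfer test: {self.tissue}\n"
            f"  external mean AUROC      {self.mean_auroc:.3f} (null {self.null_mean_auroc:.3f})\n"
            f"  external mean rel. AUPR  {self.mean_relative_aupr:.3f}\n"
            f"  rank-sum p (AUROC/AUPR)  {self.p_auroc:.3g} / {self.p_aupr:.3g}\n"
            f"  signature preserved      {self.preserved}"
        )


def _transfer_decision(
    true_metrics,
    null_metrics,
    alpha: float,
    auroc_min: float,
    rel_aupr_min: float,
):
    t_auroc = np.array([r.auroc for r in true_metrics])
    n_auroc = np.array([r.auroc for r in null_metrics])
    t_aupr = np.array([r.aupr for r in true_metrics])
    n_aupr = np.array([r.aupr for r in null_metrics])

    def pval(a, b):
        if np.array_equal(np.sort(a), np.sort(b)) and np.unique(a).size == 1:
            return 1.0
        return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)

    p_auroc, p_aupr = pval(t_auroc, n_auroc), pval(t_aupr, n_aupr)
    beats_null = (
        p_auroc < alpha
        and p_aupr < alpha
        and np.median(t_auroc) > np.median(n_auroc)
        and np.median(t_aupr) > np.median(n_aupr)
    )
    robust = (
        float(np.mean(t_auroc)) >= auroc_min
        and float(np.mean([r.relative_aupr for r in true_metrics])) >= rel_aupr_min
    )
    return p_auroc, p_aupr, bool(beats_null and robust)


def transfer_verdict(
    report: TransferReport,
    alpha: float = 0.05,
    auroc_min: float = DEFAULT_AUROC_MIN,
    rel_aupr_min: float = DEFAULT_REL_AUPR_MIN,
) -> bool:
    """Re-derive the preservation verdict of a report at given thresholds."""
    _, _, preserved = _transfer_decision(
        report.true_metrics, report.null_metrics, alpha, auroc_min, rel_aupr_min
    )
    return preserved


class TransferStudy:
    """Score trained and null models on an external cohort and decide
    whether the tissue signature is preserved there."""

    def __init__(
        self,
        trained: SignatureResults,
        null: SignatureResults,
        external_counts: CountMatrix,
        external_meta: SampleMetadata,
        feature_universe=None,
        alpha: float = 0.05,
        auroc_min: float = DEFAULT_AUROC_MIN,
        rel_aupr_min: float = DEFAULT_REL_AUPR_MIN,
        quantile: float = DEFAULT_QUANTILE,
        scale_constant: float = DEFAULT_SCALE,
    ):
        if trained.tissue != null.tissue:
            raise ValueError("true and null results must target the same tissue")
        self.trained = trained
        self.null = null
        self.external_counts = external_counts
        self.external_meta = external_meta
        self.feature_universe = feature_universe
        self.alpha = alpha
        self.auroc_min = auroc_min
        self.rel_aupr_min = rel_aupr_min
        self.quantile = quantile
        self.scale_constant = scale_constant

    def fit(self) -> TransferReport:
        kwargs = dict(
            feature_universe=self.feature_universe,
            quantile=self.quantile,
            scale_constant=self.scale_constant,
        )
        true_metrics = transfer_test(
            self.trained, self.external_counts, self.external_meta, **kwargs
        )
        null_metrics = transfer_test(
            self.null, self.external_counts, self.external_meta, **kwargs
        )
        p_auroc, p_aupr, preserved = _transfer_decision(
            true_metrics, null_metrics, self.alpha, self.auroc_min, self.rel_aupr_min
        )
        return TransferReport(
            tissue=self.trained.tissue,
            true_metrics=true_metrics,
            null_metrics=null_metrics,
            p_auroc=p_auroc,
            p_aupr=p_aupr,
            preserved=preserved,
        )
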