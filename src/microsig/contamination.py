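"""In-silico contamination resilience testing.

Twelve pseudo-contaminant features are injected into CSS-normalized
profiles — two volume categories crossed with the three pipeline routes
real contamination can enter through (collection site, DNA/RNA isolation
batch, sequencing batch). High-volume contaminants hit a small fraction of
samples hard, within a single linkage unit; low-volume contaminants touch
a broad sample set weakly, across units. Contaminated and uncontaminated
model iterations run on paired split seeds, and a tissue's signature is
called contamination-driven when the contaminated arm performs
significantly better (rank-sum on AUROC and AUPR, contaminated medians
higher) AND contaminants carry real importance (total share >= 5% or any
contaminant inside the top-10 mean importances); otherwise resilient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import CountMatrix, NormalizedMatrix, SampleMetadata
from .models import (
    MetricsRecord,
    ModelSpec,
    derive_seed,
    evaluate,
    stratified_split,
    train_boosted_model,
    upsample_minority,
)
from .normalize import DEFAULT_QUANTILE, DEFAULT_SCALE, css_normalize
from .io import align_features

ROUTES = ("collection_site", "isolation_batch", "sequencing_batch")

# Fig-2-style defaults: the schematic fixes the structure (two volume
# categories x three routes, six contaminants per category) but not the
# numbers; these magnitudes/fractions make high-volume contaminants
# dominate a few samples and low-volume ones broad but weak.
HIGH_VOLUME = {"affected_fraction": 0.05, "magnitude_quantile": 0.95, "linkage": "within_one_unit"}
LOW_VOLUME = {"affected_fraction": 0.40, "magnitude_quantile": 0.25, "linkage": "across_units"}


@dataclass(frozen=True)
class ContaminantSpec:
    """One pseudo-contaminant: volume category, entry route, how many
    samples it touches, how strong it is (as a quantile of the nonzero
    normalized-abundance distribution) and its sample-linkage rule."""

    id: str
    category: str  # high_volume | low_volume
    route: str  # one of ROUTES
    affected_fraction: float
    magnitude_quantile: float
    linkage: str  # within_one_unit | across_units
    magnitude_scale: float = 1.0  # 0 gives a null injection (all-zero rows)
    unit: str | None = None  # pin a within_one_unit contaminant to this unit

    def __post_init__(self):
        if self.category not in ("high_volume", "low_volume"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if not 0 < self.affected_fraction <= 1:
            raise ValueError("affected_fraction must lie in (0, 1]")
        if not 0 < self.magnitude_quantile <= 1:
            raise ValueError("magnitude_quantile must lie in (0, 1]")
        if self.linkage not in ("within_one_unit", "across_units"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


@dataclass(frozen=True)
class ContaminationScenario:
    contaminants: tuple[ContaminantSpec, ...]
    seed: int = 0

    def __post_init__(self):
        ids = [c.id for c in self.contaminants]
        if len(set(ids)) != len(ids):
            raise ValueError("contaminant ids must be unique")

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.contaminants]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "contaminants": [vars(c) for c in self.contaminants],
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def build_default_scenario(meta: SampleMetadata, seed: int = 0) -> ContaminationScenario:
    """The default 12-contaminant scenario: per route, two high-volume and
    two low-volume contaminants (six of each category overall)."""
    missing = [r for r in ROUTES if r not in meta.table.columns]
    if missing:
        raise ValueError(f"metadata lacks linkage columns required by the scenario: {missing}")
    specs = []
    for route in ROUTES:
        for category, params in (("high_volume", HIGH_VOLUME), ("low_volume", LOW_VOLUME)):
            for copy in (1, 2):
                specs.append(
                    ContaminantSpec(
                        id=f"contam_{category}_{route}_{copy}",
                        category=category,
                        route=route,
                        **params,
                    )
                )
    return ContaminationScenario(contaminants=tuple(specs), seed=seed)


def inject(
    nm: NormalizedMatrix,
    scenario: ContaminationScenario,
    meta: SampleMetadata,
    iteration_seed: int,
) -> NormalizedMatrix:
    """Append the scenario's contaminant rows to a normalized matrix.

    The affected sample set is redrawn per iteration: within-one-unit
    contaminants pick a random linkage unit and contaminate samples inside
    it, across-units contaminants draw from the whole cohort. Affected
    cells are set to the contaminant's magnitude (its quantile of the
    pooled nonzero normalized values); everything biological is left
    bitwise untouched.
    """
    clash = set(scenario.ids) & set(nm.features)
    if clash:
        raise ValueError(f"contaminant ids collide with biological features: {sorted(clash)}")
    meta_sub = meta.table.set_index("sample_id").loc[nm.samples]
    rng = np.random.default_rng(derive_seed(scenario.seed, iteration_seed))
    nonzero = nm.values[nm.values > 0]
    n = nm.n_samples
    rows = np.zeros((len(scenario.contaminants), n))
    for k, spec in enumerate(scenario.contaminants):
        magnitude = float(np.quantile(nonzero, spec.magnitude_quantile)) if nonzero.size else 1.0
        magnitude *= spec.magnitude_scale
        n_affected = max(1, int(round(spec.affected_fraction * n)))
        if spec.linkage == "within_one_unit":
            unit = spec.unit if spec.unit is not None else rng.choice(meta_sub[spec.route].unique())
            candidates = np.flatnonzero((meta_sub[spec.route] == unit).to_numpy())
            if candidates.size == 0:
                raise ValueError(f"linkage unit {unit!r} has no samples in this matrix")
        else:
            candidates = np.arange(n)
        take = min(n_affected, candidates.size)
        affected = rng.choice(candidates, size=take, replace=False)
        rows[k, affected] = magnitude
    return NormalizedMatrix(
        features=list(nm.features) + scenario.ids,
        samples=list(nm.samples),
        values=np.vstack([nm.values, rows]),
        scaling_factors=nm.scaling_factors,
        quantile_used=nm.quantile_used,
        scale_constant=nm.scale_constant,
        log_transformed=nm.log_transformed,
    )


@dataclass(frozen=True)
class ResilienceReport:
    """Verdict on whether a tissue's signature survives contamination."""

    tissue: str
    p_auroc: float
    p_aupr: float
    direction: int  # sign of median AUROC difference (contaminated - clean)
    contaminant_importance_share_total: float
    top_rank_of_any_contaminant: int
    verdict: str  # resilient | contamination_driven

    def to_dict(self) -> dict:
        return vars(self).copy()


def compare_and_verdict(
    contaminated: list[MetricsRecord],
    uncontaminated: list[MetricsRecord],
    contaminant_share_total: float,
    top_rank_of_any_contaminant: int,
    tissue: str = "",
    alpha: float = 0.05,
    share_threshold: float = 0.05,
    top_k: int = 10,
) -> ResilienceReport:
    """Two-sided rank-sum comparison of the two iteration streams plus the
    importance criterion; at least 10 iterations per arm required."""
    if len(contaminated) < 10 or len(uncontaminated) < 10:
        raise ValueError("need at least 10 iterations in each arm")
    c_auroc = np.array([r.auroc for r in contaminated])
    u_auroc = np.array([r.auroc for r in uncontaminated])
    c_aupr = np.array([r.aupr for r in contaminated])
    u_aupr = np.array([r.aupr for r in uncontaminated])

    def pval(a, b):
        if np.array_equal(np.sort(a), np.sort(b)) and np.unique(a).size == 1:
            return 1.0  # identical constant streams: no evidence either way
        return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)

    p_auroc = pval(c_auroc, u_auroc)
    p_aupr = pval(c_aupr, u_aupr)
    d_auroc = float(np.median(c_auroc) - np.median(u_auroc))
    d_aupr = float(np.median(c_aupr) - np.median(u_aupr))
    significant_gain = (
        p_auroc < alpha and p_aupr < alpha and d_auroc > 0 and d_aupr > 0
    )
    important = (
        contaminant_share_total >= share_threshold
        or top_rank_of_any_contaminant <= top_k
    )
    return ResilienceReport(
        tissue=tissue,
        p_auroc=p_auroc,
        p_aupr=p_aupr,
        direction=int(np.sign(d_auroc)),
        contaminant_importance_share_total=float(contaminant_share_total),
        top_rank_of_any_contaminant=int(top_rank_of_any_contaminant),
        verdict="contamination_driven" if (significant_gain and important) else "resilient",
    )


@dataclass
class TissueContaminationResult:
    tissue: str
    contaminated: list[MetricsRecord]
    uncontaminated: list[MetricsRecord]
    contaminant_share_total: float  # mean over contaminated iterations
    top_rank_of_any_contaminant: int  # in mean importances, 1-based
    report: ResilienceReport


@dataclass
class ResilienceResults:
    """Per-tissue paired contaminated/uncontaminated experiment results."""

    per_tissue: dict[str, TissueContaminationResult]
    scenario: ContaminationScenario
    spec: ModelSpec

    def verdicts(self) -> dict[str, str]:
        return {t: r.report.verdict for t, r in self.per_tissue.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, r in self.per_tissue.items():
            rows.append(
                {
                    "tissue": t,
                    "mean_auroc_contaminated": float(np.mean([m.auroc for m in r.contaminated])),
                    "mean_auroc_uncontaminated": float(np.mean([m.auroc for m in r.uncontaminated])),
                    "p_auroc": r.report.p_auroc,
                    "p_aupr": r.report.p_aupr,
                    "contaminant_share": r.report.contaminant_importance_share_total,
                    "top_contaminant_rank": r.report.top_rank_of_any_contaminant,
                    "verdict": r.report.verdict,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.to_frame()
        lines = ["Contamination resilience study", "-" * 32]
        for _, row in frame.iterrows():
            lines.append(
                f"  {row['tissue']:<12s} AUROC {row['mean_auroc_contaminated']:.3f} (contam.) "
                f"vs {row['mean_auroc_uncontaminated']:.3f} (clean), "
                f"p={row['p_auroc']:.3g}, share={row['contaminant_share']:.3f} "
                f"-> {row['verdict']}"
            )
        return "\n".join(lines)


class ContaminationStudy:
    """Paired contaminated / uncontaminated signature experiments.

    Both arms of each iteration share the same split seed and training
    seed, so the only difference is the presence of the injected
    contaminant features (added after per-split CSS normalization).
    """

    def __init__(
        self,
        counts: CountMatrix,
        metadata: SampleMetadata,
        tissues,
        feature_universe,
        scenario: ContaminationScenario,
        spec: ModelSpec | None = None,
        quantile: float = DEFAULT_QUANTILE,
        scale_constant: float = DEFAULT_SCALE,
        alpha: float = 0.05,
        share_threshold: float = 0.05,
        top_k: int = 10,
    ):
        if len(list(tissues)) < 1:
            raise ValueError("need at least one target tissue")
        if len(set(metadata.tissues)) < 2:
            raise ValueError("need at least two tissues in the cohort")
        self.counts = counts
        self.metadata = metadata
        self.tissues = list(tissues)
        self.feature_universe = [str(f) for f in feature_universe]
        self.scenario = scenario
        self.spec = spec or ModelSpec()
        self.quantile = quantile
        self.scale_constant = scale_constant
        self.alpha = alpha
        self.share_threshold = share_threshold
        self.top_k = top_k

    def _normalize_split(self, idx):
        sub = CountMatrix(
            features=list(self.counts.features),
            samples=[self.counts.samples[i] for i in idx],
            counts=self.counts.counts[:, idx],
        )
        return css_normalize(sub, quantile=self.quantile, scale_constant=self.scale_constant)

    def _run_tissue(self, tissue: str) -> TissueContaminationResult:
        labels = (self.metadata.tissue_labels() == tissue).astype(int)
        contaminated_universe = self.feature_universe + self.scenario.ids
        n_contam = len(self.scenario.ids)
        contaminated, clean = [], []
        share_totals = []
        importance_sum = np.zeros(len(contaminated_universe))
        for i in range(self.spec.iterations):
            seed = derive_seed(self.spec.master_seed, i)
            train_idx, test_idx = stratified_split(labels, self.spec.train_fraction, seed)
            nm_train = self._normalize_split(train_idx)
            nm_test = self._normalize_split(test_idx)
            y_train, y_test = labels[train_idx], labels[test_idx]
            local = (
                upsample_minority(np.arange(train_idx.size), y_train, seed)
                if self.spec.upsample
                else np.arange(train_idx.size)
            )

            # both arms share the contaminated universe: in the clean arm the
            # contaminant columns are zero-filled, so the learner sees the same
            # feature dimensionality and the arms are exactly paired
            for arm, inject_it in (("clean", False), ("contaminated", True)):
                if inject_it:
                    tr = inject(nm_train, self.scenario, self.metadata, iteration_seed=2 * seed)
                    te = inject(nm_test, self.scenario, self.metadata, iteration_seed=2 * seed + 1)
                else:
                    tr, te = nm_train, nm_test
                X_train = align_features(tr, contaminated_universe)[0].values.T
                X_test = align_features(te, contaminated_universe)[0].values.T
                fitted = train_boosted_model(
                    X_train[local], y_train[local], self.spec, seed
                )
                record = evaluate(fitted, X_test, y_test)
                if inject_it:
                    contaminated.append(record)
                    shares = fitted.importance_shares()
                    share_totals.append(float(shares[-n_contam:].sum()))
                    importance_sum += shares
                else:
                    clean.append(record)
        mean_importance = importance_sum / self.spec.iterations
        order = np.argsort(mean_importance)[::-1]
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, order.size + 1)
        top_rank = int(ranks[-n_contam:].min())
        share_total = float(np.mean(share_totals))
        report = compare_and_verdict(
            contaminated,
            clean,
            share_total,
            top_rank,
            tissue=tissue,
            alpha=self.alpha,
            share_threshold=self.share_threshold,
            top_k=self.top_k,
        )
        return TissueContaminationResult(
            tissue=tissue,
            contaminated=contaminated,
            uncontaminated=clean,
            contaminant_share_total=share_total,
            top_rank_of_any_contaminant=top_rank,
            report=report,
        )

    def fit(self) -> ResilienceResults:
        return ResilienceResults(
            per_tissue={t: self._run_tissue(t) for t in self.tissues},
            scenario=self.scenario,
            spec=self.spec,
        )


def run_contamination_experiment(
    counts,
    metadata,
    tissues,
    feature_universe,
    scenario,
    spec=None,
    **kwargs,
) -> ResilienceResults:
    """Functional wrapper around :class:`ContaminationStudy`."""
    return ContaminationStudy(
        counts, metadata, tissues, feature_universe, scenario, spec, **kwargs
    ).fit()
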