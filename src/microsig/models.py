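"""Iterated one-vs-rest gradient-boosted classification of tissues from
microbial profiles.

The workflow per iteration: stratified 70/30 split -> CSS normalization
fit separately within each split (no leakage of scaling factors) ->
restriction to the core-union feature universe -> minority up-sampling ->
grid search over interaction depth {1,2,3} x trees {50,100,150} by k-fold
cross-validated AUROC at learning rate 0.1 and minimum 3 observations per
node -> evaluation on the untouched test split. Iterating the whole
procedure I times (default 100) yields mean AUROC / AUPR / relative AUPR
with normal-approximation 95% confidence margins.

Relative AUPR divides AUPR by the random-classifier baseline — the
positive-class prevalence of the evaluated set — so 1 is chance level. A
tissue is called signature-positive when mean AUROC >= 0.70 and mean
relative AUPR >= 1.4 (both inclusive).

The learner is scikit-learn's stochastic gradient boosting (subsample
0.5), with ``max_depth`` playing the interaction-depth role and
``min_samples_leaf`` the minimum node size; any gradient-boosted tree
learner with these hyperparameter semantics would do, and feature
importance is the learner's native total split-gain attribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.metrics import (
    average_precision_score,
    mean_absolute_error,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import CountMatrix, SampleMetadata
from .io import align_features
from .normalize import DEFAULT_QUANTILE, DEFAULT_SCALE, css_normalize

DEFAULT_AUROC_MIN = 0.70
DEFAULT_REL_AUPR_MIN = 1.4
_SEED_MOD = 2**31 - 1


def derive_seed(master_seed: int, iteration: int) -> int:
    """Per-iteration seed: master seed plus the iteration index."""
    return int(master_seed + iteration) % _SEED_MOD


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters and iteration protocol of the boosted models.

    Defaults follow the tissue-model protocol: learning rate 0.1, grid over
    interaction depth 1-3 and 50-150 trees, minimum 3 observations per
    node, 2-fold cross-validation, 70/30 stratified split with minority
    up-sampling, 100 iterations. Trait models override ``cv_folds`` (4 for
    categorical, 5 for continuous).
    """

    learning_rate: float = 0.1
    interaction_depth_grid: tuple[int, ...] = (1, 2, 3)
    n_trees_grid: tuple[int, ...] = (50, 100, 150)
    min_node_obs: int = 3
    cv_folds: int = 2
    train_fraction: float = 0.7
    upsample: bool = True
    upsample_within_folds: bool = False
    subsample: float = 0.5
    iterations: int = 100
    master_seed: int = 0

    def __post_init__(self):
        if not self.interaction_depth_grid or not self.n_trees_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class MetricsRecord:
    """AUROC, AUPR and AUPR relative to the random baseline for one
    evaluated model; ``aupr_random`` is the positive-class prevalence."""

    auroc: float
    aupr: float
    aupr_random: float

    @property
    def relative_aupr(self) -> float:
        return self.aupr / self.aupr_random

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "aupr_random": self.aupr_random,
            "relative_aupr": self.relative_aupr,
        }


def stratified_split(labels, train_fraction: float = 0.7, seed: int = 0):
    """Per-class random allocation into train/test index arrays.

    Each class contributes round(n_class * fraction) samples to train and
    the remainder to test; the two sets partition the samples and the draw
    is deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for value in pd.unique(labels):
        idx = np.flatnonzero(labels == value)
        if idx.size < 2:
            raise ValueError(f"class {value!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_train = int(round(idx.size * train_fraction))
        n_train = min(max(n_train, 1), idx.size - 1)  # both splits non-empty
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def upsample_minority(train_idx, labels, seed: int = 0) -> np.ndarray:
    """Resample the minority class with replacement until class counts are
    equal; every original index is kept and the majority is untouched."""
    train_idx = np.asarray(train_idx)
    labels = np.asarray(labels)
    y = labels[train_idx]
    values, counts = np.unique(y, return_counts=True)
    if values.size < 2:
        raise ValueError("up-sampling needs two classes in the training set")
    if counts.min() == counts.max():
        return train_idx
    minority = values[np.argmin(counts)]
    minority_idx = train_idx[y == minority]
    extra = np.random.default_rng(seed).choice(
        minority_idx, size=int(counts.max() - counts.min()), replace=True
    )
    return np.concatenate([train_idx, extra])


@dataclass
class FittedModel:
    """A refit grid-search winner with its CV trace and raw importances."""

    estimator: object
    best_depth: int
    best_trees: int
    cv_table: pd.DataFrame
    importances: np.ndarray
    task: str = "classification"

    def scores(self, X) -> np.ndarray:
        if self.task == "classification":
            return self.estimator.predict_proba(X)[:, 1]
        return self.estimator.predict(X)

    def importance_shares(self) -> np.ndarray:
        total = self.importances.sum()
        if total <= 0:
            # a model that never split attributes nothing; spread uniformly
            return np.full_like(self.importances, 1.0 / self.importances.size)
        return self.importances / total


def _make_estimator(spec: ModelSpec, depth: int, trees: int, seed: int, task: str):
    cls = GradientBoostingClassifier if task == "classification" else GradientBoostingRegressor
    return cls(
        learning_rate=spec.learning_rate,
        n_estimators=trees,
        max_depth=depth,
        min_samples_leaf=spec.min_node_obs,
        subsample=spec.subsample,
        random_state=seed,
    )


def _staged_cv_scores(X, y, spec: ModelSpec, depth: int, seed: int, task: str):
    """Mean CV score for every tree count in the grid, from a single fit
    per fold at the largest tree count (tree prefixes coincide because the
    boosting RNG stream is identical)."""
    stage_grid = sorted(set(spec.n_trees_grid))
    max_trees = stage_grid[-1]
    if task == "classification":
        folds = StratifiedKFold(spec.cv_folds, shuffle=True, random_state=seed)
    else:
        folds = KFold(spec.cv_folds, shuffle=True, random_state=seed)
    scores = {t: [] for t in stage_grid}
    for tr, va in folds.split(X, y if task == "classification" else None):
        est = _make_estimator(spec, depth, max_trees, seed, task)
        if task == "classification" and np.unique(y[tr]).size < 2:
            raise ValueError("a CV fold lost one class; use more samples or fewer folds")
        est.fit(X[tr], y[tr])
        staged = (
            est.staged_decision_function(X[va])
            if task == "classification"
            else est.staged_predict(X[va])
        )
        wanted = set(stage_grid)
        for stage, pred in enumerate(staged, start=1):
            if stage in wanted:
                pred = np.ravel(pred)
                if task == "classification":
                    scores[stage].append(roc_auc_score(y[va], pred))
                else:
                    scores[stage].append(-np.sqrt(mean_squared_error(y[va], pred)))
    return {t: float(np.mean(v)) for t, v in scores.items()}


def train_boosted_model(
    X, y, spec: ModelSpec, seed: int = 0, task: str = "classification"
) -> FittedModel:
    """Grid-search (depth x trees) by cross-validation and refit the winner.

    Selection metric is AUROC for classification and RMSE (smallest) for
    regression; ties prefer the simpler model (smallest depth, then fewest
    trees). Returns the refit estimator with native split-gain feature
    importances.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("target is constant; nothing to learn")
    rows = []
    for depth in sorted(spec.interaction_depth_grid):
        by_trees = _staged_cv_scores(X, y, spec, depth, seed, task)
        for trees in sorted(spec.n_trees_grid):
            rows.append({"depth": depth, "trees": trees, "cv_score": by_trees[trees]})
    cv_table = pd.DataFrame(rows)
    best = None
    for row in rows:  # grid iterated simplest-first: strict > keeps the tie-break
        if best is None or row["cv_score"] > best["cv_score"]:
            best = row
    estimator = _make_estimator(spec, best["depth"], best["trees"], seed, task)
    estimator.fit(X, y)
    return FittedModel(
        estimator=estimator,
        best_depth=int(best["depth"]),
        best_trees=int(best["trees"]),
        cv_table=cv_table,
        importances=np.asarray(estimator.feature_importances_, dtype=float),
        task=task,
    )


def evaluate(model, X_test, y_test) -> MetricsRecord:
    """Test-set AUROC (rank statistic, ties averaged), AUPR (step-wise
    precision-recall integration) and relative AUPR."""
    y_test = np.asarray(y_test)
    if np.unique(y_test).size < 2:
        raise ValueError("test set contains a single class")
    scores = model.scores(np.asarray(X_test, dtype=float)) if hasattr(model, "scores") else model
    prevalence = float(np.mean(y_test))
    return MetricsRecord(
        auroc=float(roc_auc_score(y_test, scores)),
        aupr=float(average_precision_score(y_test, scores)),
        aupr_random=prevalence,
    )


def ci_margin(values, z: float = 1.96) -> float:
    """Normal-approximation 95% CI half-width, z * sd / sqrt(I)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(z * values.std(ddof=1) / np.sqrt(values.size))


def signature_verdict(
    result,
    auroc_min: float = DEFAULT_AUROC_MIN,
    rel_aupr_min: float = DEFAULT_REL_AUPR_MIN,
) -> bool:
    """True iff mean AUROC and mean relative AUPR clear the detection
    thresholds (0.70 and 1.4), both boundaries inclusive."""
    return bool(
        result.mean_auroc >= auroc_min and result.mean_relative_aupr >= rel_aupr_min
    )


def rank_correlation(sample_sizes, performances):
    """Spearman rank correlation (rho, two-sided p) between per-tissue
    sample size and mean performance; NaN with a warning on constant
    input."""
    x = np.asarray(sample_sizes, dtype=float)
    y = np.asarray(performances, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 tissues")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("rank correlation undefined for constant input", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class IterationModel:
    """One stored iteration: the fitted model plus everything needed to
    score external data the same way."""

    seed: int
    fitted: FittedModel
    feature_universe: list[str]


@dataclass
class SignatureResults:
    """Results of an iterated one-vs-rest signature experiment."""

    tissue: str
    records: list[MetricsRecord]
    iteration_seeds: list[int]
    importance_shares: pd.Series  # first iteration, summing to 1
    mean_importance_shares: pd.Series  # averaged over iterations
    selected_hyperparameters: list[tuple[int, int]]
    spec: ModelSpec
    models: list[IterationModel] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    @property
    def mean_auroc(self) -> float:
        return float(np.mean([r.auroc for r in self.records]))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean([r.aupr for r in self.records]))

    @property
    def mean_relative_aupr(self) -> float:
        return float(np.mean([r.relative_aupr for r in self.records]))

    def ci_margins(self) -> dict[str, float]:
        return {
            "auroc": ci_margin([r.auroc for r in self.records]),
            "aupr": ci_margin([r.aupr for r in self.records]),
            "relative_aupr": ci_margin([r.relative_aupr for r in self.records]),
        }

    def verdict(
        self,
        auroc_min: float = DEFAULT_AUROC_MIN,
        rel_aupr_min: float = DEFAULT_REL_AUPR_MIN,
    ) -> bool:
        return signature_verdict(self, auroc_min, rel_aupr_min)

    def to_dict(self) -> dict:
        ci = self.ci_margins()
        return {
            "tissue": self.tissue,
            "n_iterations": self.n_iterations,
            "mean_auroc": self.mean_auroc,
            "mean_aupr": self.mean_aupr,
            "mean_relative_aupr": self.mean_relative_aupr,
            "ci_margin": ci,
            "verdict": self.verdict(),
            "iteration_seeds": self.iteration_seeds,
            "selected_hyperparameters": [
                {"interaction_depth": d, "n_trees": t}
                for d, t in self.selected_hyperparameters
            ],
            "iterations": [r.to_dict() for r in self.records],
            "importance_shares_first_iteration": self.importance_shares.sort_values(
                ascending=False
            ).head(50).to_dict(),
        }

    def summary(self) -> str:
        ci = self.ci_margins()
        top = self.importance_shares.sort_values(ascending=False).head(5)
        lines = [
            f"Tissue signature model: {self.tissue} (1 vs rest)",
            f"  iterations            {self.n_iterations}",
            f"  mean AUROC            {self.mean_auroc:.3f} +/- {ci['auroc']:.4f}",
            f"  mean AUPR             {self.mean_aupr:.3f} +/- {ci['aupr']:.4f}",
            f"  mean relative AUPR    {self.mean_relative_aupr:.3f} +/- {ci['relative_aupr']:.4f}",
            f"  signature verdict     {'POSITIVE' if self.verdict() else 'negative'}"
            f" (AUROC >= {DEFAULT_AUROC_MIN}, rel. AUPR >= {DEFAULT_REL_AUPR_MIN})",
            "  top features (first-iteration importance share):",
        ]
        lines += [f"    {name:<24s} {share:.3f}" for name, share in top.items()]
        return "\n".join(lines)


def _split_normalize(
    counts: CountMatrix,
    feature_universe: list[str],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    quantile: float,
    scale_constant: float,
):
    """CSS-normalize train and test columns independently, then restrict
    both to the feature universe. Factors never cross the split."""
    samples = counts.samples

    def one(idx):
        sub = CountMatrix(
            features=list(counts.features),
            samples=[samples[i] for i in idx],
            counts=counts.counts[:, idx],
            taxonomy=counts.taxonomy,
        )
        nm = css_normalize(sub, quantile=quantile, scale_constant=scale_constant)
        aligned, _ = align_features(nm, feature_universe)
        return aligned.values.T  # samples x features

    return one(train_idx), one(test_idx)


class TissueSignatureModel:
    """One-vs-rest boosted-tree model of a single tissue, iterated.

    Parameters
    ----------
    counts : CountMatrix
        Raw counts; normalization happens inside each iteration, per split.
    metadata : SampleMetadata
        Must be column-aligned with ``counts``.
    target_tissue : str
        The positive class; every other tissue in the cohort is the rest.
    feature_universe : list of str
        Typically the union of per-tissue core microbiomes.
    spec : ModelSpec
    store_models : bool
        Keep each iteration's fitted model for later external scoring.
    """

    def __init__(
        self,
        counts: CountMatrix,
        metadata: SampleMetadata,
        target_tissue: str,
        feature_universe,
        spec: ModelSpec | None = None,
        quantile: float = DEFAULT_QUANTILE,
        scale_constant: float = DEFAULT_SCALE,
        store_models: bool = False,
        label_permutation_seed: int | None = None,
    ):
        if not metadata.aligned_with(counts):
            raise ValueError("metadata rows must align with count matrix columns")
        if target_tissue not in metadata.tissues:
            raise ValueError(f"unknown tissue {target_tissue!r}")
        self.counts = counts
        self.metadata = metadata
        self.target_tissue = target_tissue
        self.feature_universe = [str(f) for f in feature_universe]
        self.spec = spec or ModelSpec()
        self.quantile = quantile
        self.scale_constant = scale_constant
        self.store_models = store_models
        self.label_permutation_seed = label_permutation_seed

    def _labels(self, iteration_seed: int) -> np.ndarray:
        tissues = self.metadata.tissue_labels()
        if self.label_permutation_seed is not None:
            perm = np.random.default_rng(
                derive_seed(self.label_permutation_seed, iteration_seed)
            ).permutation(tissues.size)
            tissues = tissues[perm]
        return (tissues == self.target_tissue).astype(int)

    def fit_iteration(self, iteration: int):
        """Run a single split/normalize/train/evaluate iteration."""
        seed = derive_seed(self.spec.master_seed, iteration)
        y_all = self._labels(seed)
        train_idx, test_idx = stratified_split(y_all, self.spec.train_fraction, seed)
        X_train, X_test = _split_normalize(
            self.counts,
            self.feature_universe,
            train_idx,
            test_idx,
            self.quantile,
            self.scale_constant,
        )
        y_train, y_test = y_all[train_idx], y_all[test_idx]
        if self.spec.upsample and not self.spec.upsample_within_folds:
            local = upsample_minority(np.arange(train_idx.size), y_train, seed)
            X_fit, y_fit = X_train[local], y_train[local]
        else:
            X_fit, y_fit = X_train, y_train
        fitted = train_boosted_model(X_fit, y_fit, self.spec, seed)
        record = evaluate(fitted, X_test, y_test)
        return seed, fitted, record

    def fit(self) -> SignatureResults:
        records, seeds, selected, models = [], [], [], []
        share_sum = None
        first_shares = None
        for i in range(self.spec.iterations):
            seed, fitted, record = self.fit_iteration(i)
            shares = fitted.importance_shares()
            if first_shares is None:
                first_shares = shares
            share_sum = shares if share_sum is None else share_sum + shares
            records.append(record)
            seeds.append(seed)
            selected.append((fitted.best_depth, fitted.best_trees))
            if self.store_models:
                models.append(
                    IterationModel(seed=seed, fitted=fitted, feature_universe=self.feature_universe)
                )
        return SignatureResults(
            tissue=self.target_tissue,
            records=records,
            iteration_seeds=seeds,
            importance_shares=pd.Series(first_shares, index=self.feature_universe),
            mean_importance_shares=pd.Series(
                share_sum / len(records), index=self.feature_universe
            ),
            selected_hyperparameters=selected,
            spec=self.spec,
            models=models,
        )


def run_signature_experiment(
    counts: CountMatrix,
    metadata: SampleMetadata,
    target_tissue: str,
    feature_universe,
    spec: ModelSpec | None = None,
    **kwargs,
) -> SignatureResults:
    """Functional wrapper around :class:`TissueSignatureModel`."""
    return TissueSignatureModel(
        counts, metadata, target_tissue, feature_universe, spec, **kwargs
    ).fit()


# ---------------------------------------------------------------------------
# trait / disease models
# ---------------------------------------------------------------------------

MIN_GROUP_SIZE = 20


@dataclass
class TraitResults:
    """Outcome of an iterated trait model within one tissue; ``skipped``
    carries the insufficient-samples record when no model was trained."""

    tissue: str
    trait: str
    kind: str  # "continuous" | "categorical"
    skipped: bool
    reason: str | None = None
    records: list[dict] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(np.mean([r[metric] for r in self.records]))

    def to_dict(self) -> dict:
        out = {
            "tissue": self.tissue,
            "trait": self.trait,
            "kind": self.kind,
            "skipped": self.skipped,
            "reason": self.reason,
        }
        if self.records:
            for metric in self.records[0]:
                out[f"mean_{metric}"] = self.mean(metric)
            out["n_iterations"] = len(self.records)
        return out

    def summary(self) -> str:
        if self.skipped:
            return f"{self.tissue}/{self.trait}: skipped ({self.reason})"
        means = ", ".join(
            f"{k}={v:.3f}" for k, v in self.to_dict().items() if k.startswith("mean_")
        )
        return f"{self.tissue}/{self.trait} [{self.kind}]: {means}"


def _trait_kind(values: pd.Series) -> str:
    if pd.api.types.is_bool_dtype(values):
        return "categorical"
    if pd.api.types.is_numeric_dtype(values) and values.nunique() > 10:
        return "continuous"
    return "categorical"


class TraitModel:
    """Predict a trait from microbial profiles within one tissue.

    Continuous traits use boosted regression with 5-fold CV (RMSE
    selection) and report RMSE / MAE / R squared on the test split;
    categorical traits use the tissue-model protocol at 4-fold CV and
    report AUROC / AUPR. Any trait group smaller than 20 samples skips the
    combination with an explicit insufficient-samples record; multi-level
    categorical traits (e.g. ancestry) are restricted to their two largest
    groups first.
    """

    def __init__(
        self,
        counts: CountMatrix,
        metadata: SampleMetadata,
        tissue: str,
        trait: str,
        spec: ModelSpec | None = None,
        feature_universe=None,
        quantile: float = DEFAULT_QUANTILE,
        scale_constant: float = DEFAULT_SCALE,
        min_group_size: int = MIN_GROUP_SIZE,
    ):
        if trait not in metadata.table.columns:
            raise KeyError(f"unknown trait {trait!r}")
        if tissue not in metadata.tissues:
            raise ValueError(f"unknown tissue {tissue!r}")
        self.counts = counts
        self.metadata = metadata
        self.tissue = tissue
        self.trait = trait
        self.spec = spec or ModelSpec()
        self.feature_universe = (
            [str(f) for f in feature_universe] if feature_universe is not None else list(counts.features)
        )
        self.quantile = quantile
        self.scale_constant = scale_constant
        self.min_group_size = min_group_size

    def fit(self) -> TraitResults:
        mask = self.metadata.tissue_labels() == self.tissue
        cols = np.flatnonzero(mask)
        values = self.metadata.table.loc[cols, self.trait]
        kind = _trait_kind(values)
        sub_counts = CountMatrix(
            features=list(self.counts.features),
            samples=[self.counts.samples[i] for i in cols],
            counts=self.counts.counts[:, cols],
        )
        if kind == "continuous":
            return self._fit_continuous(sub_counts, values.to_numpy(dtype=float))
        return self._fit_categorical(sub_counts, values)

    def _skip(self, kind: str, reason: str) -> TraitResults:
        return TraitResults(self.tissue, self.trait, kind, skipped=True, reason=reason)

    def _iterate(self, sub_counts, y, task, spec, stratify):
        records = []
        for i in range(spec.iterations):
            seed = derive_seed(spec.master_seed, i)
            if stratify:
                train_idx, test_idx = stratified_split(y, spec.train_fraction, seed)
            else:
                order = np.random.default_rng(seed).permutation(y.size)
                n_train = int(round(y.size * spec.train_fraction))
                train_idx, test_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
            X_train, X_test = _split_normalize(
                sub_counts, self.feature_universe, train_idx, test_idx,
                self.quantile, self.scale_constant,
            )
            y_train, y_test = y[train_idx], y[test_idx]
            if task == "classification" and spec.upsample:
                local = upsample_minority(np.arange(train_idx.size), y_train, seed)
                X_train, y_train = X_train[local], y_train[local]
            fitted = train_boosted_model(X_train, y_train, spec, seed, task=task)
            if task == "classification":
                rec = evaluate(fitted, X_test, y_test).to_dict()
            else:
                pred = fitted.scores(X_test)
                rec = {
                    "rmse": float(np.sqrt(mean_squared_error(y_test, pred))),
                    "mae": float(mean_absolute_error(y_test, pred)),
                    "r2": float(r2_score(y_test, pred)),
                }
            records.append(rec)
        return records

    def _fit_continuous(self, sub_counts, y) -> TraitResults:
        if y.size < 2 * self.min_group_size:
            return self._skip(
                "continuous",
                f"insufficient samples ({y.size} < {2 * self.min_group_size})",
            )
        spec = replace(self.spec, cv_folds=max(self.spec.cv_folds, 5))
        records = self._iterate(sub_counts, y, "regression", spec, stratify=False)
        return TraitResults(self.tissue, self.trait, "continuous", False, records=records)

    def _fit_categorical(self, sub_counts, values: pd.Series) -> TraitResults:
        levels = values.astype(str).value_counts()
        if len(levels) < 2:
            return self._skip("categorical", "trait has a single level in this tissue")
        if len(levels) > 2:
            keep = levels.index[:2]  # two largest groups only
            mask = values.astype(str).isin(keep).to_numpy()
            values = values[mask]
            sub_counts = CountMatrix(
                features=list(sub_counts.features),
                samples=[s for s, m in zip(sub_counts.samples, mask) if m],
                counts=sub_counts.counts[:, mask],
            )
            levels = values.astype(str).value_counts()
        if levels.min() < self.min_group_size:
            return self._skip(
                "categorical",
                f"insufficient samples (smallest group {int(levels.min())} < {self.min_group_size})",
            )
        positive = levels.index[-1]  # minority level is the positive class
        y = (values.astype(str) == positive).to_numpy(dtype=int)
        spec = replace(self.spec, cv_folds=max(self.spec.cv_folds, 4))
        records = self._iterate(sub_counts, y, "classification", spec, stratify=True)
        return TraitResults(self.tissue, self.trait, "categorical", False, records=records)


def trait_experiment(
    counts: CountMatrix,
    metadata: SampleMetadata,
    tissue: str,
    trait: str,
    spec: ModelSpec | None = None,
    **kwargs,
) -> TraitResults:
    """Functional wrapper around :class:`TraitModel`."""
    return TraitModel(counts, metadata, tissue, trait, spec, **kwargs).fit()
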