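"""Core in-memory containers for taxon-by-sample profiles.

A :class:`CountMatrix` holds raw non-negative integer abundances
(features x samples); a :class:`NormalizedMatrix` holds the real-valued
profile after cumulative-sum-scaling together with the per-sample scaling
factors that produced it, so every normalized value is auditable.
:class:`SampleMetadata` wraps a pandas table keyed by sample id with the
tissue label, subject id and the three linkage units (collection site,
isolation batch, sequencing batch) that contamination scenarios act on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class TableFormatError(ValueError):
    """A tabular input violates the expected format (duplicate ids,
    negative or non-integer cells, ragged rows); carries a line number
    when one can be attributed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ConfigurationError(ValueError):
    """An invalid configuration value; names the offending field."""

    def __init__(self, field_name: str, message: str):
        super().__init__(f"{field_name}: {message}")
        self.field = field_name


REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "tissue",
    "collection_site",
    "isolation_batch",
    "sequencing_batch",
)


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate {what} identifiers: {dup[:5]}")


@dataclass
class CountMatrix:
    """Integer taxon-by-sample abundance table.

    Parameters
    ----------
    features : list of str
        Taxon identifiers (species or genus names), one per row.
    samples : list of str
        Sample identifiers, one per column.
    counts : ndarray of int, shape (n_features, n_samples)
        Non-negative read counts.
    taxonomy : dict, optional
        Species -> genus map for the features, if known.
    """

    features: list[str]
    samples: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self):
        self.features = list(map(str, self.features))
        self.samples = list(map(str, self.samples))
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.features), len(self.samples)):
            raise TableFormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise TableFormatError("counts must be integers")
        if counts.size and counts.min() < 0:
            raise TableFormatError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        _check_unique(self.features, "feature")
        _check_unique(self.samples, "sample")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_sums(self) -> np.ndarray:
        """Per-sample library size (total classified reads)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.features, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, taxonomy=None) -> "CountMatrix":
        return cls(
            features=list(frame.index),
            samples=list(frame.columns),
            counts=frame.to_numpy(),
            taxonomy=taxonomy,
        )

    def select_samples(self, sample_ids) -> "CountMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return CountMatrix(
            features=list(self.features),
            samples=list(sample_ids),
            counts=self.counts[:, idx],
            taxonomy=self.taxonomy,
        )


@dataclass
class NormalizedMatrix:
    """CSS-normalized real-valued profile with its normalization audit trail.

    Invariant: ``values[i, j] == raw_count[i, j] * scale_constant /
    scaling_factors[j]`` — zeros stay zeros, and any positive constant
    ``scale_constant`` only rescales all features uniformly.
    """

    features: list[str]
    samples: list[str]
    values: np.ndarray
    scaling_factors: np.ndarray
    quantile_used: float
    scale_constant: float = 1000.0
    log_transformed: bool = False

    def __post_init__(self):
        self.features = list(map(str, self.features))
        self.samples = list(map(str, self.samples))
        self.values = np.asarray(self.values, dtype=float)
        self.scaling_factors = np.asarray(self.scaling_factors, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise TableFormatError("normalized matrix shape mismatch")
        if self.scaling_factors.shape != (len(self.samples),):
            raise TableFormatError("one scaling factor per sample required")
        if np.any(self.scaling_factors <= 0):
            raise TableFormatError("scaling factors must be positive")
        if not (0 < self.quantile_used < 1):
            raise ConfigurationError("quantile_used", "must lie in (0, 1)")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.samples)


@dataclass
class SampleMetadata:
    """Per-sample annotations: tissue, subject and linkage units, plus any
    number of trait columns (age, BMI, sex, smoking, ...)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise TableFormatError(f"metadata missing required columns: {missing}")
        _check_unique(self.table["sample_id"], "sample")
        if (self.table["tissue"].astype(str).str.len() == 0).any():
            raise TableFormatError("empty tissue label")
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.table["sample_id"].astype(str).tolist()

    @property
    def tissues(self) -> list[str]:
        """Unique tissue labels in order of first appearance."""
        return list(dict.fromkeys(self.table["tissue"].astype(str)))

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in REQUIRED_METADATA_COLUMNS]

    def tissue_labels(self) -> np.ndarray:
        return self.table["tissue"].to_numpy(dtype=object)

    def column(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"unknown metadata column {name!r}")
        return self.table[name].to_numpy()

    def select_samples(self, sample_ids) -> "SampleMetadata":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleMetadata(sub)

    def aligned_with(self, matrix: CountMatrix) -> bool:
        return self.samples == matrix.samples
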