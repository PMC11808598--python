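"""Alpha-diversity metrics and core-microbiome construction.

The core microbiome of a tissue is the set of taxa present (nonzero raw
count) in at least a threshold fraction — 10% by default — of that
tissue's samples; the union of per-tissue cores is the feature universe
the classifiers see. Presence means raw count > 0, with no minimum-count
floor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .containers import CountMatrix, SampleMetadata

DEFAULT_PREVALENCE_THRESHOLD = 0.10


def richness(sample_counts) -> int:
    """Number of taxa with nonzero abundance in one sample."""
    return int(np.count_nonzero(np.asarray(sample_counts)))


def shannon(sample_counts) -> float:
    """Shannon diversity index H = -sum p_i ln p_i (natural log).

    Undefined for an all-zero profile: returns NaN with a warning.
    """
    x = np.asarray(sample_counts, dtype=float)
    if x.sum() <= 0:
        warnings.warn("Shannon index undefined for an all-zero sample", stacklevel=2)
        return float("nan")
    return float(entropy(x))


@dataclass(frozen=True)
class CoreSet:
    """The core microbiome of one tissue at a prevalence threshold."""

    tissue: str
    species: frozenset[str]
    prevalence: dict[str, float]
    threshold: float = DEFAULT_PREVALENCE_THRESHOLD

    def __len__(self) -> int:
        return len(self.species)

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "threshold": self.threshold,
            "species": sorted(self.species),
            "prevalence": {s: self.prevalence[s] for s in sorted(self.species)},
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def core_microbiome(
    matrix: CountMatrix,
    meta: SampleMetadata,
    tissue: str,
    threshold: float = DEFAULT_PREVALENCE_THRESHOLD,
) -> CoreSet:
    """Species present in at least ``threshold`` of the tissue's samples.

    The boundary is inclusive: with 20 samples and a 10% threshold, a
    species seen in exactly 2 samples is kept.
    """
    labels = meta.tissue_labels()
    cols = np.flatnonzero(labels == tissue)
    if cols.size == 0:
        raise ValueError(f"unknown tissue {tissue!r}")
    prevalence = (matrix.counts[:, cols] > 0).mean(axis=1)
    kept = {
        f: float(p)
        for f, p in zip(matrix.features, prevalence)
        if p >= threshold and p > 0
    }
    return CoreSet(
        tissue=tissue,
        species=frozenset(kept),
        prevalence=kept,
        threshold=threshold,
    )


def core_union_and_intersections(cores: list[CoreSet]):
    """Union of core sets plus exact exclusive-intersection sizes.

    The union (ordered by feature id) is the model feature universe. The
    intersection table follows UpSet semantics: each species is counted in
    exactly one class, defined by the full pattern of cores it belongs to.
    Returns ``(union_list, table)`` where the table is a DataFrame with a
    ``tissues`` tuple column and a ``size`` column, largest classes first.
    """
    if not cores:
        raise ValueError("need at least one core set")
    membership: dict[str, tuple[str, ...]] = {}
    for species in set().union(*(c.species for c in cores)):
        membership[species] = tuple(c.tissue for c in cores if species in c.species)
    union = sorted(membership)
    sizes: dict[tuple[str, ...], int] = {}
    for pattern in membership.values():
        sizes[pattern] = sizes.get(pattern, 0) + 1
    table = (
        pd.DataFrame(
            {"tissues": list(sizes), "size": list(sizes.values())}
        )
        .sort_values("size", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return union, table


def write_intersections(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["tissues"] = out["tissues"].map(lambda t: "&".join(t))
    out.to_csv(path, sep="\t", index=False)
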