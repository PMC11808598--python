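"""Reading, writing, aggregating and aligning taxonomic profile tables.

All on-disk formats are plain TSV: count tables carry the feature id in the
first column and sample ids in the header; taxonomy maps are two columns
(species, genus); normalized matrices travel with a JSON sidecar recording
the scaling factors, the quantile and the scale constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix, SampleMetadata, TableFormatError


def read_count_table(path) -> CountMatrix:
    """Read a taxon-by-sample TSV into a :class:`CountMatrix`.

    Rejects duplicate feature/sample ids, ragged rows and negative or
    non-integer cells, reporting the offending 1-based line number.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        pos = int(np.flatnonzero(frame.index.duplicated())[0])
        raise TableFormatError(
            f"duplicate feature id {frame.index[pos]!r}", line=pos + 2
        )
    if pd.Index(frame.columns).has_duplicates:
        raise TableFormatError("duplicate sample ids in header", line=1)
    values = np.empty(frame.shape, dtype=np.int64)
    for i, (fid, row) in enumerate(frame.iterrows()):
        for j, cell in enumerate(row):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise TableFormatError(f"ragged or empty cell in row {fid!r}", line=i + 2)
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"non-integer count {cell!r} for feature {fid!r}", line=i + 2
                ) from None
            if v < 0:
                raise TableFormatError(
                    f"negative count {v} for feature {fid!r}", line=i + 2
                )
            values[i, j] = v
    return CountMatrix(list(frame.index), list(frame.columns), values)


def write_count_table(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> dict[str, str]:
    """Two-column TSV (species, genus) -> species->genus map."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["species", "genus"], dtype=str)
    if frame["species"].duplicated().any():
        dup = frame.loc[frame["species"].duplicated(), "species"].iloc[0]
        raise TableFormatError(f"species {dup!r} mapped more than once")
    if (frame["genus"].isna() | (frame["genus"].str.len() == 0)).any():
        raise TableFormatError("empty genus id in taxonomy map")
    return dict(zip(frame["species"], frame["genus"]))


def write_taxonomy(taxonomy: dict[str, str], path) -> None:
    pd.DataFrame(sorted(taxonomy.items())).to_csv(path, sep="\t", header=False, index=False)


def aggregate_taxa(matrix: CountMatrix, taxonomy: dict[str, str]) -> CountMatrix:
    """Collapse species rows into genus rows by summing raw counts per sample.

    Aggregation happens on raw counts, before any normalization, so
    per-sample totals are conserved exactly. Genus order follows first
    appearance in the species list.
    """
    unmapped = [f for f in matrix.features if f not in taxonomy]
    if unmapped:
        raise TableFormatError(f"features missing from taxonomy map: {unmapped[:10]}")
    genera = [taxonomy[f] for f in matrix.features]
    frame = matrix.to_frame().groupby(genera, sort=False).sum()
    return CountMatrix.from_frame(frame)


@dataclass(frozen=True)
class AlignmentReport:
    """Bookkeeping from aligning a matrix onto a reference feature list."""

    n_kept: int
    n_filled: int
    n_dropped: int
    filled: tuple[str, ...]
    dropped: tuple[str, ...]


def align_features(matrix, reference_features):
    """Reorder/restrict a matrix to ``reference_features``.

    Features absent from the matrix are zero-filled (absence of evidence is
    encoded as zero abundance); features outside the reference are dropped.
    Works on :class:`CountMatrix` and :class:`NormalizedMatrix` alike and
    returns ``(aligned, AlignmentReport)``.
    """
    reference = [str(f) for f in reference_features]
    if not reference:
        raise ValueError("reference feature list is empty")
    if len(set(reference)) != len(reference):
        raise TableFormatError("duplicate ids in reference feature list")
    have = set(matrix.features)
    filled = tuple(f for f in reference if f not in have)
    dropped = tuple(f for f in matrix.features if f not in set(reference))
    frame = matrix.to_frame().reindex(reference, fill_value=0)
    report = AlignmentReport(
        n_kept=len(reference) - len(filled),
        n_filled=len(filled),
        n_dropped=len(dropped),
        filled=filled,
        dropped=dropped,
    )
    if isinstance(matrix, NormalizedMatrix):
        aligned = NormalizedMatrix(
            features=reference,
            samples=list(matrix.samples),
            values=frame.to_numpy(dtype=float),
            scaling_factors=matrix.scaling_factors,
            quantile_used=matrix.quantile_used,
            scale_constant=matrix.scale_constant,
            log_transformed=matrix.log_transformed,
        )
    else:
        aligned = CountMatrix(reference, list(matrix.samples), frame.to_numpy())
    return aligned, report


def write_normalized(nm: NormalizedMatrix, path) -> None:
    """TSV of values plus a ``<path>.norm.json`` sidecar with the factors."""
    path = Path(path)
    nm.to_frame().to_csv(path, sep="\t", index_label="feature_id")
    sidecar = {
        "scaling_factors": dict(zip(nm.samples, nm.scaling_factors.tolist())),
        "quantile_used": nm.quantile_used,
        "scale_constant": nm.scale_constant,
        "log_transformed": nm.log_transformed,
    }
    path.with_suffix(path.suffix + ".norm.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )


def read_normalized(path) -> NormalizedMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = json.loads(path.with_suffix(path.suffix + ".norm.json").read_text())
    factors = np.array([sidecar["scaling_factors"][s] for s in frame.columns])
    return NormalizedMatrix(
        features=list(frame.index),
        samples=list(frame.columns),
        values=frame.to_numpy(dtype=float),
        scaling_factors=factors,
        quantile_used=sidecar["quantile_used"],
        scale_constant=sidecar["scale_constant"],
        log_transformed=sidecar.get("log_transformed", False),
    )
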