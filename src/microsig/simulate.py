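"""Synthetic low-biomass microbial cohort generator.

Emulates the statistical structure of tissue-resolved metatranscriptomic
taxonomic profiles: sparse, overdispersed counts at ~10^4 classified
microbial reads per sample, a shared cross-tissue core community, planted
per-tissue signature species carrying a multiplicative abundance shift, and
collection-site / isolation-batch / sequencing-batch structure with the
site partially confounded with tissue (tissues are sampled at specific
sites), which is what contamination scenarios exploit.

The count law is zero-inflated negative binomial: presence is Bernoulli
with a species-specific prevalence, and present entries are negative
binomial with a species mean scaled by a log-normal per-sample library-size
factor. Signature species are drawn from the shared core so the planted
effect is an abundance shift of consistently present taxa (and survives
prevalence filtering by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import ConfigurationError, CountMatrix, SampleMetadata

_EXTERNAL_SEED_OFFSET = 10_000_019  # decorrelates external-cohort draws from training draws


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic tissue cohort.

    Defaults describe a desk-scale cohort: 8 tissues x 40 samples, 300
    species, 3 tissues carrying a planted signature of 10 species at a
    4-fold abundance shift, and a mean library size of 4.2e4 classified
    microbial reads per sample.
    """

    n_tissues: int = 8
    samples_per_tissue: int = 40
    n_species: int = 300
    shared_core_fraction: float = 0.30
    signature_tissues: tuple[int, ...] = (0, 1, 2)
    signature_species_per_tissue: int = 10
    signature_fold_change: float = 4.0
    mean_library_size: float = 4.2e4
    library_size_cv: float = 0.6
    baseline_prevalence_range: tuple[float, float] = (0.05, 0.40)
    dispersion: float = 0.5
    n_collection_sites: int = 6
    n_isolation_batches: int = 4
    n_sequencing_batches: int = 3
    sites_per_tissue: int = 2
    seed: int = 1

    def validate(self) -> None:
        for name in (
            "n_tissues",
            "samples_per_tissue",
            "n_species",
            "signature_species_per_tissue",
            "n_collection_sites",
            "n_isolation_batches",
            "n_sequencing_batches",
            "sites_per_tissue",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(name, "must be a positive count")
        if not 0.0 <= self.shared_core_fraction <= 1.0:
            raise ConfigurationError("shared_core_fraction", "must lie in [0, 1]")
        lo, hi = self.baseline_prevalence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                "baseline_prevalence_range", "must be an ordered pair within [0, 1]"
            )
        if self.signature_fold_change <= 0:
            raise ConfigurationError("signature_fold_change", "must be positive")
        if self.mean_library_size <= 0:
            raise ConfigurationError("mean_library_size", "must be positive")
        if self.library_size_cv <= 0:
            raise ConfigurationError("library_size_cv", "must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion", "must be positive")
        if any(t < 0 or t >= self.n_tissues for t in self.signature_tissues):
            raise ConfigurationError(
                "signature_tissues", f"indices must lie in [0, {self.n_tissues})"
            )
        if self.signature_species_per_tissue * len(self.signature_tissues) > self.n_species:
            raise ConfigurationError(
                "signature_species_per_tissue",
                "total planted species exceed n_species",
            )
        if self.sites_per_tissue > self.n_collection_sites:
            raise ConfigurationError("sites_per_tissue", "exceeds n_collection_sites")


@dataclass
class _SpeciesPlan:
    """Species-level parameters shared between a training cohort and any
    matched external cohort: which species are core, where signatures sit."""

    core_idx: np.ndarray
    signature_map: dict[int, np.ndarray]  # tissue index -> species indices
    prevalence: np.ndarray
    mean_abundance: np.ndarray


def _draw_species_params(config: CohortConfig, rng: np.random.Generator):
    """Baseline prevalences and mean abundances; core species are forced to
    prevalence >= 0.5 so they are shared across all tissues."""
    lo, hi = config.baseline_prevalence_range
    prevalence = rng.uniform(lo, hi, size=config.n_species)
    n_core = int(round(config.shared_core_fraction * config.n_species))
    core_idx = rng.choice(config.n_species, size=n_core, replace=False)
    prevalence[core_idx] = rng.uniform(0.5, 0.9, size=n_core)
    weights = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_species)
    mean_abundance = weights * config.mean_library_size / float(prevalence @ weights)
    return prevalence, core_idx, mean_abundance


def _plan_species(config: CohortConfig, rng: np.random.Generator) -> _SpeciesPlan:
    prevalence, core_idx, mean_abundance = _draw_species_params(config, rng)
    # signature species: consecutive blocks of a shuffled pool, core first
    non_core = np.setdiff1d(np.arange(config.n_species), core_idx)
    pool = np.concatenate([rng.permutation(core_idx), rng.permutation(non_core)])
    signature_map: dict[int, np.ndarray] = {}
    k = config.signature_species_per_tissue
    for rank, tissue in enumerate(sorted(config.signature_tissues)):
        signature_map[tissue] = np.sort(pool[rank * k : (rank + 1) * k])
    return _SpeciesPlan(core_idx, signature_map, prevalence, mean_abundance)


def _library_factors(config: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    sigma2 = np.log1p(config.library_size_cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def _sample_counts(
    config: CohortConfig,
    plan: _SpeciesPlan,
    tissue_of: np.ndarray,
    rng: np.random.Generator,
    library_scale: float = 1.0,
) -> np.ndarray:
    n_samples = tissue_of.size
    lib = _library_factors(config, rng, n_samples) * library_scale
    present = rng.random((config.n_species, n_samples)) < plan.prevalence[:, None]
    mu = plan.mean_abundance[:, None] * lib[None, :]
    fold = np.ones((config.n_species, n_samples))
    for tissue, species in plan.signature_map.items():
        cols = np.flatnonzero(tissue_of == tissue)
        fold[np.ix_(species, cols)] = config.signature_fold_change
    mu = np.maximum(mu * fold, 1e-9)
    k = config.dispersion
    counts = rng.negative_binomial(k, k / (k + mu))
    counts[~present] = 0
    return counts.astype(np.int64)


def _assign_units(
    config: CohortConfig, tissue_of: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Round-robin-with-jitter assignment of linkage units; collection site
    is drawn per tissue from a tissue-specific subset of sites, which ties
    site to tissue and enables confounded-contaminant scenarios."""
    n = tissue_of.size
    tissue_sites = {
        t: rng.choice(config.n_collection_sites, size=config.sites_per_tissue, replace=False)
        for t in range(config.n_tissues)
    }
    site = np.empty(n, dtype=np.int64)
    for t in range(config.n_tissues):
        cols = np.flatnonzero(tissue_of == t)
        base = tissue_sites[t][np.arange(cols.size) % config.sites_per_tissue]
        jitter = rng.random(cols.size) < 0.1
        base[jitter] = rng.choice(tissue_sites[t], size=int(jitter.sum()))
        site[cols] = base

    def round_robin(n_units: int) -> np.ndarray:
        order = rng.permutation(n)
        out = np.empty(n, dtype=np.int64)
        out[order] = np.arange(n) % n_units
        return out

    return pd.DataFrame(
        {
            "collection_site": [f"site_{s:02d}" for s in site],
            "isolation_batch": [
                f"iso_{b:02d}" for b in round_robin(config.n_isolation_batches)
            ],
            "sequencing_batch": [
                f"seq_{b:02d}" for b in round_robin(config.n_sequencing_batches)
            ],
        }
    )


def _draw_traits(n_subjects: int, rng: np.random.Generator) -> pd.DataFrame:
    """Subject-level traits, drawn independently of the microbial counts."""
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(55, 12, n_subjects), 20, 80).round(1),
            "bmi": np.clip(rng.normal(27, 4, n_subjects), 16, 45).round(1),
            "sex": rng.choice(["female", "male"], n_subjects),
            "smoking": rng.choice(["no", "yes"], n_subjects, p=[0.7, 0.3]),
            "drinking": rng.choice(["no", "yes"], n_subjects, p=[0.4, 0.6]),
            "ancestry": rng.choice(
                ["group_a", "group_b", "group_c"], n_subjects, p=[0.6, 0.3, 0.1]
            ),
            "hypertension_history": rng.random(n_subjects) < 0.3,
            "diabetes2_history": rng.random(n_subjects) < 0.15,
        }
    )


def _species_names(n: int) -> list[str]:
    return [f"sp_{i:04d}" for i in range(n)]


def _taxonomy(n_species: int, species_per_genus: int = 3) -> dict[str, str]:
    return {
        name: f"genus_{i // species_per_genus:04d}"
        for i, name in enumerate(_species_names(n_species))
    }


def generate_cohort(config: CohortConfig) -> tuple[CountMatrix, SampleMetadata]:
    """Draw a full synthetic cohort; deterministic for a fixed config seed.

    Returns the taxon-by-sample :class:`CountMatrix` (with a bundled
    species->genus taxonomy) and the matching :class:`SampleMetadata`.
    Subjects span tissues (one sample per tissue per subject), mirroring a
    multi-tissue donor design.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    plan = _plan_species(config, rng)
    tissue_of = np.repeat(np.arange(config.n_tissues), config.samples_per_tissue)
    counts = _sample_counts(config, plan, tissue_of, rng)

    subject_of = np.tile(np.arange(config.samples_per_tissue), config.n_tissues)
    units = _assign_units(config, tissue_of, rng)
    traits = _draw_traits(config.samples_per_tissue, rng)
    meta = pd.DataFrame(
        {
            "sample_id": [
                f"t{t:02d}_s{s:03d}" for t, s in zip(tissue_of, subject_of)
            ],
            "subject_id": [f"subj_{s:03d}" for s in subject_of],
            "tissue": [f"tissue_{t:02d}" for t in tissue_of],
        }
    )
    meta = pd.concat(
        [meta, units, traits.iloc[subject_of].reset_index(drop=True)], axis=1
    )
    matrix = CountMatrix(
        features=_species_names(config.n_species),
        samples=meta["sample_id"].tolist(),
        counts=counts,
        taxonomy=_taxonomy(config.n_species),
    )
    return matrix, SampleMetadata(meta)


def generate_external_cohort(
    config: CohortConfig,
    n_samples_per_tissue: int,
    shift_library_size: float = 1.0,
    tissues: tuple[int, ...] | None = None,
    drop_feature_fraction: float = 0.10,
) -> tuple[CountMatrix, SampleMetadata]:
    """An independent cohort sharing the training cohort's feature universe
    and signature placement, but with freshly drawn species baselines and a
    library-size scale shift — a stand-in for cross-study covariate shift.

    A random ``drop_feature_fraction`` of non-signature features is zeroed
    out entirely to exercise feature alignment downstream.
    """
    config.validate()
    if n_samples_per_tissue < 1:
        raise ConfigurationError("n_samples_per_tissue", "must be >= 1")
    if shift_library_size <= 0:
        raise ConfigurationError("shift_library_size", "must be positive")
    # reproduce the training cohort's species plan from the same seed ...
    plan = _plan_species(config, np.random.default_rng(config.seed))
    # ... then perturb the baselines: species keep their biological identity
    # (abundance rank structure, core membership) but every baseline is
    # jittered, emulating cross-study covariate shift without erasing the
    # shared biology a transferable signature depends on
    rng = np.random.default_rng(config.seed + _EXTERNAL_SEED_OFFSET)
    prevalence = np.clip(
        plan.prevalence * rng.uniform(0.7, 1.3, size=config.n_species), 0.01, 0.95
    )
    mean_abundance = plan.mean_abundance * rng.lognormal(0.0, 0.5, size=config.n_species)
    ext_plan = replace(plan, prevalence=prevalence, mean_abundance=mean_abundance)

    tissue_list = sorted(tissues) if tissues is not None else list(range(config.n_tissues))
    if any(t < 0 or t >= config.n_tissues for t in tissue_list):
        raise ConfigurationError("tissues", "indices outside the training cohort")
    tissue_of = np.repeat(np.asarray(tissue_list, dtype=np.int64), n_samples_per_tissue)
    counts = _sample_counts(config, ext_plan, tissue_of, rng, library_scale=shift_library_size)

    signature_species = np.unique(np.concatenate(list(plan.signature_map.values())))
    droppable = np.setdiff1d(np.arange(config.n_species), signature_species)
    n_drop = int(round(drop_feature_fraction * droppable.size))
    if n_drop:
        counts[rng.choice(droppable, size=n_drop, replace=False), :] = 0

    subject_of = np.concatenate(
        [np.arange(n_samples_per_tissue) for _ in tissue_list]
    )
    units = pd.DataFrame(
        {
            "collection_site": "ext_site_00",
            "isolation_batch": "ext_iso_00",
            "sequencing_batch": "ext_seq_00",
        },
        index=range(tissue_of.size),
    )
    traits = _draw_traits(n_samples_per_tissue, rng)
    meta = pd.DataFrame(
        {
            "sample_id": [
                f"ext_t{t:02d}_s{s:03d}" for t, s in zip(tissue_of, subject_of)
            ],
            "subject_id": [f"ext_subj_{s:03d}" for s in subject_of],
            "tissue": [f"tissue_{t:02d}" for t in tissue_of],
        }
    )
    meta = pd.concat([meta, units, traits.iloc[subject_of].reset_index(drop=True)], axis=1)
    matrix = CountMatrix(
        features=_species_names(config.n_species),
        samples=meta["sample_id"].tolist(),
        counts=counts,
        taxonomy=_taxonomy(config.n_species),
    )
    return matrix, SampleMetadata(meta)


def signature_species(config: CohortConfig) -> dict[str, list[str]]:
    """Which species carry the planted signature in each signature tissue
    (recomputed from the config seed; no generation side effects)."""
    config.validate()
    plan = _plan_species(config, np.random.default_rng(config.seed))
    names = _species_names(config.n_species)
    return {
        f"tissue_{t:02d}": [names[i] for i in idx]
        for t, idx in sorted(plan.signature_map.items())
    }


def derive_trait_from_feature(
    counts: CountMatrix,
    meta: SampleMetadata,
    feature: str,
    trait_name: str,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SampleMetadata:
    """Power-testing hook: overwrite/insert a continuous trait as a
    deterministic (optionally noisy) function of one feature's abundance.

    By default traits are independent of the microbiome; this plants an
    association so trait models have something to find.
    """
    if feature not in counts.features:
        raise KeyError(f"unknown feature {feature!r}")
    rng = np.random.default_rng(seed)
    x = np.log1p(counts.counts[counts.features.index(feature)].astype(float))
    table = meta.table.copy()
    table[trait_name] = x + rng.normal(0.0, noise_sd, size=x.size)
    return SampleMetadata(table)
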