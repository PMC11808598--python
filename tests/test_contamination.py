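"""Contamination scenarios: structure, injection mechanics, verdict logic
and the headline discrimination property (biology vs confound)."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import microsig as ms
from microsig.contamination import HIGH_VOLUME, LOW_VOLUME, ROUTES
from microsig.models import MetricsRecord


def _meta(n, site="c0"):
    sites = [site] * n if isinstance(site, str) else site
    return ms.SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": [f"s{j}" for j in range(n)],
                "subject_id": [f"s{j}" for j in range(n)],
                "tissue": "t",
                "collection_site": sites,
                "isolation_batch": "i0",
                "sequencing_batch": "q0",
            }
        )
    )


class TestDefaultScenario:
    def test_structure(self, tiny_cohort):
        _, meta = tiny_cohort
        scenario = ms.build_default_scenario(meta, seed=0)
        assert len(scenario.contaminants) == 12
        by_cat = pd.Series([c.category for c in scenario.contaminants]).value_counts()
        assert by_cat["high_volume"] == 6 and by_cat["low_volume"] == 6
        by_route = pd.Series([c.route for c in scenario.contaminants]).value_counts()
        assert all(by_route[r] == 4 for r in ROUTES)

    def test_high_and_low_volume_parameters(self, tiny_cohort):
        _, meta = tiny_cohort
        for c in ms.build_default_scenario(meta, seed=0).contaminants:
            params = HIGH_VOLUME if c.category == "high_volume" else LOW_VOLUME
            assert c.affected_fraction == params["affected_fraction"]
            assert c.magnitude_quantile == params["magnitude_quantile"]
            assert c.linkage == params["linkage"]

    def test_missing_route_column_rejected(self, tiny_cohort):
        """The default scenario needs all three linkage routes."""
        _, meta = tiny_cohort

        class TwoRoutes:  # metadata-like object lacking one linkage column
            table = meta.table.drop(columns=["sequencing_batch"])

        with pytest.raises(ValueError, match="sequencing_batch"):
            ms.build_default_scenario(TwoRoutes(), seed=0)

    def test_same_seed_same_scenario(self, tiny_cohort):
        _, meta = tiny_cohort
        assert ms.build_default_scenario(meta, 3) == ms.build_default_scenario(meta, 3)


class TestInject:
    def _normalized(self, rng, n_samples=100):
        counts = rng.poisson(20, size=(30, n_samples)) + 1
        m = ms.CountMatrix(
            [f"f{i}" for i in range(30)], [f"s{j}" for j in range(n_samples)], counts
        )
        return ms.css_normalize(m)

    def test_within_unit_count_and_location(self, rng):
        nm = self._normalized(rng)
        meta = _meta(100)
        spec = ms.ContaminantSpec(
            "c1", "high_volume", "collection_site", 0.05, 0.95, "within_one_unit"
        )
        scenario = ms.ContaminationScenario((spec,), seed=1)
        out = ms.inject(nm, scenario, meta, iteration_seed=0)
        row = out.values[-1]
        assert (row > 0).sum() == 5  # exactly 5% of 100 samples

    def test_biological_rows_untouched(self, rng, tiny_cohort):
        counts, meta = tiny_cohort
        nm = ms.css_normalize(counts)
        scenario = ms.build_default_scenario(meta, seed=0)
        out = ms.inject(nm, scenario, meta, iteration_seed=5)
        assert out.features[: nm.n_features] == nm.features
        np.testing.assert_array_equal(out.values[: nm.n_features], nm.values)
        np.testing.assert_array_equal(out.scaling_factors, nm.scaling_factors)
        assert out.samples == nm.samples

    def test_magnitude_is_pooled_quantile(self, rng):
        nm = self._normalized(rng)
        meta = _meta(100)
        spec = ms.ContaminantSpec("c1", "low_volume", "isolation_batch", 0.4, 0.25, "across_units")
        out = ms.inject(nm, ms.ContaminationScenario((spec,), seed=1), meta, 0)
        row = out.values[-1]
        expected = np.quantile(nm.values[nm.values > 0], 0.25)
        assert row.max() == pytest.approx(expected)
        assert (row > 0).sum() == 40

    def test_affected_sets_differ_across_iterations(self, rng):
        nm = self._normalized(rng)
        meta = _meta(100)
        spec = ms.ContaminantSpec("c1", "low_volume", "isolation_batch", 0.2, 0.5, "across_units")
        scenario = ms.ContaminationScenario((spec,), seed=1)
        sets = {
            tuple(np.flatnonzero(ms.inject(nm, scenario, meta, it).values[-1]))
            for it in range(10)
        }
        assert len(sets) > 1

    def test_at_least_one_sample_forced(self, rng):
        nm = self._normalized(rng, n_samples=5)
        meta = _meta(5)
        spec = ms.ContaminantSpec("c1", "high_volume", "collection_site", 0.01, 0.9, "across_units")
        out = ms.inject(nm, ms.ContaminationScenario((spec,), seed=1), meta, 0)
        assert (out.values[-1] > 0).sum() == 1

    def test_id_collision_rejected(self, rng):
        nm = self._normalized(rng)
        meta = _meta(100)
        spec = ms.ContaminantSpec("f0", "high_volume", "collection_site", 0.05, 0.9, "across_units")
        with pytest.raises(ValueError, match="collide"):
            ms.inject(nm, ms.ContaminationScenario((spec,), seed=1), meta, 0)


def _records(values, aupr=None):
    aupr = aupr if aupr is not None else values
    return [MetricsRecord(auroc=a, aupr=p, aupr_random=0.2) for a, p in zip(values, aupr)]


class TestCompareAndVerdict:
    def test_exact_rank_sum_p(self):
        """[1,2,3] vs [4,5,6]: all three smallest in one arm; the two-sided
        exact p over C(6,3)=20 orderings is 2/20 = 0.1."""
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(0.1)

    def test_identical_distributions_resilient(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.7, 0.9, 20)
        report = ms.compare_and_verdict(_records(vals), _records(vals), 0.5, 1)
        assert report.p_auroc == pytest.approx(1.0, abs=0.05)
        assert report.verdict == "resilient"

    def test_contamination_driven_when_gain_and_importance(self):
        high = _records(np.linspace(0.85, 0.95, 15))
        low = _records(np.linspace(0.60, 0.70, 15))
        report = ms.compare_and_verdict(high, low, 0.30, 1)
        assert report.p_auroc < 0.001 and report.verdict == "contamination_driven"
        assert report.direction == 1

    def test_gain_without_importance_is_resilient(self):
        high = _records(np.linspace(0.85, 0.95, 15))
        low = _records(np.linspace(0.60, 0.70, 15))
        report = ms.compare_and_verdict(high, low, 0.001, 50)
        assert report.verdict == "resilient"

    def test_importance_without_gain_is_resilient(self):
        vals = np.linspace(0.7, 0.8, 15)
        report = ms.compare_and_verdict(_records(vals), _records(vals + 0.001), 0.5, 1)
        assert report.verdict == "resilient"

    def test_minimum_iterations_enforced(self):
        with pytest.raises(ValueError):
            ms.compare_and_verdict(_records([0.5] * 5), _records([0.5] * 15), 0.0, 99)


class TestContaminationStudy:
    def test_null_injection_identical_arms(self, tiny_cohort, tiny_universe):
        """With magnitude scaled to zero the contaminant rows are all-zero
        and both arms produce identical metrics per iteration."""
        counts, meta = tiny_cohort
        scenario = ms.build_default_scenario(meta, seed=0)
        null_scenario = ms.ContaminationScenario(
            tuple(replace(c, magnitude_scale=0.0) for c in scenario.contaminants),
            seed=scenario.seed,
        )
        spec = ms.ModelSpec(
            interaction_depth_grid=(2,), n_trees_grid=(40,), iterations=10, master_seed=1
        )
        study = ms.ContaminationStudy(
            counts, meta, ["tissue_00"], tiny_universe, null_scenario, spec
        )
        res = study.fit().per_tissue["tissue_00"]
        for c, u in zip(res.contaminated, res.uncontaminated):
            assert c.auroc == pytest.approx(u.auroc)
            assert c.aupr == pytest.approx(u.aupr)
        assert res.report.verdict == "resilient"
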