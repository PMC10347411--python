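"""Synthetic cohort generator: determinism, planted signal, site effects."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from brainage.connectivity import fisher_z, pearson_fc
from brainage.synthetic import (
    CohortSpec,
    GroupSpec,
    SubjectRecord,
    generate_cohort,
    plant_parameters,
    sample_connectivity_target,
    simulate_timeseries,
)


def quiet_spec(**kw):
    """Spec with all variation sources disabled unless overridden."""
    base = dict(
        groups=(GroupSpec("HC", 0.0, 12),),
        n_regions=8,
        n_sites=2,
        n_signal_edges=0,
        site_shift_sd=0.0,
        site_scale_sd=0.0,
        subject_noise_sd=0.0,
        seed=5,
    )
    base.update(kw)
    return CohortSpec(**base)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_regions": 2},
            {"n_sites": 1},
            {"n_signal_edges": 1000, "n_regions": 8},
            {"age_range": (80.0, 60.0)},
            {"subject_noise_sd": -0.1},
            {"groups": (GroupSpec("HC", float("inf"), 12),)},
        ],
    )
    def test_invalid_specs_rejected_before_sampling(self, kw):
        with pytest.raises(ValueError):
            generate_cohort(quiet_spec(**kw))

    def test_too_few_subjects_for_sites(self):
        with pytest.raises(ValueError, match="sites"):
            generate_cohort(quiet_spec(groups=(GroupSpec("HC", 0.0, 5),), n_sites=2))


class TestDeterminismAndStructure:
    def test_same_seed_bit_identical(self):
        spec = quiet_spec(subject_noise_sd=0.05, n_signal_edges=3, site_shift_sd=0.1)
        c1, c2 = generate_cohort(spec), generate_cohort(spec)
        for t1, t2 in zip(c1.timeseries, c2.timeseries):
            assert np.array_equal(t1.values, t2.values)
        assert c1.provenance().equals(c2.provenance())

    def test_no_variation_sources_gives_identical_base_matrix(self):
        spec = quiet_spec()
        planted = plant_parameters(spec)
        rng = np.random.default_rng(0)
        mats = []
        for ba in (55.0, 75.0, 95.0):
            rec = SubjectRecord("s", ba, ba, "F", "site01", "HC", 100)
            mats.append(sample_connectivity_target(rec, spec, rng, planted).values)
        assert np.array_equal(mats[0], mats[1])
        assert np.array_equal(mats[0], mats[2])

    def test_targets_are_valid_correlation_matrices(self):
        spec = quiet_spec(subject_noise_sd=0.1, n_signal_edges=5, site_shift_sd=0.2)
        cohort = generate_cohort(spec)
        planted = cohort.planted
        rng = np.random.default_rng(1)
        for rec in cohort.records[:5]:
            m = sample_connectivity_target(rec, spec, rng, planted).values
            assert np.all(np.diag(m) == 1.0)
            assert np.linalg.eigvalsh(m).min() >= -1e-8

    def test_zero_size_group_absent(self):
        spec = quiet_spec(groups=(GroupSpec("HC", 0.0, 12), GroupSpec("AD", 5.0, 0)))
        cohort = generate_cohort(spec)
        assert set(r.group for r in cohort.records) == {"HC"}

    def test_round_robin_sites_balanced(self):
        spec = quiet_spec(groups=(GroupSpec("HC", 0.0, 21),), n_sites=4)
        cohort = generate_cohort(spec)
        counts = cohort.phenotypes()["site"].value_counts()
        assert counts.min() >= 3
        assert counts.max() - counts.min() <= 1

    def test_ages_and_lengths_within_bounds(self):
        spec = quiet_spec(timeseries_length_range=(90, 110))
        cohort = generate_cohort(spec)
        for rec, ts in zip(cohort.records, cohort.timeseries):
            assert spec.age_range[0] <= rec.age <= spec.age_range[1]
            assert 90 <= ts.n_timepoints <= 110


class TestPlantedSignal:
    def test_signal_edge_z_tracks_brain_age(self):
        """Fisher-z of a signal edge correlates with latent brain age (n=200);
        non-signal edges stay near zero correlation."""
        spec = quiet_spec(
            groups=(GroupSpec("HC", 0.0, 200),),
            n_regions=12,
            n_signal_edges=1,
            signal_slope_range=(0.3, 0.3),
            subject_noise_sd=0.02,
        )
        cohort = generate_cohort(spec)
        planted = cohort.planted
        i, j = planted.signal_edges[0]
        rng = np.random.default_rng(3)
        targets = [
            sample_connectivity_target(rec, spec, rng, planted).values
            for rec in cohort.records
        ]
        ba = np.array([rec.brain_age for rec in cohort.records])
        z_sig = fisher_z(np.array([t[i, j] for t in targets]))
        assert np.corrcoef(z_sig, ba)[0, 1] > 0.9
        iu, ju = np.triu_indices(spec.n_regions, k=1)
        rs = []
        for a, b in zip(iu, ju):
            if (a, b) == (i, j):
                continue
            z = fisher_z(np.array([t[a, b] for t in targets]))
            if z.std() > 0:
                rs.append(abs(np.corrcoef(z, ba)[0, 1]))
        assert max(rs, default=0.0) < 0.25

    def test_planted_signal_recoverable_from_simulated_timeseries(self):
        """With site effects off, the Pearson FC of a top-slope signal edge
        (T=400, noise SD 0.05) correlates with brain age at |r| >= 0.5."""
        spec = quiet_spec(
            groups=(GroupSpec("HC", 0.0, 200),),
            n_regions=20,
            n_signal_edges=4,
            signal_slope_range=(0.4, 0.4),
            subject_noise_sd=0.05,
            timeseries_length_range=(400, 400),
        )
        cohort = generate_cohort(spec)
        i, j = cohort.planted.signal_edges[0]
        r_edge = np.array([pearson_fc(ts).values[i, j] for ts in cohort.timeseries])
        ba = np.array([rec.brain_age for rec in cohort.records])
        assert abs(np.corrcoef(fisher_z(r_edge), ba)[0, 1]) >= 0.5

    def test_group_offset_recovered_in_provenance(self):
        spec = quiet_spec(
            groups=(GroupSpec("HC", 0.0, 50), GroupSpec("AD", 5.0, 50)),
        )
        prov = generate_cohort(spec).provenance()
        ad = prov[prov.group == "AD"]
        gap = (ad.brain_age - ad.age).mean()
        # jitter SD 1.0 year -> SE ~ 1/sqrt(50)
        assert gap == pytest.approx(5.0, abs=3 * 1.0 / np.sqrt(50) + 0.1)
        hc = prov[prov.group == "HC"]
        assert (hc.brain_age - hc.age).mean() == pytest.approx(0.0, abs=0.5)

    def test_site_effects_detectable_before_harmonization(self):
        """One-way ANOVA of site on a fixed edge's Fisher-z is significant."""
        spec = quiet_spec(
            groups=(GroupSpec("HC", 0.0, 200),),
            n_regions=10,
            n_sites=4,
            site_shift_sd=0.1,
            subject_noise_sd=0.03,
        )
        cohort = generate_cohort(spec)
        z01 = fisher_z(np.array([pearson_fc(ts).values[0, 1] for ts in cohort.timeseries]))
        sites = np.array([r.site for r in cohort.records])
        blocks = [z01[sites == s] for s in np.unique(sites)]
        _, p = stats.f_oneway(*blocks)
        assert p < 0.01


class TestSimulateTimeseries:
    def test_identity_target_gives_small_correlations(self):
        rng = np.random.default_rng(0)
        ts = simulate_timeseries(np.eye(6), 5000, rng, "s")
        fc = pearson_fc(ts).values
        off = fc[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_single_strong_edge_recovered(self):
        target = np.eye(5)
        target[0, 1] = target[1, 0] = 0.8
        rng = np.random.default_rng(1)
        fc = pearson_fc(simulate_timeseries(target, 5000, rng, "s")).values
        assert 0.75 <= fc[0, 1] <= 0.85

    def test_invalid_target_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PSD
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_timeseries(bad, 100, np.random.default_rng(0), "s")

    def test_single_region_rejected_downstream(self):
        ts = simulate_timeseries(np.eye(1), 50, np.random.default_rng(0), "s")
        with pytest.raises(ValueError):
            pearson_fc(ts)
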