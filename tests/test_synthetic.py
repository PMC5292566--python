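"""Synthetic-cohort generator: copula calibration, occupancy, covariates."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from sertnet.correlation import partial_spearman
from sertnet.errors import ConfigurationError, SertnetError
from sertnet.synthetic import (
    THREE_WEEK_PAIR_EFFECTS,
    SyntheticConfig,
    config_from_dict,
    config_to_dict,
    generate_cohorts,
    healthy_control_scenario,
    load_config,
    nearest_psd,
    ssri_study_scenario,
    save_config,
    spearman_to_pearson,
)
from sertnet.types import RegionSet, default_region_set


def two_condition_config(rho=0.0, occupancy=0.7, noise=0.0, seed=0, n=19,
                         share_latents=False, **kw):
    regions = RegionSet(("a", "b", "c"))
    R = np.full((3, 3), rho)
    np.fill_diagonal(R, 1.0)
    return SyntheticConfig(
        n_subjects=n,
        region_set=regions,
        mu=np.array([2.0, 1.0, 0.5]),
        sigma=np.array([0.3, 0.15, 0.08]),
        R_target={"PET1": R.copy(), "PET3": R.copy()},
        occupancy={"PET1": 0.0, "PET3": occupancy},
        noise_sd=noise,
        seed=seed,
        share_latents=share_latents,
        **kw,
    )


class TestSpearmanToPearson:
    @pytest.mark.parametrize(
        "rho_s, expected",
        [(0.0, 0.0), (1.0, 1.0), (-1.0, -1.0), (0.5, 2 * np.sin(np.pi / 12))],
    )
    def test_closed_form(self, rho_s, expected):
        assert spearman_to_pearson(rho_s) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(SertnetError):
            spearman_to_pearson(1.1)

    def test_monte_carlo_calibration(self):
        # latent normal with converted Pearson r yields the target Spearman
        target = 0.6
        r = spearman_to_pearson(target)
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=100_000)
        got = stats.spearmanr(z[:, 0], z[:, 1]).statistic
        assert 0.58 <= got <= 0.62


class TestNearestPsd:
    def test_psd_input_untouched(self):
        m = np.array([[1, 0.5], [0.5, 1.0]])
        out, dist = nearest_psd(m)
        assert dist == 0.0
        np.testing.assert_allclose(out, m)

    def test_indefinite_input_repaired(self):
        m = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]])
        out, dist = nearest_psd(m)
        assert dist > 0
        assert np.linalg.eigvalsh(out).min() >= -1e-8
        np.testing.assert_allclose(np.diag(out), 1.0, atol=1e-9)

    def test_fixed_entries_held_exactly(self):
        m = np.array([[1, 0.95, -0.5], [0.95, 1, 0.9], [-0.5, 0.9, 1]])
        fixed = np.zeros((3, 3), dtype=bool)
        fixed[0, 1] = fixed[1, 0] = True
        out, _ = nearest_psd(m, fixed=fixed)
        assert out[0, 1] == pytest.approx(0.95, abs=1e-12)
        assert np.linalg.eigvalsh(out).min() >= -1e-8


class TestGenerateCohorts:
    def test_same_seed_identical_cohorts(self):
        c1 = generate_cohorts(ssri_study_scenario(seed=5))
        c2 = generate_cohorts(ssri_study_scenario(seed=5))
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.bp_matrix, b.bp_matrix)
            assert a.subject_ids == b.subject_ids

    def test_cohort_invariants_and_shared_subjects(self):
        cohorts = generate_cohorts(ssri_study_scenario(seed=2))
        assert [c.condition for c in cohorts] == ["PET1", "PET2", "PET3"]
        ids = cohorts[0].subject_ids
        for c in cohorts:
            assert c.subject_ids == ids
            assert c.n == 19
            assert np.all(np.isfinite(c.bp_matrix))
            assert np.all(c.bp_matrix >= 0)

    def test_occupancy_ratio_exact_with_shared_latents_no_noise(self):
        cfg = two_condition_config(occupancy=0.7, noise=0.0, share_latents=True)
        pet1, pet3 = generate_cohorts(cfg)
        assert getattr(pet3, "n_floored") == 0
        ratio = pet3.bp_matrix.mean(axis=0) / pet1.bp_matrix.mean(axis=0)
        np.testing.assert_allclose(ratio, 0.3, atol=1e-12)

    def test_occupancy_preserves_rank_correlations(self):
        # uniform rescaling is monotone per region: Spearman unchanged
        cfg = two_condition_config(
            rho=0.4, occupancy=0.7, noise=0.0, share_latents=True, seed=3
        )
        pet1, pet3 = generate_cohorts(cfg)
        for i in range(3):
            for j in range(i + 1, 3):
                r1 = partial_spearman(pet1.bp_matrix[:, i], pet1.bp_matrix[:, j])
                r3 = partial_spearman(pet3.bp_matrix[:, i], pet3.bp_matrix[:, j])
                assert r1 == pytest.approx(r3, abs=1e-12)

    def test_empirical_spearman_hits_target_at_large_n(self):
        cfg = two_condition_config(rho=0.6, occupancy=0.0, noise=0.0, n=10_000)
        pet1, _ = generate_cohorts(cfg)
        bp = pet1.bp_matrix
        got = stats.spearmanr(bp[:, 0], bp[:, 1]).statistic
        assert 0.58 <= got <= 0.62

    def test_floor_events_counted(self):
        cfg = two_condition_config(noise=5.0, seed=1)  # huge noise forces floors
        pet1, _ = generate_cohorts(cfg)
        assert getattr(pet1, "n_floored") > 0
        assert np.all(pet1.bp_matrix >= 0)

    def test_shared_age_effect_inflates_simple_vs_partial(self):
        # two uncorrelated regions sharing an age slope: simple Spearman
        # exceeds the age-adjusted partial in expectation — the property
        # that motivates covariate adjustment
        cfg = two_condition_config(rho=0.0, occupancy=0.0, noise=0.0, n=4000,
                                   beta_age=np.array([0.03, 0.015, 0.008]))
        pet1, _ = generate_cohorts(cfg)
        bp = pet1.bp_matrix
        ages = np.array([[r.age] for r in pet1.records])
        simple = partial_spearman(bp[:, 0], bp[:, 1])
        partial = partial_spearman(bp[:, 0], bp[:, 1], ages)
        assert simple > partial + 0.05
        assert abs(partial) < 0.06

    def test_baseline_occupancy_must_be_zero(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(
                n_subjects=10,
                region_set=RegionSet(("a", "b")),
                mu=1.0,
                sigma=0.1,
                R_target={"PET1": np.eye(2)},
                occupancy={"PET1": 0.5},
            )


class TestPaperLikeScenario:
    def test_baseline_has_zero_occupancy(self):
        cfg = ssri_study_scenario()
        assert np.all(cfg.occupancy["PET1"] == 0)
        assert cfg.n_subjects == 19
        assert len(cfg.region_set) == 9

    def test_injected_increases_match_reported_deltas(self):
        cfg = ssri_study_scenario()
        regions = cfg.region_set
        base = cfg.R_target["PET1"]
        pet3 = cfg.R_target["PET3"]
        i, j = regions.index("ACC"), regions.index("pallidum")
        assert pet3[i, j] - base[i, j] == pytest.approx(0.71)
        for a, b, delta in THREE_WEEK_PAIR_EFFECTS:
            ii, jj = regions.index(a), regions.index(b)
            assert pet3[ii, jj] - base[ii, jj] == pytest.approx(delta)

    def test_latent_matrices_are_psd_with_injected_pairs_preserved(self):
        cfg = ssri_study_scenario()
        regions = cfg.region_set
        for cond in cfg.conditions:
            vals = np.linalg.eigvalsh(cfg.pearson_latent(cond))
            assert vals.min() >= -1e-8
        realized = cfg.realized_spearman("PET3")
        for a, b, delta in THREE_WEEK_PAIR_EFFECTS:
            i, j = regions.index(a), regions.index(b)
            assert realized[i, j] == pytest.approx(0.2 + delta, abs=1e-9)

    def test_control_scenario_single_condition(self):
        cfg = healthy_control_scenario()
        assert cfg.conditions == ["PET1"]
        assert cfg.group == "HC"


class TestConfigSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = two_condition_config(rho=0.3, seed=9)
        path = tmp_path / "config.yaml"
        save_config(cfg, path)
        back = load_config(path)
        assert back.n_subjects == cfg.n_subjects
        assert back.region_set == cfg.region_set
        for cond in cfg.conditions:
            np.testing.assert_allclose(back.R_target[cond], cfg.R_target[cond])
            np.testing.assert_allclose(back.occupancy[cond], cfg.occupancy[cond])
        c1 = generate_cohorts(cfg)
        c2 = generate_cohorts(back)
        np.testing.assert_array_equal(c1[0].bp_matrix, c2[0].bp_matrix)

    def test_dict_roundtrip_preserves_fields(self):
        cfg = ssri_study_scenario(seed=4)
        # note: repair_fixed masks are a scenario detail, not serialized;
        # the round trip re-validates (baseline target is PSD as-is)
        data = config_to_dict(cfg)
        back = config_from_dict(
            {**data, "R_target": {"PET1": data["R_target"]["PET1"]},
             "occupancy": {"PET1": data["occupancy"]["PET1"]}}
        )
        np.testing.assert_allclose(back.mu, cfg.mu)
        assert back.p_female == pytest.approx(13 / 19)
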