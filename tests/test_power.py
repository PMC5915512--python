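"""Sample-size formula, voxel statistics, FDR masking, power tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from predecline.change import roi_change_table
from predecline.cohort import CohortConfig, default_strata, generate_cohort
from predecline.groups import classify_cohort
from predecline.power import (
    PowerParams,
    fdr_mask,
    invert_sample_size,
    per_arm_sample_size,
    roi_power_table,
    sample_size_map,
    voxel_decline_stats,
)


class TestSampleSizeFormula:
    @pytest.mark.parametrize(
        "delta_mu,sigma,expected",
        [
            (3.4, 2.0, 87),  # enriched above-proposed calibration
            (1.0, 1.2867, 416),  # standard-threshold calibration
            (1.0, 1.7138, 738),  # no-enrichment calibration
        ],
    )
    def test_printed_calibrations(self, delta_mu, sigma, expected):
        assert per_arm_sample_size(delta_mu, sigma) == expected

    def test_sign_of_decline_is_ignored(self):
        assert per_arm_sample_size(-3.4, 2.0) == 87

    def test_scale_invariance(self):
        assert per_arm_sample_size(1.7, 1.0) == per_arm_sample_size(3.4, 2.0)

    def test_zero_delta_mu_rejected(self):
        with pytest.raises(ValueError, match="delta_mu"):
            per_arm_sample_size(0.0, 1.0)
        with pytest.raises(ValueError, match="sigma"):
            per_arm_sample_size(1.0, -1.0)

    def test_zero_sigma_floors_at_one(self):
        assert per_arm_sample_size(1.0, 0.0) == 1

    @settings(derandomize=True, max_examples=60)
    @given(
        dm=st.floats(0.2, 5.0),
        sg=st.floats(0.1, 5.0),
        factor=st.floats(1.05, 3.0),
    )
    def test_monotonicity(self, dm, sg, factor):
        """n decreases in delta_mu and effect, increases in sigma (up to the
        ceiling/floor clamps)."""
        base = per_arm_sample_size(dm, sg)
        assert per_arm_sample_size(dm * factor, sg) <= base
        assert per_arm_sample_size(dm, sg * factor) >= base
        stronger = PowerParams(effect=min(1.0, 0.25 * factor))
        assert per_arm_sample_size(dm, sg, stronger) <= per_arm_sample_size(
            dm, sg, PowerParams(effect=0.25)
        )


class TestInvertSampleSize:
    def test_known_ratio(self):
        # r = beta*sqrt(n/2)/(power+sig): n=87 -> 0.25*sqrt(43.5)/2.802
        assert invert_sample_size(87) == pytest.approx(0.5885, abs=2e-4)

    @pytest.mark.parametrize("n", [1, 2, 10, 87, 416, 738, 5000])
    def test_roundtrip_up_to_ceiling(self, n):
        r = invert_sample_size(n)
        assert per_arm_sample_size(1.0, r) in (n, n + 1)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            invert_sample_size(0)


class TestVoxelStats:
    def test_identical_maps_flag_degenerate_sd(self):
        maps = np.stack([np.full((4, 4, 4), -2.0)] * 5)
        out = voxel_decline_stats(maps)
        assert out["degenerate"].all()
        assert np.isnan(out["p"]).all()
        np.testing.assert_allclose(out["mean"], -2.0)

    def test_pure_noise_p_values_uniform(self, rng):
        maps = rng.normal(0, 1, size=(20, 22, 22, 22))
        out = voxel_decline_stats(maps)
        p = out["p"].ravel()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_injected_decline_ranks_lowest(self, rng):
        maps = rng.normal(0, 1, size=(15, 10, 10, 10))
        maps[:, :2, :2, :2] += -3.0
        out = voxel_decline_stats(maps)
        flat = out["p"].ravel()
        injected = np.zeros((10, 10, 10), dtype=bool)
        injected[:2, :2, :2] = True
        worst_injected = out["p"][injected].max()
        assert (flat < worst_injected).sum() <= injected.sum() * 2

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            voxel_decline_stats(np.zeros((2, 4, 4, 4)))

    def test_missing_voxels_propagate(self, rng):
        maps = rng.normal(size=(5, 3, 3, 3))
        maps[2, 1, 1, 1] = np.nan
        out = voxel_decline_stats(maps)
        assert np.isnan(out["mean"][1, 1, 1])
        assert np.isnan(out["p"][1, 1, 1])


class TestFdrMask:
    def test_hand_computed_three_values(self):
        # BH at q=0.001 with m=3: step thresholds 1/3, 2/3, 3/3 of q
        p = np.array([0.0001, 0.0005, 0.5])
        mask = fdr_mask(p, q=0.001)
        np.testing.assert_array_equal(mask, [True, True, False])

    def test_all_equal_below_q(self):
        p = np.full(7, 5e-4)
        assert fdr_mask(p, q=0.001).all()

    def test_null_false_flag_fraction(self):
        """Under the null, the flagged fraction stays at or below q in at
        least 95/100 seeded runs."""
        q = 0.001
        ok = 0
        for seed in range(100):
            p = np.random.default_rng(seed).uniform(size=10_000)
            ok += fdr_mask(p, q).mean() <= q
        assert ok >= 95

    def test_invalid_q_and_p(self):
        with pytest.raises(ValueError, match="q"):
            fdr_mask(np.array([0.5]), q=1.5)
        with pytest.raises(ValueError, match="p-values"):
            fdr_mask(np.array([-0.1]), q=0.01)

    def test_missing_p_never_flagged(self):
        p = np.array([1e-6, np.nan, 0.9])
        mask = fdr_mask(p, 0.01)
        assert mask[0] and not mask[1] and not mask[2]


class TestSampleSizeMap:
    def _stats(self):
        shape = (6, 6, 6)
        mean = np.full(shape, -3.4)
        sd = np.full(shape, 2.0)
        p = np.full(shape, 1e-6)
        return {"mean": mean, "sd": sd, "p": p, "n_subjects": 17,
                "degenerate": np.zeros(shape, bool)}

    def test_masked_voxels_get_formula_value(self):
        st_ = self._stats()
        mask = np.zeros((6, 6, 6), bool)
        mask[0, 0, 0] = True
        pm = sample_size_map(st_, mask)
        assert pm.n_per_arm[0, 0, 0] == 87
        assert np.isnan(pm.n_per_arm[1, 1, 1])

    def test_empty_mask_warns(self):
        pm = sample_size_map(self._stats(), np.zeros((6, 6, 6), bool))
        assert "warning" in pm.status
        assert np.isnan(pm.minimum())

    def test_map_minimum_matches_brute_force(self, rng):
        st_ = self._stats()
        st_["mean"] = rng.uniform(-4, -1, st_["mean"].shape)
        st_["sd"] = rng.uniform(0.5, 3, st_["sd"].shape)
        mask = rng.random(st_["mean"].shape) < 0.5
        pm = sample_size_map(st_, mask)
        brute = min(
            per_arm_sample_size(abs(st_["mean"][i]), st_["sd"][i])
            for i in zip(*np.nonzero(mask))
        )
        assert pm.minimum() == brute


class TestRoiPowerTable:
    def test_large_group_recovers_analytic_n(self, rng):
        """A group generated at known (delta_mu, sigma) yields a per-arm n
        within +-2 of the analytic formula value at n=10,000."""
        q = rng.normal(-3.4, 2.0, 10_000)
        tab = pd.DataFrame(
            {"subject_id": np.arange(10_000).astype(str), "roi": "r", "q_value": q}
        )
        groups = pd.Series("g", index=tab["subject_id"])
        out = roi_power_table(tab, groups)
        assert abs(int(out["n_per_arm"].iloc[0]) - 87) <= 2

    def test_identical_groups_identical_tables(self, rng):
        q = rng.normal(-2, 1, 50)
        tab = pd.DataFrame(
            {"subject_id": np.arange(50).astype(str), "roi": "r", "q_value": q}
        )
        out1 = roi_power_table(tab, pd.Series("a", index=tab["subject_id"]))
        out2 = roi_power_table(tab, pd.Series("b", index=tab["subject_id"]))
        assert out1["n_per_arm"].iloc[0] == out2["n_per_arm"].iloc[0]

    def test_zero_variance_group_floors_at_one(self):
        tab = pd.DataFrame(
            {"subject_id": ["a", "b", "c"], "roi": "r", "q_value": [-2.0, -2.0, -2.0]}
        )
        out = roi_power_table(tab, pd.Series("g", index=tab["subject_id"]))
        assert out["n_per_arm"].iloc[0] == 1

    def test_undersized_group_rejected(self):
        tab = pd.DataFrame(
            {"subject_id": ["a", "b"], "roi": "r", "q_value": [-2.0, -1.0]}
        )
        with pytest.raises(ValueError, match="need"):
            roi_power_table(tab, pd.Series("g", index=tab["subject_id"]))


def test_enrichment_ordering_on_large_cohort():
    """Per-arm n shrinks with enrichment: above-proposed < standard
    preclinical < whole cohort, for an AD-signature ROI."""
    strata = [dataclasses.replace(s, count=s.count * 10) for s in default_strata()]
    df = generate_cohort(CohortConfig(seed=17, strata=strata))
    labelled = classify_cohort(df)
    table = roi_change_table(df)
    roi = "mediobasal_temporal"
    sub = table[table.roi == roi].set_index("subject_id")["q_value"]

    def n_for(ids):
        q = sub.loc[ids]
        return per_arm_sample_size(abs(q.mean()), q.std(ddof=1))

    above = labelled.loc[labelled["above_proposed"], "subject_id"]
    precl = labelled.loc[labelled["group"] == "preclinical", "subject_id"]
    everyone = labelled["subject_id"]
    n_above, n_precl, n_all = n_for(above), n_for(precl), n_for(everyone)
    assert n_above < n_precl < n_all
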