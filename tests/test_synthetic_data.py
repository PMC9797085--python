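"""Ground-truth consistency and determinism of the synthetic generators."""

import numpy as np
import pytest

from tunel3d.synthetic_data import (
    DevSimParams,
    MetricsSimParams,
    StackSimParams,
    generate_dev_table,
    generate_metrics_table,
    generate_stack,
    make_touching_fixture,
    _separating_threshold_exists,
)


class TestGenerateStack:
    def test_fixed_seed_is_bit_identical(self):
        s1, t1 = generate_stack(StackSimParams(seed=5))
        s2, t2 = generate_stack(StackSimParams(seed=5))
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(t1.labels.labels, t2.labels.labels)

    def test_no_nuclei_yields_background_only(self):
        stack, truth = generate_stack(StackSimParams(n_nuclei=0, seed=1))
        assert truth.n_nuclei == 0
        assert truth.labels.labels.max() == 0
        p = StackSimParams(n_nuclei=0, seed=1)
        assert stack.channel("DAPI").mean() == pytest.approx(p.background, abs=1.0)

    def test_all_apoptotic_colabels_every_nucleus(self):
        stack, truth = generate_stack(
            StackSimParams(n_nuclei=10, apoptotic_fraction=1.0, seed=2)
        )
        assert truth.n_apoptotic == 10
        tun = stack.channel("TUNEL").astype(float)
        bg = StackSimParams().background
        for lab in range(1, 11):
            inside = truth.labels.labels == lab
            assert tun[inside].mean() > bg + 30  # TUNEL signal present in each nucleus

    def test_apoptotic_count_matches_rounded_fraction(self):
        stack, truth = generate_stack(StackSimParams(n_nuclei=36, apoptotic_fraction=0.12, seed=3))
        assert truth.n_apoptotic == round(36 * 0.12)

    def test_tunel_signal_confined_to_apoptotic_nuclei(self):
        stack, truth = generate_stack(StackSimParams(seed=4))
        tun = stack.channel("TUNEL").astype(float)
        apop_mask = np.isin(truth.labels.labels, np.flatnonzero(truth.apoptotic))
        non_apop = np.isin(
            truth.labels.labels, np.flatnonzero(~truth.apoptotic[: truth.n_nuclei + 1])
        ) & (truth.labels.labels > 0)
        assert tun[apop_mask].mean() > tun[non_apop].mean() + 50

    def test_all_requested_nuclei_are_rendered(self):
        stack, truth = generate_stack(StackSimParams(n_nuclei=50, seed=6))
        present = np.unique(truth.labels.labels)
        assert set(present[present > 0]) == set(range(1, 51))

    def test_pycnotic_nuclei_are_smaller(self):
        _, truth = generate_stack(StackSimParams(seed=7))
        apop = truth.apoptotic[1:]
        assert truth.radii_um[apop].mean() < truth.radii_um[~apop].mean()

    @pytest.mark.parametrize("bad", [
        {"apoptotic_fraction": 1.2},
        {"pycnotic_shrink_factor": 0.0},
        {"n_nuclei": 4, "touching_pair_count": 3},
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            StackSimParams(**bad)

    def test_impossible_placement_raises_rather_than_dropping(self):
        from tunel3d.synthetic_data import PlacementError

        with pytest.raises(PlacementError):
            generate_stack(StackSimParams(n_nuclei=60, shell_radius_um=6.0, seed=0))


class TestTouchingFixture:
    def test_no_global_threshold_separates_the_pair(self):
        stack, truth = make_touching_fixture(bright_peak=200, dim_peak=80, seed=0)
        assert truth.n_nuclei == 2
        img = stack.channel("TUNEL")
        assert not _separating_threshold_exists(
            img, truth.labels.labels == 1, truth.labels.labels == 2
        )

    def test_truth_objects_are_in_voxel_contact(self):
        from scipy import ndimage

        _, truth = make_touching_fixture(seed=1)
        grown = ndimage.binary_dilation(truth.labels.labels == 1)
        assert (grown & (truth.labels.labels == 2)).any()

    def test_dim_at_least_bright_rejected(self):
        with pytest.raises(ValueError):
            make_touching_fixture(bright_peak=100, dim_peak=100)

    def test_deterministic_for_fixed_seed(self):
        s1, _ = make_touching_fixture(seed=3)
        s2, _ = make_touching_fixture(seed=3)
        assert np.array_equal(s1.data, s2.data)


class TestGenerateDevTable:
    def test_fixed_seed_identical_tables(self):
        g1, b1 = generate_dev_table(DevSimParams(seed=9))
        g2, b2 = generate_dev_table(DevSimParams(seed=9))
        assert g1.equals(g2) and b1.equals(b2)

    def test_null_odds_ratios_pool_to_equal_rates(self):
        # law of large numbers over many replicates: pooled treatment vs
        # control proportions agree to < 1% absolute under OR = 1
        g, _ = generate_dev_table(
            DevSimParams(n_replicates=10_000, replicate_sd=0.0, seed=10)
        )
        pooled = g.groupby("treatment").sum(numeric_only=True)
        rates = pooled["cleaved"] / pooled["n_oocytes"]
        assert rates.max() - rates.min() < 0.01
        d6 = pooled["blastocyst_d6"] / pooled["n_oocytes"]
        assert d6.max() - d6.min() < 0.01

    def test_treatment_odds_ratio_shifts_outcome(self):
        g, _ = generate_dev_table(
            DevSimParams(
                n_replicates=2000,
                replicate_sd=0.0,
                seed=11,
                odds_ratios={"blastocyst_d6": {"PFHxS": 2.0}},
            )
        )
        pooled = g.groupby("treatment").sum(numeric_only=True)
        rate = pooled["blastocyst_d6"] / pooled["n_oocytes"]
        assert rate["PFHxS"] > rate["control"] + 0.05

    def test_zero_replicate_sd_gives_equal_intercepts(self):
        g, _ = generate_dev_table(DevSimParams(replicate_sd=0.0, seed=12))
        effects = g.attrs["replicate_effects"]
        for u in effects.values():
            assert np.allclose(u, 0.0)

    def test_gt2_denominator_is_cleaved_count(self):
        g, _ = generate_dev_table(DevSimParams(seed=13))
        assert (g["cleaved_gt2"] <= g["cleaved"]).all()
        assert (g["cleaved"] <= g["n_oocytes"]).all()

    def test_blastocyst_rows_match_group_counts(self):
        g, b = generate_dev_table(DevSimParams(seed=14))
        want = g.groupby(["replicate", "treatment"])["blastocyst_d6"].sum()
        got = b.groupby(["replicate", "treatment"]).size().reindex(want.index, fill_value=0)
        assert (want == got).all()


class TestGenerateMetricsTable:
    def test_counts_and_flags_consistent(self):
        m = generate_metrics_table(MetricsSimParams(seed=15))
        assert (m["n_apoptotic"] <= m["n_nuclei"]).all()
        assert np.allclose(m["prop_apoptotic"], m["n_apoptotic"] / m["n_nuclei"])

    def test_negative_size_slope_shows_in_data(self):
        m = generate_metrics_table(
            MetricsSimParams(seed=16, prop_slope_per_nucleus=-0.0013, embryos_per_group=60)
        )
        small = m.loc[m["n_nuclei"] <= m["n_nuclei"].median(), "prop_apoptotic"].mean()
        large = m.loc[m["n_nuclei"] > m["n_nuclei"].median(), "prop_apoptotic"].mean()
        assert small > large
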