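"""Generator: planted truth tables, mean patterns, and count distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splitrootseq import (
    SimulationDesign,
    expected_mean_pattern,
    expected_shoot_label,
    expected_shoot_mean_pattern,
    plan_truth,
    simulate_counts,
)
from splitrootseq.simulate import ALL_CLASSES, ROOT_GROUPS, SHOOT_GROUPS


def design(**kw):
    kw.setdefault("n_genes", 100)
    kw.setdefault("seed", 1)
    return SimulationDesign(**kw)


class TestPlanTruth:
    def test_single_class(self):
        truth = plan_truth(design(n_genes=10, class_proportions={"background": 1.0}))
        assert len(truth) == 10
        assert (truth["response_class"] == "background").all()
        assert (truth["direction"] == "none").all()

    def test_rounding_arithmetic(self):
        truth = plan_truth(
            design(
                n_genes=100,
                class_proportions={"background": 0.5, "up_local": 0.25, "down_both": 0.25},
            )
        )
        counts = truth.groupby(["direction", "response_class"]).size()
        assert counts[("none", "background")] == 50
        assert counts[("up", "local")] == 25
        assert counts[("down", "both")] == 25

    def test_remainder_goes_to_background(self):
        truth = plan_truth(
            design(
                n_genes=10,
                class_proportions={"background": 0.33, "up_local": 0.33, "down_local": 0.34},
            )
        )
        counts = truth["response_class"].value_counts()
        # round() gives 3/3/3; the missing gene lands in background
        assert counts["background"] == 4
        assert counts["local"] == 6

    def test_seed_determinism(self):
        d = design(class_proportions={"background": 0.9, "up_local": 0.1})
        pd.testing.assert_frame_equal(plan_truth(d), plan_truth(d))

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            design(class_proportions={"background": 0.7, "up_local": 0.2})
        with pytest.raises(ValueError, match="unknown"):
            design(class_proportions={"background": 0.5, "sideways_local": 0.5})

    @given(
        weights=st.lists(
            st.floats(0.01, 1.0, allow_nan=False), min_size=1, max_size=len(ALL_CLASSES)
        ),
        n_genes=st.integers(1, 400),
    )
    def test_class_counts_always_sum_to_n_genes(self, weights, n_genes):
        total = sum(weights)
        props = {c: w / total for c, w in zip(ALL_CLASSES, weights)}
        # repair float round-off so the design validates
        props[next(iter(props))] += 1.0 - sum(props.values())
        truth = plan_truth(design(n_genes=n_genes, class_proportions=props))
        assert len(truth) == n_genes


class TestMeanPatterns:
    def test_background_is_flat(self):
        assert expected_mean_pattern("none", "background", 2.0) == {
            g: 1.0 for g in ROOT_GROUPS
        }

    def test_up_both(self):
        assert expected_mean_pattern("up", "both", 1.0) == {
            "CK_R": 1.0, "S0_R": 2.0, "SR_R": 1.0, "SPSR_R": 1.0, "SPS0_R": 1.0,
        }

    def test_down_systemic_mirror(self):
        assert expected_mean_pattern("down", "systemic", 2.0) == {
            "CK_R": 1.0, "S0_R": 0.25, "SR_R": 1.0, "SPSR_R": 0.25, "SPS0_R": 1.0,
        }

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            expected_mean_pattern("up", "sideways", 1.0)
        with pytest.raises(ValueError):
            expected_mean_pattern("diagonal", "local", 1.0)

    @pytest.mark.parametrize("cls", ["local", "systemic", "both", "none", "unrecovered"])
    def test_up_down_patterns_are_reciprocal(self, cls):
        up = expected_mean_pattern("up", cls, 1.7)
        down = expected_mean_pattern("down", cls, 1.7)
        for g in ROOT_GROUPS:
            assert up[g] * down[g] == pytest.approx(1.0)

    def test_deficient_group_always_shifted(self):
        for cls in ("local", "systemic", "both", "none", "unrecovered"):
            assert expected_mean_pattern("up", cls, 2.0)["S0_R"] == 4.0
            assert expected_mean_pattern("up", cls, 2.0)["CK_R"] == 1.0

    def test_shoot_patterns(self):
        for cls, sp in [("systemic", 1.0), ("both", 1.0), ("local", 4.0), ("none", 4.0)]:
            pat = expected_shoot_mean_pattern("up", cls, 2.0)
            assert pat == {"CK_Sh": 1.0, "S0_Sh": 4.0, "SR_Sh": 1.0, "SP_Sh": sp}
        unrec = expected_shoot_mean_pattern("up", "unrecovered", 2.0)
        assert unrec == {"CK_Sh": 1.0, "S0_Sh": 4.0, "SR_Sh": 4.0, "SP_Sh": 4.0}
        assert expected_shoot_mean_pattern("none", "background", 2.0) == {
            g: 1.0 for g in SHOOT_GROUPS
        }

    def test_shoot_label_mapping(self):
        assert expected_shoot_label("systemic") == "hetero_responsive"
        assert expected_shoot_label("both") == "hetero_responsive"
        assert expected_shoot_label("local") == "homo_only"
        assert expected_shoot_label("none") == "homo_only"
        assert expected_shoot_label("unrecovered") == "unrecovered"


class TestSimulateCounts:
    def test_seed_determinism(self):
        d = design(n_genes=200, dispersion=0.2, seed=5)
        cm1, t1 = simulate_counts(d)
        cm2, t2 = simulate_counts(d)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(t1, t2)

    def test_poisson_limit_variance_equals_mean(self):
        d = design(
            n_genes=2000,
            dispersion=0.0,
            libsize_cv=0.0,
            class_proportions={"background": 1.0},
            base_mean_log_range=(3.0, 3.0),
        )
        cm, _ = simulate_counts(d)
        x = cm.counts.to_numpy(float)
        ratio = x.var(axis=1, ddof=1).mean() / x.mean(axis=1).mean()
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_planted_fold_change_reaches_the_generating_mean(self):
        d = design(
            n_genes=2000,
            effect_log2fc=3.0,
            dispersion=0.05,
            shoot_fraction=0.0,
            class_proportions={"background": 0.9, "up_both": 0.1},
        )
        cm, truth = simulate_counts(d)
        planted = truth.loc[truth["response_class"] == "both", "gene_id"]
        s0 = cm.counts.loc[planted, cm.samples_in("S0_R")].to_numpy().mean()
        ck = cm.counts.loc[planted, cm.samples_in("CK_R")].to_numpy().mean()
        assert s0 / ck == pytest.approx(8.0, rel=0.15)

    def test_background_group_means_converge_with_replication(self):
        d = design(
            n_genes=50,
            replicates=200,
            dispersion=0.0,
            libsize_cv=0.0,
            class_proportions={"background": 1.0},
            base_mean_log_range=(2.0, 3.0),
        )
        cm, truth = simulate_counts(d)
        base = truth.set_index("gene_id")["base_mean"]
        for group in d.groups:
            means = cm.counts[cm.samples_in(group)].mean(axis=1)
            np.testing.assert_allclose(means, base.loc[means.index], rtol=0.05)

    def test_counts_are_integers_and_lengths_in_range(self):
        d = design(n_genes=300, gene_length_range=(500, 800))
        cm, _ = simulate_counts(d)
        assert np.issubdtype(cm.counts.to_numpy().dtype, np.integer)
        assert cm.gene_lengths.between(500, 800).all()

    def test_libsize_factors_move_column_totals(self):
        quiet = simulate_counts(design(n_genes=500, libsize_cv=0.0))[0]
        noisy = simulate_counts(design(n_genes=500, libsize_cv=0.5))[0]
        cv = lambda t: t.std() / t.mean()
        assert cv(noisy.counts.sum(axis=0)) > cv(quiet.counts.sum(axis=0))
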