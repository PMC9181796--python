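"""NB Wald differential-expression test: normalisation, dispersion, calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splitrootseq import (
    ContrastSpec,
    bh_adjust,
    call_degs,
    estimate_dispersion,
    run_contrast,
    simulate_counts,
    size_factors,
    wald_test,
)
from splitrootseq import SimulationDesign
from splitrootseq.detest import call_status

from .conftest import make_count_matrix


def bh_bruteforce(p):
    """Literal step-up definition: q_i = min_{j>=rank(i)} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q[idx] = min(1.0, min(p[order[j - 1]] * m / j for j in range(rank, m + 1)))
    return q


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_sample_has_double_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10], "c": [10, 20, 5]})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)
        assert f["a"] == pytest.approx(f["c"])

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 6)))
        f = size_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_fallback_to_column_sums_when_no_gene_is_everywhere(self):
        # every gene has a zero somewhere; column sums are 10 vs 30
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 30]})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(3.0)


class TestDispersion:
    def test_poisson_data_gives_zero(self):
        # within-group variance exactly equals the mean (90/100/110 -> var 100)
        norm = pd.DataFrame(
            {"a1": [90.0], "a2": [100.0], "a3": [110.0],
             "b1": [90.0], "b2": [100.0], "b3": [110.0]}
        )
        disp = estimate_dispersion(norm, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert disp["phi"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert disp["phi_raw"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_single_gene(self):
        # pooled mean 100, pooled within-group variance 600 -> (600-100)/100^2
        a = np.array([100 - np.sqrt(600), 100, 100 + np.sqrt(600)])
        norm = pd.DataFrame([np.concatenate([a, a])],
                            columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        disp = estimate_dispersion(norm, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert disp["phi"].iloc[0] == pytest.approx(0.05)

    def test_all_zero_gene_flagged_untestable(self):
        norm = pd.DataFrame(
            {"a1": [0.0, 5.0], "a2": [0.0, 9.0], "b1": [0.0, 7.0], "b2": [0.0, 8.0]}
        )
        disp = estimate_dispersion(norm, ["a1", "a2"], ["b1", "b2"])
        assert not disp["testable"].iloc[0]
        assert disp["testable"].iloc[1]

    @given(
        st.lists(
            st.lists(st.integers(0, 500), min_size=4, max_size=4),
            min_size=2,
            max_size=30,
        )
    )
    def test_never_negative(self, rows):
        norm = pd.DataFrame(rows, columns=["a1", "a2", "b1", "b2"], dtype=float)
        disp = estimate_dispersion(norm, ["a1", "a2"], ["b1", "b2"])
        assert (disp["phi"] >= 0).all()
        assert (disp["phi_raw"].dropna() >= 0).all()


class TestWald:
    def test_identical_groups_are_null(self):
        res = wald_test(np.array([50.0]), np.array([50.0]), np.array([0.1]), 3, 3)
        assert res["log2fc"].iloc[0] == 0.0
        assert res["z"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_closed_form_recomputation(self):
        # means 100 vs 400, n=3, phi=0: lfc = log2(400.5/100.5),
        # SE^2 = (1/ln2)^2 * (1/(3*100.5) + 1/(3*400.5))
        res = wald_test(np.array([400.0]), np.array([100.0]), np.array([0.0]), 3, 3)
        lfc = np.log2(400.5 / 100.5)
        se = np.sqrt((1 / np.log(2)) ** 2 * (1 / (3 * 400.5) + 1 / (3 * 100.5)))
        assert res["log2fc"].iloc[0] == pytest.approx(lfc)
        assert lfc == pytest.approx(1.995, abs=5e-4)
        assert res["z"].iloc[0] == pytest.approx(lfc / se)
        assert res["z"].iloc[0] > 20
        assert res["p"].iloc[0] < 1e-80

    def test_both_means_zero_is_untestable(self):
        res = wald_test(np.array([0.0]), np.array([0.0]), np.array([0.2]), 3, 3)
        assert res["log2fc"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0


class TestBH:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40))
    def test_matches_bruteforce_and_contracts(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_bruteforce(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCalling:
    def spec(self):
        return ContrastSpec(group_a="S0_R", group_b="CK_R")

    def table(self, **cols):
        n = len(next(iter(cols.values())))
        base = {"log2fc": [0.0] * n, "p": [1.0] * n, "fdr": [1.0] * n}
        base.update(cols)
        return pd.DataFrame(base, index=[f"g{i}" for i in range(n)])

    def test_all_null_gives_empty_sets(self):
        up, down = call_degs(self.table(log2fc=[0.0, 0.1]), self.spec())
        assert not up.genes and not down.genes

    def test_threshold_conjunction(self):
        t = self.table(
            log2fc=[3.0, 3.0, 3.0, -3.0, 0.5],
            p=[0.2, 0.001, 0.001, 0.001, 0.001],
            fdr=[0.001, 0.5, 0.001, 0.001, 0.001],
        )
        up, down = call_degs(t, self.spec())
        assert up.genes == {"g2"}
        assert down.genes == {"g3"}

    def test_boundary_is_strict_on_p_and_fdr_inclusive_on_lfc(self):
        t = self.table(log2fc=[1.0, 1.0, 1.0], p=[0.05, 0.01, 0.01],
                       fdr=[0.001, 0.01, 0.009])
        status = call_status(t, self.spec())
        assert list(status) == ["ns", "ns", "up"]


class TestOnSimulatedData:
    def test_group_swap_negates_everything(self, planted_run):
        _, cm, _ = planted_run
        ab = run_contrast(cm, ContrastSpec(group_a="S0_R", group_b="CK_R"))
        ba = run_contrast(cm, ContrastSpec(group_a="CK_R", group_b="S0_R"))
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
        np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-12)
        assert (ab["status"] == "up").equals(ba["status"] == "down")

    def test_replicate_relabelling_changes_nothing(self, planted_run):
        _, cm, _ = planted_run
        spec = ContrastSpec(group_a="S0_R", group_b="CK_R")
        base = run_contrast(cm, spec)
        shuffled = cm.counts.copy()
        a = cm.samples_in("S0_R")
        shuffled[a] = shuffled[[a[1], a[2], a[0]]].to_numpy()
        import dataclasses

        cm2 = dataclasses.replace(cm, counts=shuffled)
        np.testing.assert_allclose(base["p"], run_contrast(cm2, spec)["p"])

    def test_planted_up_genes_are_called(self, planted_run):
        _, cm, truth = planted_run
        spec = ContrastSpec(group_a="S0_R", group_b="CK_R")
        up, down = call_degs(run_contrast(cm, spec), spec)
        t = truth[truth["tissue"] == "root"].set_index("gene_id")
        planted_up = set(t.index[t["direction"] == "up"])
        background = set(t.index[t["response_class"] == "background"])
        assert len(planted_up & up.genes) / len(planted_up) >= 0.9
        assert len(background & (up.genes | down.genes)) / len(background) <= 0.01
        assert not up.genes & down.genes

    def test_degenerate_all_zero_gene_gets_ns_and_fdr_one(self):
        cm = make_count_matrix(
            [[0, 0, 0, 0], [100, 110, 90, 105], [12, 9, 14, 11]],
            groups=["S0_R", "S0_R", "CK_R", "CK_R"],
        )
        spec = ContrastSpec(group_a="S0_R", group_b="CK_R")
        table = run_contrast(cm, spec)
        assert table.loc["g0", "status"] == "ns"
        assert table.loc["g0", "fdr"] == 1.0
        assert not table.loc["g0", "detected"]
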