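"""ABEL computation, subsampling, threshold and linear-boundary classifiers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import arborclass as ac
from arborclass.abel import BoundarySearchConfig, GLIA_BELOW

from conftest import rotation_matrix, transform_morphology
from oracles import oracle_abel, oracle_threshold


def branch(path_length, contraction, terminal_degree=1):
    return ac.Branch(
        node_path=(0, 1),
        path_length=path_length,
        euclidean_length=path_length * contraction,
        branch_order=0,
        terminal_degree=terminal_degree,
    )


class TestComputeAbel:
    def test_printed_formula_arithmetic(self):
        # Euclidean lengths 10 and 5 (paths 10 & 10, contractions 1.0 & 0.5)
        p = ac.compute_abel([branch(10, 1.0), branch(10, 0.5)])
        assert p.abel == pytest.approx(7.5)

    def test_single_branch_identity(self):
        assert ac.compute_abel([branch(42.0, 1.0)]).abel == pytest.approx(42.0)

    def test_y_tree_terminal_internal_split(self, y_tree):
        p = ac.compute_abel(ac.decompose_branches(y_tree))
        assert p.abel == pytest.approx(22 / 3)
        assert p.abel_terminal == pytest.approx(6.0)
        assert p.abel_internal == pytest.approx(10.0)
        assert p.ratio_terminal_internal == pytest.approx(0.6)
        assert p.n_branches == 3
        assert p.ratio_defined

    def test_equals_mean_branch_euclidean_length(self):
        """The contraction×path route equals the direct geometric mean branch
        Euclidean length (two independent computation routes)."""
        for seed in range(10):
            m = ac.grow_tree(ac.preset("glia_like" if seed % 2 else "neuron_like"),
                             seed=seed)
            br = ac.decompose_branches(m)
            p = ac.compute_abel(br)
            mean_euc = float(np.mean([b.euclidean_length for b in br]))
            assert abs(p.abel - mean_euc) < 1e-12 * max(1.0, mean_euc)
            assert p.abel == pytest.approx(oracle_abel(m), rel=1e-9)

    def test_rigid_motion_invariance_and_linear_scaling(self):
        m = ac.grow_tree(ac.preset("neuron_like"), seed=3)
        base = ac.compute_abel(ac.decompose_branches(m)).abel
        moved = transform_morphology(m, rotation=rotation_matrix([0, 1, 1], 1.2),
                                     translation=(5, -3, 8))
        assert ac.compute_abel(ac.decompose_branches(moved)).abel == pytest.approx(
            base, rel=1e-9
        )
        scaled = transform_morphology(m, scale=3.0)
        assert ac.compute_abel(ac.decompose_branches(scaled)).abel == pytest.approx(
            3 * base, rel=1e-9
        )

    def test_no_internal_branches_flagged(self, cable):
        p = ac.compute_abel(ac.decompose_branches(cable))
        assert not p.ratio_defined
        assert math.isnan(p.abel_internal)

    def test_empty_branch_list(self):
        with pytest.raises(ValueError):
            ac.compute_abel([])

    def test_profile_bounds(self, y_tree):
        p = ac.compute_abel(ac.decompose_branches(y_tree))
        assert min(p.abel_terminal, p.abel_internal) <= p.abel <= max(
            p.abel_terminal, p.abel_internal
        )


class TestSubsample:
    def test_full_set_reproduces_abel_exactly(self):
        lengths = np.array([3.0, 7.0, 11.0, 2.0, 9.0])
        est = ac.subsample_abel(lengths, N=5, n_sets=50, seed=0)
        assert est.mean_abel == pytest.approx(lengths.mean())
        assert est.sd_abel == pytest.approx(0.0, abs=1e-12)

    def test_equal_lengths_zero_sd(self):
        est = ac.subsample_abel([4.0] * 20, N=7, n_sets=30, seed=1)
        assert est.mean_abel == pytest.approx(4.0)
        assert est.sd_abel == pytest.approx(0.0, abs=1e-12)

    def test_error_names_branch_count(self):
        with pytest.raises(ValueError, match="NB=4"):
            ac.subsample_abel([1.0, 2.0, 3.0, 4.0], N=5)

    def test_reproducible_under_seed(self):
        lengths = np.random.default_rng(2).lognormal(3, 0.5, size=40)
        a = ac.subsample_abel(lengths, N=5, seed=77)
        b = ac.subsample_abel(lengths, N=5, seed=77)
        assert a == b


class TestThreshold:
    def test_separable_midpoint(self):
        model = ac.fit_threshold([1, 2, 3, 10, 11, 12],
                                 ["glia"] * 3 + ["neuron"] * 3)
        assert model.threshold == pytest.approx(6.5)
        assert model.training_accuracy == 1.0
        assert model.polarity == "glia_below"

    def test_identical_distributions_degenerate(self):
        vals = [5.0, 5.0, 5.0, 5.0]
        model = ac.fit_threshold(vals, ["glia", "neuron", "glia", "neuron"])
        assert model.training_accuracy == pytest.approx(0.5)
        assert model.threshold < 5.0 or model.threshold > 5.0  # extreme sentinel

    def test_one_class_absent(self):
        with pytest.raises(ValueError):
            ac.fit_threshold([1.0, 2.0], ["glia", "glia"])

    def test_classify_tie_goes_to_neuron_side(self):
        model = ac.ThresholdModel(threshold=14.33)
        assert ac.classify_threshold(model, 14.0) == "glia"
        assert ac.classify_threshold(model, 15.0) == "neuron"
        assert ac.classify_threshold(model, 14.33) == "neuron"

    def test_matches_exhaustive_oracle_on_overlapping_lognormals(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 60
            vals = np.concatenate(
                [rng.lognormal(1.5, 0.7, n // 2), rng.lognormal(2.5, 0.7, n // 2)]
            )
            labels = np.array(["glia"] * (n // 2) + ["neuron"] * (n // 2))
            model = ac.fit_threshold(vals, labels)
            t, pol, acc = oracle_threshold(list(vals), list(labels))
            assert model.training_accuracy == pytest.approx(acc, abs=1e-12)
            assert model.polarity == pol
            assert model.threshold == pytest.approx(t)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        vals=st.lists(st.floats(-100, 100, allow_nan=False), min_size=4, max_size=25),
        bits=st.lists(st.booleans(), min_size=4, max_size=25),
    )
    def test_accuracy_is_max_of_any_single_cut(self, vals, bits):
        bits = (bits * len(vals))[: len(vals)]
        if all(bits) or not any(bits):
            bits[0] = not bits[0]
        labels = ["glia" if b else "neuron" for b in bits]
        model = ac.fit_threshold(vals, labels)
        _, _, acc = oracle_threshold(vals, labels)
        assert model.training_accuracy == pytest.approx(acc, abs=1e-12)


class TestLinearBoundary:
    def _separated_by_line(self, rng, n=150, slope=-0.1, intercept=20.0, gap=2.0):
        H = rng.uniform(0, 200, n)
        side = rng.random(n) < 0.5
        offset = rng.uniform(gap, 30, n)
        A = slope * H + intercept + np.where(side, offset, -offset)
        labels = np.where(side, "neuron", "glia")
        return A, H, labels

    def test_recovers_known_separating_line(self):
        rng = np.random.default_rng(8)
        A, H, labels = self._separated_by_line(rng)
        model = ac.fit_linear_boundary(A, H, labels)
        assert model.training_accuracy == 1.0
        pred = ac.classify_linear_boundary(model, A, H)
        assert (pred == labels).all()

    def test_never_below_univariate_threshold(self):
        rng = np.random.default_rng(9)
        A = np.concatenate([rng.normal(8, 3, 80), rng.normal(20, 5, 80)])
        H = rng.uniform(0, 100, 160)
        labels = np.array(["glia"] * 80 + ["neuron"] * 80)
        tm = ac.fit_threshold(A, labels)
        bm = ac.fit_linear_boundary(A, H, labels)
        assert bm.training_accuracy >= tm.training_accuracy

    def test_slope_zero_on_abel_separable_classes(self):
        A = np.array([1.0, 2, 3, 4, 20, 21, 22, 23])
        H = np.array([50.0, 60, 70, 80, 50, 60, 70, 80])
        labels = np.array(["glia"] * 4 + ["neuron"] * 4)
        model = ac.fit_linear_boundary(A, H, labels)
        assert model.training_accuracy == 1.0

    def test_swarm_mode_is_seed_deterministic(self):
        rng = np.random.default_rng(10)
        A, H, labels = self._separated_by_line(rng, n=80)
        cfg = BoundarySearchConfig(method="swarm", seed=123)
        m1 = ac.fit_linear_boundary(A, H, labels, cfg)
        m2 = ac.fit_linear_boundary(A, H, labels, cfg)
        assert m1 == m2

    def test_degenerate_predictors(self):
        with pytest.raises(ValueError):
            ac.fit_linear_boundary([1.0, 1.0], [2.0, 2.0], ["glia", "neuron"])


class TestDiagnostics:
    def test_separated_data_all_bins_zero(self):
        vals = np.array([1.0, 2, 3, 10, 11, 12])
        labels = np.array(["glia"] * 3 + ["neuron"] * 3)
        model = ac.fit_threshold(vals, labels)
        prof = ac.misclassification_profile(vals, labels, model, bin_width=2.0)
        assert prof["n_misclassified"].sum() == 0

    def test_single_wide_bin(self):
        vals = np.array([1.0, 2, 3, 10, 11, 12])
        labels = np.array(["neuron", "glia", "glia", "neuron", "neuron", "glia"])
        model = ac.fit_threshold(vals, labels)
        prof = ac.misclassification_profile(vals, labels, model, bin_width=1000.0)
        assert len(prof) == 1
        n_mis = (ac.classify_threshold(model, vals) != labels).sum()
        assert prof["n_misclassified"].iloc[0] == n_mis

    def test_errors_concentrate_around_threshold(self):
        """With two overlapping Gaussians, more misclassified mass lies
        within one sd of the cut than outside it (overlap of the densities
        peaks at the boundary)."""
        rng = np.random.default_rng(11)
        n = 4000
        sd = 3.0
        vals = np.concatenate([rng.normal(10, sd, n), rng.normal(20, sd, n)])
        labels = np.array(["glia"] * n + ["neuron"] * n)
        model = ac.fit_threshold(vals, labels)
        frac_near = ac.misclassified_fraction_in_interval(
            vals, labels, model, model.threshold - sd, model.threshold + sd
        )
        assert frac_near > 0.5

    def test_grouped_accuracy_single_group_equals_overall(self):
        vals = np.array([1.0, 2, 3, 10, 11, 2.5])
        labels = np.array(["glia", "glia", "glia", "neuron", "neuron", "neuron"])
        model = ac.fit_threshold(vals, labels)
        table = ac.grouped_accuracy(vals, labels, ["all"] * 6, model)
        overall = (ac.classify_threshold(model, vals) == labels).mean()
        assert table.loc[0, "accuracy"] == pytest.approx(overall)
        assert table.loc[0, "n"] == 6

    def test_group_by_label_gives_sensitivity_specificity(self):
        rng = np.random.default_rng(12)
        vals = np.concatenate([rng.normal(8, 3, 200), rng.normal(18, 3, 200)])
        labels = np.array(["glia"] * 200 + ["neuron"] * 200)
        model = ac.fit_threshold(vals, labels)
        table = ac.grouped_accuracy(vals, labels, labels, model).set_index("group")
        pred = ac.classify_threshold(model, vals)
        sens = (pred[labels == "neuron"] == "neuron").mean()
        spec = (pred[labels == "glia"] == "glia").mean()
        assert table.loc["neuron", "accuracy"] == pytest.approx(sens)
        assert table.loc["glia", "accuracy"] == pytest.approx(spec)

    def test_random_groups_within_binomial_ci(self):
        rng = np.random.default_rng(13)
        vals = np.concatenate([rng.normal(8, 3, 500), rng.normal(18, 3, 500)])
        labels = np.array(["glia"] * 500 + ["neuron"] * 500)
        model = ac.fit_threshold(vals, labels)
        groups = rng.integers(0, 4, size=1000)
        table = ac.grouped_accuracy(vals, labels, groups, model)
        overall = model.training_accuracy
        for _, row in table.iterrows():
            se = math.sqrt(overall * (1 - overall) / row["n"])
            assert abs(row["accuracy"] - overall) < 4 * se + 1e-9


def test_model_save_load_roundtrip(tmp_path):
    tm = ac.ThresholdModel(threshold=14.33, polarity=GLIA_BELOW, training_accuracy=0.976)
    ac.save_model(tm, tmp_path / "t.txt")
    assert ac.load_model(tmp_path / "t.txt") == tm
    bm = ac.LinearBoundaryModel(slope=-0.1352, intercept=23.04,
                                training_accuracy=0.985, seed=3)
    ac.save_model(bm, tmp_path / "b.txt")
    assert ac.load_model(tmp_path / "b.txt") == bm
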