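"""The connection algorithm: normalization and density formulas, trajectory
construction, pair selection, spatial plausibility, cluster scores."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nfcnkit import (ConnectedPairs, CountMatrix, GeneSet, LigandReceptorSpec,
                     SpatialGrid, TrajectoryScores, build_interaction_trajectory,
                     downsample_representative, kde_density, minmax_normalize,
                     nfcn_score, pair_precision_recall, select_connected,
                     spatial_proximity_filter)
from tests.conftest import rng_for


class TestDownsampling:
    def test_small_population_is_returned_whole(self):
        ids = np.array([f"C{i}" for i in range(2000)])
        strata = np.repeat(["a", "b"], 1000)
        out = downsample_representative(ids, strata, n=3000, seed=0)
        assert set(out) == set(ids)

    def test_allocation_is_proportional_to_stratum_size(self):
        ids = np.array([f"C{i}" for i in range(5000)])
        strata = np.array(["a"] * 4000 + ["b"] * 1000)
        out = downsample_representative(ids, strata, n=1000, seed=0)
        picked = strata[np.isin(ids, out)]
        assert len(out) == 1000
        assert abs((picked == "a").sum() - 800) <= 1

    def test_sampling_is_deterministic(self):
        ids = np.array([f"C{i}" for i in range(500)])
        strata = np.repeat(["a", "b"], 250)
        a = downsample_representative(ids, strata, n=100, seed=9)
        b = downsample_representative(ids, strata, n=100, seed=9)
        assert np.array_equal(a, b)


class TestMinMax:
    def test_three_point_example(self):
        assert np.allclose(minmax_normalize(np.array([0.0, 5.0, 10.0])),
                           [0.0, 0.5, 1.0], atol=1e-12)

    def test_negative_inputs(self):
        assert np.allclose(minmax_normalize(np.array([-3.0, -1.0])),
                           [0.0, 1.0], atol=1e-12)

    def test_constant_vector_is_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.full(5, 2.0))

    @given(arrays(np.float64, st.integers(2, 50),
                  elements=st.floats(-1e6, 1e6), unique=True))
    @settings(max_examples=50, deadline=None)
    def test_matches_elementwise_formula(self, x):
        out = minmax_normalize(x)
        ref = (x - x.min()) / (x.max() - x.min())
        assert np.abs(out - ref).max() < 1e-12


class TestKde:
    def test_single_atom_gaussian_closed_form(self):
        f = kde_density(np.array([0.5]), x=0.5, kernel="gaussian", h=0.5)
        assert abs(f[0] - 1.0 / (0.5 * math.sqrt(2 * math.pi))) < 1e-12

    def test_two_point_symmetry_matches_direct_sum(self):
        pts = np.array([0.0, 1.0])
        h = 0.4
        f = kde_density(pts, x=0.5, kernel="gaussian", h=h)
        k = math.exp(-0.5 * (0.5 / h) ** 2) / math.sqrt(2 * math.pi)
        assert abs(f[0] - 2 * 0.5 * k / h) < 1e-10

    def test_out_of_range_bandwidth_is_rejected(self):
        with pytest.raises(ValueError):
            kde_density(np.array([0.1, 0.9]), h=0.8)
        with pytest.raises(ValueError):
            kde_density(np.array([0.1, 0.9]), h=0.3)

    @pytest.mark.parametrize("kernel", ["gaussian", "cauchy"])
    def test_matches_brute_force_double_sum(self, kernel):
        rng = rng_for(f"kde-{kernel}")
        pts = rng.uniform(0, 1, size=40)
        xs = rng.uniform(0, 1, size=15)
        h = 0.45
        f = kde_density(pts, x=xs, kernel=kernel, h=h)
        for i, x in enumerate(xs):
            total = 0.0
            for p in pts:
                u = (x - p) / h
                if kernel == "gaussian":
                    total += math.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)
                else:
                    total += 1.0 / (math.pi * (1 + u * u))
            assert abs(f[i] - total / (len(pts) * h)) < 1e-12

    def test_density_integrates_to_one(self):
        rng = rng_for("kde-mass")
        pts = rng.uniform(0, 1, size=30)
        xs = np.linspace(-5, 6, 4001)
        f = kde_density(pts, x=xs, kernel="gaussian", h=0.5)
        assert abs(np.trapezoid(f, xs) - 1.0) < 1e-4


def toy_trajectory(n_per_side=200):
    """Hand-built trajectory with strictly increasing scores on each side."""
    n = 2 * n_per_side
    vals = np.linspace(0, 1, n_per_side)
    return TrajectoryScores(
        cell_ids=np.array([f"C{i:04d}" for i in range(n)], dtype=object),
        side=np.array(["ligand"] * n_per_side + ["receiver"] * n_per_side),
        clusters=np.array(["M"] * n_per_side + ["T"] * n_per_side),
        A_exp=np.tile(vals, 2), A_eff=np.tile(vals, 2),
        retained=np.ones(n, dtype=bool),
        n_exp=np.tile(vals, 2), n_eff=np.tile(vals, 2),
        f_hat=np.ones(n), trajectory_position=np.tile(vals, 2),
        rank=np.tile(np.arange(n_per_side)[::-1] + 1, 2))


class TestSelectConnected:
    def test_no_eligible_receiver_gives_empty_pairs(self):
        ts = toy_trajectory()
        ts.retained[ts.side == "receiver"] = False
        ts.n_exp[ts.side == "receiver"] = np.nan
        out = select_connected(ts)
        assert len(out) == 0

    def test_top_percent_of_ten_thousand_pairs_is_exactly_one_hundred(self):
        out = select_connected(toy_trajectory(200), ci=0.5, top_fraction=0.01)
        assert len(out) == 100 * 100
        assert int(out.pairs["connected"].sum()) == 100

    def test_raising_ci_shrinks_the_eligible_set(self):
        ts = toy_trajectory(100)
        prev = None
        for ci in (0.5, 0.6, 0.7, 0.8, 0.9):
            cur = set(map(tuple, select_connected(ts, ci=ci).pairs[
                ["ligand_cell", "receiver_cell"]].to_numpy()))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_lowering_top_fraction_shrinks_the_connected_set(self):
        ts = toy_trajectory(100)
        prev = None
        for tf in (0.05, 0.02, 0.01, 0.005):
            pc = select_connected(ts, top_fraction=tf).connected
            cur = set(map(tuple,
                          pc[["ligand_cell", "receiver_cell"]].to_numpy()))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_invalid_thresholds_are_rejected(self):
        ts = toy_trajectory(50)
        with pytest.raises(ValueError):
            select_connected(ts, ci=1.0)
        with pytest.raises(ValueError):
            select_connected(ts, top_fraction=0.0)


class TestTrajectory:
    def test_identical_cells_make_normalization_degenerate(self):
        m = CountMatrix(np.ones((60, 40)),
                        [f"G{i}" for i in range(60)],
                        [f"C{j}" for j in range(40)], "scaled")
        spec = LigandReceptorSpec(
            GeneSet("l", ["G0", "G1"]), GeneSet("i", ["G2", "G3"]),
            GeneSet("r", ["G4", "G5"]), GeneSet("a", ["G6", "G7"]),
            frozenset({"T"}))
        with pytest.raises(ValueError):
            build_interaction_trajectory(
                m, spec, np.array(["T"] * 20 + ["M"] * 20))

    def test_planted_senders_occupy_the_extreme_ligand_decile(
            self, trajectory, study):
        _, _, truth = study
        lig = trajectory.side == "ligand"
        pos = np.abs(trajectory.trajectory_position[lig])
        top = pos >= np.quantile(pos[~np.isnan(pos)], 0.9)
        frac = (truth.cell_labels[lig][top] == "myeloidA").mean()
        assert frac >= 0.9

    def test_removing_induction_signal_weakens_sender_placement(
            self, scaled, study, lr_spec):
        _, _, truth = study
        with_signal = build_interaction_trajectory(
            scaled, lr_spec, truth.cell_labels)
        background = [g for g in scaled.gene_ids
                      if not any(g in gs.genes for gs in
                                 truth.program_gene_members.values())]
        null_spec = LigandReceptorSpec(
            lr_spec.ligand_genes, GeneSet("null-induction", background[:20]),
            lr_spec.receptor_genes, lr_spec.activation_genes,
            lr_spec.target_cell_labels)
        without_signal = build_interaction_trajectory(
            scaled, null_spec, truth.cell_labels)
        is_sender = truth.cell_labels == "myeloidA"
        with_eff = np.nanmedian(with_signal.n_eff[is_sender])
        without_eff = np.nanmedian(without_signal.n_eff[is_sender])
        assert with_eff > without_eff + 0.2
        n_with = len(select_connected(with_signal))
        n_without = len(select_connected(without_signal))
        assert n_without < n_with

    def test_normalized_scores_respect_the_unit_interval(self, trajectory):
        for arr in (trajectory.n_exp, trajectory.n_eff):
            vals = arr[~np.isnan(arr)]
            assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_smoothed_density_is_positive_for_scored_cells(self, trajectory):
        f = trajectory.f_hat[~np.isnan(trajectory.f_hat)]
        assert (f > 0).all()


def toy_grid(peaks, side=3):
    """Square grid; ``peaks`` maps gene prefix -> spot indices of 50-count peaks."""
    gene_ids = []
    for prefix in peaks:
        gene_ids += [f"{prefix}1", f"{prefix}2"]
    n = side * side
    counts = np.ones((n, len(gene_ids)))
    for j, (prefix, spots) in enumerate(peaks.items()):
        counts[np.asarray(spots), 2 * j] = 50
        counts[np.asarray(spots), 2 * j + 1] = 50
    rows, cols = np.divmod(np.arange(n), side)
    return SpatialGrid(
        spot_ids=np.array([f"S{i}" for i in range(n)], dtype=object),
        rows=rows, cols=cols, pitch_um=200.0, counts=counts,
        gene_ids=np.array(gene_ids, dtype=object), n_rows=side, n_cols=side)


def toy_pairs():
    df = pd.DataFrame({
        "ligand_cell": ["Ca"], "receiver_cell": ["Cb"],
        "ligand_cluster": ["M"], "receiver_cluster": ["T"],
        "pair_score": [0.9], "connected": [True],
        "distance_um": [np.nan], "status": ["retained"],
    })
    return ConnectedPairs(df, {})


class TestSpatialProximity:
    def test_colocated_signatures_give_zero_distance_and_retention(self):
        grid = toy_grid({"gA": [4], "gB": [4]})
        sigs = {"M": GeneSet("M", ("gA1", "gA2")),
                "T": GeneSet("T", ("gB1", "gB2"))}
        out = spatial_proximity_filter(toy_pairs(), grid, sigs)
        assert out.pairs.loc[0, "distance_um"] == pytest.approx(0.0, abs=1e-9)
        assert out.pairs.loc[0, "status"] == "retained"

    def test_two_pitch_separation_is_excluded_at_default_threshold(self):
        # Signature territories on columns 1 and 3 of a 5x5 grid: the top-5
        # spots of each signature are its whole column, so the centroids sit
        # exactly two pitches (400 um) apart.
        cols = np.arange(25) % 5
        grid = toy_grid({"gA": np.flatnonzero(cols == 1),
                         "gB": np.flatnonzero(cols == 3)}, side=5)
        sigs = {"M": GeneSet("M", ("gA1", "gA2")),
                "T": GeneSet("T", ("gB1", "gB2"))}
        out = spatial_proximity_filter(toy_pairs(), grid, sigs)
        assert out.pairs.loc[0, "distance_um"] == pytest.approx(400.0)
        assert out.pairs.loc[0, "status"] == "excluded"
        assert out.thresholds["max_dist_um"] == 150.0

    def test_unscorable_signature_marks_pairs_unmapped(self):
        grid = toy_grid({"gA": [4], "gB": [4]})
        sigs = {"M": GeneSet("M", ("gA1", "gA2")),
                "T": GeneSet("T", ("absent1", "absent2"))}
        with pytest.warns(UserWarning):
            out = spatial_proximity_filter(toy_pairs(), grid, sigs)
        assert out.pairs.loc[0, "status"] == "unmapped"


class TestNfcnScore:
    def test_single_pair_normalizes_to_one(self):
        sm = nfcn_score(toy_pairs())
        assert sm.scores.loc["M", "T"] == 1.0

    def test_empty_pairs_give_zero_matrix_over_known_labels(self):
        empty = ConnectedPairs(toy_pairs().pairs.iloc[:0], {})
        sm = nfcn_score(empty, labels=["M", "T"])
        assert (sm.scores.to_numpy() == 0).all()
        assert list(sm.scores.index) == ["M", "T"]

    def test_planted_interaction_dominates_the_score_matrix(
            self, pairs, study):
        _, _, truth = study
        sm = nfcn_score(pairs, labels=truth.cell_labels)
        assert sm.argmax() == ("myeloidA", "Texh")

    def test_spatially_excluded_pairs_do_not_contribute(self):
        df = toy_pairs().pairs.copy()
        df.loc[0, "status"] = "excluded"
        sm = nfcn_score(ConnectedPairs(df, {}), labels=["M", "T"])
        assert (sm.scores.to_numpy() == 0).all()


class TestRecovery:
    def test_connected_pairs_recover_planted_truth(self, pairs, study):
        _, _, truth = study
        precision, recall = pair_precision_recall(pairs,
                                                  truth.connected_pairs)
        assert precision >= 0.8
        assert recall >= 0.8

    def test_flagged_subset_is_also_precise(self, pairs, study):
        _, _, truth = study
        precision, _ = pair_precision_recall(pairs, truth.connected_pairs,
                                             subset="connected")
        assert precision >= 0.8
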