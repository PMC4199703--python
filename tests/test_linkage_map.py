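"""Pairwise linkage, grouping, seriation and Kosambi distances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tetramap import linkage_map as lm
from tetramap import simulate

from conftest import truth_presence


def _presence_df(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)


class TestPairwiseRf:
    def test_identical_vectors_closed_form(self):
        v = [1, 0] * 50
        link = lm.pairwise_rf(v, v)
        assert link.rf == 0.0
        assert link.lod == pytest.approx(100 * np.log10(2), abs=1e-9)
        assert link.n_informative == 100

    def test_ten_mismatches_closed_form(self):
        a = np.array([1, 0] * 50, dtype=float)
        b = a.copy()
        b[:10] = 1 - b[:10]
        link = lm.pairwise_rf(a, b)
        assert link.rf == pytest.approx(0.10)
        expected = 10 * np.log10(0.1) + 90 * np.log10(0.9) + 100 * np.log10(2)
        assert link.lod == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(15.98, abs=5e-3)

    def test_independent_vectors_are_unlinked(self):
        rng = np.random.default_rng(2)
        a, b = rng.integers(0, 2, 4000), rng.integers(0, 2, 4000)
        link = lm.pairwise_rf(a, b)
        assert link.rf == pytest.approx(0.5, abs=0.03) or link.rf == 0.5
        assert link.lod < 1.0

    def test_repulsion_like_truncated(self):
        a = np.array([1, 0] * 50, dtype=float)
        link = lm.pairwise_rf(a, 1 - a)
        assert link.rf == 0.5
        assert link.lod == 0.0

    def test_missing_handled_pairwise_complete(self):
        a = np.array([1, 0, 1, np.nan, 1, 0], dtype=float)
        b = np.array([1, 0, np.nan, 0, 1, 1], dtype=float)
        link = lm.pairwise_rf(a, b)
        assert link.n_informative == 4
        assert link.rf == pytest.approx(0.25)

    def test_zero_overlap_is_an_error(self):
        with pytest.raises(ValueError):
            lm.pairwise_rf([1, np.nan], [np.nan, 1])

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, (6, 80)).astype(float)
        x[rng.random((6, 80)) < 0.2] = np.nan
        df = pd.DataFrame(x, index=[f"m{k}" for k in range(6)])
        rf, lod, n = lm.pairwise_rf_matrix(df)
        for i in range(6):
            for j in range(i + 1, 6):
                link = lm.pairwise_rf(x[i], x[j])
                assert rf.iloc[i, j] == pytest.approx(link.rf)
                assert lod.iloc[i, j] == pytest.approx(link.lod, abs=1e-9)
                assert n.iloc[i, j] == link.n_informative

    def test_estimator_consistency_at_known_distances(self):
        """Mean rf estimate within 3 SE of the Haldane truth, n = 384."""
        for d in (5.0, 10.0, 20.0):
            haps = np.zeros((4, 2), dtype=np.uint8)
            haps[0] = 1
            chrom = simulate.ChromosomeModel(
                "c", 100.0, ("a", "b"), np.array([40.0, 40.0 + d])
            )
            parent = simulate.SimulatedParent("p", {"c": haps})
            rng = np.random.default_rng(int(d) + 7)
            reps = []
            for _ in range(12):
                g = simulate.simulate_gametes(parent, {"c": chrom}, 384, rng)["c"]
                pres = g.sum(axis=1)
                link = lm.pairwise_rf(pres[:, 0], pres[:, 1])
                reps.append(link.rf)
            r_true = (1 - np.exp(-2 * d / 100)) / 2
            se = np.sqrt(r_true * (1 - r_true) / 384) / np.sqrt(len(reps))
            assert abs(np.mean(reps) - r_true) < 3 * se


class TestGrouping:
    def test_two_far_markers_split_at_lod14(self):
        """80 cM apart with n = 384: mismatch rate ~0.4 -> LOD << 14."""
        rng = np.random.default_rng(8)
        a = rng.integers(0, 2, 384).astype(float)
        flip = rng.random(384) < (1 - np.exp(-2 * 0.8)) / 2
        b = np.where(flip, 1 - a, a)
        df = _presence_df({"m1": list(a), "m2": list(b)})
        groups, unplaced = lm.group_markers(df)
        assert groups == []
        assert set(unplaced) == {"m1", "m2"}

    def test_empty_matrix(self):
        groups, unplaced = lm.group_markers(pd.DataFrame())
        assert groups == [] and unplaced == []

    def test_groups_recover_homolog_partition_on_truth(self):
        cfg = simulate.SimConfig(
            n_chromosomes=2, markers_per_homolog=20, n_duplex_per_chrom=0, seed=19
        )
        mother, father, chroms, info = simulate.make_parents(cfg)
        truth = simulate.make_progeny(
            mother, father, chroms, info, cfg, np.random.default_rng(19)
        )
        pres = truth_presence(truth, "maternal")
        groups, unplaced = lm.group_markers(pres)
        assert len(groups) == 8  # 2 chromosomes x 4 homologs
        assert unplaced == []
        for g in groups:
            homs = {m.split("_")[1] + m.split("_")[0] for m in g}
            assert len(homs) == 1
            assert len(g) == 20


class TestOrdering:
    def test_three_marker_additive_toy(self):
        markers = ["a", "b", "c"]
        rf = pd.DataFrame(
            [[0, 0.05, 0.10], [0.05, 0, 0.05], [0.10, 0.05, 0]],
            index=markers, columns=markers,
        )
        lod = pd.DataFrame(20.0, index=markers, columns=markers)
        assert lm.order_group(["b", "c", "a"], rf, lod) == ["a", "b", "c"]

    def test_two_marker_group(self):
        markers = ["b", "a"]
        rf = pd.DataFrame([[0, 0.1], [0.1, 0]], index=markers, columns=markers)
        lod = pd.DataFrame(10.0, index=markers, columns=markers)
        assert lm.order_group(markers, rf, lod) == ["a", "b"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(23)
        true_pos = np.sort(rng.uniform(0, 60, 12))
        markers = [f"m{k:02d}" for k in range(12)]
        r = (1 - np.exp(-2 * np.abs(true_pos[:, None] - true_pos[None, :]) / 100)) / 2
        rf = pd.DataFrame(r, index=markers, columns=markers)
        lod = pd.DataFrame(30.0, index=markers, columns=markers)
        base = lm.order_group(markers, rf, lod)
        for seed in range(3):
            perm = list(np.random.default_rng(seed).permutation(markers))
            assert lm.order_group(perm, rf, lod) == base

    def test_order_recovery_on_simulated_homolog(self):
        """25 markers at 3 cM spacing, n = 384: Spearman |rho| >= 0.95."""
        haps = np.zeros((4, 25), dtype=np.uint8)
        haps[0] = 1
        pos = np.arange(25) * 3.0
        chrom = simulate.ChromosomeModel(
            "c", 72.0, tuple(f"m{k:02d}" for k in range(25)), pos
        )
        parent = simulate.SimulatedParent("p", {"c": haps})
        rng = np.random.default_rng(29)
        g = simulate.simulate_gametes(parent, {"c": chrom}, 384, rng)["c"].sum(axis=1)
        pres = pd.DataFrame(g.T.astype(float), index=chrom.marker_ids)
        rf, lod, _ = lm.pairwise_rf_matrix(pres)
        order = lm.order_group(list(chrom.marker_ids), rf, lod)
        rho = stats.spearmanr(
            [chrom.marker_ids.index(m) for m in order], range(25)
        ).statistic
        assert abs(rho) >= 0.95

    def test_no_qualifying_pairs_falls_back_to_id_order(self):
        markers = ["b", "a"]
        rf = pd.DataFrame([[0, 0.5], [0.5, 0]], index=markers, columns=markers)
        lod = pd.DataFrame(0.0, index=markers, columns=markers)
        with pytest.warns(UserWarning):
            assert lm.order_group(markers, rf, lod) == ["a", "b"]

    def test_two_opt_never_worse_than_insertion_seed(self):
        rng = np.random.default_rng(31)
        n = 15
        pos = np.sort(rng.uniform(0, 50, n))
        markers = [f"m{k:02d}" for k in range(n)]
        r = (1 - np.exp(-2 * np.abs(pos[:, None] - pos[None, :]) / 100)) / 2
        noise = rng.normal(0, 0.02, (n, n))
        r = np.clip(r + (noise + noise.T) / 2, 0, 0.49)
        np.fill_diagonal(r, 0)
        rf = pd.DataFrame(r, index=markers, columns=markers)
        lod = pd.DataFrame(30.0, index=markers, columns=markers)
        order = lm.order_group(markers, rf, lod)
        d = lm._distance_matrix(sorted(markers), rf, lod, lm.MapConfig())
        sarf_final = lm._sarf([sorted(markers).index(m) for m in order], d)
        sarf_id = lm._sarf(list(range(n)), d)
        assert sarf_final <= sarf_id + 1e-9


class TestKosambi:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.10, 10.14), (0.25, 27.47)],
    )
    def test_closed_form_values(self, r, expected):
        assert lm.kosambi_cm(r) == pytest.approx(expected, abs=5e-3)

    def test_inverse_values(self):
        assert lm.kosambi_inverse(0.0) == 0.0
        assert lm.kosambi_inverse(10.14) == pytest.approx(0.10, abs=1e-3)
        assert lm.kosambi_inverse(1e6) == pytest.approx(0.5, abs=1e-9)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.floats(0, 0.4999))
    def test_round_trip(self, r):
        assert lm.kosambi_inverse(lm.kosambi_cm(r)) == pytest.approx(r, abs=1e-10)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            lm.kosambi_cm(0.5)
        with pytest.raises(ValueError):
            lm.kosambi_inverse(-1.0)


class TestPositionsAndNaming:
    def test_positions_accumulate_kosambi(self):
        markers = ["a", "b", "c"]
        rf = pd.DataFrame(
            [[0, 0.1, 0.18], [0.1, 0, 0.1], [0.18, 0.1, 0]],
            index=markers, columns=markers,
        )
        pos = lm.map_positions(markers, rf)
        assert pos["a"] == 0.0
        assert pos["b"] == pytest.approx(10.14, abs=5e-3)
        assert pos["c"] == pytest.approx(20.27, abs=1e-2)

    def test_single_marker_at_zero(self):
        rf = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        assert lm.map_positions(["a"], rf)["a"] == 0.0

    def test_gap_fallback_to_spanning_pair(self):
        markers = ["a", "b", "c"]
        rf = pd.DataFrame(
            [[0, np.nan, 0.18], [np.nan, 0, 0.1], [0.18, 0.1, 0]],
            index=markers, columns=markers,
        )
        pos = lm.map_positions(markers, rf)
        # a-b falls back to half of the a-c Kosambi span
        assert pos["b"] == pytest.approx(lm.kosambi_cm(0.18) / 2, abs=1e-9)

    def test_homolog_naming_by_descending_count(self):
        groups = {
            "chr01": [["m1", "m2"], ["m3", "m4", "m5"], ["m6"], ["m7", "m8", "m9", "m0"]]
        }
        named = lm.name_homologs(groups)
        assert list(named["chr01_A"]) == ["m7", "m8", "m9", "m0"]
        assert list(named["chr01_B"]) == ["m3", "m4", "m5"]
        assert list(named["chr01_D"]) == ["m6"]

    def test_tie_breaks_by_smallest_marker_id(self):
        named = lm.name_homologs({"c": [["x2", "x3"], ["x1", "x4"]]})
        assert named["c_A"] == ["x1", "x4"]

    def test_more_than_four_groups_flagged(self):
        groups = {"c": [[f"m{k}"] for k in range(5)]}
        with pytest.warns(UserWarning):
            named = lm.name_homologs(groups)
        assert "c_E" in named

    def test_map_length_within_15_percent_on_dense_homolog(self):
        """60 cM homolog, dense markers, n = 384."""
        n_m = 21
        haps = np.zeros((4, n_m), dtype=np.uint8)
        haps[0] = 1
        pos = np.linspace(0, 60, n_m)
        chrom = simulate.ChromosomeModel(
            "c", 60.0, tuple(f"m{k:02d}" for k in range(n_m)), pos
        )
        parent = simulate.SimulatedParent("p", {"c": haps})
        rng = np.random.default_rng(37)
        g = simulate.simulate_gametes(parent, {"c": chrom}, 384, rng)["c"].sum(axis=1)
        pres = pd.DataFrame(g.T.astype(float), index=chrom.marker_ids)
        table, unplaced = lm.build_parent_map(pres, "maternal")
        assert table["linkage_group"].nunique() == 1
        length = table["position_cM"].max()
        assert 0.85 * 60 <= length <= 1.15 * 60
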