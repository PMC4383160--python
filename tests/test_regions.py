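from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from signet.anneal import AnnealConfig, sa_optimize, threshold_filter
from signet.heinz import Subnetwork, heinz_extract
from signet.io import ExpressionMatrix
from signet.regions import (RegionResult, empirical_quantile,
                            find_common_genes, overlap_matrix,
                            regulation_direction, specific_subnetwork)

from conftest import random_scored, toy_scored


def region(label, nodes, edges=()):
    sub = Subnetwork(tuple(sorted(nodes)),
                     tuple(tuple(sorted(e)) for e in edges), 0.0, 0.0, {})
    return RegionResult(label, sub)


class TestOverlapMatrix:
    def test_pairwise_count(self):
        summary = overlap_matrix([region("r1", {"A", "B", "C"}),
                                  region("r2", {"B", "C", "D"})])
        assert summary.intersections[frozenset({"r1", "r2"})] == 2
        assert summary.venn_cells[frozenset({"r1"})] == 1

    def test_identical_sets(self):
        summary = overlap_matrix([region("r1", {"A", "B"}),
                                  region("r2", {"A", "B"})])
        assert summary.intersections[frozenset({"r1", "r2"})] == 2
        assert summary.venn_cells[frozenset({"r1"})] == 0

    def test_against_bitmask_oracle_and_inclusion_exclusion(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(40)]
        sets = {f"r{k}": {g for g in universe if rng.random() < 0.4}
                for k in range(3)}
        summary = overlap_matrix([region(lbl, s) for lbl, s in sets.items()])
        # oracle: tabulate each gene's membership pattern
        patterns = {}
        for g in universe:
            pat = frozenset(lbl for lbl, s in sets.items() if g in s)
            if pat:
                patterns[pat] = patterns.get(pat, 0) + 1
        for k in range(1, 4):
            for combo in combinations(sets, k):
                key = frozenset(combo)
                want = sum(c for pat, c in patterns.items() if key <= pat)
                assert summary.intersections[key] == want
                assert summary.venn_cells[key] == patterns.get(key, 0)
        # inclusion-exclusion: per-region exclusive cells sum to set size
        for lbl, s in sets.items():
            total = sum(c for pat, c in summary.venn_cells.items()
                        if lbl in pat)
            assert total == len(s)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            overlap_matrix([region("r", {"A"}), region("r", {"B"})])


class TestFindCommonGenes:
    def test_high_degree_gene_in_both_regions(self):
        # star centers exceed each region's 90% degree quantile
        leaves1 = [f"a{i}" for i in range(10)]
        leaves2 = [f"b{i}" for i in range(10)]
        r1 = region("r1", ["G"] + leaves1, [("G", x) for x in leaves1])
        r2 = region("r2", ["G"] + leaves2, [("G", x) for x in leaves2])
        # sorted-index oracle: degrees [1]*10 + [10], ceil(0.9*11) = 10th
        assert empirical_quantile([1] * 10 + [10], 0.9) == 1
        assert find_common_genes([r1, r2], 0.9) == {"G"}

    def test_gene_absent_from_one_region_not_common(self):
        r1 = region("r1", "GAB", [("G", "A"), ("G", "B")])
        r2 = region("r2", "XYZ", [("X", "Y"), ("Y", "Z")])
        assert find_common_genes([r1, r2], 0.9) == set()

    def test_equal_degrees_yield_empty_set(self):
        r1 = region("r1", "ABCD", [("A", "B"), ("B", "C"), ("C", "D"),
                                   ("D", "A")])
        r2 = region("r2", "ABCD", [("A", "B"), ("B", "C"), ("C", "D"),
                                   ("D", "A")])
        assert find_common_genes([r1, r2], 0.9) == set()

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(13)
        regions = []
        for k in range(3):
            sn = random_scored(rng, n_nodes=20, edge_p=0.3)
            regions.append(RegionResult(
                f"r{k}", Subnetwork.from_nodes(sn, sn.graph.nodes)))
        prev = None
        for q in (0.5, 0.7, 0.9, 0.95):
            cur = find_common_genes(regions, q, min_regions=2)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_quantile_validation(self):
        with pytest.raises(ValueError):
            find_common_genes([region("r1", "AB", [("A", "B")]),
                               region("r2", "AB", [("A", "B")])], 1.5)


class TestSpecificSubnetwork:
    def test_common_removed_and_disjoint(self):
        rng = np.random.default_rng(41)
        sn = random_scored(rng, n_nodes=18, edge_p=0.3)
        common = set(sorted(sn.graph.nodes)[:4])
        cfg = AnnealConfig(t_initial=0.5, t_final=0.05, cooling=0.7,
                           steps_per_temp=10, seed=5)
        sub = specific_subnetwork(sn, common, cfg)
        assert not (set(sub.nodes) & common)

    def test_no_positive_left_flags_empty(self):
        sn = toy_scored([("a", "b"), ("b", "c")],
                        {"a": 2.0, "b": -1.0, "c": -2.0})
        sub = specific_subnetwork(sn, {"a"}, AnnealConfig())
        assert sub.is_empty and sub.flags["no_specific_module"]

    def test_empty_common_matches_plain_pipeline(self):
        rng = np.random.default_rng(77)
        sn = random_scored(rng, n_nodes=15, edge_p=0.3)
        cfg = AnnealConfig(t_initial=0.5, t_final=0.05, cooling=0.7,
                           steps_per_temp=10, seed=9)
        plain = threshold_filter(
            sa_optimize(heinz_extract(sn), sn, cfg), sn, cfg.threshold)
        via = specific_subnetwork(sn, set(), cfg)
        assert via.nodes == plain.nodes and via.edges == plain.edges


class TestRegulationDirection:
    def _expr(self, delta, seed=19):
        rng = np.random.default_rng(seed)
        ctrl = rng.normal(0.0, 0.5, 10)
        case = ctrl + delta
        df = pd.DataFrame([np.concatenate([ctrl, case])], index=["g"],
                          columns=[f"s{i}" for i in range(20)])
        cond = pd.Series(["control"] * 10 + ["case"] * 10, index=df.columns)
        return ExpressionMatrix(df, cond)

    def test_up_down_unchanged(self):
        expr_up = self._expr(2.0)
        assert regulation_direction(expr_up, "g") == "up"
        # permutation oracle on the same draw confirms significance
        vals = expr_up.data.loc["g"].to_numpy()
        obs = vals[10:].mean() - vals[:10].mean()
        rng = np.random.default_rng(1)
        exceed = sum(abs(rng.permutation(vals)[10:].mean()
                         - rng.permutation(vals)[:10].mean()) >= abs(obs)
                     for _ in range(500))
        assert (exceed + 1) / 501 < 0.05
        assert regulation_direction(self._expr(-2.0), "g") == "down"
        assert regulation_direction(self._expr(0.0), "g") == "unchanged"

    def test_absent_gene_errors(self):
        with pytest.raises(KeyError):
            regulation_direction(self._expr(1.0), "nope")
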