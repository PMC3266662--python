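"""Adjacent pairs, permutation null, cluster detection, promoter sharing,
and gene-characteristic comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sppr_omics import synthetic as syn
from sppr_omics.correlation import correlate_to_sppr
from sppr_omics.genome import (
    GenomeStructureError,
    adjacent_qualifying_pairs,
    compare_characteristics,
    detect_clusters,
    gene_characteristics,
    pair_permutation_test,
    promoter_sharing,
)
from tests.conftest import make_annotation


class TestAdjacentPairs:
    def test_basic_pair(self):
        ann, corr = make_annotation([0.8, 0.9, -0.8])
        pairs = adjacent_qualifying_pairs(ann, corr)
        assert len(pairs) == 1
        assert (pairs.iloc[0]["gene1"], pairs.iloc[0]["gene2"]) == ("g1", "g2")

    def test_scaffold_boundary_breaks_pair(self):
        ann1, corr1 = make_annotation([0.8, 0.9])
        ann2, corr2 = make_annotation([0.85], scaffold="scaffold_2")
        ann2["gene_id"] = ["g3"]
        corr2.index = pd.Index(["g3"], name="gene_id")
        ann = pd.concat([ann1, ann2], ignore_index=True)
        corr = pd.concat([corr1, corr2])
        pairs = adjacent_qualifying_pairs(ann, corr)
        assert len(pairs) == 1  # only (g1, g2); g2-g3 crosses the boundary

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(-1, 1, size=40)
        ann, corr = make_annotation(r)
        got = adjacent_qualifying_pairs(ann, corr, r_cut=0.5)
        expect = sum(
            1
            for i in range(39)
            if abs(r[i]) > 0.5 and abs(r[i + 1]) > 0.5 and r[i] * r[i + 1] > 0
        )
        assert len(got) == expect

    def test_missing_annotation_gene_errors(self):
        ann, corr = make_annotation([0.8, 0.9])
        corr.loc["ghost"] = 0.5
        with pytest.raises(GenomeStructureError, match="ghost"):
            adjacent_qualifying_pairs(ann, corr)


class TestPermutationTest:
    def test_all_qualifying_gives_p_one(self):
        ann, corr = make_annotation([0.9, 0.95, 0.85, 0.99])
        res = pair_permutation_test(ann, corr, n_perm=50, seed=0)
        assert res.p == pytest.approx(1.0)

    def test_no_qualifying_gives_p_one(self):
        ann, corr = make_annotation([0.1, -0.2, 0.05])
        res = pair_permutation_test(ann, corr, n_perm=50, seed=0)
        assert res.observed == 0 and res.p == pytest.approx(1.0)

    def test_zero_permutations_error(self):
        ann, corr = make_annotation([0.9, 0.8])
        with pytest.raises(GenomeStructureError):
            pair_permutation_test(ann, corr, n_perm=0)

    def test_matches_exact_enumeration_on_six_genes(self):
        r = np.array([0.9, 0.8, -0.75, 0.2, 0.85, -0.9])
        ann, corr = make_annotation(r)
        r_cut = 0.7

        def statistic(vals):
            in_pair = set()
            for i in range(len(vals) - 1):
                a, b = vals[i], vals[i + 1]
                if abs(a) > r_cut and abs(b) > r_cut and a * b > 0:
                    in_pair.update((i, i + 1))
            return len(in_pair)

        observed = statistic(r)
        exact = np.mean(
            [statistic(p) >= observed for p in itertools.permutations(r)]
        )
        res = pair_permutation_test(ann, corr, r_cut=r_cut, n_perm=10_000, seed=1)
        se = np.sqrt(exact * (1 - exact) / res.n_perm)
        assert abs(res.p - exact) < 3 * se

    def test_valid_p_under_null(self):
        # planted r=0 genome: permutation p should be stochastically >= uniform
        ps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ann, corr = make_annotation(rng.uniform(-1, 1, 15))
            ps.append(pair_permutation_test(ann, corr, n_perm=200, seed=seed).p)
        assert np.mean(np.asarray(ps) <= 0.25) <= 0.5  # far from anti-conservative


class TestDetectClusters:
    def test_seed_triplet_positive(self):
        ann, corr = make_annotation([0.9, 0.8, 0.75, -0.2])
        found = detect_clusters(ann, corr)
        assert len(found) == 1
        assert found[0].gene_ids == ["g1", "g2", "g3"] and found[0].sign == "+"

    def test_negative_cluster_only(self):
        ann, corr = make_annotation([0.9, 0.8, -0.9, -0.8, -0.75])
        found = detect_clusters(ann, corr)
        assert len(found) == 1
        assert found[0].gene_ids == ["g3", "g4", "g5"] and found[0].sign == "-"

    def test_extension_stops_at_sign_change(self):
        ann, corr = make_annotation([0.9, 0.8, 0.75, 0.3, -0.1])
        found = detect_clusters(ann, corr)
        assert len(found) == 1
        assert found[0].gene_ids == ["g1", "g2", "g3", "g4"]
        assert found[0].seed_triplet == ["g1", "g2", "g3"]

    def test_magnitude_thresholded_extension_flag(self):
        ann, corr = make_annotation([0.9, 0.8, 0.75, 0.3, -0.1])
        found = detect_clusters(ann, corr, extend_requires_cut=True)
        assert found[0].gene_ids == ["g1", "g2", "g3"]

    def test_zero_r_terminates_and_never_seeds(self):
        ann, corr = make_annotation([0.9, 0.0, 0.9, 0.8, 0.75])
        found = detect_clusters(ann, corr)
        assert len(found) == 1 and found[0].gene_ids == ["g3", "g4", "g5"]

    def test_reversal_invariance(self):
        rng = np.random.default_rng(8)
        r = rng.uniform(-1, 1, 30)
        ann, corr = make_annotation(r)
        fwd = detect_clusters(ann, corr)
        ann_rev, corr_rev = make_annotation(r[::-1])
        rev = detect_clusters(ann_rev, corr_rev)
        fwd_sets = sorted(
            tuple(sorted(int(g[1:]) for g in c.gene_ids)) for c in fwd
        )
        rev_sets = sorted(
            tuple(sorted(31 - int(g[1:]) for g in c.gene_ids)) for c in rev
        )
        assert fwd_sets == rev_sets

    def test_every_cluster_passes_own_invariants(self):
        rng = np.random.default_rng(9)
        r = rng.uniform(-1, 1, 60)
        ann, corr = make_annotation(r)
        for c in detect_clusters(ann, corr):
            c.validate(corr["r"], 0.7)

    def test_planted_clusters_recovered_exactly(self):
        for seed in range(5):
            spec = syn.SyntheticSpec(
                n_scaffolds=3,
                genes_per_scaffold=40,
                planted_clusters=[(1, 10, 5, 1), (2, 20, 4, -1)],
                cluster_corr=1.0,  # exact linear response: |r| = 1
                seed=seed,
            )
            ann = syn.generate_genome(spec)
            expr = syn.generate_expression(ann, spec)
            corr = correlate_to_sppr(expr, spec.sppr)
            found = detect_clusters(ann, corr)
            for sc, start, length, sign in spec.planted_clusters:
                genes = {syn.gene_id(sc, k) for k in range(start, start + length)}
                holder = [
                    c
                    for c in found
                    if genes <= set(c.gene_ids)
                    and c.sign == ("+" if sign > 0 else "-")
                ]
                assert holder, f"planted cluster not recovered at seed {seed}"


class TestPromoterSharing:
    def make(self, strands, starts, length=200):
        ann, corr = make_annotation([0.9] * len(strands))
        ann["strand"] = strands
        ann["start"] = starts
        ann["end"] = [s + length - 1 for s in starts]
        pairs = pd.DataFrame(
            {
                "scaffold_id": ["scaffold_1"],
                "gene1": ["g1"],
                "gene2": ["g2"],
                "r1": [0.9],
                "r2": [0.9],
                "sign": ["+"],
            }
        )
        return pairs, ann

    def test_divergent_within_gap_counted_twice(self):
        # TSS of minus-strand g1 is its end (999); g2 starts 800 bp later
        pairs, ann = self.make(["-", "+"], [800, 1799])
        res = promoter_sharing(pairs, ann)
        assert res.divergent_pairs == 1 and res.within_gap == 1

    def test_tandem_pair_excluded(self):
        pairs, ann = self.make(["+", "+"], [800, 1799])
        res = promoter_sharing(pairs, ann)
        assert res.divergent_pairs == 0

    def test_divergent_but_distant(self):
        pairs, ann = self.make(["-", "+"], [800, 2499])  # separation 1500
        res = promoter_sharing(pairs, ann)
        assert res.divergent_pairs == 1 and res.within_gap == 0

    def test_missing_strand_errors(self):
        pairs, ann = self.make(["-", "+"], [800, 1799])
        ann.loc[0, "strand"] = "?"
        with pytest.raises(GenomeStructureError):
            promoter_sharing(pairs, ann)


class TestGeneCharacteristics:
    def test_matches_direct_recomputation(self, small_spec, small_genome):
        expr = syn.generate_expression(small_genome, small_spec)
        cmap = small_spec.condition_map
        contrasts = [("D03", "D06"), ("D03", "HD"), ("D06", "HD")]
        table = gene_characteristics(small_genome, expr, cmap, contrasts)
        g = "g01_010"
        assert table.loc[g, "max_expr"] == pytest.approx(expr.loc[g].max())
        fcs = [
            abs(
                expr.loc[g, cmap[cmap == a].index].mean()
                - expr.loc[g, cmap[cmap == b].index].mean()
            )
            for a, b in contrasts
        ]
        assert table.loc[g, "max_abs_log2fc"] == pytest.approx(max(fcs))

    def test_constant_expression(self):
        ann, _ = make_annotation([0.0])
        expr = pd.DataFrame(
            [[8.0] * 6],
            index=pd.Index(["g1"], name="gene_id"),
            columns=[f"{c}_{i}" for c in ("A", "B") for i in (1, 2, 3)],
        )
        cmap = pd.Series({c: c.split("_")[0] for c in expr.columns})
        table = gene_characteristics(ann, expr, cmap, [("A", "B")])
        assert table.loc["g1", "max_expr"] == 8.0
        assert table.loc["g1", "max_abs_log2fc"] == 0.0

    def test_gene_without_expression_excluded(self):
        ann, _ = make_annotation([0.0, 0.0])
        expr = pd.DataFrame(
            [[8.0] * 4],
            index=pd.Index(["g1"], name="gene_id"),
            columns=[f"{c}_{i}" for c in ("A", "B") for i in (1, 2)],
        )
        cmap = pd.Series({c: c.split("_")[0] for c in expr.columns})
        table = gene_characteristics(ann, expr, cmap, [("A", "B")])
        assert list(table.index) == ["g1"]
        assert table.attrs["excluded"] == ["g2"]


class TestCompareCharacteristics:
    def table(self, values_a, values_b):
        idx = [f"a{i}" for i in range(len(values_a))] + [
            f"b{i}" for i in range(len(values_b))
        ]
        t = pd.DataFrame({"gc": list(values_a) + list(values_b)}, index=idx)
        return t, [f"a{i}" for i in range(len(values_a))], [
            f"b{i}" for i in range(len(values_b))
        ]

    def test_identical_values_zero_coefficient(self):
        t, a, b = self.table([5, 5, 5], [5, 5, 5])
        res = compare_characteristics(t, a, b, "gc")
        assert res.coefficient == pytest.approx(0.0)

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(10)
        t, a, b = self.table(rng.normal(10, 1, 200), rng.normal(8, 1, 200))
        res = compare_characteristics(t, a, b, "gc")
        se = np.sqrt(2 / 200)
        assert abs(res.coefficient - 2.0) < 3 * se
        assert res.p < 1e-6

    def test_errors(self):
        t, a, b = self.table([1, 2], [3, 4])
        with pytest.raises(GenomeStructureError):
            compare_characteristics(t, [], b, "gc")
        with pytest.raises(GenomeStructureError):
            compare_characteristics(t, a, a, "gc")
        with pytest.raises(GenomeStructureError):
            compare_characteristics(t, ["a0"], b, "gc")
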