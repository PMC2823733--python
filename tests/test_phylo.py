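import math

import numpy as np
import pytest

from cladesig.msa import MSA
from cladesig.phylo import (BlockFilterParams, DistanceMatrix, PhyloError,
                            bootstrap_support, concatenate, deep_split_support,
                            filter_blocks, kimura_distance, nj_tree,
                            pairwise_kimura, KIMURA_P_MAX)
from cladesig.simulate import deep_split_alignment

from conftest import random_binary_tree, tree_path_distances


class TestConcatenate:
    def _pair(self):
        a = MSA(["t1", "t2", "t3", "t4", "t5"], ["ACDEFGHIKL"] * 5)
        b = MSA(["t1", "t2", "t3", "t4", "t5"], ["MNPQRSTVWYMNPQR"] * 5)
        return a, b

    def test_widths_and_intervals(self):
        a, b = self._pair()
        cat = concatenate([("g1", a), ("g2", b)])
        assert cat.msa.ncol == 25
        assert cat.intervals == [("g1", 0, 10), ("g2", 10, 25)]

    def test_pad_policy_fills_gaps(self):
        a, b = self._pair()
        b2 = MSA(b.ids[:-1], b.rows[:-1])
        cat = concatenate([("g1", a), ("g2", b2)], taxon_policy="pad")
        row = cat.msa.row("t5")
        assert row[10:] == "-" * 15

    def test_strict_policy_names_taxon(self):
        a, b = self._pair()
        b2 = MSA(b.ids[:-1], b.rows[:-1])
        with pytest.raises(PhyloError, match="t5"):
            concatenate([("g1", a), ("g2", b2)], taxon_policy="strict")

    def test_duplicate_gene_ids(self):
        a, b = self._pair()
        with pytest.raises(PhyloError, match="duplicate"):
            concatenate([("g1", a), ("g1", b)])

    def test_length_conservation(self):
        a, b = self._pair()
        cat = concatenate([("g1", a), ("g2", b)])
        assert cat.msa.ncol == a.ncol + b.ncol


class TestFilterBlocks:
    def test_gap_half_rule(self):
        # one column gapped in 4/6 sequences among conserved context
        rows = ["A" * 20 + "W" + "A" * 20,
                "A" * 20 + "W" + "A" * 20,
                "A" * 20 + "-" + "A" * 20,
                "A" * 20 + "-" + "A" * 20,
                "A" * 20 + "-" + "A" * 20,
                "A" * 20 + "-" + "A" * 20]
        msa = MSA([f"s{i}" for i in range(6)], rows)
        _, kept = filter_blocks(msa)
        assert 20 not in kept
        assert len(kept) == 40

    def test_fully_conserved_passes_through(self):
        msa = MSA([f"s{i}" for i in range(6)], ["ACDEFGHIKL" * 5] * 6)
        filtered, kept = filter_blocks(msa)
        assert kept == list(range(50))
        assert filtered.rows == msa.rows

    def test_long_nonconserved_stretch_removed(self):
        # 9 nonconserved columns (all-distinct residues) inside conserved runs
        rng = np.random.default_rng(0)
        letters = "ACDEFG"
        noncons = ["".join(letters[(i + j) % 6] for j in range(9))
                   for i in range(6)]
        rows = ["A" * 20 + noncons[i] + "A" * 20 for i in range(6)]
        msa = MSA([f"s{i}" for i in range(6)], rows)
        _, kept = filter_blocks(msa, BlockFilterParams(b3=8))
        assert kept == list(range(20)) + list(range(29, 49))
        # with b3 = 9 the stretch is short enough to keep
        _, kept9 = filter_blocks(msa, BlockFilterParams(b3=9))
        assert len(kept9) == 49

    def test_short_block_dropped(self):
        msa = MSA([f"s{i}" for i in range(6)], ["ACDEFGHI"] * 6)
        _, kept = filter_blocks(msa, BlockFilterParams(b4=10))
        assert kept == []

    def test_idempotence(self):
        # mostly conserved alignment with scattered noise and gaps, so the
        # first pass removes something but not everything
        rng = np.random.default_rng(3)
        base = np.frombuffer((b"ACDEFGHIKLMNPQRSTVWY" * 10), dtype=np.uint8)
        arr = np.tile(base, (8, 1)).copy()
        letters = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY-", dtype=np.uint8)
        noise = rng.random(arr.shape) < 0.45
        arr[noise] = letters[rng.integers(0, 21, size=int(noise.sum()))]
        msa = MSA([f"s{i}" for i in range(8)],
                  [bytes(r).decode() for r in arr])
        once, kept1 = filter_blocks(msa)
        assert 0 < len(kept1) < msa.ncol
        twice, kept2 = filter_blocks(once)
        assert kept2 == list(range(len(kept1)))
        assert twice.rows == once.rows

    def test_output_subset_and_gap_mode_invariant(self):
        rng = np.random.default_rng(9)
        letters = np.frombuffer(b"AC-", dtype=np.uint8)
        arr = letters[rng.integers(0, 3, size=(6, 120))]
        msa = MSA([f"s{i}" for i in range(6)],
                  [bytes(r).decode() for r in arr])
        _, kept = filter_blocks(msa)
        assert kept == sorted(set(kept))
        for j in kept:
            gapfrac = msa.column(j).count("-") / msa.nseq
            assert gapfrac <= 0.5

    def test_too_few_sequences(self):
        msa = MSA(["a", "b", "c"], ["ACDE"] * 3)
        with pytest.raises(PhyloError, match="4"):
            filter_blocks(msa)


class TestKimura:
    def test_identical_sequences_zero(self):
        msa = MSA(["a", "b"], ["ACDEFGHIKL", "ACDEFGHIKL"])
        dm = pairwise_kimura(msa)
        assert dm.matrix[0, 1] == 0.0

    def test_closed_form_p_01(self):
        # 1 difference in 10 sites: p = 0.1
        msa = MSA(["a", "b"], ["ACDEFGHIKL", "ACDEFGHIKW"])
        dm = pairwise_kimura(msa)
        assert dm.matrix[0, 1] == pytest.approx(-math.log(1 - 0.1 - 0.2 * 0.01),
                                                abs=1e-12)

    def test_domain_error_at_p_09(self):
        msa = MSA(["a", "b"], ["AAAAAAAAAA", "CCCCCCCCCA"])
        with pytest.raises(PhyloError, match="a, b"):
            pairwise_kimura(msa)

    def test_domain_boundary_constant(self):
        # 0.2 p^2 + p - 1 = 0 at the boundary
        assert 0.2 * KIMURA_P_MAX ** 2 + KIMURA_P_MAX - 1 == pytest.approx(0, abs=1e-12)
        with pytest.raises(PhyloError):
            kimura_distance(KIMURA_P_MAX)

    def test_gapped_sites_excluded(self):
        msa = MSA(["a", "b"], ["AC-EFGHIKL", "ACD-FGHIKW"])
        dm = pairwise_kimura(msa)
        # 8 comparable sites, 1 difference
        assert dm.matrix[0, 1] == pytest.approx(
            kimura_distance(1 / 8), abs=1e-12)

    def test_zero_comparable_sites(self):
        msa = MSA(["a", "b"], ["AC--", "--DE"])
        with pytest.raises(PhyloError, match="comparable"):
            pairwise_kimura(msa)

    def test_monotone_and_above_p(self):
        ps = np.linspace(0, 0.85, 200)
        ds = [kimura_distance(p) for p in ps]
        assert ds[0] == 0.0
        assert all(b > a for a, b in zip(ds, ds[1:]))
        assert all(d >= p for d, p in zip(ds, ps))


class TestNJ:
    def test_additive_quartet(self):
        # distances from tree ((a:1,b:2):1,(c:3,d:4))
        taxa = ["a", "b", "c", "d"]
        m = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(taxa, m))
        assert frozenset({"a", "b"}) in tree.bipartitions() or \
            frozenset({"c", "d"}) in tree.bipartitions()
        assert tree.find("a").length == pytest.approx(1.0)
        assert tree.find("b").length == pytest.approx(2.0)
        assert tree.find("c").length == pytest.approx(3.0)
        assert tree.find("d").length == pytest.approx(4.0)

    def test_three_taxa_closed_form(self):
        taxa = ["a", "b", "c"]
        m = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(taxa, m))
        assert tree.find("a").length == pytest.approx(0.5)
        assert tree.find("b").length == pytest.approx(1.5)
        assert tree.find("c").length == pytest.approx(2.5)

    def test_nan_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(PhyloError, match="NaN"):
            DistanceMatrix(["a", "b", "c"], m)

    def test_too_few_taxa(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    @pytest.mark.parametrize("seed", range(10))
    def test_consistency_on_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        true = random_binary_tree(n, rng, rooted=False)
        taxa, D = tree_path_distances(true)
        recovered = nj_tree(DistanceMatrix(taxa, D))
        assert recovered.robinson_foulds(true) == 0


class TestBootstrap:
    def test_deterministic_and_resampling_contract(self):
        msa, _ = deep_split_alignment(seed=3, ncol=120)
        t1, s1 = bootstrap_support(msa, n_reps=20, seed=11)
        t2, s2 = bootstrap_support(msa, n_reps=20, seed=11)
        assert s1 == s2
        assert t1.write() == t2.write()
        _, s3 = bootstrap_support(msa, n_reps=20, seed=12)
        assert set(s3) == set(s1)  # same bipartitions of the base tree

    def test_deep_split_high_support(self):
        msa, left = deep_split_alignment(seed=7, ncol=400)
        tree, support = bootstrap_support(msa, n_reps=100, seed=7)
        value = deep_split_support(tree, support, left)
        assert value is not None and value >= 95.0
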