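"""Canonical k-mer sets, Jaccard/UPGMA, anchoring and crossover calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panmosaic import kmer as km

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(RC)[::-1]


def py_canonical_set(seqs, k):
    """Independent string-level canonicalization oracle."""
    out = set()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) <= set("ACGT"):
                out.add(min(w, revcomp(w)))
    return out


def decode_set(arr, k):
    return {km.decode_kmer(c, k) for c in arr}


dna = st.text(alphabet="ACGT", min_size=12, max_size=60)


class TestCanonicalization:
    def test_hand_enumeration(self):
        # windows ACG,CGT,GTA,TAC,ACG -> canonical {ACG, GTA}
        assert decode_set(km.canonical_set(["ACGTACG"], 3), 3) == {"ACG", "GTA"}

    @given(dna)
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_reverse_complement_symmetry(self, seq):
        a = km.canonical_set([seq], 11)
        b = km.canonical_set([revcomp(seq)], 11)
        assert np.array_equal(a, b)

    @given(dna)
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_matches_string_oracle(self, seq):
        assert decode_set(km.canonical_set([seq], 11), 11) == py_canonical_set([seq], 11)

    def test_non_acgt_windows_skipped(self):
        with_n = km.canonical_set(["ACGTNACGTACGT"], 11)
        assert decode_set(with_n, 11) == py_canonical_set(["ACGTNACGTACGT"], 11)

    def test_all_n_genome_is_empty_and_flagged(self):
        with pytest.warns(UserWarning, match="no valid"):
            idx = km.build_index({"g": "N" * 100}, k=11)
        assert idx.sets["g"].size == 0

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            km.build_index({"g": "ACGTACGTACGTACGT"}, k=12)


class TestJaccard:
    def test_identical_and_disjoint(self):
        idx = km.build_index(
            {"a": "ACGTACGTACGTACG", "b": "ACGTACGTACGTACG"}, k=11
        )
        assert km.jaccard_matrix(idx).value("a", "b") == 1.0

    def test_fraction(self):
        idx = km.KmerIndex(
            k=11,
            genome_ids=["a", "b"],
            sets={
                "a": np.array([1, 2, 3], dtype=np.uint64),
                "b": np.array([3, 10, 11], dtype=np.uint64),
            },
        )
        assert km.jaccard_matrix(idx).value("a", "b") == pytest.approx(1 / 5)

    def test_empty_genome_is_missing_not_zero(self):
        idx = km.KmerIndex(
            k=11,
            genome_ids=["a", "b"],
            sets={"a": np.array([1], dtype=np.uint64), "b": np.empty(0, np.uint64)},
        )
        sim = km.jaccard_matrix(idx)
        assert np.isnan(sim.value("a", "b"))
        assert sim.missing_pairs() == [("a", "b")]

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, deadline=None, max_examples=25)
    def test_jaccard_distance_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        universe = np.arange(40, dtype=np.uint64)
        sets = {
            g: np.unique(rng.choice(universe, size=rng.integers(5, 30)))
            for g in "abc"
        }
        idx = km.KmerIndex(k=11, genome_ids=list("abc"), sets=sets)
        d = 1.0 - km.jaccard_matrix(idx).values
        for i, j, l in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
            assert d[i, j] <= d[i, l] + d[l, j] + 1e-12


class TestUPGMA:
    def test_three_genome_arithmetic(self):
        sim = km.SimilarityMatrix(
            genome_ids=["A", "B", "C"],
            values=np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.5], [0.5, 0.5, 1.0]]),
        )
        newick = km.average_linkage_tree(sim)
        assert newick == "((A:0.05,B:0.05):0.2,C:0.25);"

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(5)
        n = 6
        d = rng.uniform(0.1, 0.9, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"g{i}" for i in range(n)]
        sim = km.SimilarityMatrix(genome_ids=ids, values=1.0 - d)
        newick = km.average_linkage_tree(sim)
        linkage = average(squareform(d))
        # scipy merge heights should appear as 2x the node heights in the newick
        import re

        bls = sorted(float(x) for x in re.findall(r":([0-9.]+)", newick))
        assert len(bls) == 2 * n - 2
        # reconstruct node heights: leaf-to-root path sums must be ultrametric
        heights = sorted(linkage[:, 2] / 2)
        # the largest merge height equals the tree's total depth
        depth = _tree_depth(newick)
        assert depth == pytest.approx(heights[-1], rel=1e-9)

    def test_missing_entry_error_names_pair(self):
        sim = km.SimilarityMatrix(
            genome_ids=["A", "B"], values=np.array([[1.0, np.nan], [np.nan, 1.0]])
        )
        with pytest.raises(ValueError, match="A"):
            km.average_linkage_tree(sim)


def _tree_depth(newick: str) -> float:
    """Depth of the first leaf (ultrametric: all leaves equal)."""
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    leaf = tree.get_terminals()[0]
    return sum(c.branch_length or 0 for c in tree.get_path(leaf))


class TestKmerScoreHistogram:
    def test_identical_and_disjoint_genomes(self):
        seq = "ACGTACGTAGCTAGCTACG"
        idx = km.build_index({"a": seq, "b": seq}, k=11)
        hist = km.kmer_score_histogram(idx)
        assert hist.counts[1] == 0 and hist.counts[2] > 0

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACGT"), 300))
        genomes = {}
        for g in range(4):
            arr = list(base)
            for p in rng.choice(300, size=15, replace=False):
                arr[p] = "ACGT"[rng.integers(4)]
            genomes[f"g{g}"] = "".join(arr)
        idx = km.build_index(genomes, k=11)
        hist = km.kmer_score_histogram(idx)
        tally = {}
        per_genome = {g: py_canonical_set([s], 11) for g, s in genomes.items()}
        for kmer in set().union(*per_genome.values()):
            s = sum(kmer in ks for ks in per_genome.values())
            tally[s] = tally.get(s, 0) + 1
        assert {s: int(c) for s, c in enumerate(hist.counts) if c} == tally

    def test_total_equals_union_size(self):
        idx = km.build_index(
            {"a": "ACGTACGTAGCTAGCTACG", "b": "TTTTACGTACGTAGCAAAA"}, k=11
        )
        hist = km.kmer_score_histogram(idx)
        assert hist.total == idx.union().size


class TestAnchoring:
    def test_verbatim_substring_fully_conserved(self):
        rng = np.random.default_rng(2)
        ref = "".join(rng.choice(list("ACGT"), 30_000))
        idx = km.build_index({"ref": ref}, k=31)
        track = km.anchor_conservation(idx, ref[5_000:25_000], window=2_000, step=2_000)
        assert all(w.fraction == 1.0 for w in track.windows if w.informative)

    def test_unrelated_query_near_zero(self):
        rng = np.random.default_rng(3)
        ref = "".join(rng.choice(list("ACGT"), 30_000))
        query = "".join(rng.choice(list("ACGT"), 20_000))
        idx = km.build_index({"ref": ref}, k=31)
        track = km.anchor_conservation(idx, query, window=2_000, step=2_000)
        assert track.mean_conservation() < 0.01

    def test_window_shorter_than_k_rejected(self):
        idx = km.build_index({"r": "ACGT" * 100}, k=31)
        with pytest.raises(ValueError, match="window"):
            km.anchor_conservation(idx, "ACGT" * 100, window=20, step=20)


class TestVarinHaplotype:
    def test_donor_copy_selected(self):
        rng = np.random.default_rng(4)
        donor = "".join(rng.choice(list("ACGT"), 40_000))
        other = "".join(rng.choice(list("ACGT"), 40_000))
        idx = km.build_index({"donor": donor}, k=31)
        res = km.identify_varin_haplotype(idx, donor, other, window=4_000, step=4_000)
        assert res.label == "A" and res.gap > 0.9

    def test_identical_haplotypes_ambiguous(self):
        rng = np.random.default_rng(5)
        donor = "".join(rng.choice(list("ACGT"), 40_000))
        idx = km.build_index({"donor": donor}, k=31)
        res = km.identify_varin_haplotype(idx, donor, donor, window=4_000, step=4_000)
        assert res.label == "ambiguous"


def _track(fracs, window=1_000, ref="A"):
    wins = [
        km.AnchorWindow(start=i * window, end=(i + 1) * window, fraction=f,
                        n_valid=900, n_total=1000)
        for i, f in enumerate(fracs)
    ]
    return km.AnchorTrack(query_id="q", reference_id=ref, window_size=window,
                          step=window, windows=wins)


class TestCallCrossovers:
    def test_single_parent_no_calls(self):
        ta = _track([0.9] * 10, ref="A")
        tb = _track([0.3] * 10, ref="B")
        assert km.call_crossovers(ta, tb) == []

    def test_single_switch_at_boundary(self):
        ta = _track([0.9] * 5 + [0.3] * 5, ref="A")
        tb = _track([0.3] * 5 + [0.9] * 5, ref="B")
        calls = km.call_crossovers(ta, tb)
        assert len(calls) == 1
        assert calls[0].position == 5_000
        assert (calls[0].from_parent, calls[0].to_parent) == ("A", "B")

    def test_short_flips_suppressed(self):
        fa = [0.9, 0.9, 0.9, 0.3, 0.9, 0.9, 0.9, 0.3, 0.9, 0.9]
        ta = _track(fa, ref="A")
        tb = _track([1.2 - f for f in fa], ref="B")
        assert km.call_crossovers(ta, tb, min_run=3) == []

    def test_uninformative_windows_ignored(self):
        ta = _track([0.9] * 4 + [0.5] * 2 + [0.3] * 4, ref="A")
        tb = _track([0.3] * 4 + [0.5] * 2 + [0.9] * 4, ref="B")
        calls = km.call_crossovers(ta, tb, margin=0.2, min_run=3)
        assert len(calls) == 1
        assert calls[0].position == (4_000 + 6_000) // 2

    def test_mismatched_windows_rejected(self):
        with pytest.raises(ValueError):
            km.call_crossovers(_track([0.9] * 3), _track([0.9] * 4, ref="B"))
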