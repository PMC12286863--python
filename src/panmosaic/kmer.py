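"""Canonical k-mer indexing, Jaccard similarity, UPGMA clustering and
reference anchoring with trio crossover calling.

Genomes are reduced to sets of canonical k-mers (the lexicographic minimum
of each k-mer and its reverse complement, so a sequence and its reverse
complement index identically).  k defaults to 31 and must be odd so no
k-mer is its own reverse complement.  K-mers are packed 2 bits/base into
uint64 (k <= 31), which keeps whole-genome sets as sorted integer arrays
and makes window queries vectorizable.

Anchoring scores each window of a query sequence by the fraction of its
valid canonical k-mers found in a reference index; on a haplotype-resolved
offspring anchored against both parents, a sustained switch of the better-
conserved parent marks a meiotic crossover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "KmerIndex",
    "SimilarityMatrix",
    "AnchorWindow",
    "AnchorTrack",
    "CrossoverCall",
    "build_index",
    "jaccard_matrix",
    "average_linkage_tree",
    "kmer_score_histogram",
    "anchor_conservation",
    "identify_varin_haplotype",
    "call_crossovers",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
    _CODE[base + 32] = i  # lower case

_CHUNK = 1 << 20


def encode_canonical(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes for every window of ``seq``.

    Returns ``(kmers, valid)`` of length ``len(seq) - k + 1``: packed uint64
    canonical codes and a validity mask (False where the window contains a
    non-ACGT symbol; the code there is meaningless).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical form would be ambiguous)")
    if not 1 <= k <= 31:
        raise ValueError("k must be in 1..31")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    fwd_w = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    rev_w = (4 ** np.arange(k, dtype=np.uint64))
    kmers = np.empty(n, dtype=np.uint64)
    valid = np.empty(n, dtype=bool)
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        win = np.lib.stride_tricks.sliding_window_view(codes[lo : hi + k - 1], k)
        ok = (win < 4).all(axis=1)
        w64 = np.where(win < 4, win, 0).astype(np.uint64)
        fwd = w64 @ fwd_w
        rev = (np.uint64(3) - w64) @ rev_w
        kmers[lo:hi] = np.minimum(fwd, rev)
        valid[lo:hi] = ok
    return kmers, valid


def canonical_set(seqs: Iterable[str], k: int) -> np.ndarray:
    """Sorted unique canonical k-mers over a collection of sequences."""
    parts = []
    for seq in seqs:
        kmers, valid = encode_canonical(seq, k)
        if valid.any():
            parts.append(kmers[valid])
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(k - 1, -1, -1):
        out.append("ACGT"[(int(code) >> (2 * shift)) & 3])
    return "".join(out)


@dataclass
class KmerIndex:
    """Per-genome canonical k-mer sets, stored as sorted uint64 arrays."""

    k: int
    genome_ids: list[str]
    sets: dict[str, np.ndarray]
    _union: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if set(self.genome_ids) != set(self.sets):
            raise ValueError("genome_ids and sets disagree")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def union(self) -> np.ndarray:
        if self._union is None:
            arrays = [self.sets[g] for g in self.genome_ids if self.sets[g].size]
            self._union = (
                np.unique(np.concatenate(arrays)) if arrays else np.empty(0, np.uint64)
            )
        return self._union

    def empty_genomes(self) -> list[str]:
        return [g for g in self.genome_ids if self.sets[g].size == 0]


def build_index(
    sequences: Mapping[str, object], k: int = 31
) -> KmerIndex:
    """Index genomes from FASTA paths or in-memory sequence lists.

    ``sequences`` maps genome id -> FASTA path, a single sequence string,
    or an iterable of sequence strings.  K-mers containing non-ACGT symbols
    are skipped; a genome with no valid k-mers is kept with an empty set
    and a warning.
    """
    if not sequences:
        raise ValueError("no sequences given")
    sets: dict[str, np.ndarray] = {}
    for gid, src in sequences.items():
        seqs = _as_sequences(src)
        sets[gid] = canonical_set(seqs, k)
        if sets[gid].size == 0:
            warnings.warn(f"genome {gid!r} yielded no valid {k}-mers")
    return KmerIndex(k=k, genome_ids=list(sequences), sets=sets)


def _as_sequences(src: object) -> list[str]:
    if isinstance(src, Path) or (
        isinstance(src, str) and len(src) < 250 and Path(src).exists()
    ):
        from Bio import SeqIO

        return [str(rec.seq) for rec in SeqIO.parse(str(src), "fasta")]
    if isinstance(src, str):
        return [src]
    return [str(s) for s in src]  # type: ignore[union-attr]


@dataclass
class SimilarityMatrix:
    genome_ids: list[str]
    values: np.ndarray  # NaN where a genome's k-mer set was empty

    def value(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.values[i, j])

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.genome_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.genome_ids[i], self.genome_ids[j]))
        return out


def jaccard_matrix(index: KmerIndex) -> SimilarityMatrix:
    """Pairwise Jaccard similarity |A∩B| / |A∪B| over genome k-mer sets.

    Similarity involving an empty set is undefined and reported as NaN.
    """
    if index.n_genomes < 2:
        raise ValueError("need at least two genomes")
    ids = index.genome_ids
    n = len(ids)
    values = np.ones((n, n))
    for i in range(n):
        a = index.sets[ids[i]]
        if a.size == 0:
            values[i, :] = values[:, i] = np.nan
            values[i, i] = 1.0
    for i in range(n):
        a = index.sets[ids[i]]
        if a.size == 0:
            continue
        for j in range(i + 1, n):
            b = index.sets[ids[j]]
            if b.size == 0:
                continue
            inter = np.intersect1d(a, b, assume_unique=True).size
            values[i, j] = values[j, i] = inter / (a.size + b.size - inter)
    return SimilarityMatrix(genome_ids=list(ids), values=values)


@dataclass
class _Cluster:
    members: tuple[str, ...]
    height: float
    newick: str


def average_linkage_tree(similarity: SimilarityMatrix) -> str:
    """UPGMA dendrogram of distance = 1 - Jaccard, as a Newick string.

    Ties in the minimum inter-cluster distance are broken by the
    lexicographically smallest pair of cluster labels, making the merge
    order deterministic.  Branch lengths follow the ultrametric convention
    (node height = half the merge distance).
    """
    if np.isnan(similarity.values).any():
        pairs = similarity.missing_pairs()
        raise ValueError(f"similarity missing for pairs: {pairs[:3]}")
    dist = {}
    ids = list(similarity.genome_ids)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            dist[frozenset((a, b))] = 1.0 - float(similarity.values[i, j])
    clusters: dict[str, _Cluster] = {
        g: _Cluster(members=(g,), height=0.0, newick=g) for g in ids
    }
    while len(clusters) > 1:
        labels = sorted(clusters)
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                d = dist[frozenset((a, b))]
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best  # type: ignore[misc]
        ca, cb = clusters.pop(a), clusters.pop(b)
        height = d / 2.0
        merged = _Cluster(
            members=ca.members + cb.members,
            height=height,
            newick=(
                f"({ca.newick}:{height - ca.height:.10g},"
                f"{cb.newick}:{height - cb.height:.10g})"
            ),
        )
        label = min(a, b)
        na, nb = len(ca.members), len(cb.members)
        for other in clusters:
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((label, other))] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset((a, b)), None)
        clusters[label] = merged
    root = next(iter(clusters.values()))
    return root.newick + ";"


def kmer_score_histogram(index: KmerIndex):
    """P(s) over k-mers: how many distinct canonical k-mers occur in exactly
    ``s`` genomes.  Plugs directly into :func:`panmosaic.curves.collector_curve`.
    """
    from .curves import ScoreHistogram

    H = index.n_genomes
    arrays = [index.sets[g] for g in index.genome_ids if index.sets[g].size]
    counts = np.zeros(H + 1, dtype=np.int64)
    if arrays:
        _, occ = np.unique(np.concatenate(arrays), return_counts=True)
        tally = np.bincount(occ, minlength=H + 1)
        counts[: tally.size] = tally[: H + 1]
    return ScoreHistogram(H=H, counts=counts)


@dataclass
class AnchorWindow:
    start: int
    end: int
    fraction: float  # conserved fraction; NaN when no valid k-mers
    n_valid: int
    n_total: int

    @property
    def informative(self) -> bool:
        # windows dominated by Ns/masked sequence carry no anchoring signal
        return self.n_total > 0 and self.n_valid / self.n_total >= 0.5

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class AnchorTrack:
    query_id: str
    reference_id: str
    window_size: int
    step: int
    windows: list[AnchorWindow]

    def fractions(self) -> np.ndarray:
        return np.array([w.fraction for w in self.windows])

    def mean_conservation(self) -> float:
        vals = [w.fraction for w in self.windows if w.informative]
        return float(np.mean(vals)) if vals else float("nan")


def anchor_conservation(
    reference: KmerIndex,
    query: str,
    window: int = 10_000,
    step: int = 10_000,
    query_id: str = "query",
    reference_id: str = "reference",
) -> AnchorTrack:
    """Per-window conserved k-mer fraction of ``query`` in ``reference``.

    Each window [start, start+window) is scored by the fraction of its
    valid canonical k-mers present in the union of the reference's sets.
    """
    k = reference.k
    if window < k:
        raise ValueError(f"window {window} shorter than k={k}")
    if window < 10 * k:
        warnings.warn(f"window {window} < 10*k; fractions will be noisy")
    if step < 1:
        raise ValueError("step must be positive")
    ref = reference.union()
    kmers, valid = encode_canonical(query, k)
    # membership of every window k-mer in the sorted reference array
    hit = np.zeros(kmers.size, dtype=bool)
    if kmers.size and ref.size:
        pos = np.searchsorted(ref, kmers)
        pos[pos == ref.size] = ref.size - 1
        hit = ref[pos] == kmers
    windows = []
    L = len(query)
    for start in range(0, max(L - k + 1, 1), step):
        end = min(start + window, L)
        lo, hi = start, max(min(end - k + 1, kmers.size), start)
        n_total = hi - lo
        v = valid[lo:hi]
        n_valid = int(v.sum())
        frac = float(hit[lo:hi][v].mean()) if n_valid else float("nan")
        windows.append(
            AnchorWindow(start=start, end=end, fraction=frac,
                         n_valid=n_valid, n_total=n_total)
        )
        if end >= L:
            break
    return AnchorTrack(query_id=query_id, reference_id=reference_id,
                       window_size=window, step=step, windows=windows)


@dataclass
class VarinHaplotypeResult:
    label: str  # "A", "B", or "ambiguous"
    mean_a: float
    mean_b: float
    gap: float


def identify_varin_haplotype(
    donor_index: KmerIndex,
    haplotype_a: str,
    haplotype_b: str,
    window: int = 10_000,
    step: int = 10_000,
    margin: float = 0.02,
) -> VarinHaplotypeResult:
    """Pick the offspring haplotype inherited from the donor parent.

    The haplotype with the higher genome-wide mean window conservation in
    the donor's k-mer index is selected; a mean gap below ``margin`` yields
    an explicit "ambiguous" result rather than a silent pick.
    """
    if not haplotype_a or not haplotype_b:
        raise ValueError("both haplotypes must be non-empty")
    ma = anchor_conservation(donor_index, haplotype_a, window, step).mean_conservation()
    mb = anchor_conservation(donor_index, haplotype_b, window, step).mean_conservation()
    gap = abs(ma - mb)
    if not np.isfinite(gap) or gap < margin:
        label = "ambiguous"
    else:
        label = "A" if ma > mb else "B"
    return VarinHaplotypeResult(label=label, mean_a=ma, mean_b=mb, gap=gap)


@dataclass
class CrossoverCall:
    query_id: str
    position: int
    from_parent: str
    to_parent: str
    support: tuple[int, int]  # run lengths (windows) on either side


def call_crossovers(
    track_a: AnchorTrack,
    track_b: AnchorTrack,
    margin: float = 0.2,
    min_run: int = 3,
) -> list[CrossoverCall]:
    """Call haplotype switches between two parental anchor tracks.

    Windows are labeled by the better-conserved parent when the
    conservation gap exceeds ``margin`` (uninformative otherwise); maximal
    same-label runs of at least ``min_run`` informative windows are kept,
    and a crossover is emitted at the midpoint between consecutive kept
    runs with different labels.
    """
    wa, wb = track_a.windows, track_b.windows
    if len(wa) != len(wb) or any(
        (x.start, x.end) != (y.start, y.end) for x, y in zip(wa, wb)
    ):
        raise ValueError("tracks must share identical windows")
    labeled: list[tuple[str, AnchorWindow]] = []
    for x, y in zip(wa, wb):
        if not (x.informative and y.informative):
            continue
        gap = x.fraction - y.fraction
        if gap >= margin:
            labeled.append((track_a.reference_id, x))
        elif -gap >= margin:
            labeled.append((track_b.reference_id, x))
    runs: list[tuple[str, list[AnchorWindow]]] = []
    for label, win in labeled:
        if runs and runs[-1][0] == label:
            runs[-1][1].append(win)
        else:
            runs.append((label, [win]))
    kept = [(lab, ws) for lab, ws in runs if len(ws) >= min_run]
    calls: list[CrossoverCall] = []
    for (lab1, ws1), (lab2, ws2) in zip(kept, kept[1:]):
        if lab1 == lab2:
            continue
        pos = (ws1[-1].end + ws2[0].start) // 2
        calls.append(
            CrossoverCall(
                query_id=track_a.query_id,
                position=pos,
                from_parent=lab1,
                to_parent=lab2,
                support=(len(ws1), len(ws2)),
            )
        )
    return calls
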