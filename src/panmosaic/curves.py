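"""Collector's-curve mathematics for gene- and k-mer-based pangenomes.

A pangenome over ``H`` haplotypes assigns every orthogroup (or k-mer) ``x``
a *score* ``s_x`` in ``[0, H]``: the number of haplotypes that contain it.
The score histogram ``P(s)`` — the number of orthogroups with each score —
is a sufficient statistic for all rarefaction ("collector's curve")
expectations under uniform subsampling of haplotypes without replacement:

    C_n(h) = sum_{s=1..H} P(s) * Pr[X >= n],  X ~ Hypergeom(H, s, h)

``C_1`` is the pan-genome curve (expected number of orthogroups seen in at
least one of ``h`` sampled haplotypes); ``C_h(h)`` is the core curve
(expected number present in *all* ``h`` sampled haplotypes).  Orthogroups
with score 0 are tallied but never contribute to curves.

The occupancy partition into unique / cloud / shell / nearly-core / core
classes is a function of ``H`` alone: integer breakpoints at 1%, 5% and
95% of ``H`` (rounded half away from zero) delimit contiguous score bands,
with the core fixed at ``s = H`` (present in 100% of genomes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
from scipy.stats import hypergeom

#: sentinel for the core curve C_h(h), where the threshold tracks the draw size
CORE = "core"

Threshold = Union[int, str]


@dataclass
class PresenceMatrix:
    """Binary orthogroup-by-haplotype membership matrix.

    ``present[i, j] == 1`` iff orthogroup ``orthogroup_ids[i]`` is present in
    haplotype ``haplotype_ids[j]``.
    """

    orthogroup_ids: list[str]
    haplotype_ids: list[str]
    present: np.ndarray

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=np.uint8)
        if self.present.ndim != 2:
            raise ValueError("presence matrix must be 2-dimensional")
        x, h = self.present.shape
        if x != len(self.orthogroup_ids) or h != len(self.haplotype_ids):
            raise ValueError("matrix shape does not match identifier lists")
        if h < 1:
            raise ValueError("at least one haplotype required")
        if len(set(self.orthogroup_ids)) != x:
            raise ValueError("orthogroup identifiers must be unique")
        if len(set(self.haplotype_ids)) != h:
            raise ValueError("haplotype identifiers must be unique")
        if not np.isin(self.present, (0, 1)).all():
            raise ValueError("presence indicators must be 0 or 1")

    @property
    def n_haplotypes(self) -> int:
        return self.present.shape[1]

    @property
    def n_orthogroups(self) -> int:
        return self.present.shape[0]

    def scores(self) -> np.ndarray:
        """Per-orthogroup score s_x (row sums)."""
        return self.present.sum(axis=1).astype(np.int64)


@dataclass
class ScoreHistogram:
    """P(s): number of orthogroups present in exactly ``s`` of ``H`` haplotypes.

    ``counts[s]`` for ``s`` in ``0..H``.  ``counts[0]`` records orthogroups
    absent from every haplotype; curve sums run over ``s = 1..H`` only.
    """

    H: int
    counts: np.ndarray
    empty: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.H < 1:
            raise ValueError("H must be >= 1")
        if self.counts.shape != (self.H + 1,):
            raise ValueError("counts must have length H + 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        """Total number of orthogroups X (including score-0 rows)."""
        return int(self.counts.sum())

    @property
    def total_observed(self) -> int:
        """Orthogroups with s >= 1 (the curves' asymptote)."""
        return int(self.counts[1:].sum())

    def as_dict(self) -> dict[int, int]:
        return {s: int(c) for s, c in enumerate(self.counts) if c}


@dataclass
class CollectorCurve:
    """Expected orthogroup counts as a function of sample size ``h``.

    ``values[h - 1]`` is the expectation at ``h`` haplotypes, ``h = 1..H``.
    ``stderr`` is populated only by the subsampling oracle.
    """

    n_threshold: Threshold
    H: int
    values: np.ndarray
    stderr: np.ndarray | None = None
    flagged: bool = False

    def value_at(self, h: int) -> float:
        if not 1 <= h <= self.H:
            raise ValueError(f"h must be in 1..{self.H}")
        return float(self.values[h - 1])


@dataclass
class ClassBands:
    """Occupancy-class score bands for a pangenome of ``H`` haplotypes.

    Bands are inclusive integer intervals over ``s``; a band with
    ``lower > upper`` is empty.  Together with ``core = {H}`` the bands
    partition ``1..H-1``.
    """

    H: int
    b_unique: int
    b_cloud: int
    b_nearly: int
    bands: dict[str, tuple[int, int]] = field(default_factory=dict)

    ORDER = ("unique", "cloud", "shell", "nearly_core", "core")

    def class_of(self, s: int) -> str | None:
        if not 0 <= s <= self.H:
            raise ValueError(f"score {s} outside 0..{self.H}")
        if s == 0:
            return None
        for name in self.ORDER:
            lo, hi = self.bands[name]
            if lo <= s <= hi:
                return name
        raise AssertionError("bands failed to cover a valid score")


def score_histogram(matrix: PresenceMatrix) -> ScoreHistogram:
    """Tally P(s) from a presence matrix."""
    H = matrix.n_haplotypes
    counts = np.bincount(matrix.scores(), minlength=H + 1)
    return ScoreHistogram(H=H, counts=counts, empty=matrix.n_orthogroups == 0)


def hypergeom_at_least(n: int, H: int, s: int, h: int) -> float:
    """Pr[X >= n] for X ~ Hypergeometric(population H, successes s, draws h).

    Computed through log-gamma arithmetic (scipy's hypergeometric survival
    function); exact shortcuts at the boundaries.
    """
    if not 0 <= s <= H:
        raise ValueError(f"s={s} outside 0..H={H}")
    if not 1 <= h <= H:
        raise ValueError(f"h={h} outside 1..H={H}")
    if n <= 0:
        return 1.0
    if n > min(s, h):
        return 0.0
    return float(hypergeom.sf(n - 1, H, s, h))


def collector_curve(hist: ScoreHistogram, n: Threshold = 1) -> CollectorCurve:
    """Closed-form collector's curve C_n(h) for h = 1..H.

    ``n = 1`` gives the pan curve, ``n = "core"`` the core curve C_h(h)
    (the threshold tracks the number of haplotypes drawn).  ``n > H``
    yields an all-zero curve, flagged.
    """
    H = hist.H
    s = np.arange(1, H + 1)
    P = hist.counts[1:].astype(np.float64)
    values = np.zeros(H, dtype=np.float64)
    flagged = False
    if n != CORE and int(n) > H:
        return CollectorCurve(n_threshold=n, H=H, values=values, flagged=True)
    for h in range(1, H + 1):
        thr = h if n == CORE else int(n)
        if thr <= 0:
            surv = np.ones_like(s, dtype=np.float64)
        else:
            surv = hypergeom.sf(thr - 1, H, s, h)
        # math.fsum: extended-precision accumulation of the weighted sum
        values[h - 1] = math.fsum(P * surv)
    return CollectorCurve(n_threshold=n, H=H, values=values, flagged=flagged)


def subsample_oracle(
    matrix: PresenceMatrix,
    n: Threshold = 1,
    reps: int = 1000,
    seed: int = 0,
) -> CollectorCurve:
    """Monte-Carlo estimate of C_n(h) by explicit haplotype subsampling.

    Independent of the closed form: for each ``h`` it draws ``reps``
    uniform random h-subsets of haplotypes and averages the count of
    orthogroups present in >= n (or all ``h``, for the core curve) of them.
    Deterministic given ``seed``; standard errors reported per ``h``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    H = matrix.n_haplotypes
    present = matrix.present.astype(np.float64)
    rng = np.random.default_rng(seed)
    values = np.zeros(H)
    stderr = np.zeros(H)
    for h in range(1, H + 1):
        thr = h if n == CORE else int(n)
        # reps random h-subsets: first h positions of random permutations
        order = np.argsort(rng.random((reps, H)), axis=1)[:, :h]
        mask = np.zeros((reps, H), dtype=np.float64)
        np.put_along_axis(mask, order, 1.0, axis=1)
        hits = present @ mask.T  # (X, reps) counts within each subset
        tallies = (hits >= max(thr, 1)).sum(axis=0).astype(np.float64)
        values[h - 1] = tallies.mean()
        stderr[h - 1] = tallies.std(ddof=1) / math.sqrt(reps) if reps > 1 else 0.0
    return CollectorCurve(n_threshold=n, H=H, values=values, stderr=stderr)


def _round_half_up(x: float) -> int:
    """Round half away from zero (x >= 0 here)."""
    return int(math.floor(x + 0.5))


def class_bands(H: int) -> ClassBands:
    """Occupancy-class bands for ``H`` haplotypes.

    Breakpoints at 1%, 5% and 95% of ``H`` with half-up rounding; bands are
    clamped to stay within ``1..H-1`` and may be empty at small ``H``.
    For H = 193 this yields unique 1-2, cloud 3-9, shell 10-182,
    nearly-core 183-192, core 193.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    b_u = _round_half_up(0.01 * H)
    b_c = _round_half_up(0.05 * H)
    b_n = _round_half_up(0.95 * H)
    unique = (1, min(b_u, H - 1))
    cloud = (b_u + 1, min(b_c - 1, H - 1))
    shell = (max(b_c, b_u + 1), min(b_n - 1, H - 1))
    nearly = (max(b_n, b_c, b_u + 1), H - 1)
    bands = {
        "unique": unique,
        "cloud": cloud,
        "shell": shell,
        "nearly_core": nearly,
        "core": (H, H),
    }
    return ClassBands(H=H, b_unique=b_u, b_cloud=b_c, b_nearly=b_n, bands=bands)


def classify_scores(hist: ScoreHistogram) -> tuple[ClassBands, dict[str, int]]:
    """Partition orthogroups into occupancy classes by score.

    Returns the band definitions and per-class orthogroup counts; score-0
    orthogroups are excluded from the classes and reported under "absent".
    """
    bands = class_bands(hist.H)
    counts = {name: 0 for name in ClassBands.ORDER}
    counts["absent"] = int(hist.counts[0])
    for s in range(1, hist.H + 1):
        c = int(hist.counts[s])
        if c:
            counts[bands.class_of(s)] += c
    return bands, counts
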