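"""Transposable-element landscape analytics.

Covers LTR retrotransposon insertion-age dating, solo-LTR calling with the
full filter cascade and audit trail, solo:intact ratios, flanking-
enrichment statistics (enrichment score + Fisher point probability with
Benjamini-Hochberg correction), and gene-TE nearest distances.

A *solo LTR* is a lone terminal repeat left behind when unequal
recombination excises an element's internal region and one LTR; the
solo:intact ratio indexes how aggressively a genome purges LTR
retrotransposons.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

ROLES = ("intact_element", "long_terminal_repeat", "internal", "fragment")
METHODS = ("structural", "homology")

#: Arabidopsis-derived substitution rate (per site per year) used to date
#: LTR divergence.
DEFAULT_MU = 6.1e-9


@dataclass
class TERecord:
    """One TE annotation interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    superfamily: str = ""
    role: str = "fragment"
    method: str = "homology"
    name: str = ""          # family / element identifier (GFF3 Name)
    element_id: str | None = None  # shared by parts of one intact element
    identity: float | None = None
    score: float | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.identity is not None and not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


def insertion_age(identity: float, mu: float = DEFAULT_MU) -> float:
    """Insertion age in years from LTR-LTR identity: T = (1 - identity) / (2 mu).

    The two LTRs of an element are identical at insertion and diverge
    neutrally afterwards, so half the per-site divergence divided by the
    substitution rate dates the insertion.
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must be in [0, 1]")
    if mu <= 0:
        raise ValueError("mu must be positive")
    return (1.0 - identity) / (2.0 * mu)


_FILTERS = (
    "candidate",
    "min_length",
    "min_identity",
    "min_score",
    "neighbor_id",
    "min_distance",
    "max_length_p95",
)


@dataclass
class SoloCall:
    """A candidate solo LTR with its per-filter audit trail."""

    record: TERecord
    audit: dict[str, bool | None]  # None = filter skipped

    @property
    def passed(self) -> bool:
        return all(v is not False for v in self.audit.values())


def _gap(a: TERecord, b: TERecord) -> int:
    """Edge-to-edge gap between two intervals (0 when overlapping)."""
    if a.chrom != b.chrom:
        raise ValueError("gap across chromosomes")
    return max(a.start, b.start) - min(a.end, b.end) if max(
        a.start, b.start
    ) >= min(a.end, b.end) else 0


def identify_solo_ltrs(
    annotations: Sequence[TERecord],
    min_length: int = 100,
    min_identity: float = 0.8,
    min_score: float = 300.0,
    min_distance: int = 5_000,
    neighbor_window: int = 2,
    id_field: str = "name",
    length_percentile: float = 95.0,
) -> list[SoloCall]:
    """Call solo LTRs from a TE annotation set with a seven-step cascade.

    Candidates are homology-method LTR records not assigned to an intact
    element.  Filters, each recorded in the audit trail:

    1. length >= ``min_length`` (100 bp);
    2. identity >= ``min_identity`` (0.8) relative to the reference LTR;
    3. alignment score >= ``min_score`` (300);
    4. none of the four genomically adjacent LTR-RT annotations (two
       upstream, two downstream on the same chromosome) shares the
       candidate's family/element identifier;
    5. gap >= ``min_distance`` (5 kb) to the nearest other candidate,
       intact LTR or internal record;
    6. length within the ``length_percentile`` (95th) of structural LTR
       lengths, computed per superfamily; skipped with a warning when no
       structural LTRs exist.

    Returns one :class:`SoloCall` per candidate (passing or not); the
    passing subset is ``[c for c in calls if c.passed]``.
    """
    intact_ids = {
        r.element_id for r in annotations if r.role == "intact_element" and r.element_id
    }
    ltr_rt = sorted(
        (r for r in annotations if r.role in ("intact_element", "long_terminal_repeat", "internal")),
        key=lambda r: (r.chrom, r.start, r.end),
    )
    by_chrom: dict[str, list[TERecord]] = {}
    for r in ltr_rt:
        by_chrom.setdefault(r.chrom, []).append(r)

    candidates = [
        r
        for r in annotations
        if r.method == "homology"
        and r.role == "long_terminal_repeat"
        and (r.element_id is None or r.element_id not in intact_ids)
    ]

    # 95th percentile of structural LTR lengths, per superfamily
    struct_lengths: dict[str, list[int]] = {}
    for r in annotations:
        if r.method == "structural" and r.role == "long_terminal_repeat":
            struct_lengths.setdefault(r.superfamily, []).append(r.length)
    p95 = {
        sf: float(np.percentile(lens, length_percentile))
        for sf, lens in struct_lengths.items()
    }
    if not p95:
        warnings.warn("no structural LTRs available; length-percentile filter skipped")

    cand_set = {id(c) for c in candidates}
    # distance neighbors: other candidates, intact (structural) LTRs, internals
    dist_neighbors: dict[str, list[TERecord]] = {}
    for r in annotations:
        is_neighbor = (
            id(r) in cand_set
            or (r.role == "long_terminal_repeat" and r.method == "structural")
            or r.role == "internal"
        )
        if is_neighbor:
            dist_neighbors.setdefault(r.chrom, []).append(r)
    for lst in dist_neighbors.values():
        lst.sort(key=lambda r: (r.start, r.end))

    calls: list[SoloCall] = []
    for cand in candidates:
        audit: dict[str, bool | None] = {f: None for f in _FILTERS}
        audit["candidate"] = True
        audit["min_length"] = cand.length >= min_length
        audit["min_identity"] = (
            cand.identity is not None and cand.identity >= min_identity
        )
        audit["min_score"] = cand.score is not None and cand.score >= min_score

        neighbors = _adjacent(by_chrom.get(cand.chrom, []), cand, neighbor_window)
        cid = getattr(cand, id_field) or cand.element_id
        audit["neighbor_id"] = not any(
            cid and (getattr(nb, id_field) or nb.element_id) == cid for nb in neighbors
        )

        near = [
            r
            for r in dist_neighbors.get(cand.chrom, [])
            if r is not cand
        ]
        audit["min_distance"] = all(_gap(cand, r) >= min_distance for r in near)

        if cand.superfamily in p95:
            audit["max_length_p95"] = cand.length <= p95[cand.superfamily]
        elif p95:
            # superfamily unseen among structural LTRs: no yardstick, skip
            audit["max_length_p95"] = None
        else:
            audit["max_length_p95"] = None
        calls.append(SoloCall(record=cand, audit=audit))
    return calls


def _adjacent(
    sorted_records: list[TERecord], cand: TERecord, window: int
) -> list[TERecord]:
    """The ``window`` nearest LTR-RT annotations on each side of ``cand``."""
    others = [r for r in sorted_records if r is not cand]
    before = [r for r in others if (r.start, r.end) <= (cand.start, cand.end)]
    after = [r for r in others if (r.start, r.end) > (cand.start, cand.end)]
    return before[-window:] + after[:window]


def solo_intact_ratio(
    calls: Sequence[SoloCall],
    annotations: Sequence[TERecord],
    regions: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
) -> pd.DataFrame:
    """Solo:intact ratios grouped by superfamily x chromosome (or region).

    ``regions`` optionally maps region names to interval lists; records are
    assigned by midpoint containment.  Groups with zero intact elements get
    a missing (NaN) ratio, never infinity.
    """
    def group_of(chrom: str, start: int, end: int) -> str | None:
        if regions is None:
            return chrom
        mid = (start + end) // 2
        for name, ivals in regions.items():
            for c, s, e in ivals:
                if c == chrom and s <= mid < e:
                    return name
        return None

    rows: dict[tuple[str, str], dict[str, int]] = {}
    for call in calls:
        if not call.passed:
            continue
        r = call.record
        g = group_of(r.chrom, r.start, r.end)
        if g is None:
            continue
        rows.setdefault((r.superfamily, g), {"solo": 0, "intact": 0})["solo"] += 1
    for r in annotations:
        if r.role != "intact_element":
            continue
        g = group_of(r.chrom, r.start, r.end)
        if g is None:
            continue
        rows.setdefault((r.superfamily, g), {"solo": 0, "intact": 0})["intact"] += 1
    out = [
        {
            "superfamily": sf,
            "group": g,
            "n_solo": v["solo"],
            "n_intact": v["intact"],
            "ratio": v["solo"] / v["intact"] if v["intact"] else np.nan,
        }
        for (sf, g), v in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["superfamily", "group", "n_solo", "n_intact", "ratio"])


def flank_intervals(
    features: Sequence[tuple[str, int, int]],
    flank: int,
    chrom_sizes: Mapping[str, int],
) -> list[tuple[str, int, int, int, str]]:
    """Upstream/downstream flank intervals of each feature.

    Returns (chrom, start, end, feature_index, side) tuples with the
    feature body excluded and flanks truncated at chromosome ends; empty
    flanks are dropped.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for idx, (chrom, start, end) in enumerate(features):
        size = chrom_sizes[chrom]
        if not 0 <= start < end <= size:
            raise ValueError(f"feature {chrom}:{start}-{end} outside chromosome")
        up = (max(start - flank, 0), start)
        down = (end, min(end + flank, size))
        if up[0] < up[1]:
            out.append((chrom, up[0], up[1], idx, "upstream"))
        if down[0] < down[1]:
            out.append((chrom, down[0], down[1], idx, "downstream"))
    return out


def fisher_point_probability(a: int, b: int, c: int, d: int) -> float:
    """Single-table Fisher probability (a+b)!(c+d)!(a+c)!(b+d)! / (a!b!c!d!N!).

    This is the point probability of the observed 2x2 table at fixed
    margins, not a tail sum; computed in log space.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    logp = (
        gammaln(a + b + 1)
        + gammaln(c + d + 1)
        + gammaln(a + c + 1)
        + gammaln(b + d + 1)
        - gammaln(a + 1)
        - gammaln(b + 1)
        - gammaln(c + 1)
        - gammaln(d + 1)
        - gammaln(n + 1)
    )
    return float(np.exp(logp))


@dataclass
class EnrichmentResult:
    te_type: str
    feature_class: str
    a: int
    b: int
    c: int
    d: int
    es: float  # NaN when undefined (c == 0)
    p: float
    q: float = np.nan
    significant: bool = False


def te_enrichment_test(
    tables: Sequence[tuple[str, str, int, int, int, int]],
    fdr: float = 0.05,
    es_min: float = 2.0,
    tail: bool = False,
) -> list[EnrichmentResult]:
    """Flanking-enrichment test over a batch of 2x2 count tables.

    Each table is (te_type, feature_class, a, b, c, d) where a = focal TE
    type in focal-feature flanks, b = focal type in all-feature flanks,
    c = all TEs in focal-feature flanks, d = all TEs in all-feature flanks.
    ES = (a/b)/(c/d); p is the Fisher point probability (``tail=True``
    substitutes the conventional two-sided Fisher tail instead — not the
    default convention of this package).  q values are Benjamini-Hochberg
    adjusted across the batch; significant iff q < ``fdr`` and ES >= ``es_min``.
    """
    results = []
    for te_type, feature_class, a, b, c, d in tables:
        if b <= 0 or d <= 0:
            raise ValueError("b and d must be positive")
        es = (a / b) / (c / d) if c > 0 else np.nan
        p = _two_sided_tail(a, b, c, d) if tail else fisher_point_probability(a, b, c, d)
        results.append(
            EnrichmentResult(te_type=te_type, feature_class=feature_class,
                             a=a, b=b, c=c, d=d, es=es, p=p)
        )
    if results:
        qs = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q = float(q)
            r.significant = bool(q < fdr and np.isfinite(r.es) and r.es >= es_min)
    return results


def _two_sided_tail(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher tail over tables with the same margins as (a,b,c,d)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    obs = fisher_point_probability(a, b, c, d)
    total = 0.0
    for aa in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        bb, cc = r1 - aa, c1 - aa
        dd = n - aa - bb - cc
        p = fisher_point_probability(aa, bb, cc, dd)
        if p <= obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def enrichment_counts(
    focal_features: Sequence[tuple[str, int, int]],
    all_features: Sequence[tuple[str, int, int]],
    tes: Sequence[TERecord],
    flank: int,
    chrom_sizes: Mapping[str, int],
) -> list[tuple[str, int, int, int, int]]:
    """Build (te_type, a, b, c, d) tables from feature flanks.

    A TE counts once per flank interval it intersects.
    """
    focal_flanks = flank_intervals(focal_features, flank, chrom_sizes)
    all_flanks = flank_intervals(all_features, flank, chrom_sizes)

    def tally(flanks):
        per_type: dict[str, int] = {}
        total = 0
        for chrom, s, e, _, _ in flanks:
            for te in tes:
                if te.chrom == chrom and te.start < e and te.end > s:
                    per_type[te.superfamily] = per_type.get(te.superfamily, 0) + 1
                    total += 1
        return per_type, total

    focal_by_type, c = tally(focal_flanks)
    all_by_type, d = tally(all_flanks)
    return [
        (t, focal_by_type.get(t, 0), all_by_type.get(t, 0), c, d)
        for t in sorted(all_by_type)
    ]


def gene_te_distances(
    genes: Sequence[tuple[str, int, int, str]],
    tes: Sequence[TERecord],
) -> pd.DataFrame:
    """Nearest-TE distance per gene, with per-category summaries.

    Distance is the gap between closest interval edges (0 when
    overlapping); the nearest feature considered is always a TE, never
    another gene.  Genes on chromosomes without TEs of a category get a
    missing distance.  Returns a long table (gene_id, category, distance);
    summary via :func:`summarize_distances`.
    """
    by_cat: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for cat in sorted({t.superfamily for t in tes}):
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in {t.chrom for t in tes if t.superfamily == cat}:
            ivals = sorted(
                (t.start, t.end) for t in tes if t.superfamily == cat and t.chrom == chrom
            )
            starts = np.array([s for s, _ in ivals])
            ends = np.array([e for _, e in ivals])
            per_chrom[chrom] = (starts, ends)
        by_cat[cat] = per_chrom

    rows = []
    for chrom, gstart, gend, gid in genes:
        for cat, per_chrom in by_cat.items():
            if chrom not in per_chrom:
                rows.append({"gene_id": gid, "category": cat, "distance": np.nan})
                continue
            starts, ends = per_chrom[chrom]
            # overlap or nearest gap on either side
            d = np.where(
                (starts < gend) & (ends > gstart),
                0,
                np.where(starts >= gend, starts - gend, gstart - ends),
            )
            rows.append({"gene_id": gid, "category": cat, "distance": int(d.min())})
    return pd.DataFrame(rows, columns=["gene_id", "category", "distance"])


def summarize_distances(distances: pd.DataFrame) -> pd.DataFrame:
    """Mean and median nearest distance per TE category."""
    return (
        distances.dropna(subset=["distance"])
        .groupby("category")["distance"]
        .agg(["mean", "median", "count"])
        .reset_index()
    )
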