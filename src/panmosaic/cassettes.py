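"""Cannabinoid-synthase cassette labeling from tabular alignment hits.

Cannabinoid synthase genes (THCAS, CBDAS, CBCAS) occur in tandem cassettes
interleaved with LTR retrotransposons.  Hits of reference synthase
sequences against a genome are labeled Full (near-intact: < 10 mismatches,
zero gap openings) or Partial, with Partial hits rescued to CBDAS when they
lie within 60 kb of a hit of the LTR08 element — an LTR associated
specifically with CBDAS-bearing cassettes.  Hit tables use the common
12-column tabular alignment layout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

SYNTHASE_TYPES = ("THCAS", "CBDAS", "CBCAS")


@dataclass
class HitRecord:
    """One 12-field tabular alignment hit (outfmt-6 layout)."""

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatches: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("alignment length must be positive")
        if self.bitscore < 0:
            raise ValueError("bitscore must be non-negative")

    @property
    def strand(self) -> str:
        return "-" if self.sstart > self.send else "+"

    @property
    def sub_start(self) -> int:
        """0-based half-open subject start."""
        return min(self.sstart, self.send) - 1

    @property
    def sub_end(self) -> int:
        return max(self.sstart, self.send)


@dataclass
class CassetteLabel:
    subject_id: str
    start: int  # 0-based half-open subject interval
    end: int
    strand: str
    synthase_type: str
    completeness: str  # Full | Partial
    rule: str  # full_rule | ltr08_rule | best_bitscore_rule
    bitscore: float

    def __post_init__(self) -> None:
        if self.rule == "ltr08_rule" and (
            self.completeness != "Partial" or self.synthase_type != "CBDAS"
        ):
            raise ValueError("ltr08_rule labels must be Partial CBDAS")


def synthase_type_of(query_id: str, aliases: Mapping[str, str] | None = None) -> str:
    """Synthase type from a reference query identifier."""
    if aliases and query_id in aliases:
        return aliases[query_id]
    q = query_id.upper()
    for t in SYNTHASE_TYPES:
        if t in q:
            return t
    raise ValueError(f"cannot infer synthase type from query {query_id!r}")


def filter_hits(
    synthase_hits: Sequence[HitRecord],
    ltr08_hits: Sequence[HitRecord],
    min_length: int = 500,
    min_ltr_bitscore: float = 1250.0,
) -> tuple[list[HitRecord], list[HitRecord]]:
    """Drop synthase hits shorter than 500 bp and LTR08 hits below
    bitscore 1,250 (both thresholds strict: the boundary values are kept).
    """
    syn = [h for h in synthase_hits if h.length >= min_length]
    ltr = [h for h in ltr08_hits if h.bitscore >= min_ltr_bitscore]
    return syn, ltr


def label_hits(
    synthase_hits: Sequence[HitRecord],
    ltr08_hits: Sequence[HitRecord],
    max_ltr_distance: int = 60_000,
    max_mismatches: int = 10,
    aliases: Mapping[str, str] | None = None,
) -> list[CassetteLabel]:
    """Label filtered synthase hits and deduplicate by subject start.

    Hits with mismatches < ``max_mismatches`` and zero gap openings are
    Full, typed by their query.  The rest are Partial; a Partial hit whose
    subject interval lies within ``max_ltr_distance`` (edge-to-edge, either
    direction) of a retained LTR08 hit on the same subject is typed CBDAS.
    Hits sharing a subject start position collapse to one record with
    precedence Full > LTR08-proximal Partial > highest bitscore.
    """
    ltr_by_subject: dict[str, list[tuple[int, int]]] = {}
    for h in ltr08_hits:
        ltr_by_subject.setdefault(h.subject_id, []).append((h.sub_start, h.sub_end))

    def near_ltr(h: HitRecord) -> bool:
        for ls, le in ltr_by_subject.get(h.subject_id, ()):
            gap = max(ls - h.sub_end, h.sub_start - le, 0)
            if gap <= max_ltr_distance:
                return True
        return False

    labels: dict[tuple[str, int], tuple[int, float, CassetteLabel]] = {}
    for h in synthase_hits:
        full = h.mismatches < max_mismatches and h.gapopen == 0
        if full:
            rank, label = 2, CassetteLabel(
                subject_id=h.subject_id, start=h.sub_start, end=h.sub_end,
                strand=h.strand, synthase_type=synthase_type_of(h.query_id, aliases),
                completeness="Full", rule="full_rule", bitscore=h.bitscore,
            )
        elif near_ltr(h):
            rank, label = 1, CassetteLabel(
                subject_id=h.subject_id, start=h.sub_start, end=h.sub_end,
                strand=h.strand, synthase_type="CBDAS",
                completeness="Partial", rule="ltr08_rule", bitscore=h.bitscore,
            )
        else:
            rank, label = 0, CassetteLabel(
                subject_id=h.subject_id, start=h.sub_start, end=h.sub_end,
                strand=h.strand, synthase_type=synthase_type_of(h.query_id, aliases),
                completeness="Partial", rule="best_bitscore_rule", bitscore=h.bitscore,
            )
        key = (h.subject_id, h.sub_start)
        prev = labels.get(key)
        if prev is None or (rank, h.bitscore) > (prev[0], prev[1]):
            labels[key] = (rank, h.bitscore, label)
    return [v[2] for _, v in sorted(labels.items())]


@dataclass
class CassetteSignature:
    signature: tuple[tuple[str, str, str], ...]  # (type, completeness, strand)
    subjects: list[str]

    @property
    def count(self) -> int:
        return len(self.subjects)


def summarize_cassettes(
    labels: Sequence[CassetteLabel], min_hits: int = 4
) -> list[CassetteSignature]:
    """Group subject regions by their ordered cassette arrangement.

    Labels are grouped per subject sequence and sorted by position; regions
    with fewer than ``min_hits`` synthase hits are suppressed.  The
    signature of a region is the ordered tuple of (type, completeness,
    strand); identical signatures are grouped with occurrence counts.
    """
    per_subject: dict[str, list[CassetteLabel]] = {}
    for lab in labels:
        per_subject.setdefault(lab.subject_id, []).append(lab)
    sig_map: dict[tuple, list[str]] = {}
    for subject, labs in sorted(per_subject.items()):
        if len(labs) < min_hits:
            continue
        labs.sort(key=lambda x: x.start)
        sig = tuple((x.synthase_type, x.completeness, x.strand) for x in labs)
        sig_map.setdefault(sig, []).append(subject)
    return [
        CassetteSignature(signature=sig, subjects=subs)
        for sig, subs in sorted(sig_map.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]
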