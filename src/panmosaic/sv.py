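"""Structural-variant breakpoint statistics.

Two analyses: (1) association between TE families and SV breakpoints,
testing the observed per-SV flank TE content against a length- and
chromosome-matched shuffled null with bootstrap replication and Welch's
t-test; (2) classification of inversion breakpoints as inverted repeats or
segmental duplications from alignments between 8-kb breakpoint windows.

Flanks are 500 bp on each side of a breakpoint (1 kb per breakpoint); a
family is *associated* with an SV only when it appears in the flanks of
both breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .te import TERecord

SV_TYPES = ("INV", "DUP", "TRANS", "INVTR")


@dataclass
class SVRecord:
    chrom: str
    start: int
    end: int
    sv_type: str
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty SV interval {self.id}")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _family_intervals(
    tes: Sequence[TERecord],
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """family -> chrom -> (sorted starts, sorted ends) for fast intersection."""
    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for fam in sorted({t.superfamily for t in tes}):
        per: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted({t.chrom for t in tes if t.superfamily == fam}):
            ivals = sorted(
                (t.start, t.end)
                for t in tes
                if t.superfamily == fam and t.chrom == chrom
            )
            per[chrom] = (
                np.array([s for s, _ in ivals]),
                np.sort(np.array([e for _, e in ivals])),
            )
        out[fam] = per
    return out


def _count_overlaps(
    starts: np.ndarray, ends_sorted: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Number of intervals intersecting each query [lo, hi)."""
    return np.searchsorted(starts, hi, side="left") - np.searchsorted(
        ends_sorted, lo, side="right"
    )


def breakpoint_flank_tes(
    svs: Sequence[SVRecord],
    tes: Sequence[TERecord],
    flank: int = 500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-SV, per-family flank TE counts and both-breakpoint indicators.

    Each breakpoint's flank is [bp - flank, bp + flank), truncated at
    chromosome ends when sizes are given.  Columns: sv_id, sv_type,
    family, start_count, end_count, both (family present in both flanks),
    count (= start_count + end_count).
    """
    fam_ivals = _family_intervals(tes)
    rows = []
    for sv in svs:
        size = chrom_sizes.get(sv.chrom) if chrom_sizes else None
        lo_s, hi_s = _clip(sv.start - flank, sv.start + flank, size)
        lo_e, hi_e = _clip(sv.end - flank, sv.end + flank, size)
        for fam, per in fam_ivals.items():
            if sv.chrom in per:
                starts, ends = per[sv.chrom]
                cs = int(_count_overlaps(starts, ends, np.array([lo_s]), np.array([hi_s]))[0])
                ce = int(_count_overlaps(starts, ends, np.array([lo_e]), np.array([hi_e]))[0])
            else:
                cs = ce = 0
            rows.append(
                {
                    "sv_id": sv.id,
                    "sv_type": sv.sv_type,
                    "family": fam,
                    "start_count": cs,
                    "end_count": ce,
                    "both": cs > 0 and ce > 0,
                    "count": cs + ce,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sv_id", "sv_type", "family", "start_count", "end_count", "both", "count"],
    )


def _clip(lo: int, hi: int, size: int | None) -> tuple[int, int]:
    lo = max(lo, 0)
    if size is not None:
        hi = min(hi, size)
    return lo, hi


def shuffle_matched_null(
    svs: Sequence[SVRecord],
    chrom_sizes: Mapping[str, int],
    seed: int = 0,
) -> list[SVRecord]:
    """Length- and chromosome-matched uniform random repositioning of SVs."""
    rng = np.random.default_rng(seed)
    out = []
    for sv in svs:
        size = chrom_sizes[sv.chrom]
        if sv.length > size:
            raise ValueError(f"SV {sv.id} longer than chromosome {sv.chrom}")
        start = int(rng.integers(0, size - sv.length + 1))
        out.append(
            SVRecord(chrom=sv.chrom, start=start, end=start + sv.length,
                     sv_type=sv.sv_type, id=sv.id)
        )
    return out


@dataclass
class BreakpointReport:
    te_family: str
    sv_type: str
    observed: np.ndarray  # per-SV flank count vector for this family
    mean_t: float
    mean_p: float
    q: float
    n_reps: int
    n_reps_used: int
    seed: int
    significant: bool = False


def bootstrap_te_association(
    svs: Sequence[SVRecord],
    tes: Sequence[TERecord],
    chrom_sizes: Mapping[str, int],
    reps: int = 1000,
    flank: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    by_subtype: bool = True,
) -> list[BreakpointReport]:
    """Bootstrap test of TE-family enrichment at SV breakpoints.

    For each replicate the SV set is re-placed uniformly at random (same
    lengths, same chromosomes) and the per-SV flank TE count vector of the
    focal family is compared with the observed vector by Welch's two-sided
    t-test; the replicate t statistics and p values are averaged, then
    Benjamini-Hochberg correction is applied across family x sv_type
    combinations.  Replicates where both vectors are constant are skipped
    and tallied in ``n_reps_used``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not tes:
        return []
    fam_ivals = _family_intervals(tes)
    groups = sorted({sv.sv_type for sv in svs}) if by_subtype else ["all"]
    rng = np.random.default_rng(seed)

    reports: list[BreakpointReport] = []
    for group in groups:
        gsvs = [sv for sv in svs if (not by_subtype) or sv.sv_type == group]
        if not gsvs:
            continue
        n = len(gsvs)
        lengths = np.array([sv.length for sv in gsvs])
        sizes = np.array([chrom_sizes[sv.chrom] for sv in gsvs])
        if (lengths > sizes).any():
            raise ValueError("SV longer than its chromosome")
        # replicate start positions: (reps, n)
        starts = (rng.random((reps, n)) * (sizes - lengths + 1)).astype(np.int64)
        ends = starts + lengths
        for fam, per in fam_ivals.items():
            obs = _flank_counts(gsvs, per, flank, chrom_sizes)
            shuf = np.zeros((reps, n), dtype=np.int64)
            for j, sv in enumerate(gsvs):
                if sv.chrom not in per:
                    continue
                st, en = per[sv.chrom]
                size = chrom_sizes[sv.chrom]
                for bp in (starts[:, j], ends[:, j]):
                    lo = np.maximum(bp - flank, 0)
                    hi = np.minimum(bp + flank, size)
                    shuf[:, j] += _count_overlaps(st, en, lo, hi)
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p = stats.ttest_ind(
                    np.broadcast_to(obs, (reps, n)), shuf, axis=1, equal_var=False
                )
            ok = np.isfinite(t) & np.isfinite(p)
            used = int(ok.sum())
            mean_t = float(np.mean(t[ok])) if used else np.nan
            mean_p = float(np.mean(p[ok])) if used else np.nan
            reports.append(
                BreakpointReport(
                    te_family=fam, sv_type=group, observed=obs,
                    mean_t=mean_t, mean_p=mean_p, q=np.nan,
                    n_reps=reps, n_reps_used=used, seed=seed,
                )
            )
    scored = [r for r in reports if np.isfinite(r.mean_p)]
    if scored:
        qs = multipletests([r.mean_p for r in scored], method="fdr_bh")[1]
        for r, q in zip(scored, qs):
            r.q = float(q)
            r.significant = bool(q < alpha)
    return reports


def _flank_counts(
    svs: Sequence[SVRecord],
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    flank: int,
    chrom_sizes: Mapping[str, int],
) -> np.ndarray:
    counts = np.zeros(len(svs), dtype=np.int64)
    for j, sv in enumerate(svs):
        if sv.chrom not in per_chrom:
            continue
        st, en = per_chrom[sv.chrom]
        size = chrom_sizes[sv.chrom]
        for bp in (sv.start, sv.end):
            lo, hi = max(bp - flank, 0), min(bp + flank, size)
            counts[j] += int(
                _count_overlaps(st, en, np.array([lo]), np.array([hi]))[0]
            )
    return counts


def reports_to_frame(reports: Sequence[BreakpointReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "te_family": r.te_family,
                "sv_type": r.sv_type,
                "mean_t": r.mean_t,
                "mean_p": r.mean_p,
                "q": r.q,
                "n_reps": r.n_reps,
                "n_reps_used": r.n_reps_used,
                "significant": r.significant,
            }
            for r in reports
        ]
    )


# ---------------------------------------------------------------------------
# Inversion-breakpoint repeat classification


@dataclass
class InversionRepeatCall:
    inversion_id: str
    repeat_class: str  # inverted_repeat | segmental_duplication | none
    score: int = 0
    orientation: str | None = None
    detail: str | None = None


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtNn", "TGCAtgcaNn"))[::-1]


def _max_exact_match(
    w1: str, w2: str, seed_len: int = 31, self_mode: bool = False
) -> tuple[int, str] | None:
    """Longest gap-free exact match between windows, either orientation.

    Seeds are shared ``seed_len``-mers chained along diagonals; the trivial
    full-length self-to-self diagonal is excluded in ``self_mode``.
    Returns (match length, orientation) or None.
    """
    best: tuple[int, str] | None = None
    for orient, target in (("+", w2), ("-", _revcomp(w2))):
        pos1: dict[str, list[int]] = {}
        for i in range(len(w1) - seed_len + 1):
            pos1.setdefault(w1[i : i + seed_len], []).append(i)
        diags: dict[int, list[int]] = {}
        for j in range(len(target) - seed_len + 1):
            kmer = target[j : j + seed_len]
            for i in pos1.get(kmer, ()):
                if self_mode and orient == "+" and i == j:
                    continue  # identity diagonal of the self alignment
                diags.setdefault(j - i, []).append(j)
        for offsets in diags.values():
            offsets.sort()
            run_start = offsets[0]
            prev = offsets[0]
            for j in offsets[1:] + [None]:  # type: ignore[list-item]
                if j is not None and j == prev + 1:
                    prev = j
                    continue
                length = prev - run_start + seed_len
                if best is None or length > best[0]:
                    best = (length, orient)
                if j is not None:
                    run_start = prev = j
    return best


def classify_inversion_breakpoints(
    inversions: Sequence[SVRecord],
    genome: Mapping[str, str],
    window: int = 8_000,
    min_size: int = 10_000,
    seed_len: int = 31,
) -> list[InversionRepeatCall]:
    """Classify inversion breakpoints by flanking repeat structure.

    For each inversion of at least ``min_size``, 8-kb windows centred on
    the start and end breakpoints are compared self-to-self (excluding the
    trivial full-length alignment) and start-to-end using a built-in exact-
    match detector (maximal gap-free matches >= ``seed_len``).  The top
    alignment per breakpoint decides the call: opposing orientation ->
    inverted repeat, same orientation -> segmental duplication, no
    qualifying alignment -> none.  Inversions below ``min_size`` are skipped.
    """
    calls = []
    half = window // 2
    for inv in inversions:
        if inv.sv_type != "INV":
            continue
        if inv.length < min_size:
            continue
        if inv.chrom not in genome:
            raise ValueError(f"missing sequence for inversion {inv.id} ({inv.chrom})")
        seq = genome[inv.chrom]
        win_start = seq[max(inv.start - half, 0) : inv.start + half]
        win_end = seq[max(inv.end - half, 0) : inv.end + half]
        per_bp = []
        for own, other in ((win_start, win_end), (win_end, win_start)):
            cands = []
            m = _max_exact_match(own, own, seed_len, self_mode=True)
            if m:
                cands.append(m)
            m = _max_exact_match(own, other, seed_len, self_mode=False)
            if m:
                cands.append(m)
            per_bp.append(max(cands) if cands else None)
        hits = [h for h in per_bp if h]
        if not hits:
            calls.append(InversionRepeatCall(inversion_id=inv.id, repeat_class="none"))
            continue
        top = max(hits)
        repeat_class = (
            "inverted_repeat" if any(o == "-" for _, o in hits) else "segmental_duplication"
        )
        calls.append(
            InversionRepeatCall(
                inversion_id=inv.id,
                repeat_class=repeat_class,
                score=top[0],
                orientation=top[1],
            )
        )
    return calls
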