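"""Alignment, dinucleotide and population-genetic sequence statistics.

* MSA entropy: mean per-column Shannon entropy (bits) of a multiple
  sequence alignment; bounded by log2(20) = 4.32 for proteins and
  log2(4) = 2.0 for DNA.  Gaps are excluded from column frequencies.
* CpG observed/expected: (N_CG / L) / ((N_C / L) * (N_G / L)); depressed
  by historical cytosine methylation.  CpG islands are regions > 200 bp
  with GC > 50% and o/e > 0.6, outside any methylated mask.
* F_IS = (HS - HO) / HS: per-site inbreeding coefficient, the deficit of
  observed heterozygotes relative to the Hardy-Weinberg expectation
  HS = 2 p (1 - p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import entropy as _shannon

GAP_CHARS = frozenset("-.")


class TooFewSequencesError(ValueError):
    """Raised when an alignment has fewer than the required five rows."""


@dataclass
class AlignmentBlock:
    ids: list[str]
    rows: list[str]
    alphabet: str = "protein"  # or "dna"

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows differ in length")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError("alphabet must be 'protein' or 'dna'")

    @property
    def length(self) -> int:
        return len(self.rows[0])


def column_entropy(column: Sequence[str]) -> float | None:
    """Shannon entropy (bits) of one alignment column; gaps excluded.

    Returns None for an all-gap column.
    """
    symbols = [c.upper() for c in column if c not in GAP_CHARS]
    if not symbols:
        return None
    _, counts = np.unique(symbols, return_counts=True)
    return float(_shannon(counts, base=2))


def msa_mean_entropy(block: AlignmentBlock, min_sequences: int = 5) -> float:
    """Mean per-column entropy of an alignment, in bits.

    Alignments with fewer than ``min_sequences`` rows are rejected (too few
    sequences for a meaningful diversity estimate); all-gap columns are
    skipped.
    """
    if len(block.rows) < min_sequences:
        raise TooFewSequencesError(
            f"alignment has {len(block.rows)} sequences; minimum is {min_sequences}"
        )
    ents = []
    for j in range(block.length):
        e = column_entropy([r[j] for r in block.rows])
        if e is not None:
            ents.append(e)
    if not ents:
        raise ValueError("alignment has no non-gap columns")
    return float(np.mean(ents))


@dataclass
class CpGWindow:
    chrom: str
    start: int
    end: int
    cpg_count: int
    c_count: int
    g_count: int
    length: int  # non-N bases
    gc_fraction: float
    oe_ratio: float | None  # None when C or G absent


def cpg_observed_expected(
    sequence: str, start: int = 0, end: int | None = None, chrom: str = ""
) -> CpGWindow:
    """Observed/expected CpG ratio of a sequence window.

    oe = (N_CG / L) / ((N_C / L)(N_G / L)); CG dinucleotides are counted by
    a step-1 scan; case-insensitive; Ns excluded from L.  oe is missing
    (None), not zero, when the window has no C or no G.
    """
    if end is None:
        end = len(sequence)
    if not 0 <= start < end <= len(sequence):
        raise ValueError("window outside sequence")
    win = sequence[start:end].upper()
    n_c = win.count("C")
    n_g = win.count("G")
    L = sum(1 for ch in win if ch != "N")
    n_cg = sum(1 for i in range(len(win) - 1) if win[i] == "C" and win[i + 1] == "G")
    gc = (n_c + n_g) / L if L else 0.0
    oe = (n_cg * L) / (n_c * n_g) if n_c and n_g else None
    return CpGWindow(
        chrom=chrom, start=start, end=end, cpg_count=n_cg, c_count=n_c,
        g_count=n_g, length=L, gc_fraction=gc, oe_ratio=oe,
    )


def call_cpg_islands(
    sequence: str,
    min_len: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
    window: int = 200,
    step: int = 50,
    methylation_mask: Sequence[tuple[int, int]] | None = None,
    chrom: str = "",
) -> list[CpGWindow]:
    """Sliding-window CpG island caller.

    Windows of ``window`` bp (step ``step``) passing GC > ``gc_min`` and
    o/e > ``oe_min`` are merged when overlapping; each merged region is
    re-evaluated as a whole and reported only if longer than ``min_len``
    with both thresholds still holding.  Regions intersecting the
    methylated mask are dropped (islands are unmethylated by definition).
    """
    if min(min_len, window, step) <= 0 or min(gc_min, oe_min) <= 0:
        raise ValueError("thresholds must be positive")
    L = len(sequence)
    passing: list[tuple[int, int]] = []
    for start in range(0, max(L - window + 1, 0), step):
        w = cpg_observed_expected(sequence, start, start + window)
        if w.oe_ratio is not None and w.gc_fraction > gc_min and w.oe_ratio > oe_min:
            passing.append((start, start + window))
    merged: list[list[int]] = []
    for s, e in passing:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    islands = []
    for s, e in merged:
        if e - s <= min_len:
            continue
        w = cpg_observed_expected(sequence, s, e, chrom=chrom)
        if w.oe_ratio is None or w.gc_fraction <= gc_min or w.oe_ratio <= oe_min:
            continue
        if methylation_mask and any(s < me and e > ms for ms, me in methylation_mask):
            continue
        islands.append(w)
    return islands


@dataclass
class GenotypeSite:
    """Biallelic diploid genotypes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing."""

    site_id: str
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if not np.isin(self.genotypes, (-1, 0, 1, 2)).all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")


def site_fis(site: GenotypeSite) -> float | None:
    """Per-site inbreeding coefficient F_IS = (HS - HO) / HS.

    HO is the observed heterozygote fraction among non-missing calls; HS is
    2 p (1 - p) from the allele frequency over the same calls.  Returns
    None for monomorphic sites (HS = 0) or when every call is missing.
    """
    g = site.genotypes[site.genotypes >= 0]
    n = g.size
    if n == 0:
        return None
    p = float(g.sum()) / (2 * n)  # alt-allele frequency
    hs = 2.0 * p * (1.0 - p)
    if hs == 0.0:
        return None
    ho = float((g == 1).sum()) / n
    return (hs - ho) / hs


def mean_fis(sites: Sequence[GenotypeSite]) -> float:
    """Plain mean of per-site F_IS over polymorphic sites."""
    vals = [f for f in (site_fis(s) for s in sites) if f is not None]
    if not vals:
        raise ValueError("no polymorphic sites")
    return float(np.mean(vals))
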