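"""Synthetic-data generators with machine-readable ground truth.

Every analysis in this package can be exercised end-to-end on data from
these generators.  Each generator returns the in-memory inputs its
consumer expects plus a :class:`TruthBundle` recording every planted
feature, the generator parameters and the seed.  All randomness flows from
one seeded generator per bundle, with per-component sub-streams derived
deterministically from the seed, so regeneration under a fixed seed is
byte-identical.

What is emulated (and what is not): presence/absence matrices follow a
configurable score distribution but carry no phylogenetic correlation
between orthogroups; TE-annotated genomes have realistic interval
geometry and the EDTA-style attribute dialect but random sequence content;
trio haplotypes have true substitution divergence but no indels or
structural variation; genotype matrices are sites drawn independently at a
target inbreeding coefficient with no linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cassettes import HitRecord
from .curves import PresenceMatrix
from .seqstats import GenotypeSite
from .sv import SVRecord
from .te import TERecord



@dataclass
class TruthBundle:
    """Ground truth for one generated dataset."""

    kind: str
    seed: int
    params: dict
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)


def _rng(seed: int, component: int) -> np.random.Generator:
    # per-component sub-stream: stable when unrelated spec fields change
    return np.random.default_rng(np.random.SeedSequence([seed, component]))


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_gc = gc / 2
    p_at = (1 - gc) / 2
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASE_BYTES[codes].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases at ``rate`` per site, never to the original base."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = rng.binomial(len(arr), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(arr), size=n, replace=False)
    old = np.searchsorted(_BASE_BYTES, arr[pos])
    arr[pos] = _BASE_BYTES[(old + 1 + rng.integers(0, 3, size=n)) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# presence matrices


def simulate_presence_matrix(
    H: int,
    X: int,
    score_dist: Mapping[int, float] | Sequence[float],
    seed: int = 0,
) -> tuple[PresenceMatrix, TruthBundle]:
    """Presence/absence matrix with scores drawn from ``score_dist``.

    ``score_dist`` gives P(score = s) for s in 0..H (mapping or length-H+1
    sequence, must sum to 1); the haplotypes carrying each orthogroup are
    chosen uniformly at random.
    """
    if isinstance(score_dist, Mapping):
        probs = np.zeros(H + 1)
        for s, p in score_dist.items():
            if not 0 <= s <= H:
                raise ValueError(f"score {s} outside 0..{H}")
            probs[s] = p
    else:
        probs = np.asarray(score_dist, dtype=float)
        if probs.shape != (H + 1,):
            raise ValueError("score_dist must have length H + 1")
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("score_dist must be a probability distribution over 0..H")
    rng = _rng(seed, 0)
    scores = rng.choice(H + 1, size=X, p=probs)
    present = np.zeros((X, H), dtype=np.uint8)
    order = np.argsort(rng.random((X, H)), axis=1)
    for i, s in enumerate(scores):
        present[i, order[i, :s]] = 1
    matrix = PresenceMatrix(
        orthogroup_ids=[f"OG{i:06d}" for i in range(X)],
        haplotype_ids=[f"hap{j:03d}" for j in range(H)],
        present=present,
    )
    hist = np.bincount(scores, minlength=H + 1)
    bundle = TruthBundle(
        kind="presence_matrix",
        seed=seed,
        params={"H": H, "X": X},
        truth={
            "histogram": pd.DataFrame(
                {"score": np.arange(H + 1), "count": hist}
            ),
            "scores": pd.DataFrame(
                {"orthogroup_id": matrix.orthogroup_ids, "score": scores}
            ),
        },
    )
    return matrix, bundle


# ---------------------------------------------------------------------------
# TE-annotated genomes


_SOLO_CATEGORIES = ("pass", "fail_length", "fail_identity", "fail_score")


def simulate_te_genome(
    length: int = 200_000,
    n_intact: int = 3,
    n_solo: int = 5,
    n_fragment: int = 4,
    n_adjacent_pair: int = 1,
    n_close_pair: int = 1,
    superfamilies: Sequence[str] = ("Ty1/Copia", "Ty3/Gypsy"),
    solo_fail_fraction: float = 0.4,
    spacing: int = 6_000,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[dict[str, str], list[TERecord], TruthBundle]:
    """Genome with planted intact LTR-RTs, solo LTRs and TE fragments.

    Intact elements are emitted as element + two LTR + internal records
    sharing an element id (structural method).  Solos are lone homology
    LTR records whose identity/score/length are drawn from ranges that
    straddle the caller's thresholds, so the truth table can mark each one
    as destined to pass or fail, and why.  ``n_adjacent_pair`` plants
    same-family adjacent solo pairs (neighbor-identity failures) and
    ``n_close_pair`` plants < 5 kb solo pairs (distance failures); all
    other features are spaced >= ``spacing`` bp apart with distinct
    families between neighbors, so those two filters pass by construction.
    """
    rng = _rng(seed, 1)
    records: list[TERecord] = []
    truth_rows: list[dict] = []
    cursor = spacing
    fam_counter = 0

    def next_family(sf: str) -> str:
        nonlocal fam_counter
        fam_counter += 1
        return f"TE_{sf.split('/')[-1]}_{fam_counter:04d}"

    def place(total_len: int, gap: int) -> int:
        nonlocal cursor
        start = cursor
        cursor = start + total_len + gap
        return start

    # intact elements: element + LTR/internal parts, structural method
    for i in range(n_intact):
        sf = superfamilies[i % len(superfamilies)]
        fam = next_family(sf)
        ltr_len = int(rng.integers(800, 1200))
        int_len = int(rng.integers(3000, 5000))
        start = place(2 * ltr_len + int_len, spacing)
        eid = f"intact_{i:03d}"
        ident = float(rng.uniform(0.9, 0.999))
        common = dict(chrom=chrom, strand="+", superfamily=sf, name=fam,
                      element_id=eid, method="structural", identity=ident)
        records.append(TERecord(start=start, end=start + 2 * ltr_len + int_len,
                                role="intact_element", score=1000.0, **common))
        records.append(TERecord(start=start, end=start + ltr_len,
                                role="long_terminal_repeat", score=800.0, **common))
        records.append(TERecord(start=start + ltr_len, end=start + ltr_len + int_len,
                                role="internal", score=900.0, **common))
        records.append(TERecord(start=start + ltr_len + int_len,
                                end=start + 2 * ltr_len + int_len,
                                role="long_terminal_repeat", score=800.0, **common))
        truth_rows.append({"feature_id": eid, "kind": "intact", "family": fam,
                           "start": start, "end": start + 2 * ltr_len + int_len,
                           "should_pass": False, "fail_reason": "not_a_solo"})

    def plant_solo(idx: int, category: str, *, start: int | None = None,
                   fam: str | None = None, gap: int = spacing) -> TERecord:
        sf = superfamilies[idx % len(superfamilies)]
        fam = fam or next_family(sf)
        if category == "fail_length":
            slen = int(rng.integers(40, 100))
        else:
            slen = int(rng.integers(300, 700))
        ident = (
            float(rng.uniform(0.5, 0.79)) if category == "fail_identity"
            else float(rng.uniform(0.85, 0.99))
        )
        score = (
            float(rng.integers(50, 300)) if category == "fail_score"
            else float(rng.integers(400, 1000))
        )
        if start is None:
            start = place(slen, gap)
        rec = TERecord(chrom=chrom, start=start, end=start + slen, strand="+",
                       superfamily=sf, role="long_terminal_repeat", method="homology",
                       name=fam, element_id=None, identity=ident, score=score)
        records.append(rec)
        return rec

    solo_idx = 0
    for _ in range(n_solo):
        if rng.random() < solo_fail_fraction:
            category = str(rng.choice(_SOLO_CATEGORIES[1:]))
        else:
            category = "pass"
        rec = plant_solo(solo_idx, category)
        truth_rows.append({"feature_id": f"solo_{solo_idx:03d}", "kind": "solo",
                           "family": rec.name, "start": rec.start, "end": rec.end,
                           "should_pass": category == "pass", "fail_reason":
                           "" if category == "pass" else category})
        solo_idx += 1

    # same-family adjacent pairs: spacing >= 5 kb but shared family id
    for _ in range(n_adjacent_pair):
        sf = superfamilies[solo_idx % len(superfamilies)]
        fam = next_family(sf)
        for _ in range(2):
            rec = plant_solo(solo_idx, "pass", fam=fam)
            truth_rows.append({"feature_id": f"solo_{solo_idx:03d}", "kind": "solo",
                               "family": fam, "start": rec.start, "end": rec.end,
                               "should_pass": False, "fail_reason": "neighbor_id"})
            solo_idx += 1

    # close pairs: distinct families but < 5 kb apart
    for _ in range(n_close_pair):
        rec1 = plant_solo(solo_idx, "pass", gap=3_000)
        truth_rows.append({"feature_id": f"solo_{solo_idx:03d}", "kind": "solo",
                           "family": rec1.name, "start": rec1.start, "end": rec1.end,
                           "should_pass": False, "fail_reason": "min_distance"})
        solo_idx += 1
        rec2 = plant_solo(solo_idx, "pass")
        truth_rows.append({"feature_id": f"solo_{solo_idx:03d}", "kind": "solo",
                           "family": rec2.name, "start": rec2.start, "end": rec2.end,
                           "should_pass": False, "fail_reason": "min_distance"})
        solo_idx += 1

    for i in range(n_fragment):
        sf = ("Helitron", "Mutator", "Harbinger")[i % 3]
        flen = int(rng.integers(200, 2000))
        start = place(flen, spacing)
        records.append(TERecord(chrom=chrom, start=start, end=start + flen,
                                strand="+", superfamily=sf, role="fragment",
                                method="homology", name=f"TE_{sf}_{i:04d}",
                                identity=float(rng.uniform(0.7, 0.99)),
                                score=float(rng.integers(100, 1000))))
        truth_rows.append({"feature_id": f"frag_{i:03d}", "kind": "fragment",
                           "family": f"TE_{sf}_{i:04d}", "start": start,
                           "end": start + flen, "should_pass": False,
                           "fail_reason": "not_a_solo"})

    if cursor > length:
        raise ValueError(
            f"planted features need {cursor} bp but genome length is {length}"
        )
    genome = {chrom: _random_seq(rng, length)}
    bundle = TruthBundle(
        kind="te_genome", seed=seed,
        params={"length": length, "n_intact": n_intact, "n_solo": n_solo,
                "n_fragment": n_fragment, "spacing": spacing},
        truth={"features": pd.DataFrame(truth_rows)},
    )
    return genome, records, bundle


# ---------------------------------------------------------------------------
# trios


def simulate_trio(
    parent_length: int = 300_000,
    divergence: float = 0.02,
    n_crossovers: int = 3,
    mutation_rate: float = 1e-4,
    min_spacing: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], TruthBundle]:
    """Parent-parent-offspring haplotypes with known crossover breakpoints.

    Both parents descend from a common random ancestor by independent
    substitution at ``divergence / 2`` each (so they differ at roughly
    ``divergence`` of sites); the child haplotype alternates parental
    segments at ``n_crossovers`` breakpoints at least ``min_spacing`` bp
    apart, with fresh point mutations sprinkled at ``mutation_rate``.
    """
    if divergence <= 0:
        import warnings

        warnings.warn("zero divergence: anchoring cannot discriminate parents")
    rng = _rng(seed, 2)
    ancestor = _random_seq(rng, parent_length)
    parent_a = _mutate(ancestor, divergence / 2, rng)
    parent_b = _mutate(ancestor, divergence / 2, rng)
    if min_spacing is None:
        min_spacing = max(parent_length // (3 * (n_crossovers + 1)), 30_000)
    breakpoints: list[int] = []
    if n_crossovers:
        # uniform positions conditional on all gaps >= min_spacing: place the
        # mandatory gaps first, then spread the remaining slack uniformly
        slack = parent_length - (n_crossovers + 1) * min_spacing
        if slack < 0:
            raise ValueError("cannot satisfy breakpoint spacing; reduce n_crossovers")
        offsets = np.sort(rng.integers(0, slack + 1, size=n_crossovers))
        breakpoints = [
            int(off + (i + 1) * min_spacing) for i, off in enumerate(offsets)
        ]
    start_parent = "A" if rng.random() < 0.5 else "B"
    segments = []
    bounds = [0, *breakpoints, parent_length]
    cur = start_parent
    for lo, hi in zip(bounds, bounds[1:]):
        src = parent_a if cur == "A" else parent_b
        segments.append(src[lo:hi])
        cur = "B" if cur == "A" else "A"
    child = _mutate("".join(segments), mutation_rate, rng)
    bundle = TruthBundle(
        kind="trio", seed=seed,
        params={"parent_length": parent_length, "divergence": divergence,
                "n_crossovers": n_crossovers, "mutation_rate": mutation_rate,
                "min_spacing": min_spacing, "start_parent": start_parent},
        truth={"breakpoints": pd.DataFrame({"position": breakpoints})},
    )
    return {"parentA": parent_a, "parentB": parent_b, "child": child}, bundle


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    n_sites: int = 2_000,
    n_samples: int = 100,
    freq_range: tuple[float, float] = (0.1, 0.9),
    F: float = 0.0,
    seed: int = 0,
) -> tuple[list[GenotypeSite], TruthBundle]:
    """Biallelic genotype matrix at inbreeding coefficient ``F``.

    Per site the alt-allele frequency p is uniform on ``freq_range`` and
    genotypes are drawn with P(het) = 2 p (1 - p)(1 - F) and homozygote
    probabilities inflated accordingly; F = 1 yields no heterozygotes.
    Sites that come out monomorphic are flagged in the truth table and
    excluded from its summaries.
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must be in [0, 1]")
    rng = _rng(seed, 3)
    sites = []
    rows = []
    for i in range(n_sites):
        p = float(rng.uniform(*freq_range))
        q = 1.0 - p
        probs = [q * q + F * p * q, 2 * p * q * (1 - F), p * p + F * p * q]
        g = rng.choice(3, size=n_samples, p=probs).astype(np.int8)
        site = GenotypeSite(site_id=f"site{i:05d}", genotypes=g)
        sites.append(site)
        rows.append({"site_id": site.site_id, "p": p,
                     "polymorphic": bool(0 < g.sum() < 2 * n_samples)})
    bundle = TruthBundle(
        kind="genotypes", seed=seed,
        params={"n_sites": n_sites, "n_samples": n_samples, "F": F},
        truth={"sites": pd.DataFrame(rows)},
    )
    return sites, bundle


# ---------------------------------------------------------------------------
# SV datasets


def simulate_sv_dataset(
    chrom_sizes: Mapping[str, int] | None = None,
    n_svs: Mapping[str, int] | int = 20,
    te_per_mb: float = 60.0,
    families: Sequence[str] = ("Ty1/Copia", "Ty3/Gypsy", "Helitron"),
    focal_family: str = "Ty1/Copia",
    association_rate: float = 0.0,
    associated_types: Sequence[str] = ("DUP",),
    flank: int = 500,
    seed: int = 0,
) -> tuple[list[SVRecord], list[TERecord], TruthBundle]:
    """SV set plus TE background with a controlled breakpoint association.

    TEs of each family are placed uniformly at ``te_per_mb`` per family;
    for the ``association_rate`` fraction of SVs of the ``associated_types``
    subtypes, a TE of ``focal_family`` is planted inside both 500-bp
    breakpoint flanks.  Truth records which SVs carry a planted association.
    """
    if not 0.0 <= association_rate <= 1.0:
        raise ValueError("association rate must be in [0, 1]")
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 2_000_000, "chr2": 2_000_000}
    if isinstance(n_svs, int):
        n_svs = {t: n_svs for t in ("INV", "DUP", "TRANS", "INVTR")}
    rng = _rng(seed, 4)
    chroms = sorted(chrom_sizes)

    svs: list[SVRecord] = []
    truth_rows = []
    tes: list[TERecord] = []
    k = 0
    for sv_type, count in sorted(n_svs.items()):
        for _ in range(count):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = chrom_sizes[chrom]
            length = int(rng.integers(2_000, 20_000))
            start = int(rng.integers(flank, size - length - flank))
            sv = SVRecord(chrom=chrom, start=start, end=start + length,
                          sv_type=sv_type, id=f"sv_{k:04d}")
            svs.append(sv)
            associated = (
                sv_type in associated_types and rng.random() < association_rate
            )
            if associated:
                for bp in (sv.start, sv.end):
                    te_len = int(rng.integers(150, 300))
                    lo = bp - flank
                    te_start = int(rng.integers(lo, bp + flank - te_len))
                    tes.append(TERecord(chrom=chrom, start=te_start,
                                        end=te_start + te_len, strand="+",
                                        superfamily=focal_family,
                                        role="fragment", method="homology",
                                        name=f"planted_{k}_{bp}"))
            truth_rows.append({"sv_id": sv.id, "sv_type": sv_type,
                               "chrom": chrom, "start": sv.start, "end": sv.end,
                               "associated": associated})
            k += 1

    for fam in families:
        for chrom in chroms:
            n = rng.poisson(te_per_mb * chrom_sizes[chrom] / 1e6)
            for j in range(n):
                te_len = int(rng.integers(300, 3_000))
                start = int(rng.integers(0, chrom_sizes[chrom] - te_len))
                tes.append(TERecord(chrom=chrom, start=start, end=start + te_len,
                                    strand="+", superfamily=fam, role="fragment",
                                    method="homology",
                                    name=f"bg_{fam.split('/')[-1]}_{chrom}_{j}"))
    bundle = TruthBundle(
        kind="sv_dataset", seed=seed,
        params={"chrom_sizes": dict(chrom_sizes), "te_per_mb": te_per_mb,
                "association_rate": association_rate,
                "focal_family": focal_family, "flank": flank},
        truth={"svs": pd.DataFrame(truth_rows)},
    )
    return svs, tes, bundle


# ---------------------------------------------------------------------------
# cassettes, MSAs, CpG sequences


def simulate_cassette_region(
    signature: Sequence[tuple[str, str, str]],
    subject_id: str = "chrom7",
    spacing: int = 70_000,
    seed: int = 0,
) -> tuple[list[HitRecord], list[HitRecord], TruthBundle]:
    """Noiseless synthase/LTR08 hit tables realizing a requested signature.

    ``signature`` is an ordered list of (type, completeness, strand).
    Partial CBDAS entries are realized through the LTR08-proximity rule
    (the hit's own query is THCAS, with a qualifying LTR08 hit nearby);
    other entries are realized directly.  ``spacing`` must exceed the
    60-kb proximity radius so a planted LTR08 can only affect its own hit.
    """
    if spacing <= 62_000:
        raise ValueError("spacing must exceed the LTR08 proximity radius")
    rng = _rng(seed, 5)
    syn_hits: list[HitRecord] = []
    ltr_hits: list[HitRecord] = []
    pos = 100_000
    for syn_type, completeness, strand in signature:
        if syn_type not in ("THCAS", "CBDAS", "CBCAS"):
            raise ValueError(f"unknown synthase type {syn_type!r}")
        if completeness not in ("Full", "Partial"):
            raise ValueError(f"unknown completeness {completeness!r}")
        length = int(rng.integers(1200, 1700))
        sstart, send = pos + 1, pos + length
        if strand == "-":
            sstart, send = send, sstart
        if completeness == "Full":
            mism, gaps, query = int(rng.integers(0, 9)), 0, f"{syn_type}_ref"
        else:
            mism, gaps = int(rng.integers(15, 40)), int(rng.integers(0, 3))
            if syn_type == "CBDAS":
                # realized via the LTR08-proximity rule
                query = "THCAS_ref"
                ls = pos + length + 5_000
                ltr_hits.append(HitRecord(
                    query_id="LTR08", subject_id=subject_id, pident=98.0,
                    length=2_000, mismatches=5, gapopen=0, qstart=1, qend=2_000,
                    sstart=ls + 1, send=ls + 2_000, evalue=0.0, bitscore=2_500.0,
                ))
            else:
                query = f"{syn_type}_ref"
        syn_hits.append(HitRecord(
            query_id=query, subject_id=subject_id, pident=95.0, length=length,
            mismatches=mism, gapopen=gaps, qstart=1, qend=length,
            sstart=sstart, send=send, evalue=0.0,
            bitscore=float(2 * length - 20 * mism),
        ))
        pos += spacing
    bundle = TruthBundle(
        kind="cassette_region", seed=seed,
        params={"subject_id": subject_id, "spacing": spacing},
        truth={"signature": pd.DataFrame(
            [{"order": i, "type": t, "completeness": c, "strand": s}
             for i, (t, c, s) in enumerate(signature)]
        )},
    )
    return syn_hits, ltr_hits, bundle


def simulate_msa(
    n_seqs: int = 8,
    length: int = 120,
    diversity: float = 0.1,
    alphabet: str = "protein",
    seed: int = 0,
):
    """MSA at a target per-column diversity.

    Each column starts from a single ancestral symbol; with probability
    ``diversity`` per row the symbol is replaced by a uniform random draw
    from the alphabet.  ``diversity = 0`` gives identical rows (zero
    entropy).
    """
    from .seqstats import AlignmentBlock

    symbols = list("ACDEFGHIKLMNPQRSTVWY") if alphabet == "protein" else list("ACGT")
    rng = _rng(seed, 6)
    anc = rng.choice(symbols, size=length)
    rows = []
    for _ in range(n_seqs):
        row = anc.copy()
        mask = rng.random(length) < diversity
        row[mask] = rng.choice(symbols, size=int(mask.sum()))
        rows.append("".join(row))
    block = AlignmentBlock(
        ids=[f"seq{i}" for i in range(n_seqs)], rows=rows, alphabet=alphabet
    )
    bundle = TruthBundle(
        kind="msa", seed=seed,
        params={"n_seqs": n_seqs, "length": length, "diversity": diversity,
                "alphabet": alphabet},
    )
    return block, bundle


def simulate_cpg_sequence(
    length: int = 5_000,
    islands: Sequence[tuple[int, int]] = ((2_000, 300),),
    background_gc: float = 0.35,
    island_gc: float = 0.65,
    island_cpg: float = 0.15,
    seed: int = 0,
) -> tuple[str, TruthBundle]:
    """Sequence embedding CpG islands in a CpG-poor, AT-rich background.

    ``islands`` lists (start, length) pairs.  Island sequence is built
    dinucleotide-wise: with probability ``island_cpg`` a CG pair, otherwise
    two independent bases at ``island_gc`` GC content — giving o/e well
    above the 0.6 calling threshold.  The background's GC content sits
    below the 50% threshold, so no spurious islands arise.
    """
    if island_cpg >= 0.5 or island_gc <= 0 or island_gc >= 1:
        raise ValueError("unsatisfiable island composition")
    rng = _rng(seed, 7)
    seq = list(_random_seq(rng, length, gc=background_gc))
    rows = []
    for start, ilen in islands:
        if not 0 <= start < start + ilen <= length:
            raise ValueError("island outside sequence")
        chunk: list[str] = []
        while len(chunk) < ilen:
            if rng.random() < island_cpg:
                chunk.extend("CG")
            else:
                chunk.extend(_random_seq(rng, 2, gc=island_gc))
        seq[start : start + ilen] = chunk[:ilen]
        rows.append({"start": start, "end": start + ilen})
    bundle = TruthBundle(
        kind="cpg_sequence", seed=seed,
        params={"length": length, "background_gc": background_gc,
                "island_gc": island_gc, "island_cpg": island_cpg},
        truth={"islands": pd.DataFrame(rows, columns=["start", "end"])},
    )
    return "".join(seq), bundle
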