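"""Readers and writers for the formats the analyses consume and emit.

Internal coordinates are 0-based half-open everywhere; conversion happens
only at the I/O boundary (GFF3 and VCF are 1-based closed on disk, BED and
the tabular outputs are 0-based half-open).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cassettes import HitRecord
from .curves import CollectorCurve, PresenceMatrix
from .seqstats import GenotypeSite
from .sv import SVRecord
from .te import SoloCall, TERecord

# ---------------------------------------------------------------------------
# presence matrices


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    """Read a presence matrix from TSV.

    Accepts the wide format (header of haplotype ids, one 0/1 row per
    orthogroup, first column the orthogroup id) or a two-column long
    format (orthogroup_id, haplotype_id) listing present pairs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] == 2 and set(df.columns) >= {"orthogroup_id", "haplotype_id"}:
        ogs = sorted(df["orthogroup_id"].unique())
        haps = sorted(df["haplotype_id"].unique())
        present = np.zeros((len(ogs), len(haps)), dtype=np.uint8)
        og_idx = {o: i for i, o in enumerate(ogs)}
        hap_idx = {h: j for j, h in enumerate(haps)}
        for o, h in zip(df["orthogroup_id"], df["haplotype_id"]):
            present[og_idx[o], hap_idx[h]] = 1
        return PresenceMatrix(orthogroup_ids=ogs, haplotype_ids=haps, present=present)
    first = df.columns[0]
    ogs = df[first].tolist()
    haps = list(df.columns[1:])
    present = df[haps].astype(np.uint8).to_numpy()
    return PresenceMatrix(orthogroup_ids=ogs, haplotype_ids=haps, present=present)


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.present, index=matrix.orthogroup_ids, columns=matrix.haplotype_ids
    )
    df.index.name = "orthogroup_id"
    df.to_csv(path, sep="\t")


def write_curve(curve: CollectorCurve, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "h": np.arange(1, curve.H + 1),
            "expected_count": curve.values,
            "n_threshold": str(curve.n_threshold),
        }
    )
    if curve.stderr is not None:
        df["stderr"] = curve.stderr
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TE GFF3 dialect (EDTA-style attributes Identity/Method/Classification/Name)

_ROLE_TO_TYPE = {
    "intact_element": "LTR_retrotransposon",
    "long_terminal_repeat": "long_terminal_repeat",
    "internal": "internal_region",
    "fragment": "repeat_fragment",
}
_TYPE_TO_ROLE = {v: k for k, v in _ROLE_TO_TYPE.items()}


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key] = value
    return out


def read_te_gff3(path: str | Path) -> list[TERecord]:
    """Read TE annotations from the EDTA-style GFF3 dialect.

    1-based closed coordinates are converted to 0-based half-open; the
    attributes Identity (fraction), Method (structural|homology),
    Classification (superfamily) and Name (family id) are promoted to
    record fields, other attributes preserved.  Records missing Identity
    are kept with identity missing.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _, ftype, start, end, score, strand, _, attr_field = fields
            attrs = _parse_attrs(attr_field)
            role = _TYPE_TO_ROLE.get(ftype)
            if role is None:
                low = ftype.lower()
                if "long_terminal_repeat" in low:
                    role = "long_terminal_repeat"
                elif attrs.get("Name", "").endswith("_INT") or "internal" in low:
                    role = "internal"
                elif "retrotransposon" in low or "te" == low:
                    role = "intact_element"
                else:
                    role = "fragment"
            identity = attrs.get("Identity")
            records.append(
                TERecord(
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    superfamily=attrs.get("Classification", ""),
                    role=role,
                    method=attrs.get("Method", "homology"),
                    name=attrs.get("Name", ""),
                    element_id=(
                        attrs.get("ID") if role == "intact_element" else attrs.get("Parent")
                    ),
                    identity=float(identity) if identity not in (None, "", "NA") else None,
                    score=float(score) if score not in (".", "") else None,
                    attrs={k: v for k, v in attrs.items()
                           if k not in ("Identity", "Method", "Classification", "Name")},
                )
            )
    return records


def write_te_gff3(records: Sequence[TERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sorted(records, key=lambda x: (x.chrom, x.start, x.end, x.name)):
            attrs = []
            if r.element_id:
                key = "ID" if r.role == "intact_element" else "Parent"
                attrs.append(f"{key}={r.element_id}")
            if r.name:
                attrs.append(f"Name={r.name}")
            if r.superfamily:
                attrs.append(f"Classification={r.superfamily}")
            attrs.append(f"Method={r.method}")
            if r.identity is not None:
                attrs.append(f"Identity={r.identity:.4g}")
            for k, v in r.attrs.items():
                attrs.append(f"{k}={v}")
            score = f"{r.score:.6g}" if r.score is not None else "."
            fh.write(
                "\t".join(
                    [
                        r.chrom, "panmosaic", _ROLE_TO_TYPE[r.role],
                        str(r.start + 1), str(r.end), score, r.strand, ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_solo_calls(calls: Sequence[SoloCall], gff_path: str | Path,
                     audit_path: str | Path) -> None:
    write_te_gff3([c.record for c in calls if c.passed], gff_path)
    rows = []
    for c in calls:
        row = {"chrom": c.record.chrom, "start": c.record.start,
               "end": c.record.end, "name": c.record.name, "passed": c.passed}
        row.update({k: ("skip" if v is None else v) for k, v in c.audit.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(audit_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[tuple]:
    """Read BED3+ as (chrom, start, end, *extra) tuples (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return out


def write_bed(intervals: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x[0], int(x[1]), int(x[2]))):
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_sv_bed(path: str | Path) -> list[SVRecord]:
    """SVs from BED with sv_type in column 4 (id optional in column 5)."""
    out = []
    for i, row in enumerate(read_bed(path)):
        chrom, start, end, *extra = row
        if not extra:
            raise ValueError(f"SV BED needs sv_type in column 4 (row {i + 1})")
        sv_id = extra[1] if len(extra) > 1 else f"sv_{i:04d}"
        out.append(SVRecord(chrom=chrom, start=start, end=end,
                            sv_type=extra[0], id=sv_id))
    return out


# ---------------------------------------------------------------------------
# 12-column tabular alignment hits


def read_hits_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular alignment file (outfmt-6 layout)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 fields, got {len(f)}")
            try:
                out.append(
                    HitRecord(
                        query_id=f[0], subject_id=f[1], pident=float(f[2]),
                        length=int(f[3]), mismatches=int(f[4]), gapopen=int(f[5]),
                        qstart=int(f[6]), qend=int(f[7]), sstart=int(f[8]),
                        send=int(f[9]), evalue=float(f[10]), bitscore=float(f[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_hits_table(hits: Sequence[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, h.pident, h.length, h.mismatches,
                        h.gapopen, h.qstart, h.qend, h.sstart, h.send, h.evalue,
                        h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF genotypes


def read_genotypes_vcf(path: str | Path) -> tuple[list[GenotypeSite], dict[str, int]]:
    """Read biallelic SNP genotypes from a VCF.

    Phased and unphased GT are treated identically; missing calls become
    code -1.  Multi-allelic and indel sites are skipped and tallied in the
    returned counter.
    """
    import pysam

    sites = []
    skipped = {"multiallelic": 0, "indel": 0}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                skipped["multiallelic"] += 1
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                skipped["indel"] += 1
                continue
            codes = []
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    codes.append(-1)
                else:
                    codes.append(sum(gt))
            sites.append(
                GenotypeSite(site_id=f"{rec.chrom}:{rec.pos}", genotypes=np.array(codes))
            )
    return sites, skipped


def write_genotypes_vcf(
    sites: Sequence[GenotypeSite],
    path: str | Path,
    chrom: str = "chr1",
    n_samples: int | None = None,
) -> None:
    """Write biallelic SNP genotypes as a minimal plain-text VCF."""
    if n_samples is None:
        n_samples = len(sites[0].genotypes)
    gt_map = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={10 * len(sites) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"s{i:03d}" for i in range(n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for i, site in enumerate(sites):
            gts = "\t".join(gt_map[int(g)] for g in site.genotypes)
            fh.write(
                f"{chrom}\t{10 * i + 1}\t{site.site_id}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# FASTA and alignments


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_alignment(path: str | Path, alphabet: str = "protein"):
    from .seqstats import AlignmentBlock

    seqs = read_fasta(path)
    return AlignmentBlock(ids=list(seqs), rows=list(seqs.values()), alphabet=alphabet)


# ---------------------------------------------------------------------------
# anchor tracks / crossovers / manifests


def write_anchor_track(track, path: str | Path) -> None:
    """AnchorTrack as BED-graph-style TSV (0-based half-open)."""
    rows = [
        {
            "chrom": track.query_id,
            "start": w.start,
            "end": w.end,
            "fraction": w.fraction,
            "n_valid": w.n_valid,
            "informative": w.informative,
        }
        for w in track.windows
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_crossovers(calls, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.query_id}\t{c.position}\t{c.position + 1}\t"
                f"{c.from_parent}->{c.to_parent}\t{c.support[0]},{c.support[1]}\n"
            )


def write_manifest(path: str | Path, command: str, params: Mapping) -> None:
    """Machine-readable run manifest sufficient to reproduce a run."""
    from . import __version__

    payload = {"tool": "panmosaic", "version": __version__, "command": command,
               "params": {k: str(v) for k, v in params.items()}}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
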