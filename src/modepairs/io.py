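"""Readers and writers for the formats the pipeline touches.

Minimal VCF 4.x subset (CHROM, POS, REF, ALT, QUAL, FORMAT with GT/DP) via
cyvcf2, BED3 masks, TSV tables for study designs / SV calls / branch scores /
TE fractions, and JSON for results. Only GT and DP FORMAT keys are consumed;
unknown keys are ignored.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    BranchScore,
    CallableMask,
    Genotype,
    SpeciesEntry,
    StudyDesign,
    SVRecord,
    VariantRecord,
)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _validate_vcf_layout(path: str) -> None:
    """Light structural check so malformed files fail with a line number.

    cyvcf2/htslib silently skips some malformed lines; the pipeline's error
    contract requires a parse error naming the line instead.
    """
    n_cols = None
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise ParseError(f"{path}: line 1: missing ##fileformat=VCF header")
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    raise ParseError(
                        f"{path}: line {lineno}: #CHROM line has {len(fields)} "
                        "columns; need FORMAT plus at least one sample"
                    )
                n_cols = len(fields)
                continue
            if not line.strip():
                continue
            if n_cols is None:
                raise ParseError(f"{path}: line {lineno}: data before #CHROM header")
            if len(fields) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(fields)}"
                )
            if "GT" not in fields[8].split(":"):
                raise ParseError(f"{path}: line {lineno}: FORMAT lacks GT")
    if n_cols is None:
        raise ParseError(f"{path}: missing #CHROM header line")


def _classify(alleles: Sequence[int]) -> Genotype:
    # Any genotype with two distinct allele indices counts as het (multi-
    # allelic calls like 1/2 included); any missing allele -> missing.
    if any(a < 0 for a in alleles):
        return Genotype.MISSING
    if len(set(alleles)) > 1:
        return Genotype.HET
    return Genotype.HOM_REF if alleles[0] == 0 else Genotype.HOM_ALT


def read_vcf_minimal(path: str) -> list[VariantRecord]:
    """Read a minimal VCF into VariantRecords (one per data line)."""
    from cyvcf2 import VCF

    _validate_vcf_layout(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for var in vcf:
        gts = {s: _classify(g[:-1]) for s, g in zip(samples, var.genotypes)}
        dp = var.format("DP")
        if dp is None:
            depths = {s: 0 for s in samples}
        else:
            dp = dp.reshape(len(samples), -1)[:, 0]
            depths = {s: int(d) if d >= 0 else 0 for s, d in zip(samples, dp)}
        records.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=",".join(var.ALT) if var.ALT else ".",
                qual=float(var.QUAL) if var.QUAL is not None else 0.0,
                genotypes=gts,
                depths=depths,
            )
        )
    return records


_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf_minimal(
    records: Iterable[VariantRecord],
    path: str,
    samples: Sequence[str] | None = None,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write VariantRecords as an uncompressed minimal VCF."""
    records = list(records)
    if samples is None:
        samples = sorted({s for r in records for s in r.genotypes})
        if not samples:
            raise ValueError("no samples; pass samples= for an empty VCF")
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(contigs):
            fh.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            cols = [
                r.chrom,
                str(r.pos),
                ".",
                r.ref,
                r.alt,
                f"{r.qual:.1f}",
                "PASS",
                ".",
                "GT:DP",
            ]
            for s in samples:
                gt = _GT_STRING[r.genotypes.get(s, Genotype.MISSING)]
                dp = r.depths.get(s, 0)
                cols.append(f"{gt}:{dp}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BED masks
# ---------------------------------------------------------------------------

def read_mask(path: str) -> CallableMask:
    """Read a BED3 file (0-based half-open) into a normalized CallableMask."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: need 3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if end <= start:
                raise ParseError(
                    f"{path}: line {lineno}: end ({end}) must exceed start ({start})"
                )
            intervals.setdefault(chrom, []).append((start, end))
    return CallableMask(intervals)


def write_mask(mask: CallableMask, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in mask.chroms():
            for s, e in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

def read_design(path: str) -> StudyDesign:
    """Read a design TSV: species_id, pair_id, mode, individuals (comma-sep)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_id", "pair_id", "mode", "individuals"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing design columns {sorted(missing)}")
    entries = [
        SpeciesEntry(
            species_id=row.species_id,
            pair_id=row.pair_id,
            mode=row.mode,
            individuals=tuple(row.individuals.split(",")) if row.individuals else (),
        )
        for row in df.itertuples()
    ]
    return StudyDesign(tuple(entries))


def write_design(design: StudyDesign, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tpair_id\tmode\tindividuals\n")
        for s in design.species:
            fh.write(f"{s.species_id}\t{s.pair_id}\t{s.mode}\t{','.join(s.individuals)}\n")


# ---------------------------------------------------------------------------
# SV tables
# ---------------------------------------------------------------------------

SV_COLUMNS = [
    "chrom", "start", "end", "sv_type", "length", "strand_pair",
    "support_sr", "support_pe", "sample", "genotype", "sample_coverage",
]


def read_sv_table(path: str) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(SV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing SV columns {sorted(missing)}")
    return [
        SVRecord(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            sv_type=row.sv_type,
            length=int(row.length),
            strand_pair=row.strand_pair,
            support_sr=int(row.support_sr),
            support_pe=int(row.support_pe),
            sample=row.sample,
            genotype=row.genotype,
            sample_coverage=float(row.sample_coverage),
        )
        for row in df.itertuples()
    ]


def write_sv_table(
    records: Iterable[SVRecord], path: str, origins: Sequence[str] | None = None
) -> None:
    """Write SV calls as TSV; ``origins`` adds a simulation ground-truth column."""
    records = list(records)
    with open(path, "w") as fh:
        cols = list(SV_COLUMNS) + (["origin"] if origins is not None else [])
        fh.write("\t".join(cols) + "\n")
        for i, r in enumerate(records):
            row = [
                r.chrom, str(r.start), str(r.end), r.sv_type, str(r.length),
                r.strand_pair, str(r.support_sr), str(r.support_pe), r.sample,
                r.genotype, f"{r.sample_coverage:.2f}",
            ]
            if origins is not None:
                row.append(origins[i])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Branch scores and TE fractions
# ---------------------------------------------------------------------------

def read_branch_scores(path: str) -> list[BranchScore]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "species_id": str})
    required = {"gene_id", "species_id", "delta_lnl"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing score columns {sorted(missing)}")

    def _opt(row, name):
        if name not in df.columns:
            return None
        v = getattr(row, name)
        return None if pd.isna(v) else float(v)

    return [
        BranchScore(
            gene_id=row.gene_id,
            species_id=row.species_id,
            delta_lnl=float(row.delta_lnl),
            pvalue=_opt(row, "pvalue"),
            qvalue=_opt(row, "qvalue"),
            prop_sites_selected=_opt(row, "prop_sites_selected"),
        )
        for row in df.itertuples()
    ]


def write_branch_scores(scores: Iterable[BranchScore], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tspecies_id\tdelta_lnl\tpvalue\tqvalue\tprop_sites_selected\n")
        for s in scores:
            fields = [s.gene_id, s.species_id, f"{s.delta_lnl:.6g}"]
            for v in (s.pvalue, s.qvalue, s.prop_sites_selected):
                fields.append("" if v is None else f"{v:.6g}")
            fh.write("\t".join(fields) + "\n")


def read_te_fractions(path: str) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str})
    if not {"species_id", "te_fraction"} <= set(df.columns):
        raise ParseError(f"{path}: need columns species_id, te_fraction")
    return {row.species_id: float(row.te_fraction) for row in df.itertuples()}


def write_te_fractions(fractions: dict[str, float], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tte_fraction\n")
        for sp, f in fractions.items():
            fh.write(f"{sp}\t{f:.6f}\n")


# ---------------------------------------------------------------------------
# JSON results
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj: dict, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, allow_nan=True)
        fh.write("\n")
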