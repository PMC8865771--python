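"""Heterozygosity and SNP-sharing statistics.

A conservative SNP set is retained (quality >= 300 and depth >= 15x in at
least one individual), and per-individual heterozygosity is the number of
heterozygous SNPs divided by the number of callable sites. Species pairs are
compared through the fold-difference of species-mean rates, and the origin of
parthenogen variation through the fraction of its SNP positions that are also
polymorphic in the sexual relative.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .datamodel import CallableMask, Genotype, HetEstimate, SVRecord, VariantRecord

DEFAULT_MIN_QUAL = 300.0
DEFAULT_MIN_DEPTH = 15


def filter_snps(
    records: Iterable[VariantRecord],
    min_qual: float = DEFAULT_MIN_QUAL,
    min_depth: int = DEFAULT_MIN_DEPTH,
    depth_rule: str = "any_sample",
) -> list[VariantRecord]:
    """Keep records with qual >= min_qual and sufficient depth.

    ``depth_rule="any_sample"`` (default) requires depth >= min_depth in at
    least one sample of the record; ``"per_sample"`` requires it in every
    sample. Filtering is idempotent.
    """
    if min_qual < 0 or min_depth < 0:
        raise ValueError("thresholds must be >= 0")
    if depth_rule not in ("any_sample", "per_sample"):
        raise ValueError(f"unknown depth_rule {depth_rule!r}")
    out = []
    for r in records:
        if r.qual < min_qual:
            continue
        depths = [r.depths.get(s, 0) for s in r.genotypes]
        ok = (
            any(d >= min_depth for d in depths)
            if depth_rule == "any_sample"
            else all(d >= min_depth for d in depths)
        )
        if ok:
            out.append(r)
    return out


def snp_heterozygosity(
    records: Sequence[VariantRecord],
    mask: CallableMask,
    sample: str,
    species_id: str = "",
) -> HetEstimate:
    """Heterozygosity of one sample: het SNPs inside the mask / callable sites.

    Records are assumed already filtered. Missing genotypes never enter the
    numerator; the denominator comes only from the mask.
    """
    n_callable = mask.total_length()
    if n_callable == 0:
        raise ValueError("callable length is zero; heterozygosity undefined")
    n_het = sum(
        1
        for r in records
        if r.genotypes.get(sample) == Genotype.HET and mask.contains(r.chrom, r.pos - 1)
    )
    return HetEstimate(species_id=species_id, sample=sample, n_het=n_het, n_callable=n_callable)


def sv_het_rate(
    svrecords: Iterable[SVRecord],
    mask: CallableMask,
    sample: str,
    species_id: str = "",
) -> HetEstimate:
    """Heterozygous-SV rate for one sample over the callable sites."""
    n_callable = mask.total_length()
    if n_callable == 0:
        raise ValueError("callable length is zero; SV rate undefined")
    n_het = sum(1 for r in svrecords if r.sample == sample and r.genotype == "het")
    return HetEstimate(species_id=species_id, sample=sample, n_het=n_het, n_callable=n_callable)


def fold_difference(
    sexual_rates: Sequence[float],
    asexual_rates: Sequence[float],
    aggregate: str = "mean",
) -> tuple[float, bool]:
    """Fold-difference between species-level rates: agg(sexual) / agg(asexual).

    Returns ``(ratio, is_infinite)``; when the parthenogen aggregate is zero
    the ratio is ``inf`` and the flag is set. ``aggregate`` is ``"mean"``
    (default) or ``"median"``.
    """
    if len(sexual_rates) == 0 or len(asexual_rates) == 0:
        raise ValueError("both rate lists must be non-empty")
    agg = {"mean": np.mean, "median": np.median}.get(aggregate)
    if agg is None:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    num = float(agg(sexual_rates))
    den = float(agg(asexual_rates))
    if den == 0.0:
        return math.inf, True
    return num / den, False


def shared_snp_fraction(
    asex_positions: set, sex_polymorphic_positions: set
) -> float:
    """Fraction of parthenogen SNP positions also polymorphic in the sexual.

    Positions are compared as given (e.g. ``(chrom, pos)`` keys on a shared
    coordinate system); no coordinate lifting is performed here.
    """
    if not asex_positions:
        raise ValueError("empty parthenogen position set; fraction undefined")
    return len(asex_positions & sex_polymorphic_positions) / len(asex_positions)


def het_positions(
    records: Iterable[VariantRecord], samples: Sequence[str]
) -> set[tuple[str, int]]:
    """Positions at which any of ``samples`` carries a heterozygous genotype."""
    out = set()
    for r in records:
        if any(r.genotypes.get(s) == Genotype.HET for s in samples):
            out.add((r.chrom, r.pos))
    return out


def polymorphic_positions(
    records: Iterable[VariantRecord], samples: Sequence[str]
) -> set[tuple[str, int]]:
    """Positions with an alternate allele observed in >= 1 of ``samples``."""
    out = set()
    for r in records:
        for s in samples:
            if r.genotypes.get(s) in (Genotype.HET, Genotype.HOM_ALT):
                out.add((r.chrom, r.pos))
                break
    return out
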