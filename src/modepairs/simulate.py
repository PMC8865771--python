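"""Synthetic study generator.

Emulates the data structure of a replicated sexual-vs-parthenogenetic
resequencing study: P species pairs, up to five resequenced individuals per
species, per-individual SNP calls over a callable mask, Manta-like SV call
tables with planted false positives at twice the expected coverage,
per-branch likelihood-ratio scores with a configurable excess of selection on
sexual branches, and TE read fractions with a clade effect but no
reproductive-mode effect. Everything is deterministic under a master seed
with named child streams, so adding individuals does not perturb branch
scores.

The generator works at desk scale (a single chromosome of ``L`` callable
sites); it emulates the statistical structure of the study, not sequence
data.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats as sps

from . import io as mio
from .datamodel import (
    PARTHENOGENETIC,
    SEXUAL,
    BranchScore,
    CallableMask,
    Genotype,
    SpeciesEntry,
    StudyDesign,
    SVRecord,
    VariantRecord,
)

_BASES = np.array(list("ACGT"))


def child_rng(master_seed: int, *keys) -> np.random.Generator:
    """A named, reproducible child stream of the master seed."""
    ints = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Defaults echo the scales of the real study: five pairs with five
    resequenced individuals per species, sexual per-site heterozygosity a few
    per mille, parthenogen heterozygosity below 1e-5, 6-19% of parthenogen
    SNPs drawn from the ancestral polymorphism pool, TE read fractions around
    20-23.6% differing between clades but not between modes, and 7155 genes
    scored on every terminal branch.
    """

    n_pairs: int = 5
    n_individuals: int = 5
    L: int = 1_000_000
    pi_sexual: float = 4e-3
    pi_asexual: float = 5e-6
    # heterozygosity-decay model for parthenogens (used when use_decay=True)
    h0: float = 5e-3
    lambda_loss: float = 0.01
    mu_het: float = 6e-9
    t_gens: int = 1000
    use_decay: bool = False
    f_shared: float = 0.12
    # SV model
    sv_rate: float = 2e-5
    fp_sv_rate: float = 5e-6
    sv_short_frac: float = 0.15
    sv_carrier_prob: float = 0.7
    het_sv_prob_sexual: float = 0.7
    het_sv_prob_asexual: float = 0.02
    # selection model
    n_genes: int = 7155
    sel_frac_sexual: float = 0.06
    sel_frac_asexual: float = 0.03
    effect_size: float = 25.0
    null_mixture: bool = False
    # TE model
    te_mean: float = 0.218
    te_sd: float = 0.004
    te_clade_shift: float = 0.013
    # sequencing nuisance parameters
    mean_depth: float = 40.0
    filter_fail_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_sexual", "pi_asexual", "f_shared", "sv_rate", "fp_sv_rate",
                     "sv_short_frac", "sv_carrier_prob", "sel_frac_sexual",
                     "sel_frac_asexual", "filter_fail_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.L < 1 or self.n_pairs < 1 or self.n_individuals < 1:
            raise ValueError("L, n_pairs and n_individuals must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def make_design(n_pairs: int, n_individuals: int) -> StudyDesign:
    """Standard study design: pair01..pairNN, one species per mode each."""
    entries = []
    for j in range(1, n_pairs + 1):
        pid = f"pair{j:02d}"
        for mode, tag in ((SEXUAL, "sex"), (PARTHENOGENETIC, "asex")):
            sp = f"{pid}_{tag}"
            entries.append(
                SpeciesEntry(
                    species_id=sp,
                    pair_id=pid,
                    mode=mode,
                    individuals=tuple(
                        f"{sp}_i{k}" for k in range(1, n_individuals + 1)
                    ),
                )
            )
    return StudyDesign(tuple(entries))


def expected_heterozygosity(
    h0: float, lambda_loss: float, mu_het: float, t: float
) -> float:
    """Expected heterozygosity after t generations of automictic decay.

    Recurrence h_{t+1} = (1 - lambda) h_t + 2 mu: each generation a fraction
    ``lambda_loss`` of heterozygous sites becomes homozygous (as under
    inbreeding-like automixis) while new mutation injects 2*mu of
    heterozygosity per site. Closed form for lambda > 0:
    h_t = (h0 - h*) (1 - lambda)^t + h*, with equilibrium h* = 2 mu / lambda;
    for lambda = 0 heterozygosity accumulates linearly, h_t = h0 + 2 mu t.
    """
    if not (0.0 <= lambda_loss <= 1.0):
        raise ValueError("lambda_loss must lie in [0, 1]")
    if mu_het < 0 or t < 0:
        raise ValueError("mu_het and t must be >= 0")
    if lambda_loss == 0.0:
        return h0 + 2.0 * mu_het * t
    h_star = 2.0 * mu_het / lambda_loss
    return (h0 - h_star) * (1.0 - lambda_loss) ** t + h_star


def simulate_genotypes(
    pi: float,
    L: int,
    n_individuals: int,
    seed,
    sample_names: Sequence[str] | None = None,
    chrom: str = "chr1",
    mean_depth: float = 40.0,
    fail_frac: float = 0.0,
    positions_pool: np.ndarray | None = None,
) -> tuple[dict[str, list[VariantRecord]], CallableMask]:
    """Per-individual heterozygous SNP records over a fully callable genome.

    Each individual carries Binomial(L, pi) heterozygous sites at uniform
    positions. Emitted qualities and depths pass the default SNP filters
    (qual >= 300, depth >= 15) except for a fraction ``fail_frac`` planted to
    fail them. ``positions_pool`` optionally supplies the positions to draw
    from (used for the shared-SNP structure); default is the whole genome.
    """
    if not (0.0 <= pi <= 1.0):
        raise ValueError("pi must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sample_names is None:
        sample_names = [f"ind{k}" for k in range(1, n_individuals + 1)]
    mask = CallableMask({chrom: [(0, L)]})
    out: dict[str, list[VariantRecord]] = {}
    for sample in sample_names:
        n_het = rng.binomial(L, pi)
        if positions_pool is not None:
            pos0 = rng.choice(positions_pool, size=min(n_het, len(positions_pool)), replace=False)
        else:
            pos0 = rng.choice(L, size=n_het, replace=False)
        pos0 = np.sort(pos0)
        quals = 300.0 + rng.exponential(150.0, size=len(pos0))
        depths = 15 + rng.poisson(max(mean_depth - 15.0, 1.0), size=len(pos0))
        if fail_frac > 0 and len(pos0):
            bad = rng.random(len(pos0)) < fail_frac
            low_qual = rng.random(len(pos0)) < 0.5
            quals[bad & low_qual] = rng.uniform(0, 299.0, size=int((bad & low_qual).sum()))
            depths[bad & ~low_qual] = rng.integers(1, 15, size=int((bad & ~low_qual).sum()))
        refs = _BASES[rng.integers(0, 4, size=len(pos0))]
        alts = np.array(
            [_BASES[(list(_BASES).index(r) + rng.integers(1, 4)) % 4] for r in refs]
        )
        out[sample] = [
            VariantRecord(
                chrom=chrom,
                pos=int(p) + 1,
                ref=str(r),
                alt=str(a),
                qual=float(q),
                genotypes={sample: Genotype.HET},
                depths={sample: int(d)},
            )
            for p, r, a, q, d in zip(pos0, refs, alts, quals, depths)
        ]
    return out, mask


def simulate_shared_positions(
    n_asex_snps: int,
    f_shared: float,
    ancestral_pool: np.ndarray,
    L: int,
    seed,
) -> np.ndarray:
    """Parthenogen SNP positions, a fraction of which sit in the ancestral pool.

    Each position is drawn from ``ancestral_pool`` with probability
    ``f_shared`` and uniformly outside it otherwise; all returned positions
    are distinct, 0-based in [0, L).
    """
    if not (0.0 <= f_shared <= 1.0):
        raise ValueError("f_shared must lie in [0, 1]")
    pool = np.asarray(ancestral_pool)
    if len(pool) > L or (len(pool) and (pool.min() < 0 or pool.max() >= L)):
        raise ValueError("ancestral pool must be a subset of [0, L)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_shared = rng.binomial(n_asex_snps, f_shared)
    n_shared = min(n_shared, len(pool))
    shared = rng.choice(pool, size=n_shared, replace=False)
    complement = np.setdiff1d(np.arange(L, dtype=np.int64), pool, assume_unique=False)
    n_new = n_asex_snps - n_shared
    if n_new > len(complement):
        raise ValueError("genome too small for the requested SNP count")
    novel = rng.choice(complement, size=n_new, replace=False)
    return np.sort(np.concatenate([shared, novel]))


def _sv_locus(rng: np.random.Generator, L: int, short: bool) -> dict:
    sv_type = ("DEL", "INS", "DUP", "INV")[rng.integers(0, 4)]
    if short:
        length = int(rng.integers(1, 31))  # planted to fail the length filter
    else:
        length = 31 + int(rng.lognormal(4.5, 1.0))
    start = int(rng.integers(1, max(L - length, 2)))
    end = start if sv_type == "INS" else start + length
    strand = "+/-" if sv_type == "INV" else "+/+"
    return {"sv_type": sv_type, "length": length, "start": start, "end": end,
            "strand_pair": strand}


def simulate_sv_calls(
    config: SimConfig,
    species_mode: Mapping[str, str],
    samples_by_species: Mapping[str, Sequence[str]],
    seed: int | None = None,
    chrom: str = "chr1",
) -> tuple[list[SVRecord], list[str]]:
    """Manta-like SV calls per individual, with planted filter failures.

    Species-level SV loci are shared by carrier individuals (with small
    breakpoint jitter, so population merging can recover them). True calls
    get locus coverage near the sample mean; planted false positives sit near
    twice that coverage, and a configurable fraction of true loci is 30 bp or
    shorter. Returns the records and a parallel origin label per record
    (``true`` / ``short`` / ``fp_2x``).
    """
    master = config.seed if seed is None else seed
    records: list[SVRecord] = []
    origins: list[str] = []
    for si, (species, samples) in enumerate(sorted(samples_by_species.items())):
        rng = child_rng(master, "sv", species)
        het_p = (
            config.het_sv_prob_sexual
            if species_mode[species] == SEXUAL
            else config.het_sv_prob_asexual
        )
        n_true = rng.binomial(config.L, config.sv_rate)
        n_fp = rng.binomial(config.L, config.fp_sv_rate)
        loci = []
        for _ in range(n_true):
            short = bool(rng.random() < config.sv_short_frac)
            loci.append((_sv_locus(rng, config.L, short), "short" if short else "true"))
        for _ in range(n_fp):
            loci.append((_sv_locus(rng, config.L, False), "fp_2x"))
        for locus, origin in loci:
            for sample in samples:
                if rng.random() > config.sv_carrier_prob:
                    continue
                jitter_s = int(rng.integers(-30, 31))
                start = max(1, locus["start"] + jitter_s)
                if locus["sv_type"] == "INS":
                    end = start
                else:
                    end = max(start, locus["end"] + int(rng.integers(-30, 31)))
                if origin == "fp_2x":
                    cov = float(
                        np.clip(
                            rng.normal(2.0 * config.mean_depth, 0.05 * config.mean_depth),
                            1.9 * config.mean_depth,
                            2.1 * config.mean_depth,
                        )
                    )
                    genotype = "het"  # 2x-coverage het calls are the FP signature
                else:
                    cov = float(
                        np.clip(
                            rng.normal(config.mean_depth, 0.1 * config.mean_depth),
                            0.65 * config.mean_depth,
                            1.35 * config.mean_depth,
                        )
                    )
                    genotype = "het" if rng.random() < het_p else "hom"
                sr = int(rng.poisson(8))
                pe = int(rng.poisson(8))
                if sr + pe == 0:
                    sr = 1
                records.append(
                    SVRecord(
                        chrom=chrom,
                        start=start,
                        end=end,
                        sv_type=locus["sv_type"],
                        length=locus["length"],
                        strand_pair=locus["strand_pair"],
                        support_sr=sr,
                        support_pe=pe,
                        sample=sample,
                        genotype=genotype,
                        sample_coverage=cov,
                    )
                )
                origins.append(origin)
    return records, origins


def simulate_branch_scores(
    config: SimConfig,
    design: StudyDesign,
    seed: int | None = None,
) -> list[BranchScore]:
    """Per-gene, per-terminal-branch LRT statistics.

    Null branches draw from chi-square(1) (or, with ``null_mixture``, a 50:50
    mixture with a point mass at zero); truly selected branches draw from a
    noncentral chi-square(1) with noncentrality ``effect_size``. Sexual
    branches are selected with probability ``sel_frac_sexual``, parthenogens
    with ``sel_frac_asexual``. The stored statistic is on the scale to which
    the chi-square null applies.
    """
    master = config.seed if seed is None else seed
    rng = child_rng(master, "scores")
    genes = [f"g{k:05d}" for k in range(1, config.n_genes + 1)]
    scores: list[BranchScore] = []
    for sp in design.species:
        sel_frac = (
            config.sel_frac_sexual if sp.mode == SEXUAL else config.sel_frac_asexual
        )
        selected = rng.random(config.n_genes) < sel_frac
        stat = rng.chisquare(1, size=config.n_genes)
        if config.null_mixture:
            stat = np.where(rng.random(config.n_genes) < 0.5, 0.0, stat)
        if config.effect_size > 0:
            stat_sel = rng.noncentral_chisquare(1, config.effect_size, size=config.n_genes)
            stat = np.where(selected, stat_sel, stat)
        pvals = sps.chi2.sf(stat, df=1)
        if config.null_mixture:
            pvals = np.where(stat > 0, 0.5 * pvals, 1.0)
        for g, s, p in zip(genes, stat, pvals):
            scores.append(
                BranchScore(
                    gene_id=g, species_id=sp.species_id,
                    delta_lnl=float(s), pvalue=float(p),
                )
            )
    return scores


def simulate_te_fractions(
    config: SimConfig, design: StudyDesign, seed: int | None = None
) -> dict[str, float]:
    """Per-species TE read fractions: a clade effect, no mode effect.

    Pairs in the second half of the design form the shifted clade; both
    members of a pair share the clade, so reproductive mode carries no
    signal.
    """
    master = config.seed if seed is None else seed
    rng = child_rng(master, "te")
    pair_ids = design.pair_ids
    clade = {pid: (1 if i >= len(pair_ids) // 2 else 0) for i, pid in enumerate(pair_ids)}
    out = {}
    for sp in design.species:
        val = (
            config.te_mean
            + clade[sp.pair_id] * config.te_clade_shift
            + rng.normal(0.0, config.te_sd)
        )
        out[sp.species_id] = float(np.clip(val, 0.0, 1.0))
    return out


def _species_pi(config: SimConfig, mode: str) -> float:
    if mode == SEXUAL:
        return config.pi_sexual
    if config.use_decay:
        return expected_heterozygosity(
            config.h0, config.lambda_loss, config.mu_het, config.t_gens
        )
    return config.pi_asexual


def simulate_study(config: SimConfig, out_dir: str | os.PathLike) -> Path:
    """Write a complete synthetic study to ``out_dir``.

    Emits design.tsv, one VCF and one callable BED per individual,
    sv_calls.tsv (with a simulation ground-truth ``origin`` column),
    branch_scores.tsv, te_fractions.tsv and the config as sim_config.yaml.
    Deterministic given ``config.seed``.

    The parthenogen SNP positions of each pair are drawn so that an expected
    fraction ``f_shared`` coincides with positions polymorphic in the sexual
    sister (the ancestral pool), the remainder landing outside it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = make_design(config.n_pairs, config.n_individuals)
    mio.write_design(design, str(out / "design.tsv"))
    config.to_yaml(str(out / "sim_config.yaml"))

    contigs = {"chr1": config.L + 1}
    for pair_id in design.pair_ids:
        sexual, asex = design.pair_members(pair_id)
        rng_sex = child_rng(config.seed, "genotypes", sexual.species_id)
        by_sample, mask = simulate_genotypes(
            config.pi_sexual,
            config.L,
            len(sexual.individuals),
            rng_sex,
            sample_names=sexual.individuals,
            mean_depth=config.mean_depth,
            fail_frac=config.filter_fail_frac,
        )
        ancestral_pool = np.unique(
            np.concatenate(
                [[r.pos - 1 for r in recs] for recs in by_sample.values()]
                or [np.array([], dtype=np.int64)]
            )
        ).astype(np.int64)
        for sample, recs in by_sample.items():
            mio.write_vcf_minimal(recs, str(out / f"{sample}.vcf"), samples=[sample], contigs=contigs)
            mio.write_mask(mask, str(out / f"{sample}.callable.bed"))

        # parthenogen: per individual, positions drawn via the shared-pool model
        pi_asex = _species_pi(config, PARTHENOGENETIC)
        rng_asex = child_rng(config.seed, "genotypes", asex.species_id)
        mask_a = CallableMask({"chr1": [(0, config.L)]})
        for sample in asex.individuals:
            n_snps = rng_asex.binomial(config.L, pi_asex)
            pos0 = simulate_shared_positions(
                n_snps, config.f_shared, ancestral_pool, config.L, rng_asex
            )
            recs = _records_at_positions(
                pos0, sample, rng_asex, config.mean_depth, config.filter_fail_frac
            )
            mio.write_vcf_minimal(recs, str(out / f"{sample}.vcf"), samples=[sample], contigs=contigs)
            mio.write_mask(mask_a, str(out / f"{sample}.callable.bed"))

    mode_by_species = {s.species_id: s.mode for s in design.species}
    samples_by_species = {s.species_id: list(s.individuals) for s in design.species}
    sv_records, origins = simulate_sv_calls(
        config, mode_by_species, samples_by_species
    )
    mio.write_sv_table(sv_records, str(out / "sv_calls.tsv"), origins=origins)

    scores = simulate_branch_scores(config, design)
    mio.write_branch_scores(scores, str(out / "branch_scores.tsv"))

    te = simulate_te_fractions(config, design)
    mio.write_te_fractions(te, str(out / "te_fractions.tsv"))
    return out


def _records_at_positions(
    pos0: np.ndarray,
    sample: str,
    rng: np.random.Generator,
    mean_depth: float,
    fail_frac: float,
    chrom: str = "chr1",
) -> list[VariantRecord]:
    quals = 300.0 + rng.exponential(150.0, size=len(pos0))
    depths = 15 + rng.poisson(max(mean_depth - 15.0, 1.0), size=len(pos0))
    if fail_frac > 0 and len(pos0):
        bad = rng.random(len(pos0)) < fail_frac
        low = rng.random(len(pos0)) < 0.5
        quals[bad & low] = rng.uniform(0, 299.0, size=int((bad & low).sum()))
        depths[bad & ~low] = rng.integers(1, 15, size=int((bad & ~low).sum()))
    refs = _BASES[rng.integers(0, 4, size=len(pos0))]
    shift = rng.integers(1, 4, size=len(pos0))
    ref_idx = np.array([list(_BASES).index(r) for r in refs], dtype=np.int64)
    alts = _BASES[(ref_idx + shift) % 4]
    return [
        VariantRecord(
            chrom=chrom, pos=int(p) + 1, ref=str(r), alt=str(a), qual=float(q),
            genotypes={sample: Genotype.HET}, depths={sample: int(d)},
        )
        for p, r, a, q, d in zip(pos0, refs, alts, quals, depths)
    ]
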