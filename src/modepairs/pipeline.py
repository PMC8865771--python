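"""End-to-end orchestration of a study directory.

Reads a simulated (or suitably formatted real) study — design table,
per-individual VCF + callable BED, SV table, branch-score table, TE
fractions — and produces the full comparative summary: per-individual
heterozygosity, pair fold-differences, filtered/merged SVs and SV rates,
selection counts and overlap tests, and the three reproductive-mode
permutation tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import het as mhet
from . import io as mio
from . import selection as msel
from . import sv as msv
from .datamodel import PARTHENOGENETIC, SEXUAL, Genotype, StudyDesign
from .permutation import (
    mode_permutation_test,
    paired_count_test,
    score_permutation_glm,
)


def run_study(
    study_dir: str | Path,
    min_qual: float = mhet.DEFAULT_MIN_QUAL,
    min_depth: int = mhet.DEFAULT_MIN_DEPTH,
    q_threshold: float = 0.05,
    null: str = "chisq1",
    seed: int = 0,
    out_json: str | None = None,
) -> dict:
    """Run the full comparative pipeline on a study directory."""
    study = Path(study_dir)
    design = mio.read_design(str(study / "design.tsv"))

    het_rates: dict[str, list[float]] = {}
    sv_rates: dict[str, list[float]] = {}
    depth_lists: dict[str, list[int]] = {}
    callable_by_sample: dict[str, int] = {}
    snp_records: dict[str, list] = {}

    for sp in design.species:
        het_rates[sp.species_id] = []
        for sample in sp.individuals:
            records = mio.read_vcf_minimal(str(study / f"{sample}.vcf"))
            mask = mio.read_mask(str(study / f"{sample}.callable.bed"))
            depth_lists[sample] = [r.depths.get(sample, 0) for r in records]
            kept = mhet.filter_snps(records, min_qual=min_qual, min_depth=min_depth)
            snp_records[sample] = kept
            est = mhet.snp_heterozygosity(kept, mask, sample, species_id=sp.species_id)
            callable_by_sample[sample] = est.n_callable
            het_rates[sp.species_id].append(est.rate)

    species_het = {sp: float(np.mean(v)) for sp, v in het_rates.items()}
    fold_by_pair = {}
    shared_by_pair = {}
    for pair_id in design.pair_ids:
        sexual, asex = design.pair_members(pair_id)
        fold, inf_flag = mhet.fold_difference(
            het_rates[sexual.species_id], het_rates[asex.species_id]
        )
        fold_by_pair[pair_id] = {"fold": fold, "infinite": inf_flag}
        asex_pos = set()
        for sample in asex.individuals:
            asex_pos |= {(r.chrom, r.pos) for r in snp_records[sample]
                         if r.genotypes.get(sample) == Genotype.HET}
        sex_pos = set()
        for sample in sexual.individuals:
            sex_pos |= mhet.polymorphic_positions(snp_records[sample], [sample])
        if asex_pos:
            shared_by_pair[pair_id] = mhet.shared_snp_fraction(asex_pos, sex_pos)

    het_test = mode_permutation_test(
        species_het, design, statistic="mean_pair_diff", scheme="within_pair",
        side="greater", transform="log10", seed=seed,
    )

    # SV stage: windows from each sample's SNP depth distribution
    sv_path = study / "sv_calls.tsv"
    sv_summary = {}
    sv_test = None
    if sv_path.exists():
        sv_records = mio.read_sv_table(str(sv_path))
        windows = msv.default_windows(
            {s: d for s, d in depth_lists.items() if d}
        )
        for r in sv_records:
            if r.sample not in windows:
                windows[r.sample] = msv.CoverageWindow(r.sample, 0.0, float("inf"))
        kept_svs = msv.filter_svs(sv_records, windows)
        merged = msv.merge_svs(kept_svs)
        for sp in design.species:
            sv_rates[sp.species_id] = []
            for sample in sp.individuals:
                n_callable = callable_by_sample[sample]
                n_het = sum(
                    1 for r in kept_svs if r.sample == sample and r.genotype == "het"
                )
                sv_rates[sp.species_id].append(n_het / n_callable)
        species_sv = {sp: float(np.mean(v)) for sp, v in sv_rates.items()}
        sv_test = mode_permutation_test(
            species_sv, design, statistic="mean_pair_diff", scheme="within_pair",
            side="greater", transform="log10", seed=seed,
        )
        sv_summary = {
            "n_input": len(sv_records),
            "n_pass": len(kept_svs),
            "n_merged": len(merged),
            "species_het_sv_rate": species_sv,
        }

    # selection stage
    scores_path = study / "branch_scores.tsv"
    selection_summary = {}
    count_test = score_test = None
    if scores_path.exists():
        scores = mio.read_branch_scores(str(scores_path))
        scores = msel.attach_pq(scores, null=null)
        summaries = msel.count_selected(scores, threshold=q_threshold)
        counts = {sp: (s.n_selected, s.n_tested) for sp, s in summaries.items()}
        count_test = paired_count_test(
            counts, design, scheme="within_pair", side="greater", seed=seed
        )
        score_test = score_permutation_glm(
            scores, design, scheme="within_pair", side="greater", seed=seed
        )
        gene_sets = msel.selected_gene_sets(scores, threshold=q_threshold)
        n_genes = len({s.gene_id for s in scores})
        overlaps = msel.pairwise_overlap_tests(gene_sets, n_genes)
        selection_summary = {
            "threshold": q_threshold,
            "counts": {
                sp: {"n_selected": s.n_selected, "n_tested": s.n_tested}
                for sp, s in summaries.items()
            },
            "overlap_min_q": (
                float(overlaps["qvalue"].min()) if not overlaps.empty else None
            ),
            "n_overlap_combinations": int(len(overlaps)),
        }

    # TE stage
    te_path = study / "te_fractions.tsv"
    te_test = None
    te = {}
    if te_path.exists():
        te = mio.read_te_fractions(str(te_path))
        te_test = mode_permutation_test(
            te, design, statistic="anova_F", scheme="within_pair",
            side="greater", seed=seed,
        )

    results = {
        "design": {
            "n_pairs": design.n_pairs,
            "species": [s.species_id for s in design.species],
        },
        "heterozygosity": {
            "per_individual": {
                sp: rates for sp, rates in het_rates.items()
            },
            "species_mean": species_het,
            "fold_difference_by_pair": fold_by_pair,
            "shared_snp_fraction_by_pair": shared_by_pair,
            "mode_test": het_test.to_dict(),
        },
        "structural_variants": {**sv_summary,
                                "mode_test": sv_test.to_dict() if sv_test else None},
        "selection": {
            **selection_summary,
            "count_test": count_test.to_dict() if count_test else None,
            "score_test": score_test.to_dict() if score_test else None,
        },
        "te_content": {
            "fractions": te,
            "mode_test": te_test.to_dict() if te_test else None,
        },
    }
    if out_json:
        mio.write_json(results, out_json)
    return results
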