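"""Synthetic-study generator: determinism, distributional structure, formats."""

import filecmp
import os

import numpy as np
import pytest
from scipy import stats as sps

from modepairs import io as mio
from modepairs.datamodel import PARTHENOGENETIC, SEXUAL
from modepairs.selection import attach_pq, count_selected
from modepairs.simulate import (
    SimConfig,
    expected_heterozygosity,
    make_design,
    simulate_branch_scores,
    simulate_genotypes,
    simulate_shared_positions,
    simulate_study,
    simulate_sv_calls,
    simulate_te_fractions,
)

SMALL = dict(n_pairs=2, n_individuals=2, L=20_000, n_genes=100)


def test_same_seed_gives_byte_identical_study(tmp_path):
    cfg = SimConfig(seed=7, **SMALL)
    a = simulate_study(cfg, tmp_path / "a")
    b = simulate_study(cfg, tmp_path / "b")
    files = sorted(os.listdir(a))
    assert files == sorted(os.listdir(b))
    for f in files:
        assert filecmp.cmp(a / f, b / f, shallow=False), f


def test_study_file_counts(tmp_path):
    out = simulate_study(SimConfig(seed=1, n_pairs=2, n_individuals=1, L=5000,
                                   n_genes=20), tmp_path / "s")
    vcfs = [f for f in os.listdir(out) if f.endswith(".vcf")]
    assert len(vcfs) == 4  # 2 pairs x 2 species x 1 individual
    design = mio.read_design(str(out / "design.tsv"))
    assert design.n_pairs == 2
    modes = sorted(s.mode for s in design.species)
    assert modes.count(SEXUAL) == 2 and modes.count(PARTHENOGENETIC) == 2


def test_default_design_shape():
    design = make_design(5, 5)
    assert len(design.species) == 10
    assert sum(len(s.individuals) for s in design.species) == 50


def test_generated_files_parse_back(tmp_path):
    cfg = SimConfig(seed=3, **SMALL)
    out = simulate_study(cfg, tmp_path / "s")
    design = mio.read_design(str(out / "design.tsv"))
    sample = design.species[0].individuals[0]
    recs = mio.read_vcf_minimal(str(out / f"{sample}.vcf"))
    mask = mio.read_mask(str(out / f"{sample}.callable.bed"))
    assert mask.total_length() == cfg.L
    assert all(1 <= r.pos <= cfg.L for r in recs)
    assert mio.read_sv_table(str(out / "sv_calls.tsv"))
    assert mio.read_branch_scores(str(out / "branch_scores.tsv"))
    assert len(mio.read_te_fractions(str(out / "te_fractions.tsv"))) == 4


def test_het_count_within_binomial_bounds():
    pi, L = 1e-3, 1_000_000
    recs, _ = simulate_genotypes(pi, L, 1, seed=5)
    n = len(recs["ind1"])
    sd = np.sqrt(L * pi * (1 - pi))
    assert abs(n - L * pi) < 3 * sd


def test_zero_pi_gives_no_records():
    recs, mask = simulate_genotypes(0.0, 10_000, 2, seed=0)
    assert all(len(v) == 0 for v in recs.values())
    assert mask.total_length() == 10_000


def test_genotypes_deterministic_under_seed():
    a, _ = simulate_genotypes(1e-3, 50_000, 2, seed=42)
    b, _ = simulate_genotypes(1e-3, 50_000, 2, seed=42)
    assert [(r.pos, r.qual) for r in a["ind1"]] == [(r.pos, r.qual) for r in b["ind1"]]


@pytest.mark.parametrize(
    "h0,lam,mu,t,expected",
    [
        (0.005, 1.0, 1e-6, 5, 2e-6),          # complete loss each generation
        (0.005, 0.0, 0.0, 1000, 0.005),       # frozen
        (0.005, 0.1, 0.0, 10, 0.005 * 0.9**10),
        (0.001, 0.0, 1e-6, 100, 0.001 + 2e-4),  # linear accumulation at lambda=0
    ],
)
def test_expected_heterozygosity_closed_form(h0, lam, mu, t, expected):
    assert expected_heterozygosity(h0, lam, mu, t) == pytest.approx(expected, rel=1e-12)


def test_decay_equilibrium():
    # long-run heterozygosity is the mutation-loss balance 2*mu/lambda
    assert expected_heterozygosity(0.01, 0.05, 1e-6, 10**6) == pytest.approx(
        2e-6 / 0.05, rel=1e-9
    )


def test_empirical_decay_heterozygosity_matches_expectation():
    h = expected_heterozygosity(0.005, 0.1, 1e-7, 20)
    L, n_rep = 100_000, 100
    recs, _ = simulate_genotypes(h, L, n_rep, seed=9)
    total = sum(len(v) for v in recs.values())
    exp = n_rep * L * h
    assert abs(total - exp) < 3 * np.sqrt(exp)


def test_shared_positions_extremes():
    pool = np.arange(0, 500)
    all_in = simulate_shared_positions(100, 1.0, pool, 10_000, seed=1)
    assert set(all_in) <= set(pool.tolist())
    none_in = simulate_shared_positions(100, 0.0, pool, 10_000, seed=1)
    assert not set(none_in) & set(pool.tolist())
    assert len(none_in) == 100 == len(np.unique(none_in))


def test_shared_positions_fraction_within_3_sigma():
    pool = np.arange(0, 30_000)
    n, f = 10_000, 0.12
    pos = simulate_shared_positions(n, f, pool, 200_000, seed=2)
    frac = np.isin(pos, pool).mean()
    assert abs(frac - f) < 3 * np.sqrt(f * (1 - f) / n)


def test_shared_positions_pool_must_fit_genome():
    with pytest.raises(ValueError, match="subset"):
        simulate_shared_positions(10, 0.5, np.arange(0, 100), 50, seed=0)


def test_sv_calls_structure():
    cfg = SimConfig(seed=4, n_pairs=1, n_individuals=3, L=200_000)
    recs, origins = simulate_sv_calls(
        cfg,
        {"sp_sex": SEXUAL, "sp_asex": PARTHENOGENETIC},
        {"sp_sex": ["x1", "x2"], "sp_asex": ["y1"]},
    )
    assert len(recs) == len(origins)
    assert set(origins) <= {"true", "short", "fp_2x"}
    for r, o in zip(recs, origins):
        if o == "fp_2x":
            assert r.sample_coverage > 1.5 * cfg.mean_depth
            assert r.genotype == "het"
        elif o == "short":
            assert r.length <= 30
        else:
            assert r.length >= 31
            assert 0.5 * cfg.mean_depth <= r.sample_coverage <= 1.5 * cfg.mean_depth
        assert r.support_sr + r.support_pe >= 1
    # deterministic under the same seed
    recs2, origins2 = simulate_sv_calls(
        cfg,
        {"sp_sex": SEXUAL, "sp_asex": PARTHENOGENETIC},
        {"sp_sex": ["x1", "x2"], "sp_asex": ["y1"]},
    )
    assert [(r.start, r.end, r.sample) for r in recs] == [
        (r.start, r.end, r.sample) for r in recs2
    ]


def test_null_branch_scores_have_uniform_pvalues():
    cfg = SimConfig(seed=8, n_pairs=5, n_individuals=1, n_genes=700,
                    sel_frac_sexual=0.0, sel_frac_asexual=0.0)
    design = make_design(5, 1)
    scores = simulate_branch_scores(cfg, design)
    assert len(scores) == 7000
    pvals = np.array([s.pvalue for s in scores])
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_zero_effect_size_makes_selection_invisible():
    cfg = SimConfig(seed=8, n_pairs=1, n_individuals=1, n_genes=2000,
                    sel_frac_sexual=0.5, sel_frac_asexual=0.0, effect_size=0.0)
    design = make_design(1, 1)
    scores = simulate_branch_scores(cfg, design)
    sex = [s.delta_lnl for s in scores if s.species_id.endswith("sex")
           and not s.species_id.endswith("asex")]
    asex = [s.delta_lnl for s in scores if s.species_id.endswith("asex")]
    assert sps.ks_2samp(sex, asex).pvalue > 0.01


def test_selection_enrichment_direction_across_seeds():
    design = make_design(5, 1)
    wins = 0
    for seed in range(20):
        cfg = SimConfig(seed=seed, n_pairs=5, n_individuals=1, n_genes=300,
                        sel_frac_sexual=0.05, sel_frac_asexual=0.01,
                        effect_size=25.0)
        scores = attach_pq(simulate_branch_scores(cfg, design))
        counts = count_selected(scores)
        higher = sum(
            counts[f"{p}_sex"].n_selected > counts[f"{p}_asex"].n_selected
            for p in design.pair_ids
        )
        if higher >= 4:
            wins += 1
    assert wins >= 18  # sexual excess in >= 4/5 pairs for nearly every study


def test_te_fractions_have_clade_but_no_mode_structure():
    cfg = SimConfig(seed=5, te_sd=0.001)
    design = make_design(4, 1)
    te = simulate_te_fractions(cfg, design)
    # both pair members share the clade shift
    first = np.mean([te["pair01_sex"], te["pair01_asex"],
                     te["pair02_sex"], te["pair02_asex"]])
    second = np.mean([te["pair03_sex"], te["pair03_asex"],
                      te["pair04_sex"], te["pair04_asex"]])
    assert second - first == pytest.approx(cfg.te_clade_shift, abs=5 * cfg.te_sd)
    sex = np.mean([v for k, v in te.items() if k.endswith("_sex")])
    asex = np.mean([v for k, v in te.items() if k.endswith("_asex")])
    assert abs(sex - asex) < 5 * cfg.te_sd


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(pi_sexual=1.5)
    with pytest.raises(ValueError):
        SimConfig(n_pairs=0)


def test_config_yaml_roundtrip(tmp_path):
    cfg = SimConfig(seed=13, n_pairs=3, pi_sexual=2e-3)
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(str(p))
    assert SimConfig.from_yaml(str(p)) == cfg
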