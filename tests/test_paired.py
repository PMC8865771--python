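"""Paired permutation machinery: enumeration, exact p-values, cross-checks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from modepairs.datamodel import BranchScore
from modepairs.permutation import (
    _species_arrays,
    anova_F_batch,
    binom_glm_mode_coef_batch,
    enumerate_within_pair_assignments,
    mode_permutation_test,
    ols_mode_coef_batch,
    paired_count_test,
    score_permutation_glm,
)
from modepairs.simulate import make_design


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_pairs,expected", [(1, 2), (3, 8), (5, 32)])
def test_enumeration_counts(n_pairs, expected):
    labelings = enumerate_within_pair_assignments(n_pairs)
    assert labelings.shape == (expected, n_pairs)
    # identity present exactly once, as the first row
    identity = ~labelings.any(axis=1)
    assert identity.sum() == 1 and identity[0]
    # all labelings distinct
    assert len({tuple(row) for row in labelings}) == expected


def test_enumeration_cap():
    with pytest.raises(ValueError, match="Monte-Carlo"):
        enumerate_within_pair_assignments(25)


# ---------------------------------------------------------------------------
# mode_permutation_test
# ---------------------------------------------------------------------------

def _separated_values(design, delta=1.0):
    """Sexual species strictly above its partner in every pair."""
    rng = np.random.default_rng(0)
    vals = {}
    for i, pid in enumerate(design.pair_ids):
        sexual, asex = design.pair_members(pid)
        base = rng.normal(10 * i, 0.1)
        vals[sexual.species_id] = base + delta
        vals[asex.species_id] = base
    return vals


def test_exact_paired_p_is_1_over_32(design5):
    vals = _separated_values(design5)
    res = mode_permutation_test(
        vals, design5, statistic="mean_pair_diff", scheme="within_pair",
        side="greater",
    )
    assert res.B == "exact"
    assert res.pvalue == pytest.approx(1 / 32)


def test_constant_values_give_p_1(design5):
    vals = {s.species_id: 3.0 for s in design5.species}
    res = mode_permutation_test(vals, design5, statistic="anova_F")
    assert res.pvalue == 1.0
    assert "warning" in res.extras
    res2 = mode_permutation_test(vals, design5, statistic="mean_pair_diff")
    assert res2.pvalue == 1.0


def test_montecarlo_close_to_exact(design5):
    rng = np.random.default_rng(4)
    vals = {s.species_id: float(rng.normal()) for s in design5.species}
    exact = mode_permutation_test(
        vals, design5, statistic="mean_pair_diff", side="greater"
    )
    B = 5000
    mc = mode_permutation_test(
        vals, design5, statistic="mean_pair_diff", side="greater",
        B=B, exact_cap=1, seed=99,
    )
    assert mc.B == B
    se = np.sqrt(exact.pvalue * (1 - exact.pvalue) / B)
    assert abs(mc.pvalue - exact.pvalue) <= 3 * se + 2 / B


def test_exact_p_on_grid_and_never_zero(design5):
    rng = np.random.default_rng(8)
    for _ in range(10):
        vals = {s.species_id: float(rng.normal()) for s in design5.species}
        for side in ("greater", "less", "two_sided"):
            p = mode_permutation_test(
                vals, design5, statistic="mean_pair_diff", side=side
            ).pvalue
            assert p >= 1 / 32
            assert (p * 32) == pytest.approx(round(p * 32))


def test_pair_constant_shift_invariance(design5):
    rng = np.random.default_rng(2)
    vals = {s.species_id: float(rng.normal()) for s in design5.species}
    shifted = dict(vals)
    for pid, c in zip(design5.pair_ids, [5.0, -3.0, 100.0, 0.7, -42.0]):
        sexual, asex = design5.pair_members(pid)
        shifted[sexual.species_id] += c
        shifted[asex.species_id] += c
    for statistic in ("anova_F", "mean_pair_diff"):
        a = mode_permutation_test(vals, design5, statistic=statistic)
        b = mode_permutation_test(shifted, design5, statistic=statistic)
        assert a.observed == pytest.approx(b.observed)
        assert a.pvalue == b.pvalue


def test_anova_F_matches_statsmodels(design5):
    rng = np.random.default_rng(14)
    y = rng.normal(size=10)
    _, mode0, pair_idx, G = _species_arrays(design5)
    df = pd.DataFrame({"y": y, "mode": mode0, "pair": pair_idx.astype(str)})
    tab = anova_lm(smf.ols("y ~ C(mode) + C(pair)", df).fit())
    ours = anova_F_batch(y, mode0[None, :], G)[0]
    assert ours == pytest.approx(tab.loc["C(mode)", "F"], rel=1e-9)


def test_free_scheme_is_seeded_montecarlo(design5):
    rng = np.random.default_rng(3)
    vals = {s.species_id: float(rng.normal()) for s in design5.species}
    res = mode_permutation_test(
        vals, design5, statistic="anova_F", scheme="free", side="greater",
        B=999, seed=5,
    )
    assert res.B == 999
    assert res.extras["n_labelings"] == 999
    again = mode_permutation_test(
        vals, design5, statistic="anova_F", scheme="free", side="greater",
        B=999, seed=5,
    )
    assert res.pvalue == again.pvalue
    with pytest.raises(ValueError, match="within_pair"):
        mode_permutation_test(vals, design5, statistic="mean_pair_diff", scheme="free")


def test_missing_species_value_is_an_error(design5):
    vals = {s.species_id: 1.0 for s in design5.species[:-1]}
    with pytest.raises(ValueError, match="missing"):
        mode_permutation_test(vals, design5)


def test_log_transform_stabilizes_rate_scales(design5):
    # rates spanning orders of magnitude: on the raw scale the largest pair
    # dominates the mean difference; on the log scale every pair contributes
    vals = _separated_values(design5, delta=5.0)
    vals = {k: 10.0 ** v for k, v in vals.items()}
    raw = mode_permutation_test(vals, design5, statistic="mean_pair_diff",
                                side="greater")
    logd = mode_permutation_test(vals, design5, statistic="mean_pair_diff",
                                 side="greater", transform="log10")
    assert logd.pvalue == pytest.approx(1 / 32)
    assert raw.pvalue > logd.pvalue


# ---------------------------------------------------------------------------
# paired_count_test
# ---------------------------------------------------------------------------

def _counts(design, sex=(10, 100), asex=(1, 100)):
    out = {}
    for pid in design.pair_ids:
        sexual, a = design.pair_members(pid)
        out[sexual.species_id] = sex
        out[a.species_id] = asex
    return out


def test_count_test_exact_p(design5):
    res = paired_count_test(_counts(design5), design5, side="greater")
    assert res.B == "exact"
    assert res.pvalue == pytest.approx(1 / 32)
    assert res.observed > 0
    assert 0 < res.extras["wald_p"] < 0.05


def test_count_test_identical_counts_give_p_1(design5):
    res = paired_count_test(_counts(design5, (5, 50), (5, 50)), design5)
    assert res.pvalue == 1.0


def test_count_test_single_pair():
    design = make_design(1, 1)
    res = paired_count_test(_counts(design), design, side="greater")
    assert res.pvalue in (0.5, 1.0)


def test_count_test_zero_tested_is_an_error(design5):
    counts = _counts(design5)
    counts[design5.species[0].species_id] = (0, 0)
    with pytest.raises(ValueError, match="n_tested"):
        paired_count_test(counts, design5)


def test_count_test_coefficient_matches_statsmodels(design5):
    rng = np.random.default_rng(6)
    k = rng.integers(2, 40, size=10).astype(float)
    n = np.full(10, 200.0)
    counts = {
        s.species_id: (int(k[i]), int(n[i])) for i, s in enumerate(design5.species)
    }
    res = paired_count_test(counts, design5)
    _, mode0, pair_idx, _ = _species_arrays(design5)
    X = pd.get_dummies(
        pd.DataFrame({"mode": mode0, "pair": pair_idx.astype(str)}),
        columns=["pair"], drop_first=True,
    ).astype(float)
    X = sm.add_constant(X)
    fit = sm.GLM(np.c_[k, n - k], X, family=sm.families.Binomial()).fit()
    assert res.observed == pytest.approx(fit.params["mode"], rel=1e-6)
    assert res.extras["wald_se"] == pytest.approx(fit.bse["mode"], rel=1e-4)


# ---------------------------------------------------------------------------
# score_permutation_glm
# ---------------------------------------------------------------------------

def _branch_scores(design, shift=1.0, n_genes=30, seed=0):
    rng = np.random.default_rng(seed)
    scores = []
    for sp in design.species:
        base = rng.chisquare(1, size=n_genes)
        if sp.mode == "sexual":
            base = base + shift
        for g, s in enumerate(base):
            scores.append(BranchScore(f"g{g}", sp.species_id, float(s)))
    return scores


def test_score_glm_exact_p_with_shift(design5):
    scores = _branch_scores(design5, shift=1.0)
    res = score_permutation_glm(scores, design5, side="greater")
    assert res.B == "exact"
    assert res.pvalue == pytest.approx(1 / 32)
    assert res.observed == pytest.approx(1.0, abs=0.5)


def test_score_glm_pair_shift_invariance(design5):
    scores = _branch_scores(design5, shift=0.5)
    res1 = score_permutation_glm(scores, design5)
    shifted = [
        BranchScore(s.gene_id, s.species_id,
                    s.delta_lnl + (7.0 if s.species_id.startswith("pair01") else 0.0))
        for s in scores
    ]
    res2 = score_permutation_glm(shifted, design5)
    assert res1.observed == pytest.approx(res2.observed, rel=1e-9)
    assert res1.pvalue == res2.pvalue


def test_score_glm_coefficient_matches_statsmodels_ols(design5):
    scores = _branch_scores(design5, shift=0.8, n_genes=17, seed=3)
    res = score_permutation_glm(scores, design5)
    rows = [
        {"y": s.delta_lnl, "mode": float(s.species_id.endswith("_sex")),
         "pair": s.species_id.split("_")[0]}
        for s in scores
    ]
    fit = smf.ols("y ~ mode + C(pair)", pd.DataFrame(rows)).fit()
    assert res.observed == pytest.approx(fit.params["mode"], rel=1e-9)


def test_score_glm_unbalanced_branch_counts_match_ols(design5):
    # unequal branch numbers per species exercise the weighting
    rng = np.random.default_rng(10)
    scores = []
    rows = []
    for sp in design5.species:
        n = int(rng.integers(5, 25))
        for g in range(n):
            v = float(rng.chisquare(1) + (0.5 if sp.mode == "sexual" else 0.0))
            scores.append(BranchScore(f"g{g}", sp.species_id, v))
            rows.append({"y": v, "mode": float(sp.mode == "sexual"),
                         "pair": sp.pair_id})
    fit = smf.ols("y ~ mode + C(pair)", pd.DataFrame(rows)).fit()
    res = score_permutation_glm(scores, design5)
    assert res.observed == pytest.approx(fit.params["mode"], rel=1e-9)


def test_free_scheme_studentizes_by_default(design5):
    scores = _branch_scores(design5, shift=0.5, seed=8)
    wp = score_permutation_glm(scores, design5)
    free = score_permutation_glm(scores, design5, scheme="free", B=499, seed=1)
    assert wp.statistic_name == "score_glm_mode_coef"
    assert free.statistic_name == "score_glm_mode_t"
    assert free.B == 499
    counts = _counts(design5)
    assert paired_count_test(counts, design5).statistic_name == "binomial_glm_mode_coef"
    assert (
        paired_count_test(counts, design5, scheme="free", B=499, seed=1).statistic_name
        == "binomial_glm_mode_t"
    )


def test_score_glm_missing_species_is_an_error(design5):
    scores = _branch_scores(design5)
    scores = [s for s in scores if s.species_id != "pair03_asex"]
    with pytest.raises(ValueError, match="pair03_asex"):
        score_permutation_glm(scores, design5)
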