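"""Paired permutation inference for reproductive-mode effects.

The unit of replication is the species pair (one sexual, one parthenogenetic
species). The canonical null is built by independently swapping the mode
labels inside each pair (2^P labelings for P pairs, enumerated exactly when
feasible); a ``free`` scheme that permutes mode labels across all species is
offered for fully exchangeable nulls. Three tests share this machinery:

* ``mode_permutation_test`` — permutation ANOVA (two-factor mode + pair F) or
  mean within-pair difference, for per-species quantities such as
  heterozygosity rates or TE content;
* ``paired_count_test`` — binomial regression of per-species positively
  selected gene counts on mode with fixed pair effects;
* ``score_permutation_glm`` — threshold-free linear model of per-branch LRT
  scores on mode with pair effects, species relabeled wholesale.

Statistics inside the permutation loop use closed-form batched numpy
implementations (FWL residualization for the F statistic, within-pair
weights for the OLS mode coefficient, batched IRLS for the binomial GLM);
unit tests verify each against statsmodels on fixtures.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    PARTHENOGENETIC,
    SEXUAL,
    BranchScore,
    PermTestResult,
    StudyDesign,
)

DEFAULT_B = 5000
DEFAULT_EXACT_CAP = 4096
ENUM_PAIR_CAP = 20
_TIE_TOL = 1e-12
_LOG_OFFSET = 1e-12


def enumerate_within_pair_assignments(
    n_pairs: int, cap: int = ENUM_PAIR_CAP
) -> np.ndarray:
    """All 2^P within-pair label swaps as a boolean array (2^P, P).

    Row i gives, per pair, whether the (sexual, parthenogenetic) labels are
    swapped; the identity labeling is row 0.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if n_pairs > cap:
        raise ValueError(
            f"exact enumeration capped at {cap} pairs (2^{n_pairs} labelings); "
            "use Monte-Carlo mode instead"
        )
    return np.array(
        list(itertools.product((False, True), repeat=n_pairs)), dtype=bool
    )


# ---------------------------------------------------------------------------
# internal: design arrays and labeling matrices
# ---------------------------------------------------------------------------

def _species_arrays(design: StudyDesign):
    species_ids = [s.species_id for s in design.species]
    pair_ids = list(design.pair_ids)
    pair_idx = np.array([pair_ids.index(s.pair_id) for s in design.species])
    mode0 = np.array([s.mode == SEXUAL for s in design.species], dtype=float)
    n_pairs = len(pair_ids)
    G = np.zeros((n_pairs, len(species_ids)))
    G[pair_idx, np.arange(len(species_ids))] = 1.0
    return species_ids, mode0, pair_idx, G


def _within_pair_labelings(
    mode0: np.ndarray,
    pair_idx: np.ndarray,
    B: int,
    exact_cap: int,
    rng: np.random.Generator,
):
    """Mode matrix (n_labelings, n_species) for the within-pair null.

    In exact mode the matrix enumerates every labeling (identity included);
    in Monte-Carlo mode it holds B random labelings.
    """
    n_pairs = int(pair_idx.max()) + 1
    n_exact = 2 ** n_pairs
    if n_exact <= exact_cap:
        swaps = enumerate_within_pair_assignments(n_pairs)
        flip = swaps[:, pair_idx]  # (n_lab, n_species)
        return np.where(flip, 1.0 - mode0, mode0), True
    flip = rng.random((B, n_pairs)) < 0.5
    return np.where(flip[:, pair_idx], 1.0 - mode0, mode0), False


def _free_permutations(
    n_species: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B random permutations of the species slots (free scheme).

    The free scheme shuffles each species' data wholesale across the design
    (both its mode and its pair assignment change). Unlike relabeling modes
    with pairs held fixed — which is not a symmetry of any exchangeable null
    once the statistic adjusts for pair — this is an exact randomization
    under the hypothesis that per-species data are exchangeable.
    """
    return np.array([rng.permutation(n_species) for _ in range(B)])


def _tail_pvalue(
    obs: float, null: np.ndarray, side: str, exact: bool, B: int
) -> float:
    if side == "greater":
        t_obs, t_null = obs, null
    elif side == "less":
        t_obs, t_null = -obs, -null
    elif side == "two_sided":
        t_obs, t_null = abs(obs), np.abs(null)
    else:
        raise ValueError(f"unknown side {side!r}")
    if not np.isfinite(t_obs):
        return 1.0
    t_null = np.where(np.isfinite(t_null), t_null, -np.inf)
    hits = int(np.sum(t_null >= t_obs - _TIE_TOL))
    if exact:
        return hits / len(t_null)  # identity labeling included, so > 0
    return (hits + 1) / (B + 1)


# ---------------------------------------------------------------------------
# batched statistics
# ---------------------------------------------------------------------------

def _pair_demean(x: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Residualize row vectors on pair indicators (pairs of size two)."""
    sizes = G.sum(axis=1)
    return x - (x @ G.T / sizes) @ G


def anova_F_batch(y: np.ndarray, M: np.ndarray, G: np.ndarray) -> np.ndarray:
    """F statistic for the mode factor in a mode + pair fixed-effects fit.

    Computed by the FWL decomposition: both the response and the mode
    indicator are residualized on the pair factor, giving the extra sum of
    squares for mode on 1 df over the residual on (P - 1) df. Either the
    response ``y`` or the mode indicator ``M`` (or both) may be batched as
    (n_draws, n_species) arrays.
    """
    n_pairs = G.shape[0]
    df_resid = 2 * n_pairs - n_pairs - 1
    y2 = np.atleast_2d(y)
    M2 = np.atleast_2d(M)
    y2, M2 = np.broadcast_arrays(y2, M2)
    y_t = _pair_demean(y2, G)
    m_t = _pair_demean(M2, G)
    mm = np.einsum("ls,ls->l", m_t, m_t)
    my = np.einsum("ls,ls->l", m_t, y_t)
    ss_tot = np.einsum("ls,ls->l", y_t, y_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_mode = np.where(mm > 0, my**2 / mm, np.nan)
        sse = ss_tot - ss_mode
        F = np.where(
            (sse > _TIE_TOL) & (df_resid > 0), ss_mode / (sse / max(df_resid, 1)), np.nan
        )
    return F


def _mean_pair_diff(y: np.ndarray, M: np.ndarray, n_pairs: int) -> np.ndarray:
    """Mean over pairs of (sexual value - parthenogen value).

    Valid when every pair holds exactly one sexual species, which the
    within-pair scheme guarantees: each pair then contributes
    y_sex - y_asex = sum_i y_i * (2 m_i - 1).
    """
    return ((2.0 * M - 1.0) @ y) / n_pairs


def ols_mode_coef_batch(
    n_b: np.ndarray,
    S: np.ndarray,
    M: np.ndarray,
    G: np.ndarray,
    SS: np.ndarray | None = None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Mode coefficient of OLS: branch score ~ mode + pair, batched.

    Only per-species branch counts ``n_b`` and score sums ``S`` are needed:
    with pair fixed effects the coefficient is
    sum_j w_j d_j / sum_j w_j with w_j = n_u n_v / (n_u + n_v) and d_j the
    within-pair difference of species means (FWL residualization of the mode
    indicator on the pair factor at branch level).

    With per-species sums of squares ``SS`` the t statistic (coefficient over
    its OLS standard error) is returned as well; fitted values are constant
    within species, so the residual sum of squares is also a species-level
    quantity.

    Any of ``n_b``, ``S``, ``SS`` and ``M`` may be batched as
    (n_draws, n_species) arrays (data permutations or label relabelings).
    """
    M2 = np.atleast_2d(M)
    n2 = np.atleast_2d(n_b)
    S2 = np.atleast_2d(S)
    M2, n2, S2 = np.broadcast_arrays(M2, n2, S2)
    Npair = n2 @ G.T
    Spair = S2 @ G.T
    Mn = M2 * n2
    mbar = (Mn @ G.T) / Npair  # per-pair branch-weighted mean of mode
    num = np.einsum("ls,ls->l", M2, S2) - np.einsum("lp,lp->l", mbar, Spair)
    den = np.einsum("ls,ls->l", M2, n2) - np.einsum("lp,lp->l", mbar**2, Npair)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(den > _TIE_TOL, num / den, np.nan)
    if SS is None:
        return beta
    SS2 = np.broadcast_to(np.atleast_2d(SS), M2.shape)
    n_pairs = G.shape[0]
    pair_idx = np.argmax(G.T, axis=1)
    # per-pair intercepts chosen so residuals sum to zero within each pair
    alpha = (Spair - beta[:, None] * (Mn @ G.T)) / Npair
    yhat = alpha[:, pair_idx] + beta[:, None] * M2
    sse = np.sum(SS2 - 2.0 * yhat * S2 + n2 * yhat**2, axis=1)
    df = n2.sum(axis=1) - (n_pairs + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(sse, 0.0) / np.maximum(df, 1.0) / den)
        t = np.where(se > 0, beta / se, np.nan)
    return beta, t


def binom_glm_mode_coef_batch(
    k: np.ndarray,
    n: np.ndarray,
    M: np.ndarray,
    G: np.ndarray,
    n_iter: int = 40,
    return_se: bool = False,
):
    """Mode coefficient of a binomial logit GLM k/n ~ mode + pair, batched.

    Newton/IRLS with a small ridge for numerical safety and a clipped linear
    predictor so separated fits stay finite; verified against statsmodels GLM
    in the unit tests. ``k``/``n`` as well as ``M`` may be batched as
    (n_draws, n_species) arrays.
    """
    M2 = np.atleast_2d(M)
    k2 = np.atleast_2d(np.asarray(k, dtype=float))
    n2 = np.atleast_2d(np.asarray(n, dtype=float))
    M2, k2, n2 = np.broadcast_arrays(M2, k2, n2)
    n_lab, n_sp = M2.shape
    n_pairs = G.shape[0]
    # X columns: intercept, mode, pair dummies 2..P
    n_par = 1 + 1 + (n_pairs - 1)
    X = np.zeros((n_lab, n_sp, n_par))
    X[:, :, 0] = 1.0
    X[:, :, 1] = M2
    pair_idx = np.argmax(G.T, axis=1)
    for j in range(1, n_pairs):
        X[:, pair_idx == j, 1 + j] = 1.0
    beta = np.zeros((n_lab, n_par))
    ridge = 1e-8 * np.eye(n_par)
    for _ in range(n_iter):
        eta = np.clip(np.einsum("lsp,lp->ls", X, beta), -12.0, 12.0)
        pi = 1.0 / (1.0 + np.exp(-eta))
        W = n2 * pi * (1.0 - pi) + 1e-10
        XtWX = np.einsum("ls,lsp,lsq->lpq", W, X, X)
        score = np.einsum("lsp,ls->lp", X, k2 - n2 * pi)
        step = np.linalg.solve(XtWX + ridge, score[..., None])[..., 0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    if return_se:
        se = np.sqrt(np.linalg.inv(XtWX + ridge)[:, 1, 1])
        return beta[:, 1], se
    return beta[:, 1]


# ---------------------------------------------------------------------------
# public tests
# ---------------------------------------------------------------------------

def _ordered_values(
    values: Mapping[str, float], design: StudyDesign, what: str
) -> np.ndarray:
    missing = [s.species_id for s in design.species if s.species_id not in values]
    if missing:
        raise ValueError(f"missing {what} for species {missing}")
    return np.array([float(values[s.species_id]) for s in design.species])


def _apply_transform(y: np.ndarray, transform: str | None) -> np.ndarray:
    if transform is None or transform == "none":
        return y
    if transform in ("log", "log10"):
        # offset keeps exact zeros (e.g. no het SVs in a parthenogen) finite
        fn = np.log if transform == "log" else np.log10
        return fn(y + _LOG_OFFSET)
    raise ValueError(f"unknown transform {transform!r}")


def mode_permutation_test(
    values: Mapping[str, float],
    design: StudyDesign,
    statistic: str = "anova_F",
    scheme: str = "within_pair",
    side: str = "greater",
    B: int = DEFAULT_B,
    exact_cap: int = DEFAULT_EXACT_CAP,
    seed: int | None = None,
    transform: str | None = None,
    return_null: bool = False,
) -> PermTestResult:
    """Permutation test for a reproductive-mode effect on per-species values.

    ``statistic="anova_F"`` is the F for mode in a two-factor (mode + pair)
    fixed-effects decomposition; ``"mean_pair_diff"`` is the mean over pairs
    of (sexual - parthenogen), available for the within-pair scheme only.
    Under the within-pair scheme, exact enumeration replaces Monte-Carlo
    sampling whenever 2^P is at most ``exact_cap``; the free scheme (per-
    species values permuted wholesale across the design) is always seeded
    Monte-Carlo.
    """
    y = _apply_transform(_ordered_values(values, design, "value"), transform)
    _, mode0, pair_idx, G = _species_arrays(design)
    rng = np.random.default_rng(seed)
    if scheme == "within_pair":
        M, exact = _within_pair_labelings(mode0, pair_idx, B, exact_cap, rng)
        Y = y
    elif scheme == "free":
        if statistic == "mean_pair_diff":
            raise ValueError("mean_pair_diff requires the within_pair scheme")
        idx = _free_permutations(len(y), B, rng)
        Y, M, exact = y[idx], mode0, False
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if statistic == "anova_F":
        null = anova_F_batch(Y, M, G)
        obs = float(anova_F_batch(y, mode0, G)[0])
    elif statistic == "mean_pair_diff":
        null = _mean_pair_diff(y, M, design.n_pairs)
        obs = float(_mean_pair_diff(y, mode0[None, :], design.n_pairs)[0])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    extras: dict = {"n_labelings": len(null)}
    if not np.isfinite(obs):
        # e.g. constant values: the F statistic is undefined
        extras["warning"] = "statistic undefined on observed data; p set to 1"
        p = 1.0
    else:
        p = _tail_pvalue(obs, null, side, exact, B)
    return PermTestResult(
        statistic_name=statistic,
        observed=obs,
        B="exact" if exact else B,
        scheme=scheme,
        side=side,
        pvalue=p,
        null_stats=null if return_null else None,
        extras=extras,
    )


def paired_count_test(
    counts: Mapping[str, tuple[int, int]],
    design: StudyDesign,
    scheme: str = "within_pair",
    side: str = "greater",
    B: int = DEFAULT_B,
    exact_cap: int = DEFAULT_EXACT_CAP,
    seed: int | None = None,
    studentized: bool | None = None,
    return_null: bool = False,
) -> PermTestResult:
    """Permutation test for a mode effect on (n_selected, n_tested) counts.

    The statistic is the mode coefficient of a binomial regression of the
    per-species counts on mode with fixed pair effects. The within-pair null
    swaps labels inside each pair (exact when 2^P allows); the free scheme
    permutes the per-species (n_selected, n_tested) data wholesale across the
    design by seeded Monte-Carlo. A Wald-style p-value from the observed fit
    is reported alongside in ``extras`` for comparison.

    ``studentized`` divides the coefficient by its standard error before
    comparing against the null. Default: off for the within-pair scheme
    (every labeling is balanced, so the raw coefficient is exchangeable) and
    on for the free scheme, where the heterogeneous draws make the raw
    coefficient non-pivotal.
    """
    from scipy import stats as sps

    missing = [s.species_id for s in design.species if s.species_id not in counts]
    if missing:
        raise ValueError(f"missing counts for species {missing}")
    k = np.array([float(counts[s.species_id][0]) for s in design.species])
    n = np.array([float(counts[s.species_id][1]) for s in design.species])
    if np.any(n <= 0):
        bad = [s.species_id for s, ni in zip(design.species, n) if ni <= 0]
        raise ValueError(f"species with n_tested = 0: {bad}")
    if np.any(k > n):
        raise ValueError("n_selected cannot exceed n_tested")
    if studentized is None:
        studentized = scheme == "free"

    _, mode0, pair_idx, G = _species_arrays(design)
    rng = np.random.default_rng(seed)
    if scheme == "within_pair":
        M, exact = _within_pair_labelings(mode0, pair_idx, B, exact_cap, rng)
        k_null, n_null = k, n
    elif scheme == "free":
        idx = _free_permutations(len(k), B, rng)
        M, exact = mode0, False
        k_null, n_null = k[idx], n[idx]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    null_coef, null_se = binom_glm_mode_coef_batch(k_null, n_null, M, G, return_se=True)
    obs_coef, obs_se = binom_glm_mode_coef_batch(
        k, n, mode0[None, :], G, return_se=True
    )
    if studentized:
        null = null_coef / null_se
        obs = float(obs_coef[0] / obs_se[0])
    else:
        null = null_coef
        obs = float(obs_coef[0])
    p = _tail_pvalue(obs, null, side, exact, B)
    wald_z = float(obs_coef[0]) / float(obs_se[0])
    wald_p = float(sps.norm.sf(abs(wald_z)) * (1 if side != "two_sided" else 2))
    return PermTestResult(
        statistic_name=(
            "binomial_glm_mode_t" if studentized else "binomial_glm_mode_coef"
        ),
        observed=obs,
        B="exact" if exact else B,
        scheme=scheme,
        side=side,
        pvalue=p,
        null_stats=null if return_null else None,
        extras={"n_labelings": len(null), "wald_p": wald_p,
                "wald_se": float(obs_se[0])},
    )


def score_permutation_glm(
    scores: Sequence[BranchScore],
    design: StudyDesign,
    B: int = DEFAULT_B,
    seed: int | None = None,
    scheme: str = "within_pair",
    side: str = "greater",
    exact_cap: int = DEFAULT_EXACT_CAP,
    studentized: bool | None = None,
    return_null: bool = False,
) -> PermTestResult:
    """Threshold-free permutation test on per-branch LRT scores.

    The statistic is the mode coefficient of a linear model of per-branch
    scores on mode with fixed pair effects. The canonical null switches mode
    labels of whole species within pairs (all branches of a species move
    together), with exact enumeration when 2^P allows; the free scheme
    permutes whole species' score summaries across the design by seeded
    Monte-Carlo. ``studentized`` (default: only under the free scheme) uses
    the coefficient's t statistic instead of the raw coefficient, which keeps
    the statistic pivotal across heterogeneous draws.
    """
    species_ids, mode0, pair_idx, G = _species_arrays(design)
    n_b = np.zeros(len(species_ids))
    S = np.zeros(len(species_ids))
    SS = np.zeros(len(species_ids))
    index = {sp: i for i, sp in enumerate(species_ids)}
    for s in scores:
        i = index.get(s.species_id)
        if i is None:
            continue
        n_b[i] += 1
        S[i] += s.delta_lnl
        SS[i] += s.delta_lnl**2
    empty = [sp for sp, i in index.items() if n_b[i] == 0]
    if empty:
        raise ValueError(f"species without branch scores: {empty}")
    if studentized is None:
        studentized = scheme == "free"

    rng = np.random.default_rng(seed)
    if scheme == "within_pair":
        M, exact = _within_pair_labelings(mode0, pair_idx, B, exact_cap, rng)
        null_coef, null_t = ols_mode_coef_batch(n_b, S, M, G, SS=SS)
    elif scheme == "free":
        idx = _free_permutations(len(n_b), B, rng)
        exact = False
        null_coef, null_t = ols_mode_coef_batch(
            n_b[idx], S[idx], mode0, G, SS=SS[idx]
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    obs_coef, obs_t = ols_mode_coef_batch(n_b, S, mode0[None, :], G, SS=SS)
    if studentized:
        null, obs = null_t, float(obs_t[0])
    else:
        null, obs = null_coef, float(obs_coef[0])
    p = _tail_pvalue(obs, null, side, exact, B)
    means = {sp: S[i] / n_b[i] for sp, i in index.items()}
    return PermTestResult(
        statistic_name="score_glm_mode_t" if studentized else "score_glm_mode_coef",
        observed=obs,
        B="exact" if exact else B,
        scheme=scheme,
        side=side,
        pvalue=p,
        null_stats=null if return_null else None,
        extras={"n_labelings": len(null), "species_mean_scores": means},
    )
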