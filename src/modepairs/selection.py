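"""Branch-site selection summaries.

Per-branch likelihood-ratio statistics are converted to p-values under a
chi-square(1) null (or the 50:50 boundary mixture of chi-square(1) and a
point mass at zero), pooled into q-values across all branches of all genes,
counted per species at a q threshold, and gene-set overlaps across species
are tested against the uniform-draw expectation.

Convention: the stored statistic is the quantity to which the null applies,
i.e. the doubled log-likelihood difference of the branch-site test.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import BranchScore, SelectionSummary  # noqa: F401  (re-export)


def lrt_pvalue(stat, null: str = "chisq1"):
    """Upper-tail p-value of the branch-site LRT statistic.

    ``chisq1``: p = P(chi2_1 >= stat). ``mixture50``: the 50:50 boundary
    mixture, p = 0.5 * P(chi2_1 >= stat) for stat > 0 and p = 1 at stat = 0.
    Accepts scalars or arrays.
    """
    arr = np.asarray(stat, dtype=float)
    if np.any(arr < 0):
        raise ValueError("LRT statistic must be >= 0")
    if null == "chisq1":
        p = sps.chi2.sf(arr, df=1)
    elif null == "mixture50":
        p = np.where(arr > 0, 0.5 * sps.chi2.sf(arr, df=1), 1.0)
    else:
        raise ValueError(f"unknown null {null!r}")
    return float(p) if np.isscalar(stat) else p


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_pq(
    scores: Iterable[BranchScore], null: str = "chisq1"
) -> list[BranchScore]:
    """Compute p-values from delta_lnl and pooled BH q-values in place.

    Pooling is across all branches of all genes, matching how the q-value is
    defined for the branch-site scan.
    """
    scores = list(scores)
    stats_arr = np.array([s.delta_lnl for s in scores], dtype=float)
    p = lrt_pvalue(stats_arr, null=null) if scores else np.array([])
    q = bh_qvalues(p) if scores else np.array([])
    for s, pi, qi in zip(scores, p, q):
        s.pvalue = float(pi)
        s.qvalue = float(qi)
    return scores


def count_selected(
    scores: Iterable[BranchScore], threshold: float = 0.05
) -> dict[str, SelectionSummary]:
    """Per-species counts of branches with q strictly below ``threshold``."""
    summaries: dict[str, SelectionSummary] = {}
    for s in scores:
        if s.qvalue is None:
            raise ValueError(
                f"branch {s.gene_id}/{s.species_id} lacks a q-value; run attach_pq first"
            )
        cur = summaries.get(s.species_id)
        if cur is None:
            cur = SelectionSummary(
                species_id=s.species_id, n_tested=0, n_selected=0, threshold=threshold
            )
            summaries[s.species_id] = cur
        cur.n_tested += 1
        if s.qvalue < threshold:
            cur.n_selected += 1
    return summaries


def selected_gene_sets(
    scores: Iterable[BranchScore], threshold: float = 0.05
) -> dict[str, set[str]]:
    """Per-species sets of gene ids with q < threshold."""
    sets: dict[str, set[str]] = {}
    for s in scores:
        sets.setdefault(s.species_id, set())
        if s.qvalue is not None and s.qvalue < threshold:
            sets[s.species_id].add(s.gene_id)
    return sets


def multiset_overlap_test(
    sets: Sequence[set],
    background_n: int,
    method: str = "exact2",
    B: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Test whether the intersection of k gene sets exceeds chance.

    Expected overlap under independent uniform draws is
    ``background_n * prod(|set_i| / background_n)``. ``exact2`` gives the
    hypergeometric upper-tail p-value (k = 2 only); ``montecarlo`` draws
    uniform sets of the same sizes B times (seeded) for any k >= 2.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    sizes = [len(s) for s in sets]
    union = set().union(*sets)
    if len(union) > background_n:
        raise ValueError("sets exceed the background size")
    observed = len(set.intersection(*map(set, sets)))
    expected = background_n * math.prod(n / background_n for n in sizes)

    if method == "exact2":
        if len(sets) != 2:
            raise ValueError("exact2 applies only to k = 2")
        # P(overlap >= observed) for two uniform subsets of the background
        p = float(sps.hypergeom.sf(observed - 1, background_n, sizes[0], sizes[1]))
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(B):
            draw = [
                frozenset(rng.choice(background_n, size=n, replace=False))
                for n in sizes
            ]
            inter = set(draw[0])
            for d in draw[1:]:
                inter &= d
            if len(inter) >= observed:
                hits += 1
        p = (hits + 1) / (B + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "observed": observed,
        "expected": expected,
        "pvalue": min(1.0, p),
        "k": len(sets),
        "method": method,
    }


def pairwise_overlap_tests(
    gene_sets: Mapping[str, set], background_n: int
) -> pd.DataFrame:
    """Exact two-set overlap tests for every species pair, BH-corrected."""
    rows = []
    for a, b in itertools.combinations(sorted(gene_sets), 2):
        res = multiset_overlap_test(
            [gene_sets[a], gene_sets[b]], background_n, method="exact2"
        )
        rows.append(
            {
                "species_a": a,
                "species_b": b,
                "observed": res["observed"],
                "expected": res["expected"],
                "pvalue": res["pvalue"],
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["qvalue"] = bh_qvalues(df["pvalue"].to_numpy())
    return df
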