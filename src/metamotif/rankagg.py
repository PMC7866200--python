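"""Robust rank aggregation across studies and DEG calling.

The score of a gene is the order-statistic rho: given the sorted
normalized ranks r_(1) <= ... <= r_(m) the gene achieved across the n
studies that measured it (studies that measured it but did not retain
it contribute rank 1), rho = min_k P(X >= k) with X ~ Binomial(n, r_(k)).
Under the null of uniform independent ranks, n * rho is a conservative
p-value (Bonferroni over k); Benjamini-Hochberg across genes then gives
the adjusted p used for the DEG call (padj < 0.01).

Normalized ranks entering the matrix are positions rescaled against the
study's measured-gene universe (position / universe size), so a gene
near the top of a short retained list in a large study still scores as
extreme — which is what makes consistent cross-study signal detectable.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .ingest import RankedGeneList

__all__ = [
    "binomial_tail",
    "rho_score",
    "aggregate",
    "compare_deg_sets",
]

DEG_PADJ_CUTOFF = 0.01


def binomial_tail(k: int, n: int, r: float) -> float:
    """P(X >= k) for X ~ Binomial(n, r), via the incomplete-beta identity.

    P(X >= k) = I_r(k, n - k + 1), the regularized incomplete beta
    function, which is numerically stable for extreme tails.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    if k == 0:
        return 1.0
    return float(special.betainc(k, n - k + 1, r))


def rho_score(sorted_ranks, n: int) -> float:
    """Order-statistic rho for one gene: min_k P(Binomial(n, r_(k)) >= k).

    ``sorted_ranks`` are the gene's normalized ranks in ascending order;
    ranks of 1 (measured but not retained) can never decrease rho.
    """
    r = np.asarray(sorted_ranks, dtype=float)
    if r.size == 0:
        return 1.0
    if np.any(np.diff(r) < 0):
        raise ValueError("ranks must be sorted ascending")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("ranks must lie in (0, 1]")
    if r.size > n:
        raise ValueError("more ranks than studies")
    k = np.arange(1, r.size + 1)
    return float(np.min(special.betainc(k, n - k + 1, r)))


def _rho_vectorized(rank_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise rho over a genes x studies matrix (NaN = unmeasured)."""
    n_eff = np.sum(~np.isnan(rank_matrix), axis=1)
    # sort puts NaN last; column j holds the (j+1)-th smallest rank
    sorted_r = np.sort(rank_matrix, axis=1)
    n_genes, n_studies = rank_matrix.shape
    k = np.arange(1, n_studies + 1)[None, :].repeat(n_genes, axis=0)
    n_col = n_eff[:, None]
    valid = k <= n_col
    a = np.where(valid, k, 1)
    b = np.where(valid, n_col - k + 1, 1)
    x = np.where(valid, sorted_r, 0.0)
    tails = special.betainc(a, b, x)
    tails[~valid] = np.inf
    rho = np.min(tails, axis=1)
    rho[n_eff == 0] = 1.0
    return rho, n_eff


def aggregate(
    lists: list[RankedGeneList],
    direction: str | None = None,
    min_studies: int = 2,
    bh_across_genes: bool = True,
) -> pd.DataFrame:
    """Aggregate direction-specific ranked lists into per-gene DEG calls.

    Builds the rank matrix over the union of measured universes: a gene
    measured in a study gets rank position/universe_size if retained
    there, else 1; unmeasured cells stay NaN and do not count toward
    n_eff.  Genes measured in fewer than ``min_studies`` studies are
    dropped.  Per gene, p_bonf = min(1, rho * n_eff); BH across genes
    gives padj (set ``bh_across_genes=False`` to use the Bonferroni
    bound directly as the adjusted p).

    Returns a DataFrame with columns gene_id, direction, n_eff, rho,
    p_bonf, padj, is_deg sorted by padj then gene_id.
    """
    if not lists:
        raise ValueError("need at least one ranked list")
    directions = {l.direction for l in lists}
    if len(directions) > 1:
        raise ValueError(f"lists mix directions: {sorted(directions)}")
    if direction is None:
        direction = lists[0].direction

    universe = sorted(set().union(*(l.measured_universe for l in lists)))
    if not universe:
        raise ValueError("union of measured universes is empty")
    gene_index = {g: i for i, g in enumerate(universe)}

    mat = np.full((len(universe), len(lists)), np.nan)
    for j, lst in enumerate(lists):
        measured = [gene_index[g] for g in lst.measured_universe]
        mat[measured, j] = 1.0
        if len(lst):
            idx = [gene_index[g] for g in lst.genes]
            mat[idx, j] = np.arange(1, len(lst) + 1) / lst.universe_size

    rho, n_eff = _rho_vectorized(mat)
    eligible = n_eff >= min_studies
    genes = np.array(universe)[eligible]
    rho = rho[eligible]
    n_eff = n_eff[eligible]
    if genes.size == 0:
        raise ValueError(f"no gene measured in >= {min_studies} studies")

    p_bonf = np.minimum(1.0, rho * n_eff)
    if bh_across_genes:
        padj = multipletests(p_bonf, method="fdr_bh")[1]
    else:
        padj = p_bonf
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "direction": direction,
            "n_eff": n_eff,
            "rho": rho,
            "p_bonf": p_bonf,
            "padj": padj,
            "is_deg": padj < DEG_PADJ_CUTOFF,
        }
    )
    return out.sort_values(["padj", "gene_id"]).reset_index(drop=True)


def compare_deg_sets(named_sets: dict) -> dict:
    """Exact set algebra over named DEG sets: sizes, pairwise
    intersections, and per-set unique counts (members of no other set)."""
    if len(named_sets) < 2:
        raise ValueError("need at least two sets to compare")
    names = list(named_sets)
    sizes = {n: len(named_sets[n]) for n in names}
    pairwise = {
        (a, b): len(named_sets[a] & named_sets[b]) for a, b in combinations(names, 2)
    }
    unique = {}
    for n in names:
        others = set().union(*(named_sets[m] for m in names if m != n))
        unique[n] = len(named_sets[n] - others)
    return {"sizes": sizes, "pairwise_intersections": pairwise, "unique_counts": unique}
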