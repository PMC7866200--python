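"""TFBS enrichment in DEG promoters versus a reference promoter set.

For each matrix, promoters are scored as binary occurrence (>= 1 hit at
the calibrated threshold), giving a 2x2 table

              has site   no site
    DEG           a         b
    reference     c         d

tested one-sided (enrichment) with Fisher's exact test.  The adjusted
fold enrichment FE_adj is the lower bound of the Woolf 99% confidence
interval of the odds ratio,

    FE_adj = exp( ln OR - z_0.995 * sqrt(1/a + 1/b + 1/c + 1/d) ),

computed on the Haldane-Anscombe (+0.5 everywhere) corrected table when
any cell is zero.  A TF owning several matrices is summarized by its
maximal FE_adj; a TF is called significant at FE_adj > 1.25 and
FDR < 0.05 (BH across matrices within one analysis), and highly
enriched at FE_adj > 1.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentRecord",
    "TfSummary",
    "enrich_matrix",
    "enrich_all",
    "collapse_to_tf",
    "fdr_adjust",
    "Z_99",
    "FE_MIN",
    "FE_HIGH",
    "FDR_MAX",
]

Z_99 = 2.5758293035489004  # two-sided 99% normal quantile
FE_MIN = 1.25
FE_HIGH = 1.5
FDR_MAX = 0.05


@dataclass
class EnrichmentRecord:
    matrix_id: str
    tf_name: str
    a: int  # DEG promoters with >= 1 hit
    b: int  # DEG promoters without
    c: int  # reference promoters with >= 1 hit
    d: int  # reference promoters without
    odds_ratio: float
    fe_adj: float
    fisher_p: float
    fdr: float = float("nan")


@dataclass
class TfSummary:
    tf_name: str
    fe_adj_max: float
    best_matrix_id: str
    fdr_min: float
    significant: bool
    highly_enriched: bool


def _woolf_lower(a: float, b: float, c: float, d: float, z: float = Z_99) -> tuple[float, float]:
    """(odds ratio, lower CI bound) with Haldane-Anscombe correction iff
    any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return orr, math.exp(math.log(orr) - z * se)


def enrich_matrix(
    deg_hits: pd.DataFrame,
    ref_hits: pd.DataFrame,
    n_deg: int,
    n_ref: int,
    tf_name: str = "",
    matrix_id: str | None = None,
    deg_ids: set | None = None,
    ref_ids: set | None = None,
) -> EnrichmentRecord:
    """Build the 2x2 occurrence table for one matrix and score it.

    ``deg_hits``/``ref_hits`` are hit tables (as from
    :func:`metamotif.pwm.scan_sequences`) restricted to one matrix; the
    unit of counting is the promoter (>= 1 hit), not the site.
    """
    if n_deg <= 0 or n_ref <= 0:
        raise ValueError("promoter set sizes must be positive")
    hit_deg = set(deg_hits["promoter_id"]) if len(deg_hits) else set()
    hit_ref = set(ref_hits["promoter_id"]) if len(ref_hits) else set()
    if deg_ids is not None and not hit_deg <= set(deg_ids):
        raise ValueError("DEG hits reference promoters outside the declared DEG set")
    if ref_ids is not None and not hit_ref <= set(ref_ids):
        raise ValueError("reference hits reference promoters outside the declared set")

    a = len(hit_deg)
    c = len(hit_ref)
    b, d = n_deg - a, n_ref - c
    if b < 0 or d < 0:
        raise ValueError("more hit promoters than promoters in the set")

    _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    orr, fe_adj = _woolf_lower(a, b, c, d)
    if matrix_id is None:
        matrix_id = str(deg_hits["matrix_id"].iloc[0]) if len(deg_hits) else "unknown"
    return EnrichmentRecord(
        matrix_id=matrix_id,
        tf_name=tf_name,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=float(orr),
        fe_adj=float(fe_adj),
        fisher_p=float(fisher_p),
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_all(
    hits_deg: pd.DataFrame,
    hits_ref: pd.DataFrame,
    n_deg: int,
    n_ref: int,
    matrix_to_tf: dict,
) -> pd.DataFrame:
    """Per-matrix enrichment records with BH FDR across all matrices of
    one (intervention, direction) analysis."""
    records = []
    for mid, tf in matrix_to_tf.items():
        dh = hits_deg[hits_deg["matrix_id"] == mid] if len(hits_deg) else hits_deg
        rh = hits_ref[hits_ref["matrix_id"] == mid] if len(hits_ref) else hits_ref
        records.append(
            enrich_matrix(dh, rh, n_deg, n_ref, tf_name=tf, matrix_id=mid)
        )
    df = pd.DataFrame([vars(r) for r in records])
    df["fdr"] = fdr_adjust(df["fisher_p"].to_numpy())
    return df.sort_values("fe_adj", ascending=False).reset_index(drop=True)


def collapse_to_tf(records: pd.DataFrame, matrix_to_tf: dict | None = None) -> pd.DataFrame:
    """Collapse per-matrix records to one row per TF (maximal FE_adj).

    ``records`` is the frame from :func:`enrich_all` (must carry fdr).
    Flags: significant iff fe_adj_max > 1.25 and fdr_min < 0.05;
    highly_enriched additionally requires fe_adj_max > 1.5.
    """
    df = records.copy()
    if matrix_to_tf is not None:
        unmapped = set(df["matrix_id"]) - set(matrix_to_tf)
        if unmapped:
            raise ValueError(f"matrices without a TF mapping: {sorted(unmapped)}")
        df["tf_name"] = df["matrix_id"].map(matrix_to_tf)
    if df["tf_name"].eq("").any():
        raise ValueError("records carry empty TF names and no mapping was given")

    rows = []
    for tf, grp in df.groupby("tf_name", sort=True):
        best = grp.loc[grp["fe_adj"].idxmax()]
        fe_max = float(best["fe_adj"])
        fdr_min = float(grp["fdr"].min())
        significant = (fe_max > FE_MIN) and (fdr_min < FDR_MAX)
        rows.append(
            TfSummary(
                tf_name=tf,
                fe_adj_max=fe_max,
                best_matrix_id=str(best["matrix_id"]),
                fdr_min=fdr_min,
                significant=significant,
                highly_enriched=significant and fe_max > FE_HIGH,
            )
        )
    out = pd.DataFrame([vars(r) for r in rows])
    return out.sort_values("fe_adj_max", ascending=False).reset_index(drop=True)
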