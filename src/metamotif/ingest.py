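"""Per-study differential-expression tables: reading, filtering, ranking.

A gene enters the meta-analysis for a study only if it clears the
inclusion filter: |fold change| > 1.25 (symmetric on the log2 scale),
adjusted p below the platform cutoff (0.05 for count-based assays,
0.1 for DNA microarrays), and a translated biotype.  Passing genes are
split by fold-change sign into direction-specific lists ordered by
ascending adjusted p (ties: descending |log2FC|, then gene id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PADJ_CUTOFFS",
    "TRANSLATED_BIOTYPES",
    "StudyResultTable",
    "RankedGeneList",
    "read_study_table",
    "filter_and_rank",
]

logger = logging.getLogger(__name__)

#: adjusted-p inclusion cutoff per platform; CAGE is a count-based
#: sequencing assay and takes the RNA-seq cutoff
PADJ_CUTOFFS = {"rna-seq": 0.05, "cage": 0.05, "microarray": 0.1}

#: biotypes counted as translated genes
TRANSLATED_BIOTYPES = frozenset(
    {
        "protein_coding",
        "polymorphic_pseudogene",
        "translated_processed_pseudogene",
        "translated_unprocessed_pseudogene",
    }
)

LOG2_FC_CUTOFF = float(np.log2(1.25))


@dataclass
class StudyResultTable:
    """One study's gene-level DE statistics plus its measured universe."""

    study_id: str
    platform: str
    table: pd.DataFrame  # columns: gene_id, fold_change, padj
    measured_universe: frozenset

    def __post_init__(self) -> None:
        if self.platform not in PADJ_CUTOFFS:
            raise ValueError(
                f"unknown platform {self.platform!r}; expected one of {sorted(PADJ_CUTOFFS)}"
            )


@dataclass
class RankedGeneList:
    """Direction-specific ordered gene list for one study.

    ``normalized_rank[i] = (i + 1) / len(genes)`` so the last retained
    gene has rank exactly 1.  ``universe_size`` (the number of measured
    genes in the study) is carried along so the aggregation stage can
    rescale positions against the full measured universe.
    """

    study_id: str
    direction: str  # "up" | "down"
    genes: list
    normalized_rank: np.ndarray
    universe_size: int
    measured_universe: frozenset = field(repr=False)

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.genes, "normalized_rank": self.normalized_rank}
        )


def read_study_table(path, platform: str | None = None) -> StudyResultTable:
    """Read a per-study DE table (TSV: gene_id, fold_change, padj[, platform]).

    Rows with missing fields or out-of-domain values (padj outside
    [0, 1], non-positive fold change) are dropped with a logged count.
    Duplicate gene ids are an error.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "fold_change", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    if platform is None:
        if "platform" not in df.columns or df["platform"].isna().all():
            raise ValueError(f"{path}: no platform column and none supplied")
        platform = str(df["platform"].iloc[0])
    if platform not in PADJ_CUTOFFS:
        raise ValueError(f"unknown platform {platform!r}")

    n0 = len(df)
    if n0 == 0:
        raise ValueError(f"{path}: empty study table")
    df = df.dropna(subset=["gene_id", "fold_change", "padj"])
    df = df[(df["padj"] >= 0) & (df["padj"] <= 1) & (df["fold_change"] > 0)]
    dropped = n0 - len(df)
    if dropped:
        logger.warning("%s: dropped %d malformed rows", path, dropped)
    if len(df) == 0:
        raise ValueError(f"{path}: no valid rows after cleaning")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id(s): {sorted(set(dup))[:5]}")

    study_id = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return StudyResultTable(
        study_id=study_id,
        platform=platform,
        table=df[["gene_id", "fold_change", "padj"]].reset_index(drop=True),
        measured_universe=frozenset(df["gene_id"]),
    )


def filter_and_rank(
    table: StudyResultTable, gene_biotypes: dict
) -> tuple[RankedGeneList, RankedGeneList]:
    """Apply the inclusion filter and rank passers per direction.

    Genes absent from the biotype map are excluded (and counted in the
    log); biotype must be translated.  Strict inequalities throughout.
    """
    df = table.table.copy()
    cutoff = PADJ_CUTOFFS[table.platform]

    biotype = df["gene_id"].map(gene_biotypes)
    n_uncovered = int(biotype.isna().sum())
    if n_uncovered:
        logger.info(
            "%s: %d genes lack a biotype annotation and were excluded",
            table.study_id,
            n_uncovered,
        )
    translated = biotype.isin(TRANSLATED_BIOTYPES)

    lfc = np.log2(df["fold_change"].to_numpy(dtype=float))
    passes = (np.abs(lfc) > LOG2_FC_CUTOFF) & (df["padj"].to_numpy() < cutoff) & translated.to_numpy()
    df = df.assign(log2fc=lfc)[passes]

    out = []
    for direction, sub in (("up", df[df["log2fc"] > 0]), ("down", df[df["log2fc"] < 0])):
        sub = sub.assign(abs_lfc=sub["log2fc"].abs()).sort_values(
            ["padj", "abs_lfc", "gene_id"], ascending=[True, False, True]
        )
        genes = sub["gene_id"].tolist()
        k = len(genes)
        ranks = (np.arange(1, k + 1) / k) if k else np.array([])
        out.append(
            RankedGeneList(
                study_id=table.study_id,
                direction=direction,
                genes=genes,
                normalized_rank=ranks,
                universe_size=len(table.measured_universe),
                measured_universe=table.measured_universe,
            )
        )
    return out[0], out[1]
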