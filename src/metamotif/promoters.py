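"""TSS selection and strand-aware promoter extraction.

The promoter of a gene is the window from 1500 bp upstream to 500 bp
downstream of the transcription start site of its most abundant
transcript.  Coordinates are 0-based half-open throughout; the window
comprises 1500 upstream bases, the TSS base itself, and 499 downstream
bases (2000 bp total).  Minus-strand promoters are reverse-complemented
so the emitted sequence always reads 5' -> 3' relative to transcription
with the -1500 position first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PromoterSet",
    "select_tss",
    "extract_promoters",
    "sample_reference_promoters",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

TSS_COLUMNS = ["gene_id", "transcript_id", "contig", "tss_pos", "strand", "abundance"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterSet:
    """Extracted promoter windows.

    ``intervals``: DataFrame gene_id, contig, start, end, strand,
    clipped (BED-ready, 0-based half-open genome coordinates).
    ``sequences``: gene_id -> sequence, 5'->3' in transcription sense.
    """

    intervals: pd.DataFrame
    sequences: dict

    def __len__(self) -> int:
        return len(self.sequences)

    def to_bed(self, path) -> None:
        bed = self.intervals.copy()
        bed["score"] = 0
        bed[["contig", "start", "end", "gene_id", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gid, seq in self.sequences.items():
                fh.write(f">{gid}\n{seq}\n")

    def subset(self, gene_ids) -> "PromoterSet":
        keep = set(gene_ids)
        return PromoterSet(
            intervals=self.intervals[self.intervals["gene_id"].isin(keep)].reset_index(drop=True),
            sequences={g: s for g, s in self.sequences.items() if g in keep},
        )


def select_tss(transcript_table: pd.DataFrame) -> pd.DataFrame:
    """One TSS per gene: the most abundant transcript wins.

    Ties break to the 5'-most TSS on the gene's strand (smallest
    coordinate on +, largest on -), then lexicographic transcript id.
    A gene with transcripts on both strands is an error.
    """
    df = transcript_table
    missing = set(TSS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transcript table missing columns {sorted(missing)}")
    if (df["abundance"] < 0).any():
        raise ValueError("abundances must be non-negative")

    bad = df.groupby("gene_id")["strand"].nunique()
    conflicted = sorted(bad[bad > 1].index)
    if conflicted:
        raise ValueError(f"conflicting strands within gene(s): {conflicted}")

    rows = []
    for gene, grp in df.groupby("gene_id", sort=True):
        strand = grp["strand"].iloc[0]
        best = grp[grp["abundance"] == grp["abundance"].max()]
        if len(best) > 1:
            ascending = strand == "+"
            best = best.sort_values(
                ["tss_pos", "transcript_id"], ascending=[ascending, True]
            )
        best = best.iloc[0]
        rows.append(
            {
                "gene_id": gene,
                "contig": best["contig"],
                "tss_pos": int(best["tss_pos"]),
                "strand": strand,
                "source_transcript": best["transcript_id"],
                "abundance": float(best["abundance"]),
            }
        )
    return pd.DataFrame(rows)


def _fetch(genome, contig: str, start: int, end: int) -> str:
    ref = genome[contig]
    return str(ref[start:end]).upper()


def _contig_length(genome, contig: str) -> int:
    return len(genome[contig])


def extract_promoters(
    genome,
    tss: pd.DataFrame,
    upstream: int = 1500,
    downstream: int = 500,
) -> PromoterSet:
    """Extract strand-aware promoter windows around selected TSSs.

    + strand: [pos - upstream, pos + downstream); - strand:
    [pos - downstream + 1, pos + upstream + 1), reverse-complemented so
    the upstream-most base leads.  Windows clipped at contig edges are
    flagged.  ``genome`` may be a pyfaidx.Fasta or any mapping of
    contig -> string.
    """
    records = []
    sequences = {}
    for row in tss.itertuples(index=False):
        contig = str(row.contig)
        try:
            clen = _contig_length(genome, contig)
        except KeyError as exc:
            raise KeyError(f"TSS contig {contig!r} not in genome") from exc
        pos = int(row.tss_pos)
        if row.strand == "+":
            start, end = pos - upstream, pos + downstream
        else:
            start, end = pos - downstream + 1, pos + upstream + 1
        clipped = start < 0 or end > clen
        cstart, cend = max(0, start), min(clen, end)
        seq = _fetch(genome, contig, cstart, cend)
        if row.strand == "-":
            seq = reverse_complement(seq)
        if clipped:
            logger.warning(
                "promoter of %s clipped to [%d, %d) at contig edge",
                row.gene_id, cstart, cend,
            )
        records.append(
            {
                "gene_id": row.gene_id,
                "contig": contig,
                "start": cstart,
                "end": cend,
                "strand": row.strand,
                "clipped": clipped,
            }
        )
        sequences[row.gene_id] = seq
    return PromoterSet(intervals=pd.DataFrame(records), sequences=sequences)


def sample_reference_promoters(
    all_promoters: PromoterSet,
    n: int = 5000,
    seed: int = 0,
    exclude: set | None = None,
) -> PromoterSet:
    """Uniform seed-reproducible sample of reference promoters.

    ``exclude`` (typically the DEG genes) is removed from the sampling
    universe first.  If fewer than ``n`` candidates remain, all are
    returned with a warning.
    """
    pool = sorted(set(all_promoters.sequences) - set(exclude or ()))
    if len(pool) <= n:
        if len(pool) < n:
            logger.warning(
                "reference universe has only %d promoters (< %d); using all", len(pool), n
            )
        return all_promoters.subset(pool)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.array(pool, dtype=object), size=n, replace=False)
    return all_promoters.subset(chosen)
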