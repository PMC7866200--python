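"""Motif-overlap statistic: evidence for heterodimeric binding.

TFs that bind DNA as dimers (the bZIP ATF/CREB/AP-1 superfamily being
the canonical case) leave motifs that co-locate.  For each TF we report
the percentage of its motifs that are overlapped by a motif of a
*different* TF by strictly more than half of the focal motif's own
length.  Hits are expected to come from a sparse scan (one site per
50 kb calibration) so per-promoter hit lists are short.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["overlap_percent"]


def _overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def overlap_percent(
    hits_by_tf: dict,
    min_fraction: float = 0.5,
    exclude_same_tf: bool = True,
) -> pd.DataFrame:
    """Percent of each TF's motifs overlapped by another TF's motif.

    ``hits_by_tf`` maps TF name -> hit table with columns promoter_id,
    start, end (as produced by :func:`metamotif.pwm.scan_sequences`).
    A motif of TF X counts as overlapped iff some motif of a different
    TF on the same promoter overlaps it by strictly more than
    ``min_fraction`` of X's own length.  TFs with no motifs get NaN.

    Returns a DataFrame with columns tf_name, total_motifs,
    overlapped_motifs, percent_overlapped.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")

    # flatten into per-promoter interval lists
    per_promoter: dict[str, list[tuple[int, int, str]]] = {}
    for tf, hits in hits_by_tf.items():
        for row in hits.itertuples(index=False):
            per_promoter.setdefault(str(row.promoter_id), []).append(
                (int(row.start), int(row.end), tf)
            )

    totals = {tf: 0 for tf in hits_by_tf}
    overlapped = {tf: 0 for tf in hits_by_tf}
    for intervals in per_promoter.values():
        for start, end, tf in intervals:
            totals[tf] += 1
            length = end - start
            for o_start, o_end, o_tf in intervals:
                if exclude_same_tf and o_tf == tf:
                    continue
                if (o_start, o_end, o_tf) == (start, end, tf):
                    continue
                if _overlap_len(start, end, o_start, o_end) > min_fraction * length:
                    overlapped[tf] += 1
                    break

    rows = []
    for tf in hits_by_tf:
        total = totals[tf]
        rows.append(
            {
                "tf_name": tf,
                "total_motifs": total,
                "overlapped_motifs": overlapped[tf],
                "percent_overlapped": 100.0 * overlapped[tf] / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)
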