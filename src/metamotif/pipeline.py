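"""End-to-end orchestration of the synthetic meta-analysis study.

``run_pipeline`` chains every stage — simulate multi-study DE tables,
filter and rank per study, aggregate ranks into DEG calls, build a
planted promoter corpus for the called DEGs, calibrate and scan the PWM
library, test per-matrix enrichment, compute the motif-overlap
statistic, and cluster the TF interaction graph — writing every output
under one directory and hashing it into a manifest.  Reruns with the
same config and seed are byte-identical.

All printed thresholds of the analysis live in :class:`PipelineConfig`
so the strict-inequality choices are auditable in one place.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich as enrich_mod
from . import simulate as sim
from .fileio import sha256_file, write_fasta
from .ingest import filter_and_rank, read_study_table
from .mcl import mcl_cluster
from .overlap import overlap_percent
from .pwm import (
    HIT_COLUMNS,
    calibrate_threshold,
    log_odds_matrix,
    parse_pwms,
    scan_sequences,
    write_pwms,
)
from .rankagg import aggregate, compare_deg_sets

__all__ = ["PipelineConfig", "run_pipeline", "class_intersections", "PipelineError"]

logger = logging.getLogger(__name__)


def _concat_hits(frames: list) -> pd.DataFrame:
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=HIT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of one analysis run.

    The threshold block collects every printed cutoff of the analysis:
    RRA DEG call padj < 0.01; enrichment FE_adj > 1.25 (FDR < 0.05),
    highly enriched FE_adj > 1.5; expression filter FPKM >= 0.5; site
    frequency targets 1/2000 bp (enrichment scan) and 1/50000 bp
    (overlap scan); promoter window -1500..+500.
    """

    seed: int = 1
    intervention: str = "synthetic"
    # study tables: if empty, simulate with the sizes below
    study_tables: list = field(default_factory=list)  # [{path, platform}]
    n_genes: int = 2000
    n_studies: int = 8
    n_true_up: int = 60
    n_true_down: int = 60
    penetrance: float = 0.7
    missing_rate: float = 0.1
    platform_mix: float = 0.5
    # promoter corpus
    reference_size: int = 5000
    promoter_length: int = 2000
    gc_content: float = 0.41
    planted_prevalence: float = 0.4
    background_prevalence: float = 0.05
    # PWM library
    n_pwms: int = 6
    matrices_per_tf: int = 2
    # windows and rates
    upstream: int = 1500
    downstream: int = 500
    rate_enrich: float = 1.0 / 2000
    rate_overlap: float = 1.0 / 50000
    # printed thresholds
    rra_padj: float = 0.01
    fe_min: float = 1.25
    fe_high: float = 1.5
    fdr_max: float = 0.05
    fpkm_min: float = 0.5
    min_studies: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("rra_padj", "fe_min", "fe_high", "fdr_max", "rate_enrich", "rate_overlap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for entry in self.study_tables:
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(f"study table not found: {entry['path']}")


def class_intersections(
    deg_sets: dict, class_lists: dict, fpkm_table: dict, fpkm_min: float = 0.5
) -> pd.DataFrame:
    """Intersect expression-filtered gene classes with DEG sets.

    Class genes with FPKM below ``fpkm_min`` are removed first; genes
    missing from the FPKM table count as below the cutoff (logged).
    Returns one row per (class, DEG set) with the filtered class size,
    overlap count, and overlap as a percent of the filtered class.
    """
    rows = []
    for cname, members in class_lists.items():
        uncovered = [g for g in members if g not in fpkm_table]
        if uncovered:
            logger.info(
                "class %s: %d genes lack FPKM values, treated as below cutoff",
                cname, len(uncovered),
            )
        filtered = {g for g in members if fpkm_table.get(g, 0.0) >= fpkm_min}
        for dname, degs in deg_sets.items():
            overlap = len(filtered & set(degs))
            rows.append(
                {
                    "class": cname,
                    "deg_set": dname,
                    "class_size_filtered": len(filtered),
                    "overlap": overlap,
                    "percent_of_class": 100.0 * overlap / len(filtered) if filtered else 0.0,
                }
            )
    return pd.DataFrame(rows)


def _iid_background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def _calibration_background(corpus_ref: dict, rng, length_needed: int, gc: float) -> dict:
    total = sum(len(s) for s in corpus_ref.values())
    if total >= length_needed:
        return corpus_ref
    logger.info(
        "reference promoters too short for calibration (%d < %d bp); "
        "generating an i.i.d. GC-matched background", total, length_needed,
    )
    return {"calibration_bg": _iid_background(rng, length_needed, gc)}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict[str, int] = {}

    def save_tsv(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
        return p

    stage = "validate"
    try:
        # ---- simulate ------------------------------------------------
        stage = "simulate"
        if config.study_tables:
            tables = [
                read_study_table(e["path"], e.get("platform"))
                for e in config.study_tables
            ]
            truth = None
            biotypes = {}
            for t in tables:
                biotypes.update({g: "protein_coding" for g in t.measured_universe})
        else:
            meta_cfg = sim.MetaSimConfig(
                n_genes=config.n_genes,
                n_studies=config.n_studies,
                n_true_up=config.n_true_up,
                n_true_down=config.n_true_down,
                penetrance=config.penetrance,
                missing_rate=config.missing_rate,
                platform_mix=config.platform_mix,
                seed=config.seed,
            )
            tables, truth = sim.simulate_meta_tables(meta_cfg)
            biotypes = truth.gene_biotypes
            for t in tables:
                save_tsv(t.table.assign(platform=t.platform), f"study_{t.study_id}.tsv")
            save_tsv(
                pd.DataFrame(sorted(biotypes.items()), columns=["gene_id", "biotype"]),
                "gene_biotypes.tsv",
            )
            save_tsv(
                pd.DataFrame(
                    sorted(
                        [(g, "up") for g in truth.true_up_genes]
                        + [(g, "down") for g in truth.true_down_genes]
                    ),
                    columns=["gene_id", "direction"],
                ),
                "truth_deg.tsv",
            )
        counts["studies"] = len(tables)

        pwms = sim.simulate_pwm_library(
            config.n_pwms, seed=config.seed, matrices_per_tf=config.matrices_per_tf
        )
        pwm_path = out / "pwms.transfac"
        write_pwms(pwms, pwm_path, "transfac")
        write_pwms(pwms, out / "pwms.jaspar", "jaspar")
        written += [pwm_path, out / "pwms.jaspar"]

        # ---- ingest + rank -------------------------------------------
        stage = "ingest"
        ranked = {"up": [], "down": []}
        for t in tables:
            up, down = filter_and_rank(t, biotypes)
            ranked["up"].append(up)
            ranked["down"].append(down)
            save_tsv(up.to_frame(), f"ranked_{t.study_id}_up.tsv")
            save_tsv(down.to_frame(), f"ranked_{t.study_id}_down.tsv")
        counts["genes_retained_up"] = sum(len(l) for l in ranked["up"])
        counts["genes_retained_down"] = sum(len(l) for l in ranked["down"])

        # ---- aggregate -----------------------------------------------
        stage = "aggregate"
        deg_sets = {}
        for direction in ("up", "down"):
            agg = aggregate(ranked[direction], min_studies=config.min_studies)
            agg["is_deg"] = agg["padj"] < config.rra_padj
            save_tsv(agg, f"aggregation_{direction}.tsv")
            degs = sorted(agg.loc[agg["is_deg"], "gene_id"])
            deg_sets[direction] = set(degs)
            (out / f"degs_{direction}.txt").write_text("\n".join(degs) + "\n")
            written.append(out / f"degs_{direction}.txt")
            counts[f"degs_{direction}"] = len(degs)
        overlap_summary = compare_deg_sets(deg_sets)
        p = out / "deg_set_comparison.json"
        p.write_text(
            json.dumps(
                {
                    "sizes": overlap_summary["sizes"],
                    "pairwise_intersections": {
                        f"{a}&{b}": v
                        for (a, b), v in overlap_summary["pairwise_intersections"].items()
                    },
                    "unique_counts": overlap_summary["unique_counts"],
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        written.append(p)

        # ---- promoter corpus -----------------------------------------
        stage = "promoters"
        n_deg_prom = max(len(deg_sets["up"]), 10)
        prom_cfg = sim.PromoterSimConfig(
            n_deg=n_deg_prom,
            n_ref=config.reference_size,
            promoter_length=config.promoter_length,
            gc_content=config.gc_content,
            planted_prevalence=config.planted_prevalence,
            background_prevalence=config.background_prevalence,
            seed=config.seed,
        )
        corpus, prom_truth = sim.simulate_promoter_corpus(prom_cfg, pwms)
        write_fasta(corpus.deg, out / "promoters_deg.fasta")
        write_fasta(corpus.ref, out / "promoters_ref.fasta")
        written += [out / "promoters_deg.fasta", out / "promoters_ref.fasta"]
        save_tsv(
            pd.DataFrame(
                [
                    (pid, s, e, m, st)
                    for pid, ivs in sorted(prom_truth.planted_site_coordinates.items())
                    for (s, e, m, st) in ivs
                ],
                columns=["promoter_id", "start", "end", "matrix_id", "strand"],
            ),
            "truth_planted_sites.tsv",
        )
        counts["deg_promoters"] = len(corpus.deg)
        counts["ref_promoters"] = len(corpus.ref)

        # ---- calibrate + scan ----------------------------------------
        stage = "scan"
        pwms_rt = parse_pwms(pwm_path, "transfac")  # round trip through disk
        for p_ in pwms_rt:
            log_odds_matrix(p_)
        bg_rng = sim.derived_rng(config.seed, "background")
        cal_rows, hit_frames = [], {"deg": [], "ref": []}
        overlap_hits_by_tf: dict[str, list] = {}
        bg_enrich = _calibration_background(
            corpus.ref, bg_rng, int(np.ceil(100 / config.rate_enrich)) + 10_000, config.gc_content
        )
        bg_overlap = _calibration_background(
            corpus.ref, bg_rng, int(np.ceil(100 / config.rate_overlap)) + 10_000, config.gc_content
        )
        for p_ in pwms_rt:
            cal = calibrate_threshold(p_, bg_enrich, config.rate_enrich)
            cal_rows.append(
                (p_.matrix_id, "enrich", cal.target_rate, cal.threshold, cal.achieved_rate)
            )
            hit_frames["deg"].append(scan_sequences(corpus.deg, p_, cal.threshold))
            hit_frames["ref"].append(scan_sequences(corpus.ref, p_, cal.threshold))
            cal_ov = calibrate_threshold(p_, bg_overlap, config.rate_overlap)
            cal_rows.append(
                (p_.matrix_id, "overlap", cal_ov.target_rate, cal_ov.threshold, cal_ov.achieved_rate)
            )
            tf = p_.tf_names[0] if p_.tf_names else p_.matrix_id
            overlap_hits_by_tf.setdefault(tf, []).append(
                scan_sequences(corpus.deg, p_, cal_ov.threshold)
            )
        save_tsv(
            pd.DataFrame(
                cal_rows,
                columns=["matrix_id", "purpose", "target_rate", "threshold", "achieved_rate"],
            ),
            "calibrations.tsv",
        )
        hits_deg = _concat_hits(hit_frames["deg"])
        hits_ref = _concat_hits(hit_frames["ref"])
        save_tsv(hits_deg, "hits_deg.tsv")
        save_tsv(hits_ref, "hits_ref.tsv")
        counts["hits_deg"] = len(hits_deg)
        counts["hits_ref"] = len(hits_ref)

        # ---- enrichment ----------------------------------------------
        stage = "enrich"
        matrix_to_tf = {
            p_.matrix_id: (p_.tf_names[0] if p_.tf_names else p_.matrix_id) for p_ in pwms_rt
        }
        records = enrich_mod.enrich_all(
            hits_deg, hits_ref, len(corpus.deg), len(corpus.ref), matrix_to_tf
        )
        save_tsv(records, "enrichment_matrices.tsv")
        tf_summary = enrich_mod.collapse_to_tf(records)
        save_tsv(tf_summary, "enrichment_tfs.tsv")
        counts["matrices_significant"] = int(
            ((records["fe_adj"] > config.fe_min) & (records["fdr"] < config.fdr_max)).sum()
        )

        # ---- overlap --------------------------------------------------
        stage = "overlap"
        hits_by_tf = {
            tf: _concat_hits(frames) for tf, frames in overlap_hits_by_tf.items()
        }
        save_tsv(overlap_percent(hits_by_tf), "motif_overlap.tsv")

        # ---- cluster --------------------------------------------------
        stage = "cluster"
        tf_names = sorted(set(matrix_to_tf.values()))
        half = max(1, len(tf_names) // 2)
        sizes = [half, len(tf_names) - half] if len(tf_names) > 1 else [1]
        edges, ppi_truth = sim.simulate_ppi_edges(
            sizes, p_within=0.9, p_between=0.05, seed=config.seed, node_names=tf_names
        )
        save_tsv(edges, "ppi_edges.tsv")
        partition = mcl_cluster(edges, nodes=tf_names)
        save_tsv(partition.to_frame(), "tf_clusters.tsv")
        counts["tf_clusters"] = partition.n_clusters

        # ---- manifest -------------------------------------------------
        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "stage_counts": counts,
            "files": {p.name: sha256_file(p) for p in sorted(set(written))},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        (out / "failed").mkdir(exist_ok=True)
        (out / "failed" / "STAGE").write_text(stage + "\n")
        raise PipelineError(stage, exc) from exc
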