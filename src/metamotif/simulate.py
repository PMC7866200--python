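"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline (study ingestion, rank
aggregation, promoter scanning, enrichment, overlap, clustering) is
exercised against corpora produced here, so each generator records the
planted truth it used in a :class:`TruthSet`.

All generators are deterministic under a fixed seed.  A single integer
seed fans out to independent per-generator streams via
``numpy.random.SeedSequence(seed, spawn_key=(DOMAIN,))`` where DOMAIN is
a fixed small integer per generator (see :data:`SEED_DOMAINS`), so the
modules can be run and tested independently without sharing RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import PADJ_CUTOFFS, StudyResultTable
from .pwm import PWM

__all__ = [
    "MetaSimConfig",
    "PromoterSimConfig",
    "PromoterCorpus",
    "TruthSet",
    "simulate_meta_tables",
    "simulate_promoter_corpus",
    "simulate_pwm_library",
    "simulate_ppi_edges",
    "derived_rng",
]

#: fixed spawn keys: one independent stream per generator
SEED_DOMAINS = {"meta": 0, "promoters": 1, "pwms": 2, "ppi": 3, "background": 4}

LOG2_FC_CUTOFF = float(np.log2(1.25))


def derived_rng(seed: int, domain: str) -> np.random.Generator:
    """Per-generator RNG derived from the one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(SEED_DOMAINS[domain],))
    )


@dataclass
class TruthSet:
    """Planted ground truth shared by all generators."""

    true_up_genes: set = field(default_factory=set)
    true_down_genes: set = field(default_factory=set)
    #: promoter_id -> list of (start, end, matrix_id, strand)
    planted_site_coordinates: dict = field(default_factory=dict)
    #: node -> cluster index
    planted_clusters: dict = field(default_factory=dict)
    #: gene_id -> biotype (meta-table generator only)
    gene_biotypes: dict = field(default_factory=dict)


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class MetaSimConfig:
    """Conditions for the multi-study differential-expression simulation.

    ``penetrance`` is the probability that a true DEG responds (and
    therefore passes the per-study inclusion filter) in any one study in
    which it is measured.  Null adjusted p-values are Uniform(0,1); a
    responding true DEG draws its adjusted p as ``cutoff * Beta(a, 1)``
    with ``a = true_p_scale`` so it always clears the platform cutoff
    and, for small ``a``, sorts ahead of chance passers.
    """

    n_genes: int = 5000
    n_studies: int = 10
    n_true_up: int = 100
    n_true_down: int = 100
    penetrance: float = 0.7
    true_p_scale: float = 0.1
    missing_rate: float = 0.1
    platform_mix: float = 0.5  # fraction of studies labelled microarray
    noncoding_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("penetrance", "missing_rate", "platform_mix", "noncoding_fraction"):
            _check_fraction(name, getattr(self, name))
        if not 0 < self.true_p_scale:
            raise ValueError("true_p_scale must be positive")
        if self.n_true_up + self.n_true_down > self.n_genes:
            raise ValueError("n_true_up + n_true_down exceeds n_genes")


def simulate_meta_tables(config: MetaSimConfig) -> tuple[list[StudyResultTable], TruthSet]:
    """Generate one DE result table per study with a planted DEG core.

    Returns the study tables plus a :class:`TruthSet` holding the true
    up/down gene sets and the gene->biotype map (mostly protein_coding,
    with a non-coding fraction among null genes so the translated-gene
    filter is exercised).
    """
    rng = derived_rng(config.seed, "meta")
    n = config.n_genes
    genes = np.array([f"G{i:06d}" for i in range(1, n + 1)])

    # biotypes: non-coding only among nulls so planted DEGs stay eligible
    biotypes = np.full(n, "protein_coding", dtype=object)
    order = rng.permutation(n)
    n_true = config.n_true_up + config.n_true_down
    true_idx = order[:n_true]
    up_idx = true_idx[: config.n_true_up]
    down_idx = true_idx[config.n_true_up :]
    null_idx = order[n_true:]
    n_nc = int(round(config.noncoding_fraction * n))
    nc_idx = null_idx[:n_nc]
    biotypes[nc_idx] = "lincRNA"
    if len(nc_idx) >= 4:  # sprinkle translated pseudogenes among the nulls
        biotypes[null_idx[n_nc : n_nc + 4]] = "polymorphic_pseudogene"

    sign = np.zeros(n)
    sign[up_idx] = 1.0
    sign[down_idx] = -1.0
    is_true = sign != 0.0

    n_micro = int(round(config.platform_mix * config.n_studies))
    platforms = np.array(
        ["microarray"] * n_micro + ["rna-seq"] * (config.n_studies - n_micro),
        dtype=object,
    )
    rng.shuffle(platforms)

    tables: list[StudyResultTable] = []
    for s in range(config.n_studies):
        platform = str(platforms[s])
        cutoff = PADJ_CUTOFFS[platform]
        measured = rng.random(n) >= config.missing_rate
        responding = is_true & (rng.random(n) < config.penetrance)

        padj = rng.random(n)
        lfc = rng.normal(0.0, 0.15, size=n)
        k = int(responding.sum())
        if k:
            # Beta(a,1) via inverse CDF, scaled under the platform cutoff
            padj[responding] = cutoff * rng.random(k) ** (1.0 / config.true_p_scale)
            lfc[responding] = sign[responding] * (
                LOG2_FC_CUTOFF + np.abs(rng.normal(0.35, 0.25, size=k)) + 1e-9
            )

        df = pd.DataFrame(
            {
                "gene_id": genes[measured],
                "fold_change": np.exp2(lfc[measured]),
                "padj": padj[measured],
                "platform": platform,
            }
        )
        tables.append(
            StudyResultTable(
                study_id=f"study{s + 1:02d}",
                platform=platform,
                table=df,
                measured_universe=frozenset(genes[measured]),
            )
        )

    truth = TruthSet(
        true_up_genes=set(genes[up_idx]),
        true_down_genes=set(genes[down_idx]),
        gene_biotypes=dict(zip(genes, biotypes)),
    )
    return tables, truth


@dataclass
class PromoterSimConfig:
    """Conditions for the planted-motif promoter corpus.

    Two promoter sets are produced: ``n_deg`` promoters standing in for
    DEG promoters (motifs planted at ``planted_prevalence``) and
    ``n_ref`` reference promoters (planted at ``background_prevalence``).
    """

    n_deg: int = 300
    n_ref: int = 5000
    promoter_length: int = 2000
    gc_content: float = 0.41
    planted_pwm_ids: list | None = None  # None = first matrix of the library
    planted_prevalence: float = 0.4
    background_prevalence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        _check_fraction("gc_content", self.gc_content)
        _check_fraction("planted_prevalence", self.planted_prevalence)
        _check_fraction("background_prevalence", self.background_prevalence)
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be positive")


@dataclass
class PromoterCorpus:
    """DEG and reference promoter sequences, both keyed by promoter id."""

    deg: dict
    ref: dict

    @property
    def all(self) -> dict:
        merged = dict(self.deg)
        merged.update(self.ref)
        return merged


_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    """Sample a site column-wise from the PWM probability matrix."""
    probs = pwm.probabilities
    idx = [rng.choice(4, p=probs[i]) for i in range(pwm.length)]
    return "".join(_BASES[idx])


def _plant(seq: list, pwm: PWM, rng: np.random.Generator, occupied: list) -> tuple:
    """Place one sampled site at a random non-overlapping offset/strand."""
    L = pwm.length
    if L > len(seq):
        raise ValueError(
            f"motif {pwm.matrix_id} (length {L}) longer than promoter ({len(seq)} bp)"
        )
    site = _sample_site(pwm, rng)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        site = site.translate(_COMPLEMENT)[::-1]
    for _ in range(200):
        start = int(rng.integers(0, len(seq) - L + 1))
        end = start + L
        if all(end <= s or start >= e for s, e in occupied):
            seq[start:end] = list(site)
            occupied.append((start, end))
            return (start, end, pwm.matrix_id, strand)
    raise RuntimeError("could not place a non-overlapping site after 200 attempts")


def simulate_promoter_corpus(
    config: PromoterSimConfig, pwms: list[PWM]
) -> tuple[PromoterCorpus, TruthSet]:
    """Generate DEG and reference promoters with planted motif sites.

    Backgrounds are i.i.d. nucleotides at the configured GC content;
    planted sites are sampled column-wise from the PWM probabilities and
    placed on a random strand at non-overlapping offsets.  Every planted
    interval is recorded in the returned :class:`TruthSet`.
    """
    if not pwms:
        raise ValueError("pwms must be non-empty")
    rng = derived_rng(config.seed, "promoters")
    by_id = {p.matrix_id: p for p in pwms}
    planted_ids = config.planted_pwm_ids or [pwms[0].matrix_id]
    missing = [m for m in planted_ids if m not in by_id]
    if missing:
        raise ValueError(f"planted_pwm_ids not in library: {missing}")
    max_len = max(by_id[m].length for m in planted_ids)
    if max_len > config.promoter_length:
        raise ValueError("promoter_length shorter than the longest planted motif")

    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    truth = TruthSet()

    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)

    def make_set(prefix: str, count: int, prevalence: float) -> dict:
        draws = base_bytes[
            rng.choice(4, size=(count, config.promoter_length), p=base_p)
        ]
        out = {}
        for i in range(count):
            pid = f"{prefix}{i + 1:05d}"
            seq = list(draws[i].tobytes().decode("ascii"))
            intervals = []
            if rng.random() < prevalence:
                pwm = by_id[planted_ids[int(rng.integers(len(planted_ids)))]]
                intervals.append(_plant(seq, pwm, rng, []))
            if intervals:
                truth.planted_site_coordinates[pid] = intervals
            out[pid] = "".join(seq)
        return out

    deg = make_set("DEGP", config.n_deg, config.planted_prevalence)
    ref = make_set("REFP", config.n_ref, config.background_prevalence)
    return PromoterCorpus(deg=deg, ref=ref), truth


def simulate_pwm_library(
    n_matrices: int,
    length_range: tuple[int, int] = (8, 14),
    seed: int = 0,
    matrices_per_tf: int = 1,
    total_count: int = 100,
) -> list[PWM]:
    """Generate a small PWM library spanning informativeness extremes.

    The first matrix is near-consensus (low entropy), the last is
    degenerate (near uniform); the rest draw column compositions from a
    sparse Dirichlet.  ``matrices_per_tf`` > 1 assigns consecutive
    matrices to the same TF name so per-TF collapsing has work to do.
    """
    lo, hi = length_range
    if lo < 4:
        raise ValueError("matrix length must be >= 4")
    if lo > hi:
        raise ValueError("invalid length_range")
    rng = derived_rng(seed, "pwms")
    pwms = []
    for i in range(n_matrices):
        L = int(rng.integers(lo, hi + 1))
        consensus = rng.integers(0, 4, size=L)
        if i == 0:
            # near-consensus: 97% consensus base per column, so sampled
            # sites rarely carry more than one mismatch
            counts = np.ones((L, 4))
            counts[np.arange(L), consensus] = total_count - 3
        elif i == n_matrices - 1 and n_matrices > 1:  # degenerate
            counts = rng.dirichlet([5.0] * 4, size=L) * total_count
            counts = np.maximum(np.round(counts), 0) + 1.0
        else:
            counts = rng.dirichlet([0.4] * 4, size=L) * total_count
            counts = np.maximum(np.round(counts), 0) + 1.0
        tf = f"TF{(i // max(1, matrices_per_tf)) + 1:03d}"
        pwms.append(PWM(matrix_id=f"M{i + 1:03d}", tf_names=[tf], counts=counts))
    return pwms


def simulate_ppi_edges(
    cluster_sizes: list[int],
    p_within: float = 0.9,
    p_between: float = 0.02,
    seed: int = 0,
    node_names: list[str] | None = None,
) -> tuple[pd.DataFrame, TruthSet]:
    """Planted-partition interaction graph as a weighted edge table.

    Within-cluster edges appear with probability ``p_within`` (weights
    U(0.6, 1)), between-cluster edges with ``p_between`` (weights
    U(0.1, 0.4)).  The planted node->cluster map goes into the truth.
    """
    _check_fraction("p_within", p_within)
    _check_fraction("p_between", p_between)
    if p_within <= p_between:
        raise ValueError("p_within must exceed p_between")
    rng = derived_rng(seed, "ppi")
    n = sum(cluster_sizes)
    if node_names is None:
        node_names = [f"TF{i + 1:03d}" for i in range(n)]
    if len(node_names) != n:
        raise ValueError("node_names length must equal sum(cluster_sizes)")

    membership = np.repeat(np.arange(len(cluster_sizes)), cluster_sizes)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            same = membership[i] == membership[j]
            p = p_within if same else p_between
            if rng.random() < p:
                w = rng.uniform(0.6, 1.0) if same else rng.uniform(0.1, 0.4)
                rows.append((node_names[i], node_names[j], round(float(w), 4)))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    truth = TruthSet(
        planted_clusters={node_names[i]: int(membership[i]) for i in range(n)}
    )
    return edges, truth
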