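"""Summary statistics, rounding conventions and pipeline orchestration.

Printed percentages follow the convention of the field's result tables:
whole-dataset fractions (percent of genome, percent of evaluated features)
are rounded half-up to one decimal, or two decimals below 10% where one
decimal would lose most of the information; up/down splits of a call set
are rounded to whole percent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cluster import ClusterSummary
from .integrate import CategoryPartition

logger = logging.getLogger("photolag")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 0.05 -> 0.1 at one digit, unlike banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_fraction_percent(numerator: float, denominator: float) -> float:
    """Dataset-level percent: one decimal, two decimals below 10%."""
    if denominator == 0:
        return 0.0
    pct = 100.0 * numerator / denominator
    return round_half_up(pct, 2 if pct < 10 else 1)


def format_split_percent(numerator: float, denominator: float) -> float:
    """Within-call-set percent (e.g. fraction upregulated): whole percent."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, 0)


@dataclass
class SummaryReport:
    """Paper-style headline numbers for one integrated analysis."""

    genome_size: int
    partition: CategoryPartition
    n_up_transcript: int
    n_down_transcript: int
    n_up_protein: int
    n_down_protein: int
    final_timepoint_peak_percent: float | None = None
    percent_of_genome_regulated: float = field(init=False)
    percent_of_genome_evaluated_transcript: float = field(init=False)
    percent_of_genome_evaluated_protein: float = field(init=False)
    percent_of_evaluated_regulated_transcript: float = field(init=False)
    percent_of_evaluated_regulated_protein: float = field(init=False)
    percent_up_transcript: float = field(init=False)
    percent_down_transcript: float = field(init=False)
    percent_up_protein: float = field(init=False)
    percent_down_protein: float = field(init=False)

    def __post_init__(self) -> None:
        p = self.partition
        if self.n_up_transcript + self.n_down_transcript != p.n_mrna_regulated:
            raise ValueError("transcript up+down must equal regulated count")
        if self.n_up_protein + self.n_down_protein != p.n_protein_regulated:
            raise ValueError("protein up+down must equal regulated count")
        g = self.genome_size
        if g < max(p.n_mrna_evaluated, p.n_protein_evaluated):
            raise ValueError("genome size smaller than an evaluated count")
        self.percent_of_genome_regulated = format_fraction_percent(p.n_mrna_regulated, g)
        self.percent_of_genome_evaluated_transcript = format_fraction_percent(
            p.n_mrna_evaluated, g
        )
        self.percent_of_genome_evaluated_protein = format_fraction_percent(
            p.n_protein_evaluated, g
        )
        self.percent_of_evaluated_regulated_transcript = format_fraction_percent(
            p.n_mrna_regulated, p.n_mrna_evaluated
        )
        self.percent_of_evaluated_regulated_protein = format_fraction_percent(
            p.n_protein_regulated, p.n_protein_evaluated
        )
        self.percent_up_transcript = format_split_percent(
            self.n_up_transcript, p.n_mrna_regulated
        )
        self.percent_down_transcript = format_split_percent(
            self.n_down_transcript, p.n_mrna_regulated
        )
        self.percent_up_protein = format_split_percent(self.n_up_protein, p.n_protein_regulated)
        self.percent_down_protein = format_split_percent(
            self.n_down_protein, p.n_protein_regulated
        )

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "partition"}
        out["partition"] = self.partition.to_dict()
        return out


def summarize(
    transcript_calls: pd.DataFrame,
    protein_calls: pd.DataFrame,
    partition: CategoryPartition,
    genome_size: int,
    final_timepoint_peak_percent: float | None = None,
) -> SummaryReport:
    """Build the summary report from call tables and a category partition."""
    t_reg = transcript_calls.loc[transcript_calls["regulated"]]
    p_reg = protein_calls.loc[protein_calls["regulated"]]
    return SummaryReport(
        genome_size=genome_size,
        partition=partition,
        n_up_transcript=int((t_reg["direction"] == "up").sum()),
        n_down_transcript=int((t_reg["direction"] == "down").sum()),
        n_up_protein=int((p_reg["direction"] == "up").sum()),
        n_down_protein=int((p_reg["direction"] == "down").sum()),
        final_timepoint_peak_percent=final_timepoint_peak_percent,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


DEFAULT_CONFIG = {
    "seed": 42,
    "genome_size": None,  # default: number of simulated genes
    "design": {},
    "classes": {"concordant": 30, "transcript_only": 30, "protein_only": 15, "null": 300},
    "noise": {},
    "priors": {},
    "thresholds": {
        "transcript_p": 0.01,
        "transcript_fc": 2.0,
        "protein_fdr": 0.05,
        "protein_fc": 2.0,
        "pseudocount": 1.0,
        "early_boundary": 25.0,
        "min_runs": 2,
        "knn_k": 10,
        "smoothing_weight": 0.5,
    },
    "clustering": {
        "k_init": 30,
        "tightness_quantile": 0.5,
        "merge_r": 0.8,
        "min_size": 5,
    },
    "protein_layer": True,
}


def _merged_config(config: dict) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    if "classes" in merged and merged["classes"]:
        from .simulate import _normalize_classes

        merged["classes"] = _normalize_classes(merged["classes"])
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Execute simulate -> transcript DE -> proteome -> integrate -> cluster
    -> summarize, writing every stage output plus a reproducibility manifest.

    Returns the manifest (config hash, seed, per-stage outputs with sha256
    checksums).  Rerunning with the same config reproduces identical files.
    """
    from . import __version__, cluster as cl, integrate as ig, proteome as pr
    from . import simulate as sim, transcripts as tr
    from .design import PulseDesign

    cfg = _merged_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = cfg["thresholds"]
    seed = int(cfg["seed"])

    design = PulseDesign.from_dict({**cfg["design"], "seed": seed})
    noise = sim.NoiseModel.from_dict(cfg["noise"]) if cfg["noise"] else sim.NoiseModel()
    priors = sim.GenePriors.from_dict(cfg["priors"]) if cfg["priors"] else sim.GenePriors()
    use_protein = bool(cfg.get("protein_layer", True))

    logger.info("simulate: classes=%s seed=%d", cfg["classes"], seed)
    dataset = sim.generate_dataset(cfg["classes"], design, noise, seed, priors)
    paths = dataset.write(outdir / "simulated")
    genome_size = cfg["genome_size"] or len(dataset.truth)

    # transcript layer
    normalized, factors = tr.normalize_library(dataset.transcripts)
    t_profiles = tr.fold_changes(normalized, pseudocount=thr["pseudocount"])
    t_calls = tr.call_regulated_transcripts(
        t_profiles,
        p_threshold=thr["transcript_p"],
        fc_threshold=thr["transcript_fc"],
        early_boundary=thr["early_boundary"],
    )
    logger.info(
        "de-transcripts: P<%g, fold>=%g -> %d/%d regulated",
        thr["transcript_p"], thr["transcript_fc"],
        int(t_calls["regulated"].sum()), len(t_calls),
    )
    t_profiles.to_csv(outdir / "transcript_profiles.tsv", sep="\t", index=False)
    t_calls.to_csv(outdir / "transcript_calls.tsv", sep="\t", index=False)
    factors.to_csv(outdir / "size_factors.tsv", sep="\t")

    # clustering of regulated transcript profiles
    reg_ids = t_calls.loc[t_calls["regulated"], "feature_id"]
    clus_cfg = cfg["clustering"]
    cluster_sum = ClusterSummary(0, 0, 0.0, 0.0)
    if len(reg_ids) > max(clus_cfg["k_init"], clus_cfg["min_size"]):
        Z, constant = cl.zscore_profiles(
            t_profiles.loc[t_profiles["feature_id"].isin(reg_ids)]
        )
        clusters = cl.extract_tight_clusters(
            Z, seed=seed, pre_unassigned=constant, **clus_cfg
        )
        shapes = {
            cid: cl.classify_cluster_shape(row.to_numpy())
            for cid, row in clusters.centroids.iterrows()
        }
        cluster_sum = cl.cluster_summary(clusters, n_regulated_total=len(reg_ids))
        clusters.assignments.rename("cluster").to_csv(
            outdir / "cluster_membership.tsv", sep="\t"
        )
        centroids = clusters.centroids.copy()
        centroids.insert(0, "shape", pd.Series(shapes))
        centroids.to_csv(outdir / "cluster_centroids.tsv", sep="\t")
        Z.to_csv(outdir / "cluster_zscores.tsv", sep="\t")
        logger.info(
            "cluster: %d clusters, %d/%d genes assigned",
            cluster_sum.n_clusters, cluster_sum.n_clustered, len(reg_ids)
        )
    else:
        logger.info("cluster: too few regulated transcripts, skipped")

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "stages": ["simulate", "de-transcripts", "cluster"],
    }

    if use_protein and cfg["classes"]:
        result = pr.run_proteome_pipeline(
            dataset.proteins,
            min_runs=thr["min_runs"],
            knn_k=thr["knn_k"],
            smoothing_weight=thr["smoothing_weight"],
            fdr=thr["protein_fdr"],
            fc_threshold=thr["protein_fc"],
        )
        p_profiles, p_calls = result["profiles"], result["calls"]
        logger.info(
            "proteome: FDR<%g, fold>=%g -> %d/%d regulated",
            thr["protein_fdr"], thr["protein_fc"],
            int(p_calls["regulated"].sum()), len(p_calls),
        )
        result["presence"].to_csv(outdir / "protein_presence.tsv", sep="\t", index=False)
        result["imputed"].values.to_csv(outdir / "protein_imputed.tsv", sep="\t")
        p_profiles.to_csv(outdir / "protein_profiles.tsv", sep="\t", index=False)
        p_calls.to_csv(outdir / "protein_calls.tsv", sep="\t", index=False)
        with open(outdir / "protein_overlap.json", "w") as fh:
            json.dump(result["overlap_counts"], fh, indent=2, sort_keys=True)

        universe = set(p_calls["feature_id"])
        pairs = ig.match_pairs(t_calls, p_calls, universe)
        partition = ig.partition_categories(t_calls, p_calls, universe, genome_size)
        pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        with open(outdir / "category_partition.json", "w") as fh:
            json.dump(partition.to_dict(), fh, indent=2)
        if pairs["is_pair"].sum() >= 3:
            grid = ig.lag_correlation(pairs, t_profiles, p_profiles)
            grid.write_tsv(outdir / "lag_grid.tsv")
            peak = ig.estimate_peak_lag(grid)
            ig.paired_profile_export(pairs, t_profiles, p_profiles).to_csv(
                outdir / "paired_profiles.tsv", sep="\t", index=False
            )
            logger.info("integrate: %d pairs, peak lag %.0f min",
                        int(pairs["is_pair"].sum()), peak.lag_minutes)
            lag_minutes = peak.lag_minutes
        else:
            logger.info("integrate: <3 pairs, lag grid skipped")
            lag_minutes = None

        peaks = pr.peak_time_summary(p_calls)
        summary = summarize(
            t_calls, p_calls, partition, genome_size,
            final_timepoint_peak_percent=peaks.percent_final,
        )
        summary_out = summary.to_dict()
        summary_out["cluster_summary"] = cluster_sum.__dict__
        summary_out["peak_lag_minutes"] = lag_minutes
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary_out, fh, indent=2, default=float)
        manifest["stages"] += ["proteome", "integrate", "summarize"]
    else:
        logger.info("proteome layer disabled; integration skipped")
        with open(outdir / "summary.json", "w") as fh:
            json.dump({"cluster_summary": cluster_sum.__dict__}, fh, indent=2,
                      default=float)

    outputs = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "run_manifest.json":
            outputs[str(p.relative_to(outdir))] = _sha256(p)
    manifest["outputs"] = outputs
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
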