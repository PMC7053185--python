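"""End-to-end pipeline runs and DMR bookkeeping.

``run_pipeline`` drives simulate → extract → metrics → summaries →
associations from a single structured configuration, echoes the effective
configuration (defaults included) into the run directory, and writes a
manifest with a SHA-256 checksum of every output so identical config + seed
reruns are verifiable byte-for-byte.

``summarize_dmrs`` is the bookkeeping arithmetic over an externally produced
differentially-methylated-region call set: direction counts, the
percentage hypomethylated, and optional per-feature-class proportions
against an annotation BED.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical_association as clin
from . import heterogeneity_metrics as het
from . import methylome_summaries as summ
from . import synthetic_data as synth
from .epiread_core import (
    CpGReference,
    build_cpg_index,
    compute_beta_track,
    extract_epireads,
    read_epiread_tsv,
    write_betas_bedgraph,
    write_epiread_tsv,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    mode: str = "simulate"  # simulate | epiread | bam
    outdir: str = "methylhet_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimulationConfig fields
    cohort: dict = field(default_factory=dict)  # CohortSpec fields
    metrics: dict = field(default_factory=dict)  # step, min_reads, pdr thresholds
    summaries: dict = field(default_factory=dict)  # tile_width, depth_threshold
    associations: dict = field(default_factory=dict)  # metric, survival on/off
    inputs: dict = field(default_factory=dict)  # epiread/bam/fasta paths
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "epiread", "bam"):
            raise ValueError(f"unknown mode {self.mode!r}")
        # fail fast: every block must build its module objects
        self.simulation_config()
        if self.mode == "simulate":
            self.cohort_spec()
        if self.mode in ("epiread", "bam"):
            for key in ("fasta",) + (("epireads",) if self.mode == "epiread" else ("alignments",)):
                if key not in self.inputs:
                    raise ValueError(f"mode {self.mode!r} requires inputs.{key}")

    def simulation_config(self) -> synth.SimulationConfig:
        return synth.SimulationConfig(seed=self.seed, **self.simulate)

    def cohort_spec(self) -> synth.CohortSpec:
        return synth.CohortSpec(**self.cohort)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effective_simulation"] = dataclasses.asdict(self.simulation_config())
        if self.mode == "simulate":
            d["effective_cohort"] = dataclasses.asdict(self.cohort_spec())
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stages: list[str]) -> Path:
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "stages": stages,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    On a stage failure the partial outputs are kept and a ``FAILED`` marker
    naming the stage is written before the error propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    stages: list[str] = []
    try:
        if config.mode == "simulate":
            samples = _stage_simulate(config, outdir)
            stages.append("simulate")
        else:
            samples = _stage_load(config, outdir)
            stages.append("load")
        ref = samples.pop("__ref__")
        per_sample = _stage_metrics(config, ref, samples, outdir)
        stages.append("metrics")
        _stage_summaries(config, ref, samples, outdir)
        stages.append("summaries")
        _stage_associations(config, per_sample, outdir)
        stages.append("associations")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {len(stages)}: {exc}\n")
        raise PipelineError(f"failed after stages {stages}: {exc}") from exc
    _write_manifest(outdir, stages)
    return outdir


def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    sim = config.simulation_config()
    spec = config.cohort_spec()
    ref, sequences = synth.simulate_reference(sim)
    cohort = synth.simulate_cohort(spec, sim)
    d = outdir / "epireads"
    d.mkdir(exist_ok=True)
    for s in cohort.samples:
        write_epiread_tsv(s.epireads, d / f"{s.sample_id}.epiread.tsv")
    synth.write_fasta(sequences, outdir / "reference.fa")
    synth.write_metadata_tsv(cohort.metadata, outdir / "metadata.tsv")
    truth_dir = outdir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    for s in cohort.samples:
        synth.write_ground_truth_tsv(
            s.distributions, s.config.error_rate, truth_dir / f"{s.sample_id}.truth.tsv"
        )
    out = {s.sample_id: s.epireads for s in cohort.samples}
    out["__ref__"] = ref
    out["__metadata__"] = cohort.metadata
    return out


def _stage_load(config: RunConfig, outdir: Path) -> dict:
    ref = build_cpg_index(config.inputs["fasta"])
    if config.mode == "epiread":
        paths = config.inputs["epireads"]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        samples = {Path(p).stem.replace(".epiread", ""): read_epiread_tsv(p) for p in paths}
    else:
        paths = config.inputs["alignments"]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        samples = {Path(p).stem: extract_epireads(p, ref) for p in paths}
    meta_path = config.inputs.get("metadata")
    out: dict = dict(samples)
    out["__ref__"] = ref
    if meta_path:
        meta = clin.read_metadata_tsv(meta_path)
        # echo into the run directory so the associations stage finds it
        meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        out["__metadata__"] = meta
    else:
        out["__metadata__"] = None
    return out


def _stage_metrics(
    config: RunConfig, ref: CpGReference, samples: dict, outdir: Path
) -> pd.DataFrame:
    p = config.metrics
    step = int(p.get("step", het.N_CPGS))
    min_reads = int(p.get("min_reads", het.DEFAULT_MIN_READS))
    min_cpgs = int(p.get("min_cpgs_per_read", het.DEFAULT_MIN_CPGS_PER_READ))
    min_cov = int(p.get("pdr_min_cov", het.DEFAULT_MIN_READS_PER_CPG))
    loci = het.enumerate_loci(ref, step=step)
    mdir = outdir / "metrics"
    mdir.mkdir(exist_ok=True)
    summaries = []
    for sample_id, epireads in samples.items():
        if sample_id.startswith("__"):
            continue
        tables = het.count_epialleles(epireads, loci, min_reads=min_reads)
        lm = [het.locus_metrics(t) for t in tables]
        track = het.pdr(epireads, ref, min_cpgs_per_read=min_cpgs, min_reads_per_cpg=min_cov)
        het.write_metrics_tsv(
            het.metrics_frame(lm, ref), mdir / f"{sample_id}.locus_metrics.tsv"
        )
        summaries.append(het.summarize_sample(sample_id, lm, track))
    het.write_summary_tsv(summaries, outdir / "sample_summaries.tsv")
    df = pd.DataFrame([s.__dict__ for s in summaries]).set_index("sample_id")
    return df


def _stage_summaries(
    config: RunConfig, ref: CpGReference, samples: dict, outdir: Path
) -> None:
    p = config.summaries
    tile_width = int(p.get("tile_width", summ.DEFAULT_TILE_WIDTH))
    depth_threshold = float(p.get("depth_threshold", summ.DEFAULT_DEPTH_THRESHOLD))
    sdir = outdir / "summaries"
    sdir.mkdir(exist_ok=True)
    rows = []
    for sample_id, epireads in samples.items():
        if sample_id.startswith("__"):
            continue
        track = compute_beta_track(epireads, ref)
        write_betas_bedgraph(track, ref, sdir / f"{sample_id}.betas.bedgraph")
        tiles = summ.tile_methylation(track, ref, tile_width, depth_threshold)
        tiles.to_csv(sdir / f"{sample_id}.tiles.tsv", sep="\t", index=False, float_format="%.10g")
        cv = summ.sample_cv(tiles, sample_id)
        rows.append(
            {
                "sample_id": sample_id,
                "global_methylation": summ.global_methylation(track),
                "cv": cv.cv,
                "n_eligible_tiles": cv.n_eligible_tiles,
            }
        )
    pd.DataFrame(rows).to_csv(
        outdir / "methylome_summary.tsv", sep="\t", index=False, float_format="%.10g"
    )


def _stage_associations(config: RunConfig, per_sample: pd.DataFrame, outdir: Path) -> None:
    meta = None
    meta_path = outdir / "metadata.tsv"
    if meta_path.exists():
        meta = clin.read_metadata_tsv(meta_path)
    if meta is None or per_sample.empty:
        return
    metric = config.associations.get("metric", "mean_pdr")
    adir = outdir / "associations"
    adir.mkdir(exist_ok=True)
    merged = meta.set_index("sample_id").join(per_sample, how="inner")
    results = {}
    if "group" in merged.columns and merged["group"].nunique() == 2:
        g = sorted(merged["group"].unique())
        a = merged.loc[merged["group"] == g[0], metric]
        b = merged.loc[merged["group"] == g[1], metric]
        u, pval = clin.metric_group_test(a, b)
        results["group_test"] = {"metric": metric, "groups": g, "U": u, "p": pval}
    rule = clin.StratificationRule(metric=metric)
    try:
        low, high = clin.stratify_by_metric(merged[metric], rule)
    except clin.StratificationError as exc:
        results["survival"] = {"error": str(exc)}
    else:
        rec_low = clin.records_from_frame(merged.loc[low].reset_index(), "low")
        rec_high = clin.records_from_frame(merged.loc[high].reset_index(), "high")
        clin.write_km_tsv(clin.kaplan_meier(rec_low), adir / "km_low.tsv")
        clin.write_km_tsv(clin.kaplan_meier(rec_high), adir / "km_high.tsv")
        lr = clin.log_rank_test(rec_low, rec_high)
        results["survival"] = {
            "metric": metric,
            "n_low": len(rec_low),
            "n_high": len(rec_high),
            "log_rank_chi2": None if math.isnan(lr.statistic) else lr.statistic,
            "log_rank_p": None if math.isnan(lr.p_value) else lr.p_value,
        }
    (adir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# DMR bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DmrSummary:
    """Direction counts of a DMR call set and the hypomethylated percentage."""

    n_hyper: int
    n_hypo: int
    feature_proportions: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_hyper + self.n_hypo

    @property
    def pct_hypo(self) -> float:
        return 100.0 * self.n_hypo / self.n_total

    @property
    def pct_hyper(self) -> float:
        return 100.0 * self.n_hyper / self.n_total


def summarize_dmrs(
    regions: pd.DataFrame, annotation: pd.DataFrame | None = None
) -> DmrSummary:
    """Count hyper-/hypomethylated regions and optional feature overlap.

    ``regions`` needs a ``direction`` column over {hyper, hypo}; for feature
    proportions it also needs contig/start/end, and ``annotation`` is a
    BED-style frame whose ``name`` column is the feature class. Each region
    is assigned to a feature by midpoint overlap; the result maps
    (direction, feature) to the proportion of that direction's regions in
    the feature.
    """
    if regions.empty:
        raise ValueError("no regions to summarize")
    directions = regions["direction"]
    bad = set(directions.unique()) - {"hyper", "hypo"}
    if bad:
        raise ValueError(f"unlabeled/unknown direction value(s): {sorted(bad)}")
    n_hyper = int((directions == "hyper").sum())
    n_hypo = int((directions == "hypo").sum())
    feature_proportions: dict = {}
    if annotation is not None and not annotation.empty:
        if "name" not in annotation.columns:
            raise ValueError("annotation BED needs a name column (feature class)")
        for direction in ("hyper", "hypo"):
            sub = regions[directions == direction]
            if sub.empty:
                continue
            for feature in annotation["name"].unique():
                feat = annotation[annotation["name"] == feature]
                inside = clin.assign_loci_to_regions(sub, feat, mode="midpoint")
                feature_proportions[(direction, feature)] = float(inside.mean())
    return DmrSummary(
        n_hyper=n_hyper, n_hypo=n_hypo, feature_proportions=feature_proportions
    )


def summarize_dmr_counts(n_hyper: int, n_hypo: int) -> DmrSummary:
    """DMR bookkeeping directly from direction counts."""
    if n_hyper < 0 or n_hypo < 0 or n_hyper + n_hypo == 0:
        raise ValueError("need non-negative counts with a positive total")
    return DmrSummary(n_hyper=n_hyper, n_hypo=n_hypo)
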