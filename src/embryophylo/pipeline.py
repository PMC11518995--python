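"""End-to-end orchestration: config validation, stage sequencing, and the
output bundle (classification trail, shared set, adjusted VAFs, tree,
DP clustering, timing report, run log)."""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifyConfig, select_shared_variants
from .clonality import adjust_vaf, clonality_test
from .cohort import CohortError, CohortTable, CopyNumberProfile, SampleMeta
from .io import read_cohort, read_copy_number
from .phylo import PhyloTree, build_perfect_phylogeny, call_presence, dp_cluster_vafs, reconcile
from .quality import QualityThresholds, apply_quality_filters
from .simulate import case_study_config, simulate_cohort
from .timing import TimingCalibration, TimingReport, timing_report


class ConfigError(CohortError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Normalised pipeline configuration.

    Exactly one of ``inputs`` (paths to cohort/copy-number files) or
    ``simulate`` (synthetic-cohort parameters) must be set.
    """

    outdir: str = "embryophylo_out"
    seed: int = 0
    inputs: dict | None = None
    simulate: dict | None = None
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    dp_iterations: int = 20000
    dp_burn_in: int = 10000
    run_dp: bool = True
    calibration: TimingCalibration = field(default_factory=TimingCalibration)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of 'inputs' and 'simulate' must be configured"
            )
        if self.dp_iterations <= 0 or self.dp_burn_in < 0:
            raise ConfigError("dp iterations must be positive, burn_in >= 0")
        if self.dp_burn_in >= self.dp_iterations:
            raise ConfigError("dp burn_in must be < iterations")


_TOP_KEYS = {
    "outdir", "seed", "inputs", "simulate", "quality", "classify",
    "dp", "calibration",
}
_QUALITY_KEYS = {"clpm_max", "asmd_min", "mapq_min", "baseq_min"}
_CLASSIFY_KEYS = {
    "germline_alpha", "expected_het_vaf", "guard_band", "artifact_alpha",
    "fisher_alpha", "presence_min_alt_reads", "presence_error_rate",
    "presence_alpha",
}
_DP_KEYS = {"iterations", "burn_in", "enabled"}
_INPUT_KEYS = {"cohort_paths", "format", "samples", "copy_number"}
_SIM_KEYS = {"case_study", "seed"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _check_alpha(name: str, value: float) -> float:
    if not 0.0 < value < 1.0:
        raise ConfigError(f"{name} must lie in (0, 1), got {value}")
    return float(value)


def validate_config(source: str | os.PathLike | dict) -> RunConfig:
    """Parse and normalise a YAML config (path or pre-parsed mapping).

    Unknown keys are errors (they usually mean a typo'd threshold);
    significance levels must lie in (0, 1); defaults are filled for
    everything omitted.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    quality = raw.get("quality", {})
    _check_keys(quality, _QUALITY_KEYS, "quality")
    qt = QualityThresholds(**{k: float(v) for k, v in quality.items()})

    classify = dict(raw.get("classify", {}))
    _check_keys(classify, _CLASSIFY_KEYS, "classify")
    for k in ("germline_alpha", "artifact_alpha", "fisher_alpha", "presence_alpha"):
        if k in classify:
            classify[k] = _check_alpha(k, classify[k])
    if "guard_band" in classify:
        classify["guard_band"] = tuple(classify["guard_band"])
    cc = ClassifyConfig(**classify)

    dp = raw.get("dp", {})
    _check_keys(dp, _DP_KEYS, "dp")

    cal_raw = raw.get("calibration", {})
    _check_keys(cal_raw, {"anchors", "tissue_split_anchors"}, "calibration")
    cal_kwargs = {}
    if "anchors" in cal_raw:
        cal_kwargs["anchors"] = tuple(tuple(map(float, a)) for a in cal_raw["anchors"])
    if "tissue_split_anchors" in cal_raw:
        cal_kwargs["tissue_split_anchors"] = dict(cal_raw["tissue_split_anchors"])
    calibration = TimingCalibration(**cal_kwargs)

    inputs = raw.get("inputs")
    if inputs is not None:
        _check_keys(inputs, _INPUT_KEYS, "inputs")
    simulate = raw.get("simulate")
    if simulate is not None:
        _check_keys(simulate, _SIM_KEYS, "simulate")

    return RunConfig(
        outdir=str(raw.get("outdir", "embryophylo_out")),
        seed=int(raw.get("seed", 0)),
        inputs=inputs,
        simulate=simulate,
        quality=qt,
        classify=cc,
        dp_iterations=int(dp.get("iterations", 20000)),
        dp_burn_in=int(dp.get("burn_in", 10000)),
        run_dp=bool(dp.get("enabled", True)),
        calibration=calibration,
    )


# ----------------------------------------------------------------------
# Stage assembly
# ----------------------------------------------------------------------

@dataclass
class PipelineResult:
    table: CohortTable
    quality_report: pd.DataFrame
    shared: list
    trail: pd.DataFrame
    adjusted: pd.DataFrame
    clonality: dict
    tree: PhyloTree | None
    tree_error: str | None
    clustering: object | None
    reconciliation: pd.DataFrame | None
    timing: TimingReport
    truth: object | None = None
    outputs: dict = field(default_factory=dict)


def _load_inputs(config: RunConfig):
    inp = config.inputs
    metadata = [
        SampleMeta(
            sample_id=s["sample_id"],
            tissue_role=s["tissue_role"],
            mean_coverage=s.get("mean_coverage"),
        )
        for s in inp.get("samples", [])
    ]
    paths = inp.get("cohort_paths", [])
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    table = read_cohort(paths, inp.get("format", "tsv"), metadata)
    cn = {}
    for sid, entry in (inp.get("copy_number") or {}).items():
        cn[sid] = read_copy_number(
            entry["path"],
            purity=float(entry.get("purity", 1.0)),
            coordinates=entry.get("coordinates", "bed"),
            sample_id=sid,
        )
    return table, cn, None


def _obtain_cohort(config: RunConfig):
    if config.simulate is not None:
        params = case_study_config()
        if not config.simulate.get("case_study", True):
            raise ConfigError("only the packaged case_study simulation is configurable here; "
                              "use the library API for custom SimParams")
        if "seed" in config.simulate:
            params.seed = int(config.simulate["seed"])
        return simulate_cohort(params)
    table, cn, _ = _load_inputs(config)
    return table, cn, None


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Run all stages and (optionally) write the output bundle.

    Stage order: quality filters -> classification cascade -> clonality
    of the shared set -> presence matrix + perfect phylogeny -> DP
    clustering -> reconciliation -> timing report.  Every threshold in
    use is recorded in the run log; all randomness flows from the
    config seed.
    """
    table, cn_profiles, truth = _obtain_cohort(config)

    passed, quality_report = apply_quality_filters(table, config.quality)
    shared, trail = select_shared_variants(passed, config.classify)

    tumours = passed.samples_with_role("tumour")
    site_idx = passed.site_index()

    # adjusted VAFs + clonality for the shared set
    adj_rows = []
    clonality = {}
    for v in shared:
        i = site_idx[v.key]
        obs = []
        for t in tumours:
            j = passed.sample_index(t)
            prof = cn_profiles.get(t, CopyNumberProfile(sample_id=t))
            cn = prof.cn_at(v.chrom, v.pos)
            a = adjust_vaf(int(passed.alt[i, j]), int(passed.depth[i, j]),
                           cn, purity=prof.purity)
            adj_rows.append(
                {"site": v.label(), "sample": t, "raw_vaf": a.raw_vaf,
                 "adjusted_vaf": a.adjusted_vaf, "total_cn": a.total_cn,
                 "multiplicity": a.multiplicity, "purity": a.purity,
                 "flag": a.flag}
            )
            obs.append((int(passed.alt[i, j]), int(passed.depth[i, j]),
                        a.expected_clonal_vaf))
        clonality[v.label()] = clonality_test(obs)
    adjusted = pd.DataFrame(
        adj_rows, columns=["site", "sample", "raw_vaf", "adjusted_vaf",
                           "total_cn", "multiplicity", "purity", "flag"]
    )

    # somatic, non-artifact, enriched variants feed both phylogeny routes
    somatic_mask = (
        (trail["germline_label"] == "somatic_candidate")
        & trail["artifact_real_any_tumour"]
        & trail["tumour_enriched"]
    ).to_numpy()
    somatic = passed.subset_sites(somatic_mask)

    tree, tree_error = None, None
    pm = call_presence(
        somatic.subset_samples(tumours),
        min_alt_reads=config.classify.presence_min_alt_reads,
        error_rate=config.classify.presence_error_rate,
        alpha=config.classify.presence_alpha,
    )
    try:
        tree = build_perfect_phylogeny(pm)
    except CohortError as exc:
        tree_error = str(exc)

    clustering, reconciliation = None, None
    if config.run_dp and somatic.n_sites:
        snv_mask = np.array([s.is_snv for s in somatic.sites])
        dp_table = somatic.subset_sites(snv_mask).subset_samples(tumours)
        covered = (dp_table.depth > 0).all(axis=1)
        dp_table = dp_table.subset_sites(covered)
        if dp_table.n_sites:
            clustering = dp_cluster_vafs(
                dp_table,
                iterations=config.dp_iterations,
                burn_in=config.dp_burn_in,
                seed=config.seed + 101,
            )
            if tree is not None:
                reconciliation = reconcile(tree, clustering)

    timing = timing_report(
        shared,
        passed,
        calibration=config.calibration,
        min_alt_reads=config.classify.presence_min_alt_reads,
        error_rate=config.classify.presence_error_rate,
        alpha=config.classify.presence_alpha,
    )

    result = PipelineResult(
        table=table,
        quality_report=quality_report,
        shared=shared,
        trail=trail,
        adjusted=adjusted,
        clonality=clonality,
        tree=tree,
        tree_error=tree_error,
        clustering=clustering,
        reconciliation=reconciliation,
        timing=timing,
        truth=truth,
    )
    if write:
        _write_bundle(config, result)
    return result


def _write_bundle(config: RunConfig, result: PipelineResult) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    result.quality_report.to_csv(out / "quality_report.tsv", sep="\t", index=False)
    result.trail.to_csv(out / "classification_trail.tsv", sep="\t", index=False)
    shared_df = pd.DataFrame(
        {
            "site": [v.label() for v in result.shared],
            "variant_class": [v.variant_class for v in result.shared],
            "clonality": [result.clonality[v.label()] for v in result.shared],
        }
    )
    shared_df.to_csv(out / "shared_variants.tsv", sep="\t", index=False)
    result.adjusted.to_csv(out / "adjusted_vaf.tsv", sep="\t", index=False)
    if result.tree is not None:
        (out / "phylogeny.nwk").write_text(result.tree.to_newick() + "\n")
    if result.clustering is not None:
        result.clustering.to_frame().to_csv(out / "dp_clusters.tsv", sep="\t", index=False)
    if result.reconciliation is not None:
        result.reconciliation.to_csv(out / "reconciliation.tsv", sep="\t", index=False)
    (out / "timing_report.json").write_text(result.timing.to_json() + "\n")
    result.timing.ordering.to_csv(out / "detectability.tsv", sep="\t", index=False)
    if result.truth is not None:
        truth = result.truth
        summary = {
            "trunk_size": len(truth.shared_truth),
            "trunk_sites": [v.label() for v in truth.shared_truth],
            "mrca_division": truth.mrca_division,
            "mrca_week": truth.mrca_week,
            "detectability": {
                "|".join(map(str, k)): v
                for k, v in truth.truth_detectability().items()
            },
        }
        (out / "truth.json").write_text(json.dumps(summary, indent=2) + "\n")

    log = {
        "version": __version__,
        "seed": config.seed,
        "quality": asdict(config.quality),
        "classify": {
            **{k: v for k, v in asdict(config.classify).items()},
        },
        "dp": {
            "iterations": config.dp_iterations,
            "burn_in": config.dp_burn_in,
            "enabled": config.run_dp,
        },
        "calibration": {
            "anchors": [list(a) for a in config.calibration.anchors],
            "tissue_split_anchors": config.calibration.tissue_split_anchors,
        },
        "tree_error": result.tree_error,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    result.outputs = {p.name: str(p) for p in sorted(out.iterdir())}
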