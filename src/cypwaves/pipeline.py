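"""One-shot pipeline: simulate -> normalize -> DE -> cluster -> report.

A run is fully described by a :class:`RunConfig` (typically a YAML file);
every tunable constant is echoed into the run manifest together with SHA-256
hashes of all outputs, so a run can be reproduced and verified byte for
byte from its manifest and seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import kmeans_clusters, timepoint_means, z_normalize
from .preprocess import preprocess_pipeline
from .simulate import ArrayDesign, generate_timecourse, write_intensity_table
from .temporal_de import anova_pvalue, betr_probability, call_significant, log_median_center, summary_counts


class PipelineConfigError(ValueError):
    """Raised when a run configuration is missing or inconsistent."""


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    seed: int
    outdir: str = "cypwaves_run"
    n_probes: int = 2000
    timepoints_hpf: tuple[float, ...] = (3.0, 6.0, 12.0, 24.0, 36.0, 48.0)
    replicates: tuple[str, ...] = ("A", "B", "C", "D")
    spots_per_probe: int = 2
    archetype_mix: dict = field(
        default_factory=lambda: {
            "maternal_decay": 0.15,
            "unimodal_wave": 0.25,
            "bimodal": 0.05,
            "flat": 0.50,
            "below_background": 0.05,
        }
    )
    sigma_rep: float = 0.25
    sigma_spot: float = 0.10
    floor: float = 5.0
    threshold_fraction: float = 0.02
    max_iter: int = 30
    window: int | None = None
    alpha: float = 0.01
    k: int = 10
    affinity: float = 0.7

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise PipelineConfigError("missing required configuration key: 'seed'")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("timepoints_hpf", "replicates"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    Stage order mirrors the analysis chain: simulate raw intensities, floor,
    normalize to the baseline array, average duplicate spots, QC-filter,
    call temporal DE, cluster z-normalized gene profiles.  Re-running with
    the same config and seed reproduces every output byte-identically.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        design = ArrayDesign(
            timepoints_hpf=config.timepoints_hpf,
            replicates=config.replicates,
            spots_per_probe=config.spots_per_probe,
            n_probes=config.n_probes,
        )
        table, truth = generate_timecourse(
            design=design,
            archetype_mix=config.archetype_mix,
            noise=(config.sigma_rep, config.sigma_spot),
            seed=config.seed,
        )
        raw_path = outdir / "raw.tsv"
        write_intensity_table(table, raw_path)
        truth_path = outdir / "truth.tsv"
        truth.probes.to_csv(truth_path, sep="\t", index=False)

        stage = "normalize"
        matrix, qc_report, model = preprocess_pipeline(
            table,
            floor=config.floor,
            threshold_fraction=config.threshold_fraction,
            max_iter=config.max_iter,
            window=config.window,
        )
        norm_path = outdir / "norm.tsv"
        matrix.values.to_csv(norm_path, sep="\t")
        qc_path = outdir / "qc.json"
        qc_report.to_json(qc_path)

        stage = "differential_expression"
        tc = log_median_center(matrix.values)
        posterior = betr_probability(tc)
        anova_p = anova_pvalue(tc)
        result = call_significant(posterior, anova_p, alpha=config.alpha)
        de_path = outdir / "de.tsv"
        result.frame.rename_axis("probe_id").to_csv(de_path, sep="\t")

        stage = "clustering"
        profiles = z_normalize(timepoint_means(matrix.values))
        clusters = kmeans_clusters(profiles, k=min(config.k, len(profiles.data)), seed=config.seed)
        cl_path = outdir / "clusters.tsv"
        clusters.assignment.rename_axis("probe_id").to_csv(cl_path, sep="\t")
        profile_path = outdir / "cluster_profiles.tsv"
        clusters.cluster_profiles.rename_axis("cluster").to_csv(profile_path, sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs = {
        p.name: _sha256(p)
        for p in [raw_path, truth_path, norm_path, qc_path, de_path, cl_path, profile_path]
    }
    manifest = {
        "package_version": __version__,
        "parameters": asdict(config),
        "baseline_array": model.baseline_array_id,
        "qc": qc_report.to_dict(),
        "de_summary": summary_counts(result),
        "n_clusters": int(clusters.n_clusters),
        "outputs": outputs,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
    return manifest


def _jsonable(obj):
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, (pd.Series, pd.Index)):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
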