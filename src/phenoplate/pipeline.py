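"""End-to-end pipeline: read (or simulate) → baseline → smooth →
aggregate replicates → score %RSI → rank/classify → log-ratio matrix →
cluster → export tables, CDT/GTR and Newick, with a run manifest.

Every output is plain text with deterministic ordering, so a rerun with
the same configuration and seed is byte-identical — the manifest
records counts and warnings but deliberately no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .kinetics import (
    DEFAULT_W_MAX,
    aggregate_replicates,
    baseline_transform,
    smooth_monotone,
)
from .plate_io import (
    ConditionSpec,
    KineticSeries,
    read_conditions,
    read_kinetics,
    read_strains,
    write_conditions,
    write_kinetics,
    write_matrix,
    write_strains,
    write_tolerance_table,
)
from .clustering import (
    centred_pearson_distance,
    leaf_order,
    upgma,
    write_cdt_gtr,
    write_newick,
)
from .scoring import (
    DEFAULT_CLIP,
    DEFAULT_EPS,
    DEFAULT_REFERENCE,
    RankTable,
    classify_extremes,
    log_ratio_matrix,
    rank_strains,
    score_study,
)
from .synthetic import SyntheticStudySpec, simulate_study, strain_records

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be set: the three table paths, or a
    synthetic study spec.
    """

    kinetics_path: str | None = None
    conditions_path: str | None = None
    strains_path: str | None = None
    synthetic: SyntheticStudySpec | None = None
    reference_id: str = DEFAULT_REFERENCE
    w_max: int = DEFAULT_W_MAX
    eps: float = DEFAULT_EPS
    clip: float = DEFAULT_CLIP
    k_sensitive: int = 5
    k_tolerant: int = 10
    outdir: str = "phenoplate_out"
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.kinetics_path is not None and self.conditions_path is not None
        if has_paths == (self.synthetic is not None):
            raise ValidationError(
                "PipelineConfig: exactly one of (input paths, synthetic spec) required"
            )
        if self.w_max % 2 == 0 or self.w_max < 1:
            raise ValidationError("PipelineConfig: w_max must be odd and >= 1")
        if not (0 < self.clip):
            raise ValidationError("PipelineConfig: clip must be positive")
        if self.eps < 0:
            raise ValidationError("PipelineConfig: eps must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw, synthetic=None if syn is None else SyntheticStudySpec(**syn))
        return cfg


@dataclass
class PipelineResult:
    """In-memory handles plus paths of everything a run wrote."""

    scores: list
    rank_tables: dict[str, RankTable]
    matrix: object
    dendrogram: object
    outputs: dict[str, str]
    manifest: dict


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        curves, truth = simulate_study(spec)
        return curves, spec.conditions, strain_records(spec), truth
    curves = read_kinetics(config.kinetics_path)
    conditions = read_conditions(config.conditions_path)
    strains = read_strains(config.strains_path) if config.strains_path else []
    return curves, conditions, strains, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the result bundle to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves, conditions, strains, truth = _load_inputs(config)

    # transform and smooth every replicate curve
    smoothed = [smooth_monotone(baseline_transform(c), config.w_max) for c in curves]
    cap_hits = sum(1 for s in smoothed if s.residual_negative_slopes > 0)

    # replicate means
    groups: dict[tuple[str, str], list] = {}
    for s in smoothed:
        groups.setdefault((s.strain_id, s.condition_id), []).append(s)
    mean_curves = {key: aggregate_replicates(g) for key, g in sorted(groups.items())}

    scores = score_study(mean_curves, conditions, eps=config.eps)
    n_low_control = sum(1 for s in scores if s.low_control)

    outputs: dict[str, str] = {}
    tol_path = outdir / "tolerance_scores.tsv"
    write_tolerance_table(scores, tol_path)
    outputs["tolerance_scores"] = str(tol_path)

    rank_tables: dict[str, RankTable] = {}
    stress_conditions = [c for c in conditions if not c.is_control]
    for cond in stress_conditions:
        cond_scores = [s for s in scores if s.condition_id == cond.condition_id]
        if not cond_scores:
            continue
        table = rank_strains(cond_scores)
        n = len(table.entries)
        ks = min(config.k_sensitive, n)
        kt = min(config.k_tolerant, max(0, n - ks))
        classify_extremes(table, k_sensitive=ks, k_tolerant=kt)
        rank_tables[cond.condition_id] = table
        rpath = outdir / f"rank_{cond.condition_id}.tsv"
        _write_rank_table(table, rpath)
        outputs[f"rank_{cond.condition_id}"] = str(rpath)

    matrix = log_ratio_matrix(scores, reference_id=config.reference_id, clip=config.clip)
    mat_path = outdir / "log_ratio_matrix.tsv"
    write_matrix(matrix.values, mat_path)
    outputs["log_ratio_matrix"] = str(mat_path)

    dist = centred_pearson_distance(matrix)
    dend = upgma(dist)
    cdt_path, gtr_path = write_cdt_gtr(dend, matrix, outdir / "clustered")
    outputs["cdt"] = str(cdt_path)
    outputs["gtr"] = str(gtr_path)
    nwk_path = write_newick(dend, outdir / "dendrogram.nwk")
    outputs["newick"] = str(nwk_path)

    manifest = {
        "phenoplate_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "counts": {
            "input_series": len(curves),
            "strains": len({c.strain_id for c in curves}),
            "conditions": len(conditions),
            "stress_conditions": len(stress_conditions),
            "mean_curves": len(mean_curves),
            "scores": len(scores),
            "smoothing_cap_hits": cap_hits,
            "low_control_scores": n_low_control,
            "leaves": dend.n_leaves,
        },
        "leaf_order": leaf_order(dend),
        "outputs": {k: Path(v).name for k, v in outputs.items()},
    }
    man_path = outdir / "run_manifest.json"
    with open(man_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["manifest"] = str(man_path)

    return PipelineResult(
        scores=scores,
        rank_tables=rank_tables,
        matrix=matrix,
        dendrogram=dend,
        outputs=outputs,
        manifest=manifest,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir")  # a location, not part of the analysis; keeps reruns byte-identical
    syn = d.get("synthetic")
    if syn is not None:
        syn["conditions"] = [c["condition_id"] for c in syn["conditions"]]
    return d


def _write_rank_table(table: RankTable, path: Path) -> None:
    labels = table.labels or [""] * len(table.entries)
    rows = [
        (
            pos + 1,
            strain,
            f"{pct:.6g}",
            labels[pos],
            int(strain in table.low_control),
        )
        for pos, (strain, pct) in enumerate(table.entries)
    ]
    pd.DataFrame(
        rows, columns=["rank", "strain_id", "percent_rsi", "class", "low_control_flag"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def demo_config(outdir: str, seed: int = 0) -> PipelineConfig:
    """A bundled synthetic study at full screening scale (90 strains,
    1 control + 9 stresses, 3 replicates)."""
    return PipelineConfig(synthetic=SyntheticStudySpec(seed=seed), outdir=outdir, seed=seed)


def write_synthetic_inputs(spec: SyntheticStudySpec, outdir: str | Path) -> dict[str, str]:
    """Materialise a synthetic study as input tables for the file-based pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves, truth = simulate_study(spec)
    kin = outdir / "kinetics.tsv"
    con = outdir / "conditions.tsv"
    str_ = outdir / "strains.tsv"
    write_kinetics(curves, kin)
    write_conditions(spec.conditions, con)
    write_strains(strain_records(spec), str_)
    truth.theta.to_csv(outdir / "truth_theta.tsv", sep="\t")
    truth.delta.to_csv(outdir / "truth_delta.tsv", sep="\t")
    return {"kinetics": str(kin), "conditions": str(con), "strains": str(str_)}
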