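"""End-to-end orchestration: align -> select -> flexfit -> evaluate.

The AI-prediction stage is an input boundary: the pipeline consumes
candidate model files from any source, rigid-fits each into the map,
ranks them by ligand model-to-map CC, flexibly refines the best candidate
and (when a ground-truth structure is supplied) reports per-entity
accuracies.  Every stage is deterministic given the configured seed, and
a manifest records the configuration, seeds and checksums of all outputs
so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .densmap import MapSimParams
from .evaluate import (AccuracyReport, CandidateSet, RankResult, build_report,
                       rank_candidates)
from .flexfit import FitConfig, PreRelax, AdaptiveScaling, run_flexfit
from .structio import (Structure, protein_selection, read_map, read_structure,
                       select_ligand, select_pocket, write_multi_model_pdb,
                       write_structure)

logger = logging.getLogger("emligfit")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (mirrors the YAML file layout)."""

    candidate_paths: list[str]
    map_path: str
    output_dir: str
    ground_truth_path: Optional[str] = None
    resolution: float = 3.2
    ligand_name: str = "auto"
    pocket_cutoff: float = 4.0
    rigid_restarts: int = 1
    reducer: str = "final"
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if self.reducer not in {"final", "last20"}:
            raise ValueError("reducer must be 'final' or 'last20'")
        if isinstance(self.fit, dict):
            fit_doc = dict(self.fit)
            adaptive = AdaptiveScaling(**(fit_doc.pop("adaptive", {}) or {}))
            pre_relax = PreRelax(**(fit_doc.pop("pre_relax", {}) or {}))
            self.fit = FitConfig(adaptive=adaptive, pre_relax=pre_relax,
                                 **fit_doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)

    def validate_paths(self) -> None:
        missing = [p for p in ([self.map_path] + list(self.candidate_paths)
                               + ([self.ground_truth_path]
                                  if self.ground_truth_path else []))
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if not self.candidate_paths:
            raise ValueError("need at least one candidate model")


@dataclass
class RunManifest:
    """Reproducibility record of a pipeline run (no volatile fields)."""

    config: dict
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256

    def record_stage(self, name: str, status: str, **info) -> None:
        self.stages.append({"stage": name, "status": status, **info})

    def add_output(self, path: Path, base: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[str(path.relative_to(base))] = digest

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "version": self.version,
             "stages": self.stages, "outputs": self.outputs}, indent=1,
            default=str))

    def verify(self, base: str | Path) -> bool:
        base = Path(base)
        for rel, digest in self.outputs.items():
            p = base / rel
            if not p.exists() or \
                    hashlib.sha256(p.read_bytes()).hexdigest() != digest:
                return False
        return True


def _ground_truth_ccs(gt: Structure, target_map, params: MapSimParams,
                      ligand_name: str, pocket_cutoff: float) -> dict[str, float]:
    from .densmap import entity_ccs
    lig = select_ligand(gt, ligand_name)
    pocket = select_pocket(gt, lig, cutoff=pocket_cutoff)
    prot = protein_selection(gt)
    sels = {"ligand": lig, "protein": prot}
    if len(pocket):
        sels["pocket"] = pocket
    ccs = entity_ccs(gt, sels, target_map, params)
    return {k: v.cc for k, v in ccs.items()}


def run_pipeline(config: PipelineConfig
                 ) -> tuple[RunManifest, Optional[AccuracyReport]]:
    """Execute all stages; persist intermediates; return manifest + report.

    On stage failure the manifest (with the failed stage recorded) and any
    partial outputs are written before the exception propagates.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           version=__version__)
    runtime_log = out / "runtime.log"
    t_start = time.time()
    report: Optional[AccuracyReport] = None

    def note(msg: str) -> None:
        logger.info(msg)
        with open(runtime_log, "a") as fh:
            fh.write(f"[{time.time() - t_start:9.2f}s] {msg}\n")

    stage = "load"
    try:
        note(f"loading map {config.map_path} and "
             f"{len(config.candidate_paths)} candidates")
        target_map = read_map(config.map_path)
        target_map.nominal_resolution = config.resolution
        params = MapSimParams(resolution=config.resolution,
                              grid_spec=target_map)
        models = [read_structure(p) for p in config.candidate_paths]
        ids = [Path(p).stem for p in config.candidate_paths]
        candidates = CandidateSet(ids=ids, models=models,
                                  source_note="pipeline inputs")
        ground_truth = read_structure(config.ground_truth_path) \
            if config.ground_truth_path else None
        manifest.record_stage(stage, "ok", n_candidates=len(models))

        stage = "rank"
        note("rigid-fitting and ranking candidates by ligand CC")
        rank: RankResult = rank_candidates(
            candidates, target_map, params, ligand_name=config.ligand_name,
            pocket_cutoff=config.pocket_cutoff,
            n_restarts=config.rigid_restarts, seed=config.seed)
        rank.table.to_csv(out / "ranking.csv", index=False)
        for cid, model in rank.fitted_models.items():
            write_structure(model, out / f"aligned_{cid}.pdb")
        best = rank.fitted_models[rank.best_id]
        manifest.record_stage(stage, "ok", best_id=rank.best_id)
        note(f"best candidate: {rank.best_id}")

        stage = "flexfit"
        fit_cfg = config.fit
        fit_cfg.ligand_name = config.ligand_name
        fit_cfg.pocket_cutoff = config.pocket_cutoff
        fit_cfg.seed = config.seed
        note(f"flexible fitting for {fit_cfg.duration_ps} ps "
             f"(k = {fit_cfg.force_constant_k} kJ/mol)")
        trajectory, trace = run_flexfit(best, target_map, fit_cfg, params)
        trace.to_csv(out / "trace.csv")
        write_multi_model_pdb(trajectory.frames, out / "trajectory.pdb")
        write_structure(trajectory.frames[-1], out / "fitted_final.pdb")
        manifest.record_stage(stage, "ok", n_frames=len(trajectory.frames),
                              events=[e[1] for e in trace.events])

        stage = "evaluate"
        gt_ccs = None
        if ground_truth is not None:
            gt_ccs = _ground_truth_ccs(ground_truth, target_map, params,
                                       config.ligand_name,
                                       config.pocket_cutoff)
        report = build_report(best, trajectory, trace, gt_ccs, target_map,
                              params, ligand_name=config.ligand_name,
                              pocket_cutoff=config.pocket_cutoff,
                              reducer=config.reducer)
        report.to_json(out / "report.json")
        report.to_csv(out / "report.csv")
        manifest.record_stage(stage, "ok")
        note("evaluation complete")
    except Exception as exc:
        manifest.record_stage(stage, "failed", error=str(exc))
        for p in sorted(out.rglob("*")):
            if p.is_file() and p != runtime_log and p.name != "manifest.json":
                manifest.add_output(p, out)
        manifest.to_json(out / "manifest.json")
        raise

    for p in sorted(out.rglob("*")):
        if p.is_file() and p != runtime_log and p.name != "manifest.json":
            manifest.add_output(p, out)
    manifest.to_json(out / "manifest.json")
    note("pipeline finished")
    return manifest, report
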