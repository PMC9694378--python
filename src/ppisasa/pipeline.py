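"""End-to-end orchestration: poses -> descriptors -> consensus -> screening
metrics -> ML, driven by a single YAML-able config with recorded seeds.

Every stage writes plain CSV/JSON so any stage can be replaced by external
files (e.g. real rescoring tables).  A run manifest captures the config
hash and per-file checksums; deterministic stages are byte-identical across
reruns of the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .descriptors import descriptor_table, pose_descriptors
from .fixtures import (
    PocketFixtureSpec,
    SyntheticTableSpec,
    fixture_categories,
    make_descriptor_table,
    make_pocket_complex,
    make_score_table,
)
from .metrics import screen_report
from .ml import ModelSpec, SplitSpec, cross_validate, evaluate_model, fit_model, predict_and_enrich, stratified_split
from .rescoring import HIGHER, ScoreTable, best_pose_per_compound, consensus_table
from .structio import assemble_complex, assign_vdw_radii, extract_binding_site, read_ligand_poses, read_receptor

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "out"
    seed: int = 0
    # real inputs (all optional; fixture specs used when absent)
    receptor: str | None = None
    poses: str | None = None
    score_field: str | None = None
    scores: str | None = None  # CSV: compound_id, pose_id, K score columns
    labels: str | None = None  # CSV: compound_id, label
    # synthetic inputs
    fixture_pockets: list[dict] = field(default_factory=list)
    fixture_table: dict | None = None
    fixture_scores: dict | None = None
    # stage parameters
    probe: float = 1.4
    n_points: int = 960
    site_cutoff: float = 5.0
    orientations: dict[str, str] = field(default_factory=dict)
    best_pose_by: str | None = None
    fractions: tuple[float, ...] = (0.01, 0.05)
    alpha: float = 20.0
    train_fraction: float = 0.7
    cv_folds: int = 10
    families: list[str] = field(default_factory=lambda: ["random_forest"])
    hyperparameters: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.fractions, list):
            cfg.fractions = tuple(cfg.fractions)
        return cfg

    def to_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            out[name] = list(value) if isinstance(value, tuple) else value
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage_descriptors(config: PipelineConfig, outdir: Path) -> pd.DataFrame | None:
    vectors = []
    if config.receptor and config.poses:
        receptor = assign_vdw_radii(read_receptor(config.receptor))
        poses = read_ligand_poses(config.poses, score_field=config.score_field)
        for pose in poses:
            assign_vdw_radii(pose)
            site = extract_binding_site(receptor, pose, cutoff=config.site_cutoff)
            complex_ = assemble_complex(site, pose, cutoff_used=config.site_cutoff)
            vectors.append(
                pose_descriptors(complex_, probe=config.probe, n_points=config.n_points)
            )
    elif config.fixture_pockets:
        for i, raw in enumerate(config.fixture_pockets):
            spec = PocketFixtureSpec(**{"seed": config.seed + i, **raw})
            complex_ = make_pocket_complex(spec)
            rec_cats, lig_cats = fixture_categories(complex_, seed=spec.seed)
            vectors.append(
                pose_descriptors(
                    complex_,
                    probe=config.probe,
                    n_points=config.n_points,
                    receptor_categories=rec_cats,
                    ligand_categories=lig_cats,
                )
            )
    elif config.fixture_table is not None:
        table = make_descriptor_table(
            SyntheticTableSpec(**{"seed": config.seed, **config.fixture_table})
        )
        table.to_csv(outdir / "descriptors.csv", index=False)
        return table
    else:
        return None
    labels = _load_labels(config)
    table = descriptor_table(vectors, labels=labels)
    table.to_csv(outdir / "descriptors.csv", index=False)
    return table


def _load_labels(config: PipelineConfig) -> dict[str, int] | None:
    if not config.labels:
        return None
    frame = pd.read_csv(config.labels)
    return dict(zip(frame["compound_id"].astype(str), frame["label"].astype(int)))


def _stage_consensus(config: PipelineConfig, outdir: Path) -> pd.DataFrame | None:
    if config.scores:
        frame = pd.read_csv(config.scores)
        orientations = config.orientations or {
            c: HIGHER for c in frame.columns if c not in ("compound_id", "pose_id", "label")
        }
        table = ScoreTable(frame=frame, orientations=orientations)
    elif config.fixture_scores is not None:
        table, _ = make_score_table(**{"seed": config.seed, **config.fixture_scores})
    else:
        return None
    if config.best_pose_by:
        table = best_pose_per_compound(table, config.best_pose_by)
    result = consensus_table(table)
    result.ordering.to_csv(outdir / "consensus.csv", index=False)
    return result.ordering


def _stage_screen_metrics(
    config: PipelineConfig, consensus: pd.DataFrame | None, outdir: Path
) -> pd.DataFrame | None:
    if consensus is None or "label" not in consensus.columns:
        return None
    labeled = consensus.dropna(subset=["label"])
    # consensus rank: low = good; negate so higher = better for the metrics
    report = screen_report(
        labeled["label"].astype(int).to_numpy(),
        pd.DataFrame({"consensus": -labeled["consensus_rank"].to_numpy()}),
        fractions=config.fractions,
        alpha=config.alpha,
        ids=labeled["compound_id"].to_numpy() if "compound_id" in labeled else None,
    )
    report.to_csv(outdir / "screen_metrics.csv", index=False)
    return report


def _stage_ml(
    config: PipelineConfig, descriptors: pd.DataFrame | None, outdir: Path
) -> dict | None:
    if descriptors is None or "label" not in descriptors.columns:
        return None
    labeled = descriptors.dropna(subset=["label"])
    if labeled.empty or labeled["label"].nunique() < 2:
        warnings.warn("ML stage skipped: need labeled rows of both classes")
        return None
    split = SplitSpec(train_fraction=config.train_fraction, seed=config.seed)
    train, test = stratified_split(labeled, split)
    report: dict = {"split": {"n_train": len(train), "n_test": len(test)}, "families": {}}
    for family in config.families:
        spec = ModelSpec(
            family=family,
            hyperparameters=config.hyperparameters.get(family, {}),
            seed=config.seed,
        )
        model = fit_model(spec, train)
        test_eval = evaluate_model(model, test)
        enrich = predict_and_enrich(model, test, fractions=config.fractions, alpha=config.alpha)
        cv = cross_validate(spec, train, k=min(config.cv_folds, int(train["label"].sum())))
        report["families"][family] = {
            "test": test_eval,
            "test_ef": {str(f): enrich.ef[f] for f in config.fractions},
            "test_bedroc": enrich.bedroc,
            "cv": cv["summary"],
        }
    (outdir / "ml_report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages_run: list[str] = []

    def run_stage(name: str, fn, *args):
        try:
            result = fn(config, *args)
        except Exception as exc:
            raise StageError(name, exc) from exc
        if result is not None:
            stages_run.append(name)
        else:
            logger.warning("stage %s skipped (inputs unavailable)", name)
        return result

    descriptors = run_stage("descriptors", _stage_descriptors, outdir)
    consensus = run_stage("consensus", _stage_consensus, outdir)
    run_stage("screen_metrics", _stage_screen_metrics, consensus, outdir)
    run_stage("ml", _stage_ml, descriptors, outdir)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages_run": stages_run,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.suffix in (".csv", ".json") and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
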