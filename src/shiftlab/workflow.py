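"""End-to-end experiment orchestration.

An experiment mirrors the virtual-staining evaluation loop: generate (or
load) a cohort of paired tiles, train one translator per training-set
composition, run inference on samples held out of that composition, score
score each tile with SSIM and Pearson r, and — on subsets held out by every
model —
run the paired statistics battery. A single global seed fans out
deterministically to per-stage seeds so any stage can be reproduced in
isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import DegenerateImageError, InvalidSpecError
from . import evaluation, synthetic_data, translation


@dataclass
class ExperimentConfig:
    cohort: synthetic_data.CohortSpec
    compositions: Dict[str, List[str]]          # model_id -> training sample ids
    translator: translation.TranslatorConfig = field(
        default_factory=lambda: translation.desk_config())
    ssim_params: evaluation.SsimParams = field(default_factory=evaluation.SsimParams)
    alpha: float = 0.05
    seed: int = 0

    def validate(self):
        self.cohort.validate()
        sample_ids = {s.sample_id for s in self.cohort.samples}
        if not self.compositions:
            raise InvalidSpecError("no training-set compositions given")
        for mid, comp in self.compositions.items():
            if not comp:
                raise InvalidSpecError(f"composition {mid!r} is empty")
            unknown = set(comp) - sample_ids
            if unknown:
                raise InvalidSpecError(f"composition {mid!r}: unknown samples {sorted(unknown)}")
            if set(comp) == sample_ids:
                raise InvalidSpecError(
                    f"composition {mid!r} covers all samples; nothing is held out")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived by hashing the stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % 2**31


def run_experiment(config: ExperimentConfig, out_dir: Optional[Path] = None) -> dict:
    """Train/evaluate every composition; returns {'scores': DataFrame,
    'report': dict, 'models': {model_id: Translator}}."""
    config.validate()
    cohort_seed = stage_seed(config.seed, "cohort")
    cohort_spec = config.cohort
    cohort_spec.seed = cohort_seed
    cohort = dict(synthetic_data.generate_cohort(cohort_spec))

    models: Dict[str, translation.Translator] = {}
    rows = []
    for mid, comp in config.compositions.items():
        train_pairs = []
        for sid in comp:
            train_pairs.extend((p.he, p.if_chan) for p in cohort[sid])
        cfg = translation.TranslatorConfig(**{**asdict(config.translator),
                                              "seed": stage_seed(config.seed, f"train:{mid}")})
        model = translation.train_translator(train_pairs, cfg)
        models[mid] = model
        held_out = [sid for sid in cohort if sid not in comp]
        for sid in held_out:
            for p in cohort[sid]:
                pred = translation.translate_tile(model, p.he)
                s = evaluation.ssim(pred, p.if_chan, config.ssim_params)
                try:
                    r = evaluation.pearson(pred, p.if_chan)
                except DegenerateImageError:
                    r = np.nan
                rows.append({"tile_id": f"{sid}:{p.col}", "sample_subset_id": sid,
                             "model_id": mid, "ssim": s, "pearson_r": r})
    scores = pd.DataFrame(rows)

    # statistics battery on subsets held out by every model
    common = [sid for sid in cohort
              if all(sid not in comp for comp in config.compositions.values())]
    report = None
    if len(config.compositions) >= 2 and common:
        subset_scores = scores[scores.sample_subset_id.isin(common)]
        report = evaluation.compare_models(subset_scores, metric="ssim",
                                           alpha=config.alpha)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(yaml.safe_dump(_config_dict(config)))
        scores.to_csv(out / "scores.csv", index=False)
        if report is not None:
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))

    return {"scores": scores, "report": report, "models": models,
            "held_out_common": common}


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=str))


def validate_manifest(path) -> List[dict]:
    """Check a tile manifest CSV; returns a machine-readable issue list.

    Expected columns: sample_id, row, col, he_path, if_path. Checks file
    existence, tile-size consistency, and duplicate grid cells.
    """
    path = Path(path)
    if not path.is_file():
        raise InvalidSpecError(f"manifest {path} is not a readable file")
    df = pd.read_csv(path)
    issues: List[dict] = []
    required = {"sample_id", "row", "col", "he_path", "if_path"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        return [{"kind": "missing_columns", "detail": sorted(missing_cols)}]
    import tifffile
    from imageio.v3 import imread as _imread

    seen = set()
    sizes = set()
    for _, rec in df.iterrows():
        key = (rec.sample_id, int(rec.row), int(rec.col))
        if key in seen:
            issues.append({"kind": "duplicate_grid_cell", "sample_id": rec.sample_id,
                           "row": int(rec.row), "col": int(rec.col)})
        seen.add(key)
        for col in ("he_path", "if_path"):
            p = Path(rec[col])
            if not p.is_absolute():
                p = path.parent / p
            if not p.is_file():
                issues.append({"kind": "missing_file", "path": str(rec[col])})
                continue
            try:
                img = tifffile.imread(p) if p.suffix in (".tif", ".tiff") else _imread(p)
                sizes.add(img.shape[:2])
            except Exception as e:  # noqa: BLE001 - report, don't crash
                issues.append({"kind": "unreadable_file", "path": str(rec[col]),
                               "detail": str(e)})
    if len(sizes) > 1:
        issues.append({"kind": "inconsistent_tile_size", "detail": sorted(map(str, sizes))})
    return issues
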