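"""Stage orchestration: prepare -> train -> segment -> evaluate.

Each stage writes its artifacts plus a ``manifest.json`` carrying the config
hash that produced them; re-running a completed stage with an unchanged
config is a no-op.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import PipelineConfig, config_hash
from .errors import RenalsegError
from .metrics import evaluate
from .nn.model import load_checkpoint, save_checkpoint
from .phantoms import generate_phantom_volume, write_case_dir
from .preprocess import PreprocessStats, SliceSample, slice_volume
from .training import CascadeModel, train_cascade

__all__ = ["run_pipeline", "MODES"]

MODES = ("prepare", "train", "segment", "evaluate", "all")


def _manifest_path(stage_dir: Path) -> Path:
    return stage_dir / "manifest.json"


def _stage_done(stage_dir: Path, digest: str) -> bool:
    mf = _manifest_path(stage_dir)
    if not mf.exists():
        return False
    try:
        return json.loads(mf.read_text()).get("config_hash") == digest
    except (json.JSONDecodeError, OSError):
        return False


def _write_manifest(stage_dir: Path, digest: str, **extra):
    payload = {"config_hash": digest, **extra}
    _manifest_path(stage_dir).write_text(json.dumps(payload, indent=2))


def _load_slices(path: Path) -> list[SliceSample]:
    with np.load(path) as data:
        n = int(data["n"])
        return [
            SliceSample(image=data[f"image_{i}"], label=data[f"label_{i}"],
                        case_id=str(data[f"case_{i}"]),
                        slice_index=int(data[f"index_{i}"]))
            for i in range(n)
        ]


def _save_slices(path: Path, samples: list[SliceSample]):
    arrays = {"n": np.array(len(samples))}
    for i, s in enumerate(samples):
        arrays[f"image_{i}"] = s.image
        arrays[f"label_{i}"] = s.label
        arrays[f"case_{i}"] = np.array(s.case_id)
        arrays[f"index_{i}"] = np.array(s.slice_index)
    np.savez_compressed(path, **arrays)


def _prepare(cfg: PipelineConfig, out: Path):
    stage = out / "prepare"
    stage.mkdir(parents=True, exist_ok=True)
    n_train_cases = max(1, int(round(cfg.n_cases * cfg.train_fraction)))
    n_train_cases = min(n_train_cases, cfg.n_cases - 1)
    train, test = [], []
    for c in range(cfg.n_cases):
        pcfg_c = type(cfg.phantom)(**{**cfg.phantom.__dict__,
                                      "seed": cfg.phantom.seed + c})
        img_vol, lab_vol = generate_phantom_volume(pcfg_c)
        case_id = f"case_{c:05d}"
        write_case_dir(stage / "cases" / case_id, img_vol, lab_vol)
        samples = slice_volume(img_vol, lab_vol, case_id)
        (train if c < n_train_cases else test).extend(samples)
    _save_slices(stage / "train_slices.npz", train)
    _save_slices(stage / "test_slices.npz", test)
    from .preprocess import fit_stats

    stats = fit_stats(train)
    (stage / "stats.json").write_text(json.dumps(stats.to_dict(), indent=2))
    return {"n_train": len(train), "n_test": len(test)}


def _train(cfg: PipelineConfig, out: Path):
    stage = out / "train"
    stage.mkdir(parents=True, exist_ok=True)
    train = _load_slices(out / "prepare" / "train_slices.npz")
    model = train_cascade(train, cfg.cascade, seed=cfg.seed)
    save_checkpoint(stage / "coarse.npz", model.coarse)
    save_checkpoint(stage / "fine.npz", model.fine)
    (stage / "stats.json").write_text(json.dumps(model.stats.to_dict(),
                                                 indent=2))
    return {"n_train": len(train)}


def load_cascade_model(train_dir, cascade_cfg) -> CascadeModel:
    """Rebuild a trained cascade from a training stage directory."""
    train_dir = Path(train_dir)
    coarse = load_checkpoint(train_dir / "coarse.npz")
    fine = load_checkpoint(train_dir / "fine.npz")
    stats = PreprocessStats.from_dict(
        json.loads((train_dir / "stats.json").read_text()))
    return CascadeModel(coarse=coarse, fine=fine, stats=stats,
                        cfg=cascade_cfg)


def _segment(cfg: PipelineConfig, out: Path):
    stage = out / "segment"
    stage.mkdir(parents=True, exist_ok=True)
    model = load_cascade_model(out / "train", cfg.cascade)
    test = _load_slices(out / "prepare" / "test_slices.npz")
    preds = [model.segment(s.image) for s in test]
    arrays = {"n": np.array(len(preds))}
    for i, p in enumerate(preds):
        arrays[f"pred_{i}"] = p
    np.savez_compressed(stage / "predictions.npz", **arrays)
    return {"n_segmented": len(preds)}


def _evaluate(cfg: PipelineConfig, out: Path):
    stage = out / "evaluate"
    stage.mkdir(parents=True, exist_ok=True)
    test = _load_slices(out / "prepare" / "test_slices.npz")
    with np.load(out / "segment" / "predictions.npz") as data:
        preds = [data[f"pred_{i}"] for i in range(int(data["n"]))]
    report = evaluate(preds, [s.label for s in test])
    (stage / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    frame = report.to_frame()
    frame.to_csv(stage / "report.csv", index=False)
    return {"kidney_dice": report.kidney_dice_mean,
            "tumor_dice": report.tumor_dice_mean,
            "composite": report.composite}


_STAGES = {"prepare": _prepare, "train": _train, "segment": _segment,
           "evaluate": _evaluate}
_ORDER = ("prepare", "train", "segment", "evaluate")


def run_pipeline(cfg: PipelineConfig, output_dir, mode: str = "all",
                 force: bool = False) -> dict:
    """Execute the requested stage (and its missing prerequisites).

    Returns a dict of per-stage summaries.  A stage whose manifest matches
    the current config hash is skipped unless ``force`` is set.
    """
    if mode not in MODES:
        raise RenalsegError(f"mode must be one of {MODES}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config_hash(cfg)
    wanted = _ORDER if mode == "all" else _ORDER[: _ORDER.index(mode) + 1]
    results: dict = {}
    for stage in wanted:
        stage_dir = out / stage
        if not force and _stage_done(stage_dir, digest):
            results[stage] = {"skipped": True}
            continue
        summary = _STAGES[stage](cfg, out)
        _write_manifest(stage_dir, digest, **summary)
        results[stage] = summary
    return results
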