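"""YAML run configuration: nested keys merged with flag overrides and
serialised next to every run for reproducibility."""
from __future__ import annotations

from pathlib import Path

import yaml

from .detector import ModelConfig

DEFAULTS = {
    "model": {"preset": "reduced", "input_size": None, "widths": None,
              "n_classes": 2, "five_stage": False},
    "hgnn": {"enabled": True, "lambda_thresh": 8.0, "common_grid": "middle",
             "layers": 1},
    "bbmm": {"enabled": True, "fusion": "concat+project", "kernel": 3,
             "replace_stages": ["P3", "P4", "P5"]},
    "train": {"iterations": 500, "batch_size": 8, "lr": None, "augment": True},
    "detect": {"conf": 0.25, "iou": 0.45, "max_detections": 300},
}


def _deep_merge(base: dict, over: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (over or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides=None) -> dict:
    """Defaults <- YAML file <- explicit overrides, in increasing priority."""
    cfg = DEFAULTS
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        cfg = _deep_merge(cfg, yaml.safe_load(p.read_text()) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def build_model_config(cfg: dict, seed: int = 0) -> ModelConfig:
    """Translate a nested run config into a ModelConfig."""
    m, h, b, d = cfg["model"], cfg["hgnn"], cfg["bbmm"], cfg["detect"]
    common = h.get("common_grid", "middle")
    if isinstance(common, (list, tuple)):
        common = tuple(int(v) for v in common)
    kw = dict(
        n_classes=int(m.get("n_classes", 2)),
        five_stage=bool(m.get("five_stage", False)),
        use_hgnn=bool(h.get("enabled", True)),
        lambda_thresh=float(h.get("lambda_thresh", 8.0)),
        hgnn_layers=int(h.get("layers", 1)),
        common_grid=common,
        use_bbmm=bool(b.get("enabled", True)),
        bbmm_fusion=b.get("fusion", "concat+project"),
        bbmm_kernel=int(b.get("kernel", 3)),
        bbmm_stages=tuple(b.get("replace_stages",
                                ("P2", "P3", "P4", "P5"))),
        conf_thresh=float(d.get("conf", 0.25)),
        nms_iou=float(d.get("iou", 0.45)),
        max_detections=int(d.get("max_detections", 300)),
        seed=seed,
    )
    if m.get("input_size"):
        kw["input_size"] = int(m["input_size"])
    if m.get("widths"):
        kw["widths"] = tuple(int(w) for w in m["widths"])
    if cfg["train"].get("lr"):
        kw["lr"] = float(cfg["train"]["lr"])
    if m.get("preset") == "reduced":
        return ModelConfig.reduced(**kw)
    return ModelConfig(**kw)


def save_run_config(run_dir, cfg: dict, seed: int) -> Path:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    out = dict(cfg)
    out["seed"] = int(seed)
    path = run_dir / "config.yaml"
    path.write_text(yaml.safe_dump(out))
    return path
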