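"""Configuration files, pattern fixtures, and result serialization.

Plain-text formats throughout: YAML/JSON for configurations and reports,
CSV for rasters and curve tables (floats at 17 significant digits so
re-runs are byte-comparable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .activity import PatternSchedule
from .config import SimulationConfig, validate_config


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML or JSON configuration file.

    Unknown keys are an error; missing keys take the package defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    cfg = SimulationConfig(**data)
    violations = validate_config(cfg)
    if violations:
        raise ValueError(f"{path}: " + "; ".join(violations))
    return cfg


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def make_patterns(n_hcu: int, n_mcu: int, n_patterns: int = 10,
                  duration: int = 500, seed: int = 0,
                  alpha: float = 1.0) -> PatternSchedule:
    """Random orthogonal-ish training patterns: one target minicolumn per
    hypercolumn, each trained for ``duration`` steps.

    With ``alpha < 1`` a random fraction (1 - alpha) of hypercolumns is
    deactivated (target -1) in every pattern.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0x9A7])))
    entries = []
    for _ in range(n_patterns):
        pat = rng.integers(0, n_mcu, size=n_hcu)
        if alpha < 1.0:
            off = rng.random(n_hcu) >= alpha
            pat = np.where(off, -1, pat)
        entries.append((pat, int(duration)))
    return PatternSchedule(entries, training=True)


def write_raster(raster: np.ndarray, path: str | Path) -> None:
    """Spike raster as CSV with columns step,hcu,mcu (one row per spike)."""
    t, h, m = np.nonzero(np.asarray(raster, dtype=bool))
    df = pd.DataFrame({"step": t, "hcu": h, "mcu": m})
    df.to_csv(path, index=False)


def read_raster(path: str | Path, shape: tuple[int, int, int]) -> np.ndarray:
    df = pd.read_csv(path)
    raster = np.zeros(shape, dtype=bool)
    raster[df["step"], df["hcu"], df["mcu"]] = True
    return raster


def write_curves(df: pd.DataFrame, path: str | Path) -> None:
    """Error-curve table as CSV (17 significant digits)."""
    df.to_csv(path, index=False, float_format="%.17g")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_manifest(cfg: SimulationConfig, outputs: list[str],
                 wall_time_s: float) -> dict:
    """Reproducibility manifest: config hash, seed, strategy, outputs."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "strategy": cfg.strategy,
        "approx": cfg.approx,
        "outputs": list(outputs),
        "wall_time_s": wall_time_s,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
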