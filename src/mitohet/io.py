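"""CSV/YAML interchange and run manifests.

All tables travel as UTF-8 CSV with a mandatory header row and empty
fields for missing values (matching segmentation-tool exports);
configurations are flat YAML key/value files mirroring the dataclass
fields; every CLI run writes a JSON manifest recording the command,
config snapshot, seed, package version, timestamp and file digests so
results can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .simulate import SimConfig
from .synth import GeneratorConfig


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_csv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking required columns.

    Raises ``ValueError`` listing any missing columns.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed CSV {path}: {err}") from err
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path} is missing required columns: {missing}")
    return df


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def save_config(config, path: str | Path) -> Path:
    """Write a SimConfig or GeneratorConfig as flat YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))
    return path


def load_sim_config(path: str | Path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return SimConfig(**data)
    except TypeError as err:
        raise ValueError(f"invalid simulation config {path}: {err}") from err


def load_generator_config(path: str | Path) -> GeneratorConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    sim = data.pop("sim", None)
    try:
        if sim is not None:
            data["sim"] = SimConfig(**sim)
        return GeneratorConfig(**data)
    except TypeError as err:
        raise ValueError(f"invalid generator config {path}: {err}") from err


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    command: str,
    config,
    seed: int | None,
    inputs: list[Path] = (),
    outputs: list[Path] = (),
) -> Path:
    """Record one CLI run: command, config, seed, version, digests."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": _to_plain(config) if config is not None else None,
        "seed": seed,
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    path = outdir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
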