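"""Tabular output writing and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import ValidationError


@dataclass
class RunManifest:
    """Provenance record written next to every command's outputs."""

    command: str
    config_hash: str
    seed: Optional[int]
    version: str
    started_at: str
    finished_at: str = ""
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def config_hash(settings: Any) -> str:
    """Stable hash of the run settings (dataclasses/dicts, dataframes excluded)."""

    def default(o):
        if isinstance(o, pd.DataFrame):
            return o.to_csv(index=False)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return repr(o)

    blob = json.dumps(settings, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _fmt(value: Any) -> Any:
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def write_outputs(results: dict[str, Any], out_dir) -> list[Path]:
    """Write each result to ``out_dir`` with a deterministic layout.

    DataFrames become CSV (full precision, fixed column order as given);
    dicts become sorted-key JSON.  Identical inputs produce byte-identical
    files.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out}: {exc}") from exc
    written = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False, float_format="%.12g")
        elif isinstance(obj, dict):
            path = out / f"{name}.json"
            path.write_text(
                json.dumps(obj, indent=2, sort_keys=True, default=_fmt) + "\n"
            )
        else:
            raise ValidationError(f"unsupported result type for {name!r}: {type(obj)}")
        written.append(path)
    return written


def start_manifest(command: str, settings: Any, seed: Optional[int]) -> RunManifest:
    return RunManifest(
        command=command,
        config_hash=config_hash(settings),
        seed=seed,
        version=_pkg_version,
        started_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def finish_manifest(manifest: RunManifest, outputs: list[Path], out_dir) -> Path:
    manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.outputs = sorted(p.name for p in outputs)
    path = Path(out_dir) / "manifest.json"
    path.write_text(manifest.to_json() + "\n")
    missing = [n for n in manifest.outputs if not (Path(out_dir) / n).exists()]
    if missing:  # pragma: no cover - write_outputs just created them
        raise ValidationError(f"manifest lists missing outputs: {missing}")
    return path
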