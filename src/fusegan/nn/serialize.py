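"""Checkpoint I/O: parameters in a .npz archive, provenance in a JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(path: str | Path, states: dict[str, dict], meta: dict) -> Path:
    """`states` maps model names (e.g. 'generator') to state dicts.

    Writes <path>.npz with keys '<model>/<param>' and <path>.json with
    the provenance record (spec, stage, cycle, seed, ...).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    flat = {
        f"{model}/{key}": np.asarray(arr)
        for model, state in states.items()
        for key, arr in state.items()
    }
    np.savez(path.with_suffix(".npz"), **flat)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> tuple[dict[str, dict], dict]:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    if not npz_path.exists():
        raise FileNotFoundError(f"checkpoint not found: {npz_path}")
    with np.load(npz_path) as archive:
        states: dict[str, dict] = {}
        for key in archive.files:
            model, param = key.split("/", 1)
            states.setdefault(model, {})[param] = archive[key]
    meta_path = npz_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return states, meta
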