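"""CSV / JSON serialisation of datasets, trajectories and results.

Tabular data travel as plain CSV; every CSV gets a JSON sidecar
(``<stem>.provenance.json``) recording the seed and generating model so a
dataset on disk is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ModelSpec
from .synthetic import CohortDataset, FociTrackSet, IntensityDataset

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_tracks",
    "load_tracks",
    "save_intensities",
    "load_intensities",
    "to_jsonable",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".provenance.json")


def _write_sidecar(path: Path, seed: int, model) -> None:
    payload = {"seed": seed}
    if isinstance(model, ModelSpec):
        payload["generating_model"] = dataclasses.asdict(model)
    else:
        payload["generating_model"] = str(model)
    _sidecar(path).write_text(json.dumps(payload, indent=2))


def save_cohort(dataset: CohortDataset, path) -> None:
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    _write_sidecar(path, dataset.seed, dataset.generating_model)


def load_cohort(path) -> CohortDataset:
    path = Path(path)
    df = pd.read_csv(path)
    model = "external"
    seed = -1
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        seed = meta.get("seed", -1)
        gm = meta.get("generating_model", "external")
        model = ModelSpec(**gm) if isinstance(gm, dict) else gm
    return CohortDataset.from_frame(df, generating_model=model, seed=seed)


def save_tracks(tracks: FociTrackSet, path, seed: int = -1) -> None:
    path = Path(path)
    tracks.to_frame().to_csv(path, index=False)
    _write_sidecar(path, seed, tracks.condition)


def load_tracks(path, window_min=None) -> FociTrackSet:
    df = pd.read_csv(path)
    return FociTrackSet.from_frame(df, window_min=window_min)


def save_intensities(data: IntensityDataset, path, seed: int = -1) -> None:
    path = Path(path)
    data.to_frame().to_csv(path, index=False)
    _write_sidecar(path, seed, "intensities")


def load_intensities(path) -> IntensityDataset:
    df = pd.read_csv(path)
    return IntensityDataset(
        df["intensity"].to_numpy(dtype=float),
        df["is_taf"].to_numpy().astype(bool),
    )


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy scalars for json.dump."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
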