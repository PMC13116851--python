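"""Dataset manifests, run configuration, and CSV/JSON artifact export.

A dataset is described by a manifest CSV with one row per (specimen, view)
photograph::

    specimen_id,species,view_name,image_path[,split]

The (specimen_id, view_name) pair is unique; specimens may miss some views
(they are flagged — the fusion model treats absent views as inactive
tokens, but batch training uses complete specimens only).  Run configuration
is a YAML file validated against a strict schema (unknown keys rejected)
mirroring the component configs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Manifest",
    "read_manifest",
    "manifest_to_dataset",
    "RunConfig",
    "load_run_config",
    "write_run_snapshot",
    "write_gate_trajectories",
    "write_loss_log",
    "write_predictions",
]

REQUIRED_COLUMNS = ("specimen_id", "species", "view_name", "image_path")


@dataclass
class Manifest:
    """A validated dataset manifest."""

    df: pd.DataFrame
    view_names: list[str]
    species: list[str]
    specimens: list[str]
    root: Path
    load_report: list[str] = field(default_factory=list)
    incomplete_specimens: list[str] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.species)


def read_manifest(path: str | Path, check_images: bool = True) -> Manifest:
    """Read and validate a manifest CSV.

    Raises on an empty file, missing columns, or duplicate (specimen, view)
    rows; unreadable/missing image files and specimens lacking some views are
    collected into the manifest's report fields rather than raising.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"manifest {path} is empty") from None
    if df.empty:
        raise ValueError(f"manifest {path} contains no rows")
    missing_cols = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    dup = df.duplicated(subset=["specimen_id", "view_name"])
    if dup.any():
        pairs = df.loc[dup, ["specimen_id", "view_name"]].values.tolist()
        raise ValueError(f"duplicate (specimen, view) rows: {pairs[:5]}")
    root = path.parent
    report = []
    if check_images:
        for p in df["image_path"]:
            full = root / p
            if not full.is_file():
                report.append(str(p))
    view_names = sorted(df["view_name"].unique())
    species = sorted(df["species"].unique())
    specimens = list(dict.fromkeys(df["specimen_id"]))
    counts = df.groupby("specimen_id")["view_name"].nunique()
    incomplete = sorted(counts.index[counts < len(view_names)])
    return Manifest(df=df, view_names=view_names, species=species,
                    specimens=specimens, root=root, load_report=report,
                    incomplete_specimens=incomplete)


def manifest_to_dataset(manifest: Manifest, encoder_config,
                        val_fraction: float = 0.2, seed: int = 0):
    """Assemble a :class:`~viewgate.synthdata.MultiViewDataset` from images.

    Only complete specimens (all views present, all images readable) enter
    the arrays.  If the manifest carries a ``split`` column it is honoured;
    otherwise a stratified split at ``val_fraction`` is drawn with ``seed``.
    """
    from PIL import Image

    from .encoder import preprocess
    from .synthdata import MultiViewDataset

    df = manifest.df
    skip = set(manifest.incomplete_specimens)
    h, w = encoder_config.input_size
    specs, labels, arrays, splits = [], [], [], []
    species_index = {s: i for i, s in enumerate(manifest.species)}
    for specimen, group in df.groupby("specimen_id", sort=False):
        if specimen in skip:
            continue
        views = {}
        ok = True
        for _, row in group.iterrows():
            full = manifest.root / row["image_path"]
            try:
                raw = np.asarray(Image.open(full).convert("RGB"))
            except OSError:
                ok = False
                break
            views[row["view_name"]] = preprocess(
                raw, encoder_config, view_name=row["view_name"],
                specimen_id=specimen).pixels
        if not ok:
            continue
        specs.append(specimen)
        labels.append(species_index[group["species"].iloc[0]])
        arrays.append(np.stack([views[v] for v in manifest.view_names]))
        splits.append(group["split"].iloc[0] if "split" in group else None)
    X = np.asarray(arrays)
    y = np.asarray(labels)
    if splits[0] is not None:
        is_val = np.array([s == "val" for s in splits])
    else:
        rng = np.random.default_rng(seed)
        is_val = np.zeros(len(y), dtype=bool)
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            n_val = max(1, int(round(val_fraction * len(idx))))
            is_val[idx[:n_val]] = True
    dataset = MultiViewDataset(
        X_train=X[~is_val], y_train=y[~is_val],
        X_val=X[is_val], y_val=y[is_val],
        view_names=list(manifest.view_names),
        class_names=list(manifest.species),
        mode="image", informative_views=())
    # provenance for prediction reports: real specimen ids and image paths
    specs = np.asarray(specs)
    dataset.specimen_ids = {"train": specs[~is_val].tolist(),
                            "val": specs[is_val].tolist()}
    dataset.view_paths = {
        specimen: dict(zip(group["view_name"], group["image_path"]))
        for specimen, group in df.groupby("specimen_id", sort=False)}
    return dataset


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

try:  # pydantic gives strict schema validation with unknown-key rejection
    from pydantic import BaseModel, ConfigDict

    class _Strict(BaseModel):
        model_config = ConfigDict(extra="forbid")

    class DataSection(_Strict):
        source: str = "synthetic"           # "synthetic" | "manifest"
        manifest: str | None = None
        n_classes: int = 6
        n_views: int = 8
        informative_views: list[int] = [0, 3, 5]
        mode: str = "feature"
        feature_dim: int = 16
        image_size: int = 64
        signal_strength: float = 3.0
        noise_sd: float = 1.0
        redundancy_rho: float = 0.0
        n_train: int = 240
        n_val: int = 60

    class EncoderSection(_Strict):
        backbone_name: str = "feature-mlp"
        embedding_dim: int = 32
        n_queries: int = 4
        input_size: list[int] = [64, 64]

    class FusionSection(_Strict):
        n_heads: int = 8
        n_layers: int = 1

    class GateSection(_Strict):
        zeta: float = 1.1
        gamma: float = -0.1
        beta_start: float = 0.67
        beta_end: float = 0.1
        selection_threshold: float = 0.5
        alpha_init: float = 0.0

    class LossSection(_Strict):
        lambda_contrast: float = 0.2
        tau: float = 0.1

    class TrainSection(_Strict):
        lr: float = 5e-3
        gate_lr: float = 0.3
        weight_decay: float = 1e-4
        epochs_fusion: int = 200
        epochs_single: int = 60
        restart_period: int = 200
        restart_mult: int = 2
        batch_size: int = 60
        feature_noise: float = 0.8
        freeze_fraction: float = 0.2

    class SweepSection(_Strict):
        lambda_grid: list[float] = [0.1, 0.2, 0.3, 0.4, 0.5]
        margin_pp: float = 1.0

    class RunConfig(_Strict):
        """Validated run configuration; unknown keys are rejected."""

        seed: int = 0
        output_dir: str = "runs/latest"
        data: DataSection = DataSection()
        encoder: EncoderSection = EncoderSection()
        fusion: FusionSection = FusionSection()
        gate: GateSection = GateSection()
        loss: LossSection = LossSection()
        train: TrainSection = TrainSection()
        sweep: SweepSection = SweepSection()

except ImportError:  # pragma: no cover - pydantic is a hard dependency
    raise


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run config (or the defaults) and apply overrides."""
    payload = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
    payload.update(overrides)
    return RunConfig(**payload)


def write_run_snapshot(config: RunConfig, out_dir: str | Path) -> Path:
    """Write the config snapshot plus a provenance record for the run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = config.model_dump()
    text = yaml.safe_dump(blob, sort_keys=True)
    (out_dir / "config.yaml").write_text(text)
    meta = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out_dir / "run.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def write_gate_trajectories(history: pd.DataFrame, view_names: list[str],
                            path: str | Path) -> None:
    """Long-format gate trajectory CSV: epoch, view_name,
    retention_probability — the data behind retention-trajectory plots."""
    rows = []
    for _, rec in history.iterrows():
        for name in view_names:
            rows.append({"epoch": int(rec["epoch"]), "view_name": name,
                         "retention_probability": rec[f"retention_{name}"]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_loss_log(history: pd.DataFrame, path: str | Path) -> None:
    """Per-epoch loss breakdown CSV."""
    cols = ["epoch", "ce", "contrast", "l0", "total", "beta",
            "lambda_sparsity"]
    if "val_accuracy" in history:
        cols.append("val_accuracy")
    history[cols].to_csv(path, index=False)


def write_predictions(records: list[dict], path: str | Path) -> None:
    """Top-k prediction CSV: specimen_id, rank, species, confidence,
    plus any per-view image path columns the caller includes."""
    pd.DataFrame(records).to_csv(path, index=False)
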