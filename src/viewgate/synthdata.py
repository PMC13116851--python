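"""Synthetic multi-view specimen datasets with a planted informative subset.

Real multi-view specimen surveys pair each specimen with one photograph per
named anatomical view, and only some views carry species-diagnostic signal.
The generator emulates that structure: ``C`` classes, ``V`` views per
specimen, and a planted subset ``S`` of informative views.  Class identity is
spread across the informative views through a *code*: each view ``j`` in
``S`` observes one digit of a class code constructed so that

* the full code is injective over classes (all of ``S`` suffices), and
* whenever ``C >= |S| + 1``, every view in ``S`` is necessary — dropping any
  one leaves at least two classes indistinguishable.

``S`` is therefore the unique minimal sufficient view subset, which is what
makes set-recovery (Jaccard against ``S``) a meaningful benchmark for the
gating mechanism.  Views outside ``S`` contain class-independent nuisance
variation only.

Two rendering modes are provided: ``feature`` mode emits a Gaussian feature
vector per view (fast; the default for tests and sweeps), and ``image`` mode
renders the code digits as positioned bars in small RGB images and can write
the same manifest-CSV + image-folder layout the real-data reader consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticSpec",
    "MultiViewDataset",
    "generate",
    "ground_truth_views",
    "recovery_score",
    "class_codes",
    "write_image_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic multi-view generator.

    Attributes
    ----------
    n_classes, n_views : int
        Number of species-like classes ``C`` and of anatomical views ``V``.
    informative_views : tuple of int
        The planted subset ``S`` of view indices carrying class signal.
    mode : {"feature", "image"}
        Per-view observation type.
    feature_dim : int
        Dimension of each view's feature vector (feature mode).
    image_size : int
        Square image side in pixels (image mode).
    signal_strength : float
        Norm of the class-mean directions (feature mode) relative to unit
        noise; separation scale.
    noise_sd : float
        Standard deviation of the additive Gaussian noise (feature units, or
        pixel units on [0, 1] images).
    redundancy_rho : float
        Fraction of the class signal shared across informative views; at 0
        the views are conditionally independent given the class, as rho
        grows they become redundant.
    n_train, n_val : int
        Split sizes (stratified by class).
    seed : int
        Generator seed; the dataset is a pure function of the spec.
    """

    n_classes: int = 6
    n_views: int = 8
    informative_views: tuple[int, ...] = (0, 3, 5)
    mode: str = "feature"
    feature_dim: int = 16
    image_size: int = 64
    signal_strength: float = 3.0
    noise_sd: float = 1.0
    redundancy_rho: float = 0.0
    n_train: int = 240
    n_val: int = 60
    seed: int = 0

    def __post_init__(self):
        S = tuple(sorted(set(self.informative_views)))
        object.__setattr__(self, "informative_views", S)
        if not S:
            raise ValueError("informative_views must be non-empty")
        if any(j < 0 or j >= self.n_views for j in S):
            raise ValueError("informative_views outside [0, n_views)")
        if self.mode not in ("feature", "image"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.signal_strength > 0:
            raise ValueError("signal_strength must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.redundancy_rho < 1:
            raise ValueError("redundancy_rho must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_train < self.n_classes:
            raise ValueError("n_train < n_classes: cannot stratify the split")


@dataclass
class MultiViewDataset:
    """A generated train/val split plus its ground truth.

    Feature mode arrays have shape (n, V, feature_dim); image mode arrays
    have shape (n, V, H, W, 3) with values in [0, 1].
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    view_names: list[str]
    class_names: list[str]
    mode: str
    informative_views: tuple[int, ...]

    @property
    def n_views(self) -> int:
        return len(self.view_names)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def class_codes(n_classes: int, n_informative: int) -> np.ndarray:
    """Integer code matrix (C, m): digit (c, k) is what informative view k sees.

    Construction: class 0 is the all-zero code; classes 1..m flip one digit
    each (making that view necessary); remaining classes get constant codes
    c, ..., c.  Injective for any C; every view necessary when C >= m + 1.
    """
    C, m = n_classes, n_informative
    codes = np.zeros((C, m), dtype=int)
    for c in range(1, C):
        if c <= m:
            codes[c, c - 1] = 1
        else:
            codes[c, :] = c
    return codes


def _stratified_labels(n: int, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """Near-balanced label vector of length n, shuffled."""
    base = np.arange(n) % n_classes
    rng.shuffle(base)
    return base


def generate(spec: SyntheticSpec) -> MultiViewDataset:
    """Generate a seed-deterministic multi-view dataset from `spec`."""
    rng = np.random.default_rng(spec.seed)
    codes = class_codes(spec.n_classes, len(spec.informative_views))
    y_train = _stratified_labels(spec.n_train, spec.n_classes, rng)
    y_val = _stratified_labels(spec.n_val, spec.n_classes, rng)
    if spec.mode == "feature":
        means = _feature_means(spec, codes, rng)
        X_train = _feature_render(spec, means, y_train, rng)
        X_val = _feature_render(spec, means, y_val, rng)
    else:
        X_train = _image_render(spec, codes, y_train, rng)
        X_val = _image_render(spec, codes, y_val, rng)
    view_names = [f"view_{j:02d}" for j in range(spec.n_views)]
    class_names = [f"species_{c:02d}" for c in range(spec.n_classes)]
    return MultiViewDataset(X_train, y_train, X_val, y_val, view_names,
                            class_names, spec.mode, spec.informative_views)


def _feature_means(spec: SyntheticSpec, codes: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Class-by-view mean array (C, V, d); zero outside the informative set."""
    C, V, d = spec.n_classes, spec.n_views, spec.feature_dim
    means = np.zeros((C, V, d))

    def unit(vec):
        return vec / np.linalg.norm(vec)

    # one direction per (informative view, code digit value)
    digit_dirs: dict[tuple[int, int], np.ndarray] = {}
    shared_dirs = np.array([unit(rng.standard_normal(d)) for _ in range(C)])
    rho = spec.redundancy_rho
    for k, j in enumerate(spec.informative_views):
        for c in range(C):
            digit = int(codes[c, k])
            key = (k, digit)
            if key not in digit_dirs:
                digit_dirs[key] = unit(rng.standard_normal(d))
            direction = (np.sqrt(1.0 - rho) * digit_dirs[key]
                         + np.sqrt(rho) * shared_dirs[c])
            means[c, j] = spec.signal_strength * unit(direction)
    return means


def _feature_render(spec: SyntheticSpec, means: np.ndarray, y: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    n = len(y)
    X = means[y]  # (n, V, d)
    return X + spec.noise_sd * rng.standard_normal(X.shape)


def _image_render(spec: SyntheticSpec, codes: np.ndarray, y: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Render code digits as positioned horizontal bars; nuisance views share
    one class-independent template (a centred vertical bar)."""
    n, V, s = len(y), spec.n_views, spec.image_size
    X = np.zeros((n, V, s, s, 3))
    informative = set(spec.informative_views)
    pos_of_view = {j: k for k, j in enumerate(spec.informative_views)}
    n_digits = int(codes.max()) + 1
    bar_h = max(2, s // (2 * n_digits))
    for i, c in enumerate(y):
        for j in range(V):
            img = np.full((s, s, 3), 0.2)
            if j in informative:
                digit = int(codes[c, pos_of_view[j]])
                top = int((digit + 0.5) / n_digits * (s - bar_h))
                img[top:top + bar_h, s // 8: s - s // 8, :] = (0.9, 0.6, 0.2)
            else:
                img[s // 8: s - s // 8, s // 2 - 2: s // 2 + 2, :] = 0.7
            X[i, j] = img
    X += spec.noise_sd * rng.standard_normal(X.shape)
    return np.clip(X, 0.0, 1.0)


def ground_truth_views(spec: SyntheticSpec) -> set[int]:
    """The planted informative subset S."""
    return set(spec.informative_views)


def recovery_score(selected, truth) -> float:
    """Jaccard index |selected ∩ truth| / |selected ∪ truth|.

    Both sets empty counts as perfect agreement (1.0).
    """
    selected, truth = set(selected), set(truth)
    union = selected | truth
    if not union:
        return 1.0
    return len(selected & truth) / len(union)


def write_image_dataset(dataset: MultiViewDataset, out_dir: str | Path) -> Path:
    """Write an image-mode dataset as PNG files plus a manifest CSV.

    The layout (manifest columns specimen_id, species, view_name, image_path,
    split) is exactly what :func:`viewgate.io.read_manifest` consumes.
    """
    from PIL import Image
    import pandas as pd

    if dataset.mode != "image":
        raise ValueError("only image-mode datasets can be written to disk")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, X, y in (("train", dataset.X_train, dataset.y_train),
                        ("val", dataset.X_val, dataset.y_val)):
        for i in range(len(y)):
            specimen = f"{split}_{i:04d}"
            species = dataset.class_names[y[i]]
            for j, view in enumerate(dataset.view_names):
                rel = Path("images") / specimen / f"{view}.png"
                path = out_dir / rel
                path.parent.mkdir(parents=True, exist_ok=True)
                arr = (np.clip(X[i, j], 0, 1) * 255).astype(np.uint8)
                Image.fromarray(arr).save(path)
                rows.append({"specimen_id": specimen, "species": species,
                             "view_name": view, "image_path": str(rel),
                             "split": split})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"
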