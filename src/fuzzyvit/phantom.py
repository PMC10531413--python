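"""Synthetic B-mode-like breast ultrasound phantoms.

Each phantom is a speckled grayscale image containing one hypoechoic
(darker-than-background) lesion. The class signal is purely morphological,
mirroring the clinical reading of lesion boundaries: benign lesions get a
smooth, low-frequency boundary; malignant lesions get sharp radial spicules
and high-frequency roughness on top of the same base shape. Every boundary
is rescaled to a fixed enclosed area, so mean intensity carries no class
signal and a classifier must read boundary shape, not brightness.

The lesion boundary is built in polar form ``r(theta) = R (1 + p(theta))``
around a jittered center. Speckle is modeled as a multiplicative
Rayleigh-distributed field with a short correlation length, blended toward
unity by ``speckle_contrast`` to emulate the contrast reduction of spatial
compounding in clinical B-mode processing.

Everything is deterministic given (params, label, seed); per-image seeds in
a dataset are derived from the master seed by the documented counter scheme
``(master * 1_000_003 + index) mod 2**31``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "PhantomParams",
    "LabeledImage",
    "DatasetManifest",
    "generate_phantom",
    "write_dataset",
    "read_manifest",
    "lesion_mask",
    "compactness",
]

LABELS = ("benign", "malignant")

# Rayleigh scale with unit mean (sigma * sqrt(pi/2) = 1)
_UNIT_MEAN_RAYLEIGH = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class PhantomParams:
    """Generator conditions. Defaults are the package's study conditions.

    ``speckle_scale`` is the Rayleigh sigma of the multiplicative speckle
    field (default gives the field unit mean; 0 disables noise).
    ``speckle_contrast`` in [0, 1] blends the unit-mean field toward 1,
    emulating the speckle-contrast reduction of spatial compounding
    (1 = fully developed speckle).
    ``boundary_smoothness`` is the highest boundary harmonic used for the
    benign perturbation (a low-pass cutoff). ``spicule_amplitude`` is the
    spike height as a fraction of the lesion radius.
    """

    image_size: int = 64
    lesion_radius_range: tuple[float, float] = (0.18, 0.30)
    speckle_scale: float = _UNIT_MEAN_RAYLEIGH
    speckle_contrast: float = 0.5
    background_level: float = 0.55
    lesion_contrast: float = 0.5
    spicule_count_range: tuple[int, int] = (5, 10)
    spicule_amplitude: float = 0.9
    boundary_smoothness: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("lesion_radius_range must satisfy 0 < lo <= hi < 0.5")
        if not (0 <= self.background_level <= 1 and 0 <= self.lesion_contrast <= 1):
            raise ValueError("background_level and lesion_contrast must be in [0, 1]")
        if not 0 <= self.speckle_contrast <= 1:
            raise ValueError("speckle_contrast must be in [0, 1]")
        if self.spicule_count_range[0] > self.spicule_count_range[1]:
            raise ValueError("spicule_count_range must be non-empty")
        if self.spicule_amplitude <= 0:
            raise ValueError("spicule_amplitude must be positive")


@dataclass(frozen=True)
class LabeledImage:
    image: np.ndarray  # float64 in [0, 1]
    label: str
    seed_used: int


@dataclass(frozen=True)
class DatasetManifest:
    """Rows of (path, label, fold); the on-disk form is a CSV with header."""

    frame: pd.DataFrame
    root: Path

    def __len__(self) -> int:
        return len(self.frame)

    def paths(self) -> list[Path]:
        return [self.root / p for p in self.frame["path"]]

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()


def _child_seed(master: int, index: int) -> int:
    return (master * 1_000_003 + index) % (2**31)


def _boundary_radius(
    params: PhantomParams, label: str, rng: np.random.Generator, thetas: np.ndarray
) -> np.ndarray:
    """Polar boundary r(theta) in pixels for one lesion."""
    lo, hi = params.lesion_radius_range
    base_r = params.image_size * rng.uniform(lo, hi)
    # shared smooth low-frequency component
    pert = np.zeros_like(thetas)
    for k in range(2, params.boundary_smoothness + 1):
        amp = rng.normal(0.0, 0.05 / math.sqrt(k))
        phase = rng.uniform(0, 2 * math.pi)
        pert += amp * np.cos(k * thetas + phase)
    if label == "malignant":
        n_spikes = int(rng.integers(params.spicule_count_range[0], params.spicule_count_range[1] + 1))
        for _ in range(n_spikes):
            center = rng.uniform(0, 2 * math.pi)
            width = rng.uniform(0.2, 0.35)
            height = params.spicule_amplitude * rng.uniform(0.6, 1.0)
            d = np.angle(np.exp(1j * (thetas - center)))  # wrapped angular distance
            pert += height * np.exp(-0.5 * (d / width) ** 2)
        for k in range(8, 25):  # high-frequency roughness
            amp = rng.normal(0.0, 0.04)
            phase = rng.uniform(0, 2 * math.pi)
            pert += amp * np.cos(k * thetas + phase)
    shape = np.clip(1.0 + pert, 0.2, None)
    # normalize enclosed area (= 1/2 int r^2 dtheta) to pi * base_r^2 so the
    # two classes are photometrically indistinguishable by lesion area
    shape *= math.sqrt(2.0 * math.pi / np.trapezoid(shape**2, thetas))
    return base_r * shape


def generate_phantom(
    params: PhantomParams, label: str, seed: int | None = None
) -> LabeledImage:
    """Render one labeled phantom; bitwise deterministic given params+seed."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    seed_used = params.seed if seed is None else seed
    rng = np.random.default_rng(seed_used)
    n = params.image_size

    thetas = np.linspace(0.0, 2 * math.pi, 1024, endpoint=False)
    r_theta = _boundary_radius(params, label, rng, thetas)
    cx, cy = (n / 2) * (1 + rng.uniform(-0.12, 0.12, 2))

    yy, xx = np.mgrid[0:n, 0:n]
    rho = np.hypot(yy - cy, xx - cx)
    ang = np.mod(np.arctan2(yy - cy, xx - cx), 2 * math.pi)
    r_at = np.interp(ang, thetas, r_theta, period=2 * math.pi)
    mask = (rho <= r_at).astype(np.float64)
    soft = gaussian(mask, sigma=0.7, preserve_range=True)

    image = params.background_level * (1.0 - params.lesion_contrast * soft)
    if params.speckle_scale > 0 and params.speckle_contrast > 0:
        field = rng.rayleigh(scale=params.speckle_scale, size=(n, n))
        field = gaussian(field, sigma=0.6, preserve_range=True)
        mean = field.mean() if field.mean() > 0 else 1.0
        field = field / mean  # unit mean regardless of scale
        image = image * (1.0 - params.speckle_contrast + params.speckle_contrast * field)
    return LabeledImage(image=np.clip(image, 0.0, 1.0), label=label, seed_used=seed_used)


def write_dataset(
    n_per_class: int, params: PhantomParams, out_dir: str | Path
) -> DatasetManifest:
    """Render a balanced dataset to 8-bit PNGs plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for class_idx, lab in enumerate(LABELS):
        for i in range(n_per_class):
            counter = class_idx * n_per_class + i
            item = generate_phantom(params, lab, seed=_child_seed(params.seed, counter))
            name = f"{lab}_{i:04d}.png"
            arr = np.clip(np.rint(item.image * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / name)
            rows.append({"path": name, "label": lab, "fold": ""})
    frame = pd.DataFrame(rows, columns=["path", "label", "fold"])
    frame.to_csv(out / "manifest.csv", index=False)
    return DatasetManifest(frame=frame, root=out)


def read_manifest(csv_path: str | Path) -> DatasetManifest:
    """Read a path,label,fold manifest; paths resolve relative to the CSV."""
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path, dtype={"path": str, "label": str}, keep_default_na=False)
    missing = set(frame["label"]) - set(LABELS)
    if missing:
        raise ValueError(f"manifest contains unknown labels: {sorted(missing)}")
    root = csv_path.parent
    for p in frame["path"]:
        if not (root / p).exists():
            raise FileNotFoundError(root / p)
    return DatasetManifest(frame=frame, root=root)


# -- morphology readouts -----------------------------------------------------

def lesion_mask(image: np.ndarray, smooth_sigma: float = 1.5) -> np.ndarray:
    """Segment the hypoechoic lesion: smooth, Otsu, largest dark component."""
    sm = gaussian(np.asarray(image, dtype=np.float64), sigma=smooth_sigma, preserve_range=True)
    dark = sm < threshold_otsu(sm)
    labels = cc_label(dark)
    if labels.max() == 0:
        return np.zeros_like(dark)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    return ndimage.binary_fill_holes(mask)


def compactness(mask: np.ndarray) -> float:
    """Boundary complexity: perimeter^2 / (4 pi area); 1 for a disc."""
    props = regionprops(mask.astype(np.uint8))
    if not props:
        return float("nan")
    region = props[0]
    return float(region.perimeter**2 / (4.0 * math.pi * region.area))


def phantom_for_index(params: PhantomParams, index: int, label: str) -> LabeledImage:
    """Phantom from the same counter scheme ``write_dataset`` uses."""
    return generate_phantom(params, label, seed=_child_seed(params.seed, index))
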