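"""Synthetic breast-ultrasound phantoms.

Generates seeded image/mask/label triplets whose two classes mimic the
contrasts radiologists read in B-mode ultrasound: benign-like lesions have a
smooth near-convex boundary, homogeneous interior and a sharp rim, while
malignant-like lesions are spiculated and irregular, with heterogeneous
speckle texture and a diffuse rim.  The phantoms are statistical stand-ins
for real scans — good enough that morphology and texture features separate
the classes in the constructed direction — not physical simulations.

The lesion contour is a star-convex radial function

    r(theta) = r0 * (1 + irregularity * sum_k a_k sin(k theta + phi_k)
                       + spicule spikes)

so boundary irregularity and spiculation directly control circularity,
solidity and the enclosing-ellipse ratio.  Speckle is multiplicative
Rayleigh-like noise, the modality's dominant noise source.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import polygon as _draw_polygon

BENIGN = 0
MALIGNANT = 1
CLASS_NAMES = {BENIGN: "benign", MALIGNANT: "malignant"}


class InvalidSpecError(ValueError):
    """Raised for phantom specs violating the generator's preconditions."""


class EmptyCohortError(ValueError):
    """Raised when a cohort of zero phantoms is requested."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic lesion.

    Parameters
    ----------
    image_size : int
        Side of the square 8-bit image, pixels (>= 64).
    class_label : int
        ``BENIGN`` (0) or ``MALIGNANT`` (1); recorded, not used to branch.
    boundary_irregularity : float
        Amplitude of the smooth radial perturbation, dimensionless >= 0.
    n_spicules : int
        Number of narrow radial spikes added to the contour, >= 0.
    texture_heterogeneity : float
        Standard deviation (intensity units) of the smooth intra-lesion
        intensity field, >= 0.
    speckle_sigma : float
        Strength of the multiplicative Rayleigh-like speckle, >= 0;
        0 disables speckle.
    rim_contrast : float
        Mean lesion-to-background intensity difference, intensity units.
        Lesions are hypoechoic: interior = background - rim_contrast.
    seed : int
        Per-phantom seed; identical spec + seed is bit-identical output.
    """

    image_size: int = 256
    class_label: int = BENIGN
    boundary_irregularity: float = 0.0
    n_spicules: int = 0
    texture_heterogeneity: float = 0.0
    speckle_sigma: float = 0.0
    rim_contrast: float = 60.0
    seed: int = 0
    radius_frac: float = 0.28       # base radius r0 as fraction of image size
    axis_ratio: float = 0.9         # minor/major axis of the base ellipse;
                                    # near-round so boundary perturbations
                                    # strictly lower circularity/solidity
    background_mean: float = 150.0

    def validate(self) -> None:
        if self.image_size < 64:
            raise InvalidSpecError(f"image_size must be >= 64, got {self.image_size}")
        for name in ("boundary_irregularity", "texture_heterogeneity", "speckle_sigma"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise InvalidSpecError(f"{name} must be finite and >= 0, got {v}")
        if self.n_spicules < 0:
            raise InvalidSpecError(f"n_spicules must be >= 0, got {self.n_spicules}")
        if not np.isfinite(self.rim_contrast):
            raise InvalidSpecError("rim_contrast must be finite")


# Class presets: the default study conditions for cohort generation.  Stored
# as data (not hard-coded inside the generator) so separability is tunable.
CLASS_PRESETS: dict[int, dict[str, float | int]] = {
    BENIGN: dict(
        boundary_irregularity=0.03,
        n_spicules=0,
        texture_heterogeneity=4.0,
        speckle_sigma=0.05,
        rim_contrast=70.0,
    ),
    MALIGNANT: dict(
        boundary_irregularity=0.22,
        n_spicules=7,
        texture_heterogeneity=22.0,
        speckle_sigma=0.25,
        rim_contrast=30.0,
    ),
}


def _radial_profile(spec: PhantomSpec, rng: np.random.Generator, n_theta: int = 720):
    """Radius of the star-convex contour at n_theta evenly spaced angles."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    pert = np.zeros(n_theta)
    if spec.boundary_irregularity > 0:
        # low-order smooth lobes; amplitudes decay with harmonic order.
        # Shifted to be non-negative so lobes push outward: the farthest
        # lobe stretches the major axis faster than the area grows, making
        # mean circularity and solidity strictly decrease with amplitude.
        for k in range(2, 7):
            a = rng.uniform(0.4, 1.0) / k
            phi = rng.uniform(0.0, 2.0 * np.pi)
            pert += a * np.sin(k * theta + phi)
        pert = spec.boundary_irregularity * (pert - pert.min())
    else:
        rng.uniform(size=10)  # keep the stream aligned across amplitude levels
    if spec.n_spicules > 0:
        centers = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_spicules)
        widths = rng.uniform(0.04, 0.09, size=spec.n_spicules)
        amps = rng.uniform(0.25, 0.45, size=spec.n_spicules)
        for c, w, a in zip(centers, widths, amps):
            d = np.angle(np.exp(1j * (theta - c)))  # wrapped angular distance
            pert += a * np.exp(-0.5 * (d / w) ** 2)
    r = 1.0 + pert
    return theta, np.clip(r, 0.2, 1.6)


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns
    -------
    image : (H, W) uint8 array
    mask : (H, W) uint8 array of {0, 1}, one 4-connected component strictly
        inside the border
    label : int
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    c0 = size / 2.0
    r0 = spec.radius_frac * size

    theta, rprof = _radial_profile(spec, rng)
    # base ellipse modulated by the radial profile, with a random orientation
    rot = rng.uniform(0.0, np.pi)
    a, b = r0, r0 * spec.axis_ratio
    ct, st = np.cos(theta), np.sin(theta)
    ex = a * ct * np.cos(rot) - b * st * np.sin(rot)
    ey = a * ct * np.sin(rot) + b * st * np.cos(rot)
    rows = c0 + rprof * ey
    cols = c0 + rprof * ex
    # keep strictly inside the border
    margin = 2.0
    rows = np.clip(rows, margin, size - 1 - margin)
    cols = np.clip(cols, margin, size - 1 - margin)

    mask = np.zeros((size, size), dtype=np.uint8)
    rr, cc = _draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = 1
    # enforce a single 4-connected component (spicule rasterization can pinch off)
    lab, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)

    bg = np.full((size, size), spec.background_mean, dtype=np.float64)
    lesion_base = spec.background_mean - spec.rim_contrast
    img = np.where(mask > 0, lesion_base, bg)

    if spec.texture_heterogeneity > 0:
        field_ = rng.standard_normal((size, size))
        field_ = ndimage.gaussian_filter(field_, sigma=6.0)
        field_ /= max(field_.std(), 1e-12)
        img = img + mask * spec.texture_heterogeneity * field_

    if spec.speckle_sigma > 0:
        # multiplicative Rayleigh-like speckle, unit mean, over the whole image
        ray = rng.rayleigh(scale=1.0, size=(size, size)) / np.sqrt(np.pi / 2.0)
        img = img * (1.0 + spec.speckle_sigma * (ray - 1.0))

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return image, mask, int(spec.class_label)


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    preset_overrides: dict[int, dict] | None = None,
    seed: int = 0,
    image_size: int = 256,
):
    """Generate a deterministic list of (image, mask, label) triplets.

    Per-phantom seeds are spawned reproducibly from the master ``seed``; class
    parameters come from :data:`CLASS_PRESETS` unless overridden per class in
    ``preset_overrides`` (``{BENIGN: {...}, MALIGNANT: {...}}``).
    """
    if n_benign < 0 or n_malignant < 0:
        raise InvalidSpecError("cohort sizes must be non-negative")
    if n_benign + n_malignant == 0:
        raise EmptyCohortError("cohort must contain at least one phantom")
    overrides = preset_overrides or {}
    master = np.random.default_rng(seed)
    out = []
    for label, count in ((MALIGNANT, n_malignant), (BENIGN, n_benign)):
        params = dict(CLASS_PRESETS[label])
        params.update(overrides.get(label, {}))
        for _ in range(count):
            sub = int(master.integers(0, 2**31 - 1))
            spec = PhantomSpec(image_size=image_size, class_label=label,
                               seed=sub, **params)
            out.append(generate_phantom(spec))
    return out


def save_cohort(cohort, out_dir: str | Path) -> Path:
    """Write the cohort as PNG pairs plus a manifest CSV.

    Mask files use the dataset convention ``<stem>_mask.png``.  Returns the
    manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        for i, (image, mask, label) in enumerate(cohort):
            stem = f"{CLASS_NAMES[label]}_{i:04d}"
            Image.fromarray(image).save(out_dir / f"{stem}.png")
            Image.fromarray((mask * 255).astype(np.uint8)).save(
                out_dir / f"{stem}_mask.png")
            writer.writerow([f"{stem}.png", label])
    return manifest


def load_cohort(manifest: str | Path):
    """Read a cohort back from a manifest CSV written by :func:`save_cohort`."""
    manifest = Path(manifest)
    root = manifest.parent
    cohort = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(Image.open(root / row["filename"]).convert("L"))
            stem = Path(row["filename"]).stem
            m = np.asarray(Image.open(root / f"{stem}_mask.png").convert("L"))
            cohort.append((img, (m > 0).astype(np.uint8), int(row["label"])))
    return cohort
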