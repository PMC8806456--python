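"""Synthetic lymph-node-like image patches for benchmarking the classifier.

Real nodal MRI patches are not distributable, so this module generates
grayscale patches containing a single elliptical "node" whose appearance is
controlled by the three radiological criteria used to call a node
suspicious: border irregularity, internal signal heterogeneity, and
roundness.  Metastatic (positive) patches draw these from class-conditional
distributions shifted toward irregular borders, heterogeneous texture and a
rounder shape; benign (negative) patches toward smooth, homogeneous,
elongated nodes.  Node diameters respect a minimum-size threshold, the
analogue of the clinical >3 mm inclusion rule.

The generator is a pure function of (config, seed): identical inputs yield
bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi

MANIFEST_COLUMNS = ["path", "label", "border_irregularity", "heterogeneity",
                    "roundness", "diameter_px"]


@dataclass(frozen=True)
class NodePhenotype:
    """Latent description of one rendered node."""

    label: int
    border_irregularity: float   # RMS radial boundary perturbation / mean radius
    heterogeneity: float         # std/mean contrast of internal texture
    roundness: float             # minor/major axis ratio, in (0, 1]
    diameter_px: float           # major-axis diameter in pixels

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.border_irregularity < 0 or self.heterogeneity < 0:
            raise ValueError("border_irregularity and heterogeneity must be >= 0")
        if not 0 < self.roundness <= 1:
            raise ValueError(f"roundness must be in (0, 1], got {self.roundness}")
        if self.diameter_px <= 0:
            raise ValueError("diameter_px must be positive")


@dataclass(frozen=True)
class ClassEffects:
    """Class-conditional means of the three criteria (one instance per class)."""

    irregularity: float
    heterogeneity: float
    roundness: float


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 400
    positive_fraction: float = 0.5
    image_size: int = 64
    min_diameter_px: int = 16
    max_diameter_px: int = 40
    positive: ClassEffects = field(default_factory=lambda: ClassEffects(0.14, 0.30, 0.92))
    negative: ClassEffects = field(default_factory=lambda: ClassEffects(0.03, 0.06, 0.62))
    irregularity_sd: float = 0.02
    heterogeneity_sd: float = 0.04
    roundness_sd: float = 0.06
    node_intensity: float = 0.75     # mean interior level, [0,1] scale
    background_intensity: float = 0.25
    background_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if min(self.irregularity_sd, self.heterogeneity_sd, self.roundness_sd) < 0:
            raise ValueError("phenotype standard deviations must be >= 0")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if self.min_diameter_px <= 0:
            raise ValueError("min_diameter_px must be positive")
        if self.max_diameter_px >= self.image_size:
            raise ValueError("max_diameter_px must be smaller than image_size")
        if self.max_diameter_px < self.min_diameter_px:
            raise ValueError("max_diameter_px must be >= min_diameter_px")

    def class_counts(self) -> tuple[int, int]:
        n_pos = round(self.n_samples * self.positive_fraction)
        return n_pos, self.n_samples - n_pos

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for k in ("positive", "negative"):
            if isinstance(d.get(k), dict):
                d[k] = ClassEffects(**d[k])
        return cls(**d)


def zero_signal_config(**overrides) -> SyntheticConfig:
    """Config in which the two classes are statistically identical.

    Any classifier's expected AUC on such data is 0.5.
    """
    mid = ClassEffects(0.06, 0.12, 0.75)
    return SyntheticConfig(positive=mid, negative=mid, **overrides)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal; falls back to clipping if sd=0."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(200):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_phenotype(config: SyntheticConfig, label: int,
                     rng: np.random.Generator) -> NodePhenotype:
    """Draw one node phenotype from the class-conditional distributions."""
    eff = config.positive if label == 1 else config.negative
    irr = _truncated_normal(rng, eff.irregularity, config.irregularity_sd, 0.0, 0.5)
    het = _truncated_normal(rng, eff.heterogeneity, config.heterogeneity_sd, 0.0, 1.0)
    rnd = _truncated_normal(rng, eff.roundness, config.roundness_sd, 0.2, 1.0)
    dia = float(rng.uniform(config.min_diameter_px, config.max_diameter_px))
    return NodePhenotype(label=int(label), border_irregularity=irr,
                         heterogeneity=het, roundness=rnd, diameter_px=dia)


def _radial_profile(theta: np.ndarray, irregularity: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Multiplicative boundary perturbation 1 + sum_k a_k sin(k*theta + phi_k).

    Harmonics k=3..8; amplitudes scaled so the RMS perturbation equals the
    irregularity knob (each sin contributes variance a_k^2/2 over theta).
    """
    ks = np.arange(3, 9)
    raw = rng.uniform(0.5, 1.0, size=ks.size)
    amps = raw / np.sqrt(0.5 * np.sum(raw ** 2)) * irregularity if irregularity > 0 else raw * 0
    phases = rng.uniform(0, 2 * np.pi, size=ks.size)
    pert = np.zeros_like(theta)
    for k, a, phi in zip(ks, amps, phases):
        pert += a * np.sin(k * theta + phi)
    return 1.0 + pert


def render_patch(phenotype: NodePhenotype, config: SyntheticConfig,
                 rng: np.random.Generator, return_mask: bool = False):
    """Render one grayscale patch (float array in [0,1]) containing the node.

    The node is an ellipse with axis ratio ``roundness`` and random
    orientation, its boundary perturbed radially per the irregularity knob;
    interior intensity is the base node level modulated by smoothed
    multiplicative speckle of the requested contrast; additive Gaussian
    background noise covers the whole patch.
    """
    size = config.image_size
    if phenotype.diameter_px >= size:
        raise ValueError(
            f"node diameter {phenotype.diameter_px:.1f}px does not fit image size {size}px")

    a = phenotype.diameter_px / 2.0                 # semi-major axis
    b = a * phenotype.roundness                     # semi-minor axis
    angle = rng.uniform(0, np.pi)
    margin = a * (1.0 + 2.0 * phenotype.border_irregularity)
    lo, hi = margin + 1, size - margin - 1
    cx = rng.uniform(lo, hi) if hi > lo else size / 2.0
    cy = rng.uniform(lo, hi) if hi > lo else size / 2.0

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - cx, yy - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa                           # along major axis
    v = -dx * sa + dy * ca
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)      # elliptical radius, boundary at 1
    theta = np.arctan2(v, u)
    boundary = _radial_profile(theta, phenotype.border_irregularity, rng)
    mask = rho <= boundary

    img = np.full((size, size), config.background_intensity, dtype=float)
    interior = np.full((size, size), config.node_intensity, dtype=float)
    if phenotype.heterogeneity > 0:
        speckle = rng.standard_normal((size, size))
        speckle = ndi.gaussian_filter(speckle, sigma=1.5)
        sd = speckle.std()
        if sd > 0:
            speckle = speckle / sd * phenotype.heterogeneity
        interior = interior * (1.0 + speckle)
    img[mask] = interior[mask]
    if config.background_noise_sd > 0:
        img = img + rng.normal(0.0, config.background_noise_sd, (size, size))
    img = np.clip(img, 0.0, 1.0)
    return (img, mask) if return_mask else img


def _labels_for(config: SyntheticConfig) -> np.ndarray:
    n_pos, n_neg = config.class_counts()
    return np.array([1] * n_pos + [0] * n_neg)


def generate_arrays(config: SyntheticConfig):
    """Generate the dataset in memory.

    Returns ``(images, labels, phenotypes, masks)`` where images is
    (n, size, size) float in [0,1] and masks the boolean node masks.
    """
    rng = np.random.default_rng(config.seed)
    labels = _labels_for(config)
    images = np.empty((config.n_samples, config.image_size, config.image_size), dtype=float)
    masks = np.empty((config.n_samples, config.image_size, config.image_size), dtype=bool)
    phenotypes = []
    for i, lab in enumerate(labels):
        ph = sample_phenotype(config, int(lab), rng)
        img, m = render_patch(ph, config, rng, return_mask=True)
        images[i], masks[i] = img, m
        phenotypes.append(ph)
    return images, labels, phenotypes, masks


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write PNG patches plus a CSV manifest to ``out_dir``; returns the manifest."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create dataset directory {out_dir}: {e}") from e

    images, labels, phenotypes, _ = generate_arrays(config)
    rows = []
    for i, (img, lab, ph) in enumerate(zip(images, labels, phenotypes)):
        rel = Path("images") / f"sample_{i:05d}.png"
        arr8 = np.round(img * 255.0).astype(np.uint8)
        try:
            Image.fromarray(arr8, mode="L").save(out_dir / rel)
        except OSError as e:
            raise OSError(f"failed writing image {out_dir / rel}: {e}") from e
        rows.append({
            "path": rel.as_posix(),
            "label": int(lab),
            "border_irregularity": round(ph.border_irregularity, 6),
            "heterogeneity": round(ph.heterogeneity, 6),
            "roundness": round(ph.roundness, 6),
            "diameter_px": round(ph.diameter_px, 6),
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
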