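"""Synthetic ID/OOD benchmark generator.

Emulates the statistical structure that class-conditional confidence scoring
assumes: in-distribution (ID) features are drawn from per-class multivariate
Gaussians sharing one within-class covariance, and out-of-distribution (OOD)
features come from a controllably shifted version of that mixture.  A scalar
displacement ``delta`` stands in for the qualitative near/far OOD spectrum
(near OOD: other insects or organisms sharing context with the training
classes; far OOD: faces, vehicles): ``delta = 0`` reproduces the ID mixture
exactly, large ``delta`` is trivially separable.

The module also builds the class-size profiles used to study detector
sensitivity to training-set imbalance, and an optional toy raster-image bed
(directory-per-class PNGs) for exercising the image-level classifier adapter.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import ID_DOMAIN, OOD_DOMAIN, FeatureTable, make_ids

MEAN_SHIFT = "mean-shift"
COV_INFLATION = "covariance-inflation"
MIXTURE = "mixture"
_SHIFT_MODES = (MEAN_SHIFT, COV_INFLATION, MIXTURE)

BALANCED = "balanced"
UNBALANCED_EMPIRICAL = "unbalanced-empirical"
UNBALANCED_UNIFORM = "unbalanced-uniform"
_PROFILE_KINDS = (BALANCED, UNBALANCED_EMPIRICAL, UNBALANCED_UNIFORM)

_PSD_TOL = 1e-8


@dataclass(frozen=True)
class FeatureSpaceSpec:
    """Geometry of the simulated feature space.

    Parameters
    ----------
    n_classes : int
        Number of ID classes C (the motivating insect-pest application has
        142 classes; desk-scale experiments use far fewer).
    dim : int
        Feature dimension d.
    mean_scale : float
        Standard deviation of the isotropic Gaussian from which the C class
        means are drawn; controls between-class spread.
    within_cov : float or (d, d) array
        Shared within-class covariance; a scalar means isotropic variance.
    seed : int
        Seed determining class means and all sampling streams.
    """

    n_classes: int
    dim: int
    mean_scale: float = 3.0
    within_cov: float | np.ndarray = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.mean_scale < 0:
            raise ValueError("mean_scale must be nonnegative")
        cov = self.cov_matrix()
        if not np.allclose(cov, cov.T, atol=_PSD_TOL):
            raise ValueError("within_cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -_PSD_TOL:
            raise ValueError("within_cov must be positive semi-definite")

    def cov_matrix(self) -> np.ndarray:
        if np.isscalar(self.within_cov):
            if self.within_cov < 0:
                raise ValueError("isotropic variance must be nonnegative")
            return float(self.within_cov) * np.eye(self.dim)
        return np.asarray(self.within_cov, dtype=float)

    def class_means(self) -> np.ndarray:
        """The (C, d) class means; a deterministic function of ``seed``."""
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0]))
        return self.mean_scale * rng.standard_normal((self.n_classes, self.dim))


@dataclass(frozen=True)
class OODShiftSpec:
    """How far, and in what manner, OOD samples depart from the ID mixture.

    ``delta`` is measured in feature-space units; with unit isotropic
    within-class covariance it is the displacement in within-class standard
    deviations.  ``mode`` selects mean displacement, covariance inflation
    (variance scaled by ``1 + delta``), or an even mixture of both.
    """

    delta: float
    n_samples: int
    mode: str = MEAN_SHIFT

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.n_samples < 0:
            raise ValueError("n_samples must be nonnegative")
        if self.mode not in _SHIFT_MODES:
            raise ValueError(f"mode must be one of {_SHIFT_MODES}")


@dataclass(frozen=True)
class ClassSizeProfile:
    """Per-class sample counts at a fixed total."""

    kind: str
    counts: tuple[int, ...]
    n_total: int

    def __post_init__(self) -> None:
        if self.kind not in _PROFILE_KINDS:
            raise ValueError(f"kind must be one of {_PROFILE_KINDS}")
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "counts", counts)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if sum(counts) != self.n_total:
            raise ValueError(
                f"counts sum to {sum(counts)}, expected n_total={self.n_total}"
            )
        if self.kind == BALANCED and counts and max(counts) - min(counts) > 1:
            raise ValueError("balanced profile counts may differ by at most 1")

    @property
    def n_classes(self) -> int:
        return len(self.counts)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Largest-remainder rounding; remainder ties broken toward lower index so
    the allocation is deterministic and sums exactly to ``total``.
    """
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be nonnegative")
    s = weights.sum()
    if s <= 0:
        raise ValueError("weights must not all be zero")
    quota = weights / s * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    # sort by descending fractional part, stable => lower index wins ties
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def make_class_size_profile(
    kind: str,
    n_total: int,
    n_classes: int,
    seed: int = 0,
    empirical_weights: Sequence[float] | None = None,
    min_count: int = 0,
) -> ClassSizeProfile:
    """Build a per-class count vector summing exactly to ``n_total``.

    kinds
    -----
    ``balanced``
        Counts as equal as divisibility allows; the remainder goes to the
        lowest-indexed classes. Requires at least one sample per class.
    ``unbalanced-empirical``
        Counts proportional to ``empirical_weights`` (e.g. a long-tailed
        corpus distribution), largest-remainder rounded.
    ``unbalanced-uniform``
        Each class weight an independent Uniform(0, 1) draw from ``seed``.

    ``min_count`` floors every class at that many samples before apportioning
    the rest; useful when downstream fitting needs >= 2 samples per class.
    """
    if kind not in _PROFILE_KINDS:
        raise ValueError(f"kind must be one of {_PROFILE_KINDS}")
    if n_classes < 1 or n_total < 1:
        raise ValueError("n_total and n_classes must be positive")
    if kind == BALANCED:
        if n_total < n_classes:
            raise ValueError("balanced profile requires n_total >= n_classes")
        base, rem = divmod(n_total, n_classes)
        counts = np.full(n_classes, base, dtype=int)
        counts[:rem] += 1
        return ClassSizeProfile(kind, tuple(counts), n_total)

    if kind == UNBALANCED_EMPIRICAL:
        if empirical_weights is None:
            raise ValueError("unbalanced-empirical requires empirical_weights")
        weights = np.asarray(empirical_weights, dtype=float)
        if weights.shape != (n_classes,):
            raise ValueError("empirical_weights must have length n_classes")
    else:  # unbalanced-uniform
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10]))
        weights = rng.uniform(size=n_classes)

    if min_count * n_classes > n_total:
        raise ValueError("min_count * n_classes exceeds n_total")
    counts = min_count + _largest_remainder(weights, n_total - min_count * n_classes)
    return ClassSizeProfile(kind, tuple(counts), n_total)


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root (handles rank-deficient covariance)."""
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def generate_id_features(
    spec: FeatureSpaceSpec, profile: ClassSizeProfile, stream: int = 1
) -> FeatureTable:
    """Sample labeled ID records: class c ~ N(mu_c, Sigma), counts from profile.

    ``stream`` keys an independent sampling stream under the same spec (and
    hence the same class means), so callers can draw disjoint datasets —
    e.g. a fresh detector-fitting set — without touching the geometry.
    """
    if profile.n_classes != spec.n_classes:
        raise ValueError(
            f"profile covers {profile.n_classes} classes, spec has {spec.n_classes}"
        )
    means = spec.class_means()
    factor = _cov_factor(spec.cov_matrix())
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(stream)]))
    feats, labels = [], []
    for c, n_c in enumerate(profile.counts):
        z = rng.standard_normal((n_c, spec.dim))
        feats.append(means[c] + z @ factor.T)
        labels.extend([c] * n_c)
    features = np.vstack(feats) if feats else np.empty((0, spec.dim))
    n = features.shape[0]
    return FeatureTable(
        ids=make_ids("id", n),
        domain=np.asarray([ID_DOMAIN] * n, dtype=object),
        labels=np.asarray(labels, dtype=object),
        features=features,
    )


def generate_ood_features(
    spec: FeatureSpaceSpec, shift: OODShiftSpec, stream: int = 2
) -> FeatureTable:
    """Sample unlabeled OOD records from the shifted ID mixture.

    Under ``mean-shift`` each mixture component mean is the corresponding ID
    class mean displaced by distance ``delta`` toward (and, for large
    ``delta``, past) the feature-space origin, so ``delta = 0`` reproduces
    the ID mixture exactly.  The inward direction emulates how trained
    networks embed out-of-domain images: their penultimate activations fall
    in the low-response region near the origin rather than drifting off in a
    random direction (where a linear logit map would be spuriously
    confident).  Component membership is uniform over classes.  OOD rows
    carry no class label.
    """
    means = spec.class_means()
    cov = spec.cov_matrix()
    norms = np.linalg.norm(means, axis=1, keepdims=True)
    directions = np.where(norms > 1e-12, -means / np.where(norms == 0, 1, norms), 0.0)
    if (norms <= 1e-12).any():
        # degenerate zero-norm mean: fall back to a seed-determined direction
        dir_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 3]))
        rand = dir_rng.standard_normal((spec.n_classes, spec.dim))
        rand /= np.linalg.norm(rand, axis=1, keepdims=True)
        directions = np.where(norms > 1e-12, directions, rand)

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(stream)]))
    n = shift.n_samples
    if n == 0:
        return FeatureTable(
            ids=make_ids("ood", 0),
            domain=np.asarray([], dtype=object),
            labels=np.asarray([], dtype=object),
            features=np.empty((0, spec.dim)),
        )
    comp = rng.integers(spec.n_classes, size=n)
    z = rng.standard_normal((n, spec.dim))
    if shift.mode == MEAN_SHIFT:
        centers = means[comp] + shift.delta * directions[comp]
        samples = centers + z @ _cov_factor(cov).T
    elif shift.mode == COV_INFLATION:
        samples = means[comp] + z @ _cov_factor((1.0 + shift.delta) * cov).T
    else:  # mixture: even split between the two shift mechanisms
        half = n // 2
        shifted = means[comp] + shift.delta * directions[comp]
        samples = np.empty((n, spec.dim))
        samples[:half] = shifted[:half] + z[:half] @ _cov_factor(cov).T
        samples[half:] = (
            means[comp[half:]] + z[half:] @ _cov_factor((1.0 + shift.delta) * cov).T
        )
    return FeatureTable(
        ids=make_ids("ood", n),
        domain=np.asarray([OOD_DOMAIN] * n, dtype=object),
        labels=np.asarray([None] * n, dtype=object),
        features=samples,
    )


# --------------------------------------------------------------------------
# Toy raster images: a tiny procedurally drawn image bed for the adapter.
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyImageSpec:
    """Procedural shape-image generator settings.

    Each ID class draws a centered ellipse whose aspect ratio and fill
    intensity are class-determined (with small per-image jitter); the OOD
    generator emits rectangles with intensities from a band disjoint from
    every ID class.  Images are greyscale PNG, one subdirectory per class.
    """

    n_classes: int
    image_size: int = 32
    per_class_counts: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        counts = tuple(int(c) for c in self.per_class_counts)
        if len(counts) != self.n_classes:
            raise ValueError("per_class_counts must have length n_classes")
        object.__setattr__(self, "per_class_counts", counts)


def _draw_ellipse(size: int, aspect: float, intensity: int, rng) -> "np.ndarray":
    from PIL import Image, ImageDraw

    img = Image.new("L", (size, size), color=0)
    draw = ImageDraw.Draw(img)
    half = size * 0.38
    cx = size / 2 + rng.uniform(-1.5, 1.5)
    cy = size / 2 + rng.uniform(-1.5, 1.5)
    rx, ry = half * aspect, half / aspect
    draw.ellipse([cx - rx, cy - ry, cx + rx, cy + ry], fill=int(intensity))
    arr = np.asarray(img, dtype=np.uint8).copy()
    noise = rng.integers(0, 12, size=arr.shape, dtype=np.uint8)
    return np.clip(arr.astype(int) + noise, 0, 255).astype(np.uint8)


def _draw_rect(size: int, aspect: float, intensity: int, rng) -> "np.ndarray":
    from PIL import Image, ImageDraw

    img = Image.new("L", (size, size), color=0)
    draw = ImageDraw.Draw(img)
    half = size * 0.34
    cx = size / 2 + rng.uniform(-1.5, 1.5)
    cy = size / 2 + rng.uniform(-1.5, 1.5)
    rx, ry = half * aspect, half / aspect
    draw.rectangle([cx - rx, cy - ry, cx + rx, cy + ry], fill=int(intensity))
    arr = np.asarray(img, dtype=np.uint8).copy()
    noise = rng.integers(0, 12, size=arr.shape, dtype=np.uint8)
    return np.clip(arr.astype(int) + noise, 0, 255).astype(np.uint8)


# ID intensities occupy [90, 230]; OOD rectangles use [30, 70] — disjoint.
_ID_INTENSITY_LO, _ID_INTENSITY_HI = 90, 230
_OOD_INTENSITY_LO, _OOD_INTENSITY_HI = 30, 70


def _id_class_params(spec: ToyImageSpec) -> list[tuple[float, int]]:
    aspects = np.linspace(0.6, 1.5, spec.n_classes)
    intensities = np.linspace(
        _ID_INTENSITY_LO, _ID_INTENSITY_HI, spec.n_classes
    ).astype(int)
    return list(zip(aspects, intensities))


def generate_toy_images(spec: ToyImageSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write directory-per-class PNGs; returns the file -> label manifest."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 20]))
    rows = []
    for c, ((aspect, intensity), n_c) in enumerate(
        zip(_id_class_params(spec), spec.per_class_counts)
    ):
        cls_dir = out / f"class_{c:03d}"
        cls_dir.mkdir(exist_ok=True)
        for i in range(n_c):
            a = aspect * rng.uniform(0.95, 1.05)
            arr = _draw_ellipse(spec.image_size, a, intensity, rng)
            path = cls_dir / f"img_{i:05d}.png"
            Image.fromarray(arr).save(path)
            rows.append({"file": str(path.relative_to(out)), "label": c})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def generate_toy_ood_images(
    n_samples: int, image_size: int, seed: int, out_dir: str | Path
) -> pd.DataFrame:
    """OOD counterpart: rectangles with intensities disjoint from all ID classes."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 21]))
    rows = []
    for i in range(n_samples):
        aspect = rng.uniform(0.5, 2.0)
        intensity = rng.integers(_OOD_INTENSITY_LO, _OOD_INTENSITY_HI)
        arr = _draw_rect(image_size, aspect, intensity, rng)
        path = out / f"ood_{i:05d}.png"
        Image.fromarray(arr).save(path)
        rows.append({"file": path.name, "label": ""})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_image_directory(root: str | Path, image_size: int | None = None) -> FeatureTable:
    """Read a directory-per-class image layout into a flattened feature table.

    Each subdirectory name is a class; images are loaded greyscale, optionally
    resized, scaled to [0, 1] and flattened row-major.
    """
    from PIL import Image

    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    feats, labels, ids = [], [], []
    for c, d in enumerate(class_dirs):
        for p in sorted(d.glob("*.png")) + sorted(d.glob("*.jpg")) + sorted(
            d.glob("*.jpeg")
        ):
            img = Image.open(p).convert("L")
            if image_size is not None:
                img = img.resize((image_size, image_size))
            feats.append(np.asarray(img, dtype=float).ravel() / 255.0)
            labels.append(c)
            ids.append(f"{d.name}/{p.name}")
    features = np.vstack(feats)
    n = features.shape[0]
    return FeatureTable(
        ids=np.asarray(ids, dtype=object),
        domain=np.asarray([ID_DOMAIN] * n, dtype=object),
        labels=np.asarray(labels, dtype=object),
        features=features,
    )
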