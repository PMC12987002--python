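"""Synthetic embryo phantoms rendered as defocused 7-plane focal stacks.

The generator emulates what a time-lapse incubator camera sees through a
shallow depth of field: a bright culture-well background, a dark zona
pellucida ring, one to several textured blastomeres sitting at different
depths inside the zona, and small anucleate fragments.  Every feature carries
a single scalar depth (thin-feature approximation); a focal plane at offset
``f`` renders a feature at depth ``z`` through an isotropic Gaussian defocus
kernel of width ``blur_scale * |z - f| / delta_z`` pixels, so each feature is
sharpest in the plane nearest its own depth and no single plane sees the whole
embryo sharply.

Seven phenotypical classes are supported: ``1cell``, ``2cells``, ``3cells``,
``4cells``, ``more`` (morula/blastocyst pool, rendered as >=5 blastomeres),
``empty`` (bare well) and ``not_defined`` (debris/artifact scene without a
zona ring).  Default class proportions follow the clinical distribution
19.2 / 18.5 / 4.7 / 17.4 / 21.5 / 7.6 / 11.0 percent (printed values sum to
99.9 and are renormalized).

All generators are pure functions of their seeds: the same arguments always
reproduce bit-identical scenes, stacks and datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CLASSES",
    "CLINICAL_PROPORTIONS",
    "NOISE_SIGMA",
    "Blastomere",
    "Fragment",
    "PhantomScene",
    "FocalStack",
    "DatasetItem",
    "LabeledDataset",
    "apportion",
    "make_scene",
    "render_all_in_focus",
    "render_stack",
    "make_dataset",
]

CLASSES = ("1cell", "2cells", "3cells", "4cells", "more", "empty", "not_defined")

#: Clinical stage distribution (percent; printed values sum to 99.9).
CLINICAL_PROPORTIONS = {
    "1cell": 0.192,
    "2cells": 0.185,
    "3cells": 0.047,
    "4cells": 0.174,
    "more": 0.215,
    "empty": 0.076,
    "not_defined": 0.110,
}

SPLIT_FRACTIONS = {"train": 0.68, "val": 0.12, "test": 0.20}

#: Additive Gaussian sensor noise applied to every rendered image.
NOISE_SIGMA = 0.01

_BACKGROUND_LEVEL = 0.78
_DEPTH_PALETTE = (-3.0, 3.0, -1.5, 1.5, 0.0, -2.5, 2.5, -0.5)


@dataclass(frozen=True)
class Blastomere:
    center: tuple[float, float]  # (x, y) pixels
    radius: float  # pixels
    depth: float  # micrometres relative to the equatorial plane
    texture_seed: int


@dataclass(frozen=True)
class Fragment:
    center: tuple[float, float]
    radius: float
    depth: float


@dataclass(frozen=True)
class PhantomScene:
    """Generative description of one synthetic embryo scene."""

    class_label: str
    image_size: int
    well_center: tuple[float, float]
    embryo_radius: float
    zona_thickness: float
    blastomeres: tuple[Blastomere, ...]
    fragments: tuple[Fragment, ...]
    background_seed: int

    def validate(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        expected = {"1cell": 1, "2cells": 2, "3cells": 3, "4cells": 4, "empty": 0, "not_defined": 0}
        n = len(self.blastomeres)
        if self.class_label == "more":
            if n < 5:
                raise ValueError(f"'more' scene must carry >=5 blastomeres, got {n}")
        elif n != expected[self.class_label]:
            raise ValueError(f"{self.class_label} scene has {n} blastomeres")
        cx, cy = self.well_center
        for b in self.blastomeres:
            if np.hypot(b.center[0] - cx, b.center[1] - cy) > self.embryo_radius:
                raise ValueError("blastomere center outside the embryo radius")
        if self.embryo_radius < 4.0 * self.zona_thickness:
            raise ValueError("embryo radius must be at least 4x the zona thickness")
        depths = [f.depth for f in self.blastomeres + self.fragments]
        if len(depths) >= 2 and len(set(depths)) < 2:
            raise ValueError("scenes with >=2 features must span >=2 distinct depths")

    @property
    def features(self) -> tuple:
        return self.blastomeres + self.fragments


@dataclass
class FocalStack:
    """Seven co-registered grayscale planes at focal offsets k * delta_z."""

    planes: np.ndarray  # (7, H, W) float in [0, 1]
    focal_offsets: np.ndarray  # micrometres, symmetric about 0
    delta_z: float

    def validate(self) -> None:
        if len(self.planes) != 7:
            raise ValueError(f"a focal stack has exactly 7 planes, got {len(self.planes)}")
        shapes = {p.shape for p in self.planes}
        if len(shapes) != 1:
            raise ValueError("all planes must share the same shape")
        expected = np.arange(-3, 4) * self.delta_z
        if not np.allclose(self.focal_offsets, expected):
            raise ValueError("focal offsets must equal k * delta_z for k = -3..+3")
        lo = min(float(p.min()) for p in self.planes)
        hi = max(float(p.max()) for p in self.planes)
        if lo < 0.0 or hi > 1.0:
            raise ValueError("plane intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape


@dataclass(frozen=True)
class DatasetItem:
    stack: FocalStack
    reference: np.ndarray
    class_label: str
    scene: PhantomScene


@dataclass
class LabeledDataset:
    items: list = field(default_factory=list)
    split_assignment: list = field(default_factory=list)
    seed: int = 0

    def indices(self, split: str) -> list[int]:
        return [i for i, s in enumerate(self.split_assignment) if s == split]

    def subset(self, split: str) -> list[DatasetItem]:
        return [self.items[i] for i in self.indices(split)]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for item in self.items:
            counts[item.class_label] += 1
        return counts


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) & 0x7FFFFFFF for k in keys]))


def _ring_positions(rng, n: int, spread: float):
    base = rng.uniform(0.0, 2.0 * np.pi)
    angles = base + np.arange(n) * 2.0 * np.pi / n + rng.uniform(-0.15, 0.15, size=n)
    return [(spread * np.cos(a), spread * np.sin(a)) for a in angles]


def _assign_depths(rng, n: int) -> list[float]:
    palette = list(_DEPTH_PALETTE)
    rng.shuffle(palette)
    return [palette[i % len(palette)] for i in range(n)]


def make_scene(class_label: str, image_size: int = 256, seed: int = 0) -> PhantomScene:
    """Generate a deterministic :class:`PhantomScene` for one stage class.

    The same ``(class_label, image_size, seed)`` triple always yields an
    identical scene.  ``image_size`` must be at least 64 pixels.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {CLASSES}")
    if image_size < 64:
        raise ValueError("image_size must be at least 64 pixels")

    class_idx = CLASSES.index(class_label)
    rng = _rng(seed, class_idx, image_size)
    s = float(image_size)

    cx = s / 2.0 + rng.uniform(-0.04, 0.04) * s
    cy = s / 2.0 + rng.uniform(-0.04, 0.04) * s
    embryo_radius = rng.uniform(0.30, 0.36) * s
    zona_thickness = rng.uniform(0.048, 0.068) * s
    inner = embryo_radius - zona_thickness

    n_cells = {"1cell": 1, "2cells": 2, "3cells": 3, "4cells": 4,
               "empty": 0, "not_defined": 0}.get(class_label)
    if class_label == "more":
        n_cells = int(rng.integers(5, 9))

    blastomeres: list[Blastomere] = []
    if n_cells:
        if n_cells == 1:
            offsets = [(rng.uniform(-0.05, 0.05) * inner, rng.uniform(-0.05, 0.05) * inner)]
            radius = 0.62 * inner
        elif n_cells <= 4:
            spread = {2: 0.48, 3: 0.52, 4: 0.56}[n_cells] * inner
            radius = {2: 0.47, 3: 0.42, 4: 0.39}[n_cells] * inner
            offsets = _ring_positions(rng, n_cells, spread)
        else:
            spread = 0.60 * inner
            radius = 0.30 * inner
            offsets = _ring_positions(rng, n_cells - 1, spread)
            offsets.append((rng.uniform(-0.08, 0.08) * inner, rng.uniform(-0.08, 0.08) * inner))
        depths = _assign_depths(rng, n_cells)
        centers = [(cx + dx, cy + dy) for dx, dy in offsets]
        radii = [radius * rng.uniform(0.92, 1.05) for _ in range(n_cells)]
        # shrink until cells neither overlap each other nor poke through the zona
        gap = 0.02 * s
        for _ in range(60):
            ok = all(
                np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
                >= radii[i] + radii[j] + gap
                for i in range(n_cells) for j in range(i + 1, n_cells)
            ) and all(
                np.hypot(px - cx, py - cy) + r <= inner - gap
                for (px, py), r in zip(centers, radii)
            )
            if ok:
                break
            radii = [r * 0.95 for r in radii]
        blastomeres = [
            Blastomere(center=c, radius=r, depth=d,
                       texture_seed=int(rng.integers(0, 2**31 - 1)))
            for c, r, d in zip(centers, radii, depths)
        ]

    fragments: list[Fragment] = []
    if class_label == "empty":
        n_frag = 0
    elif class_label == "not_defined":
        n_frag = int(rng.integers(4, 9))
    elif class_label == "1cell":
        n_frag = int(rng.integers(0, 3))
    else:
        n_frag = int(rng.integers(1, 5))
    frag_depths = _assign_depths(rng, max(n_frag, 0))
    for i in range(n_frag):
        if class_label == "not_defined":
            # debris spread over the well, larger and irregular in size
            fx = rng.uniform(0.15, 0.85) * s
            fy = rng.uniform(0.15, 0.85) * s
            fr = rng.uniform(0.035, 0.09) * s
        else:
            ang = rng.uniform(0.0, 2.0 * np.pi)
            rad = rng.uniform(0.15, 0.9) * inner
            fx, fy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            fr = rng.uniform(0.015, 0.032) * s
        fragments.append(Fragment(center=(fx, fy), radius=fr, depth=frag_depths[i]))

    # guarantee the multi-depth invariant for >=2 features
    all_feats = blastomeres + fragments
    if len(all_feats) >= 2 and len({f.depth for f in all_feats}) < 2:
        f = fragments[-1] if fragments else None
        if f is not None:
            fragments[-1] = Fragment(center=f.center, radius=f.radius,
                                     depth=f.depth + 1.5)
        else:
            b = blastomeres[-1]
            blastomeres[-1] = Blastomere(center=b.center, radius=b.radius,
                                         depth=b.depth + 1.5,
                                         texture_seed=b.texture_seed)

    scene = PhantomScene(
        class_label=class_label,
        image_size=image_size,
        well_center=(cx, cy),
        embryo_radius=embryo_radius,
        zona_thickness=zona_thickness,
        blastomeres=tuple(blastomeres),
        fragments=tuple(fragments),
        background_seed=int(rng.integers(0, 2**31 - 1)),
    )
    scene.validate()
    return scene


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _distance_map(size: int, center: tuple[float, float]) -> np.ndarray:
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    return np.hypot(x - center[0], y - center[1])


def _soft_disk(dist: np.ndarray, radius: float, edge: float = 1.2) -> np.ndarray:
    return np.clip((radius - dist) / edge + 0.5, 0.0, 1.0)


def _background(scene: PhantomScene) -> np.ndarray:
    s = scene.image_size
    rng = _rng(scene.background_seed, 7)
    field_ = ndimage.gaussian_filter(rng.standard_normal((s, s)), sigma=s / 10.0)
    std = field_.std()
    if std > 0:
        field_ *= 0.02 / std
    return _BACKGROUND_LEVEL + field_


def _blastomere_delta(scene: PhantomScene, b: Blastomere) -> np.ndarray:
    s = scene.image_size
    dist = _distance_map(s, b.center)
    body = _soft_disk(dist, b.radius)
    rim = _soft_disk(dist, b.radius) - _soft_disk(dist, b.radius - 0.14 * b.radius)
    rng = _rng(b.texture_seed)
    tex = ndimage.gaussian_filter(rng.standard_normal((s, s)), sigma=1.6)
    std = tex.std()
    if std > 0:
        tex *= 0.11 / std
    tex = np.clip(tex, -0.2, 0.2)
    return body * (-0.30 + tex) + rim * (-0.10)


def _fragment_delta(scene: PhantomScene, f: Fragment) -> np.ndarray:
    dist = _distance_map(scene.image_size, f.center)
    return _soft_disk(dist, f.radius) * (-0.20)


def _zona_delta(scene: PhantomScene) -> np.ndarray:
    dist = _distance_map(scene.image_size, scene.well_center)
    outer = _soft_disk(dist, scene.embryo_radius)
    inner_edge = _soft_disk(dist, scene.embryo_radius - scene.zona_thickness)
    ring = outer - inner_edge
    return ring * (-0.22) + inner_edge * (-0.06)


def _scene_layers(scene: PhantomScene) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """Background plus per-depth summed feature deltas (zona lives at z = 0)."""
    layers: dict[float, np.ndarray] = {}
    if scene.class_label not in ("empty", "not_defined"):
        layers[0.0] = _zona_delta(scene)
    for b in scene.blastomeres:
        delta = _blastomere_delta(scene, b)
        layers[b.depth] = layers.get(b.depth, 0.0) + delta
    for f in scene.fragments:
        delta = _fragment_delta(scene, f)
        layers[f.depth] = layers.get(f.depth, 0.0) + delta
    return _background(scene), layers


def _add_noise(image: np.ndarray, rng: np.random.Generator,
               sigma: float) -> np.ndarray:
    if sigma > 0:
        image = image + rng.normal(0.0, sigma, size=image.shape)
    return np.clip(image, 0.0, 1.0)


def render_all_in_focus(scene: PhantomScene, noise_sigma: float = NOISE_SIGMA) -> np.ndarray:
    """Render the ideal extended-depth-of-field reference image.

    Every feature is rendered sharp regardless of its depth.  The reference
    carries the same additive sensor-noise model as the defocused planes (an
    independent realization), emulating an ideal all-in-focus capture by the
    same camera.
    """
    scene.validate()
    background, layers = _scene_layers(scene)
    image = background + sum(layers.values()) if layers else background
    return _add_noise(image, _rng(scene.background_seed, 41), noise_sigma)


def render_stack(scene: PhantomScene, delta_z: float = 1.0, blur_scale: float = 2.0,
                 noise_sigma: float = NOISE_SIGMA) -> FocalStack:
    """Render the 7-plane defocused focal stack of a scene.

    Plane ``F_k`` sits at focal offset ``k * delta_z`` micrometres
    (k = -3..+3).  A feature at depth ``z`` is convolved with an isotropic
    Gaussian of sigma ``blur_scale * |z - k*delta_z| / delta_z`` pixels, so
    its sharpest rendition appears in the plane nearest its own depth.
    """
    if not 0.5 <= delta_z <= 1.5:
        raise ValueError(f"delta_z must lie in [0.5, 1.5] micrometres, got {delta_z}")
    if blur_scale <= 0:
        raise ValueError("blur_scale must be positive")
    scene.validate()
    background, layers = _scene_layers(scene)
    noise_rng = _rng(scene.background_seed, 97)
    planes = []
    offsets = np.arange(-3, 4) * float(delta_z)
    for f in offsets:
        plane = background.copy()
        for depth, delta in layers.items():
            sigma = blur_scale * abs(depth - f) / delta_z
            plane += ndimage.gaussian_filter(delta, sigma) if sigma > 0 else delta
        planes.append(_add_noise(plane, noise_rng, noise_sigma))
    stack = FocalStack(planes=np.stack(planes), focal_offsets=offsets, delta_z=float(delta_z))
    stack.validate()
    return stack


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def apportion(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer per-class counts by largest-remainder apportionment.

    Proportions are renormalized to sum to 1 (the clinical distribution prints
    percentages summing to 99.9).  Floors are assigned first; remaining units
    go to the largest fractional parts, ties broken by class order.
    """
    keys = [c for c in CLASSES if c in proportions] + [
        k for k in proportions if k not in CLASSES
    ]
    values = np.array([proportions[k] for k in keys], dtype=np.float64)
    if np.any(values < 0):
        raise ValueError("proportions must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("proportions must sum to a positive value")
    quotas = n * values / total
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = sorted(range(len(keys)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(keys, (int(c) for c in counts)))


def _split_tags(n: int, rng: np.random.Generator) -> list[str]:
    counts = apportion(n, SPLIT_FRACTIONS)
    tags = (["train"] * counts["train"] + ["val"] * counts["val"] + ["test"] * counts["test"])
    perm = rng.permutation(n)
    return [tags[i] for i in perm]


def make_dataset(n: int, proportions: dict[str, float] | None = None,
                 delta_z: float = 1.0, seed: int = 0, image_size: int = 256,
                 blur_scale: float = 2.0) -> LabeledDataset:
    """Generate a labeled phantom dataset with stratified class counts.

    Per-class counts follow largest-remainder apportionment of ``proportions``
    (clinical distribution by default); split tags are assigned by a seeded
    shuffle at 68 / 12 / 20 percent.  Regeneration with the same arguments is
    bit-identical.
    """
    if n < 7:
        raise ValueError("need at least 7 items (one per class)")
    proportions = dict(proportions) if proportions is not None else dict(CLINICAL_PROPORTIONS)
    counts = apportion(n, proportions)

    items: list[DatasetItem] = []
    for label in CLASSES:
        for i in range(counts.get(label, 0)):
            scene_seed = int(_rng(seed, CLASSES.index(label), i, 12345).integers(0, 2**31 - 1))
            scene = make_scene(label, image_size=image_size, seed=scene_seed)
            stack = render_stack(scene, delta_z=delta_z, blur_scale=blur_scale)
            reference = render_all_in_focus(scene)
            items.append(DatasetItem(stack=stack, reference=reference,
                                     class_label=label, scene=scene))

    rng = _rng(seed, 777)
    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    split = _split_tags(len(items), _rng(seed, 778))
    return LabeledDataset(items=items, split_assignment=split, seed=seed)
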