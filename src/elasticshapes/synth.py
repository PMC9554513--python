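"""Synthetic labelled outline datasets.

Classes of closed planar outlines are generated from star-shaped Fourier
templates: a family is a radius function

    r(theta) = 1 + sum_j a_j cos(j theta) + b_j sin(j theta)

with random low-order harmonic amplitudes, and members of a class are the
template perturbed by vertex noise and dressed with the nuisance transforms
the shape methods must be invariant to — rotation, scaling, translation,
cyclic start-point shift and smooth monotone reparametrization.  Star
shapes guarantee simple (non-self-intersecting) closed curves with analytic
area and perimeter, which keeps every downstream stage testable without
real image data.  Binary raster masks are also produced so the contour
extraction path can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from skimage.draw import polygon as _fill_polygon

from .outlines import Outline

__all__ = [
    "ShapeFamily",
    "NuisanceSpec",
    "SyntheticDataset",
    "make_families",
    "make_nested_families",
    "sample_outline",
    "rasterize",
    "make_dataset",
]


@dataclass(frozen=True)
class ShapeFamily:
    """Star-shaped Fourier template for one synthetic class.

    ``harmonic_amplitudes`` holds (a_j, b_j) pairs, j = 1..n_harmonics,
    of the radius expansion about 1; the template must stay strictly
    star-shaped (radius > 0 for all angles).
    """

    family_id: str
    harmonic_amplitudes: np.ndarray  # shape (n_harmonics, 2)
    n_harmonics: int

    def __post_init__(self):
        amps = np.asarray(self.harmonic_amplitudes, dtype=float)
        if amps.shape != (self.n_harmonics, 2) or not np.all(np.isfinite(amps)):
            raise ValueError("harmonic_amplitudes must be a finite (n_harmonics, 2) array")
        object.__setattr__(self, "harmonic_amplitudes", amps)
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        if np.min(self.radius(theta)) <= 0:
            raise ValueError("template radius must be strictly positive")

    def radius(self, theta: np.ndarray) -> np.ndarray:
        r = np.ones_like(theta)
        for j in range(1, self.n_harmonics + 1):
            a, b = self.harmonic_amplitudes[j - 1]
            r = r + a * np.cos(j * theta) + b * np.sin(j * theta)
        return r

    def template(self, n_points: int = 100) -> Outline:
        theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
        r = self.radius(theta)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        return Outline(pts, closed=True, object_id=f"{self.family_id}_template", label=self.family_id)


@dataclass(frozen=True)
class NuisanceSpec:
    """Amplitudes of the transforms a shape method should ignore.

    ``reparam_strength`` is the total sine-perturbation amplitude of the
    monotone parameter warp and must stay < 1 so the warp derivative is
    positive; ``vertex_noise_sd`` is expressed as a fraction of the local
    template radius.
    """

    rotation_range: float = 0.0  # radians; angles drawn uniformly in [0, range)
    scale_range: tuple[float, float] = (1.0, 1.0)
    translation_range: float = 0.0
    start_shift: bool = False
    reparam_strength: float = 0.0
    vertex_noise_sd: float = 0.0

    def __post_init__(self):
        lo, hi = self.scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("scale_range must be a positive interval")
        if not 0 <= self.reparam_strength < 1:
            raise ValueError("reparam_strength must be in [0, 1) for a monotone warp")
        if self.vertex_noise_sd < 0 or self.rotation_range < 0 or self.translation_range < 0:
            raise ValueError("nuisance amplitudes must be non-negative")


@dataclass
class SyntheticDataset:
    """Balanced labelled outline dataset, reproducible from its seed."""

    outlines: list
    labels: list
    seed: int
    family_specs: list

    def __post_init__(self):
        if len(self.outlines) != len(self.labels):
            raise ValueError("labels must align 1:1 with outlines")

    def __len__(self) -> int:
        return len(self.outlines)

    def to_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "object_id": [o.object_id for o in self.outlines],
                "class": self.labels,
            }
        )

    def write(self, directory: str | Path) -> None:
        """One outline CSV per object plus a manifest table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for o, lab in zip(self.outlines, self.labels):
            fname = f"{o.object_id}.csv"
            pd.DataFrame(o.points, columns=["x", "y"]).to_csv(directory / fname, index=False)
            rows.append({"object_id": o.object_id, "class": lab, "file": fname})
        pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def make_families(
    n_classes: int,
    n_harmonics: int = 4,
    separation: float = 0.25,
    seed: int = 0,
) -> list[ShapeFamily]:
    """Draw ``n_classes`` distinct star-shaped templates.

    Harmonic amplitudes are i.i.d. normal with standard deviation
    ``separation / j`` for harmonic j (the 1/j decay keeps the templates
    smooth and star-shaped); ``separation`` therefore scales how far apart
    the class means sit in shape space.  Templates whose radius dips below
    0.2 are rejected and redrawn.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_harmonics < 1 or separation <= 0:
        raise ValueError("n_harmonics and separation must be positive")
    rng = np.random.default_rng(seed)
    fams: list[ShapeFamily] = []
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    for c in range(n_classes):
        for _ in range(1000):
            scales = separation / np.arange(1, n_harmonics + 1)
            amps = rng.normal(0.0, 1.0, size=(n_harmonics, 2)) * scales[:, None]
            r = 1.0 + sum(
                amps[j - 1, 0] * np.cos(j * theta) + amps[j - 1, 1] * np.sin(j * theta)
                for j in range(1, n_harmonics + 1)
            )
            if r.min() > 0.2:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a star-shaped template")
        fams.append(ShapeFamily(f"class_{c}", amps, n_harmonics))
    return fams


def make_nested_families(
    n_parents: int = 3,
    children_per_parent: int = 2,
    separation: float = 0.35,
    child_scale: float = 0.1,
    seed: int = 0,
) -> tuple[list[ShapeFamily], dict]:
    """Two-level class hierarchy: child classes perturb a parent template.

    Parents are drawn like :func:`make_families`; each child adds amplitude
    offsets of relative size ``child_scale`` (fraction of the parent draw
    scale), so classes of the same parent sit closer in shape space than
    classes of different parents — the structure a distance tree should
    recover as monophyletic groups.  Returns the child families plus a
    ``child_id -> parent_id`` map.
    """
    if children_per_parent < 1:
        raise ValueError("children_per_parent must be >= 1")
    if not 0 < child_scale < 1:
        raise ValueError("child_scale must be in (0, 1)")
    parents = make_families(n_parents, separation=separation, seed=seed)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    children: list[ShapeFamily] = []
    family_map: dict[str, str] = {}
    for p_idx, parent in enumerate(parents):
        scales = child_scale * separation / np.arange(1, parent.n_harmonics + 1)
        for c_idx in range(children_per_parent):
            for _ in range(1000):
                amps = parent.harmonic_amplitudes + rng.normal(
                    0.0, 1.0, size=parent.harmonic_amplitudes.shape
                ) * scales[:, None]
                child_id = f"fam{p_idx}_cls{c_idx}"
                try:
                    child = ShapeFamily(child_id, amps, parent.n_harmonics)
                except ValueError:
                    continue
                break
            else:  # pragma: no cover
                raise RuntimeError("could not draw a star-shaped child template")
            children.append(child)
            family_map[child_id] = f"fam{p_idx}"
    return children, family_map


def _monotone_warp(u: np.ndarray, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth strictly monotone warp of [0, 1): u + sum of small sines.

    The derivative is 1 + sum c_j cos(2 pi j u + phi_j) with sum |c_j| =
    strength < 1, so monotonicity is guaranteed by construction.
    """
    if strength == 0:
        return u
    n_modes = 3
    raw = rng.uniform(0.3, 1.0, n_modes)
    c = raw / raw.sum() * strength
    phi = rng.uniform(0, 2 * np.pi, n_modes)
    w = u.astype(float).copy()
    for j in range(1, n_modes + 1):
        w = w + c[j - 1] / (2 * np.pi * j) * (
            np.sin(2 * np.pi * j * u + phi[j - 1]) - np.sin(phi[j - 1])
        )
    return w


def sample_outline(
    family: ShapeFamily,
    nuisance: NuisanceSpec,
    n_points: int = 100,
    rng: np.random.Generator | int | None = None,
    object_id: str = "",
) -> Outline:
    """Draw one outline: template + vertex noise, then warp, shift, rotate,
    scale, translate."""
    if n_points < 20:
        raise ValueError("n_points must be >= 20")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    u = np.arange(n_points) / n_points
    u_warped = _monotone_warp(u, nuisance.reparam_strength, rng)
    if np.any(np.diff(u_warped) <= 0):  # defensive; excluded by the spec invariant
        raise RuntimeError("parameter warp lost monotonicity")
    theta = 2 * np.pi * u_warped
    r = family.radius(theta)
    if nuisance.vertex_noise_sd > 0:
        r = r * (1.0 + rng.normal(0.0, nuisance.vertex_noise_sd, n_points))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    if nuisance.start_shift:
        pts = np.roll(pts, -int(rng.integers(n_points)), axis=0)
    if nuisance.rotation_range > 0:
        ang = rng.uniform(0, nuisance.rotation_range)
        c, s = np.cos(ang), np.sin(ang)
        pts = pts @ np.array([[c, -s], [s, c]]).T
    lo, hi = nuisance.scale_range
    if hi > lo:
        pts = pts * rng.uniform(lo, hi)
    elif lo != 1.0:
        pts = pts * lo
    if nuisance.translation_range > 0:
        pts = pts + rng.uniform(-nuisance.translation_range, nuisance.translation_range, 2)
    return Outline(pts, closed=True, object_id=object_id or f"{family.family_id}_sample", label=family.family_id)


def rasterize(outline: Outline, image_size: int = 400, margin: float = 0.05) -> np.ndarray:
    """Fill a simple closed outline into a boolean mask.

    The polygon is scaled to fit ``image_size`` with the requested margin
    fraction on every side; a border of background pixels is always kept.
    y-up coordinates map to image rows top-down.
    """
    if not outline.closed:
        raise ValueError("rasterize needs a closed outline")
    if not 0 <= margin < 0.5:
        raise ValueError("margin must be in [0, 0.5)")
    ring = shapely.LinearRing(outline.points)
    if not ring.is_simple:
        raise ValueError("outline is self-intersecting")
    pts = outline.points
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = max(hi - lo)
    if span <= 0:
        raise ValueError("degenerate outline")
    pad = max(margin * image_size, 1.0)
    scale = (image_size - 1 - 2 * pad) / span
    scaled = (pts - (lo + hi) / 2) * scale + (image_size - 1) / 2
    rows = (image_size - 1) - scaled[:, 1]
    cols = scaled[:, 0]
    rr, cc = _fill_polygon(rows, cols, shape=(image_size, image_size))
    mask = np.zeros((image_size, image_size), dtype=bool)
    mask[rr, cc] = True
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    return mask


def make_dataset(
    families,
    nuisance: NuisanceSpec,
    n_per_class: int = 30,
    n_points: int = 100,
    seed: int = 0,
) -> SyntheticDataset:
    """Balanced labelled dataset: ``n_per_class`` draws per family.

    A single seeded generator is split into one independent child stream
    per object, so each outline is reproducible on its own.
    """
    families = list(families)
    if not families:
        raise ValueError("empty family list")
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    root = np.random.default_rng(seed)
    streams = root.spawn(len(families) * n_per_class)
    outlines, labels = [], []
    k = 0
    for fam in families:
        for i in range(n_per_class):
            o = sample_outline(
                fam, nuisance, n_points=n_points, rng=streams[k],
                object_id=f"{fam.family_id}_obj{i:03d}",
            )
            outlines.append(o)
            labels.append(fam.family_id)
            k += 1
    return SyntheticDataset(outlines, labels, seed, families)
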