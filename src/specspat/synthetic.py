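"""Synthetic labeled hyperspectral scenes for testing and benchmarking.

Scenes are built from spatially contiguous class regions (rectangular
blocks or Voronoi cells), smooth per-class spectral signatures over the
bands, linear mixing at region boundaries, additive Gaussian noise, and an
optional scattered background fraction.  All randomness flows through
``numpy.random.default_rng`` so scenes are bit-identical across platforms
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter

from .core import HyperCube, LabelMap, ProbabilityMap

__all__ = ["SceneSpec", "make_scene", "corrupt_seed", "make_transfer_pair",
           "one_hot_seed"]

#: Smallest class footprint accepted, so stratified sampling stays feasible.
MIN_CLASS_PIXELS = 20


@dataclass
class SceneSpec:
    """Recipe for one synthetic scene."""

    m: int = 40
    n: int = 40
    d: int = 30
    k: int = 3
    layout: str = "rectangles"
    signature_smoothness: float = 4.0
    class_separation: float = 8.0
    noise_sd: float = 0.05
    mixed_boundary_width: int = 0
    background_fraction: float = 0.0
    open_set_classes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 classes")
        if self.class_separation <= 0:
            raise ValueError("class_separation must be positive")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.layout not in ("rectangles", "voronoi"):
            raise ValueError("layout must be 'rectangles' or 'voronoi'")
        if self.noise_sd < 0 or self.mixed_boundary_width < 0:
            raise ValueError("noise_sd and mixed_boundary_width must be >= 0")
        if not 0 <= self.open_set_classes < self.k:
            raise ValueError("open_set_classes must lie in [0, k)")


def _separation_target(spec: SceneSpec) -> float:
    # separation is expressed in noise-SD units; for noiseless scenes fall
    # back to a fixed small unit so signatures still stay distinct
    return spec.class_separation * (spec.noise_sd if spec.noise_sd > 0 else 0.01)


def _smooth_curves(rng: np.random.Generator, k: int, d: int,
                   smoothness: float) -> np.ndarray:
    raw = rng.standard_normal((k, d))
    if smoothness > 0:
        raw = gaussian_filter1d(raw, sigma=smoothness, axis=1, mode="reflect")
    return raw


def _enforce_separation(signatures: np.ndarray, target: float) -> np.ndarray:
    """Scale deviations from the mean curve until the closest signature
    pair sits at least ``target`` apart (shape is preserved)."""
    k = signatures.shape[0]
    center = signatures.mean(axis=0, keepdims=True)
    dev = signatures - center
    dmat = np.linalg.norm(dev[:, None, :] - dev[None, :, :], axis=2)
    dmin = dmat[~np.eye(k, dtype=bool)].min()
    if dmin <= 0:
        raise ValueError("degenerate signatures; try another seed")
    if dmin < target:
        dev = dev * (target / dmin)
    return center + dev


def _draw_signatures(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    sig = _smooth_curves(rng, spec.k, spec.d, spec.signature_smoothness)
    return _enforce_separation(sig, _separation_target(spec))


def _rectangle_layout(spec: SceneSpec) -> np.ndarray:
    """Block grid with classes assigned round-robin; regions contiguous."""
    nb = int(np.ceil(np.sqrt(spec.k)))
    row_edges = np.linspace(0, spec.m, nb + 1).astype(int)
    col_edges = np.linspace(0, spec.n, nb + 1).astype(int)
    labels = np.zeros((spec.m, spec.n), dtype=np.int32)
    block = 0
    for bi in range(nb):
        for bj in range(nb):
            cls = block % spec.k + 1
            labels[row_edges[bi]:row_edges[bi + 1],
                   col_edges[bj]:col_edges[bj + 1]] = cls
            block += 1
    return labels


def _voronoi_layout(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    n_sites = max(spec.k, 2 * spec.k)
    sites = np.stack([rng.uniform(0, spec.m, n_sites),
                      rng.uniform(0, spec.n, n_sites)], axis=1)
    site_cls = np.arange(n_sites) % spec.k + 1
    rows, cols = np.mgrid[0:spec.m, 0:spec.n]
    pts = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(np.float64)
    d2 = ((pts[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    labels = site_cls[np.argmin(d2, axis=1)].reshape(spec.m, spec.n)
    return labels.astype(np.int32)


def _mix_fractions(labels: np.ndarray, k: int, width: int) -> np.ndarray:
    """Per-pixel class fractions after box-window linear boundary mixing."""
    m, n = labels.shape
    frac = np.zeros((m, n, k))
    for cls in range(1, k + 1):
        frac[:, :, cls - 1] = (labels == cls).astype(np.float64)
    if width > 0:
        size = 2 * width + 1
        for c in range(k):
            frac[:, :, c] = uniform_filter(frac[:, :, c], size=size, mode="reflect")
        frac /= frac.sum(axis=2, keepdims=True)
    return frac


def _render(spec: SceneSpec, signatures: np.ndarray,
            rng: np.random.Generator) -> tuple[HyperCube, LabelMap]:
    labels = _rectangle_layout(spec) if spec.layout == "rectangles" \
        else _voronoi_layout(spec, rng)
    frac = _mix_fractions(labels, spec.k, spec.mixed_boundary_width)
    clean = frac @ signatures  # (M, N, D)
    noise = rng.normal(0.0, spec.noise_sd, size=clean.shape) if spec.noise_sd > 0 \
        else 0.0
    values = clean + noise
    if spec.background_fraction > 0:
        n_bg = int(round(spec.background_fraction * spec.m * spec.n))
        flat = rng.choice(spec.m * spec.n, size=n_bg, replace=False)
        labels = labels.copy()
        labels.ravel()[flat] = 0
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if len(ids) < spec.k or counts.min() < MIN_CLASS_PIXELS:
        raise ValueError(
            f"scene spec infeasible: a class would occupy fewer than "
            f"{MIN_CLASS_PIXELS} pixels (got {dict(zip(ids.tolist(), counts.tolist()))})"
        )
    cube = HyperCube(values=values)
    return cube, LabelMap(labels)


def make_scene(spec: SceneSpec) -> tuple[HyperCube, LabelMap]:
    """Generate one labeled scene; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    signatures = _draw_signatures(rng, spec)
    return _render(spec, signatures, rng)


def one_hot_seed(labels: LabelMap, class_ids: np.ndarray | None = None) -> ProbabilityMap:
    """One-hot probability map over the labeled pixels of a raster."""
    rows, cols = np.nonzero(labels.labels > 0)
    lab = labels.labels[rows, cols]
    if class_ids is None:
        class_ids = np.unique(lab)
    class_ids = np.asarray(class_ids, dtype=np.int32)
    probs = np.zeros((len(lab), len(class_ids)))
    probs[np.arange(len(lab)), np.searchsorted(class_ids, lab)] = 1.0
    return ProbabilityMap(probs=probs, class_ids=class_ids,
                          pixel_coords=np.stack([rows, cols], axis=1))


def corrupt_seed(prob_map: ProbabilityMap, flip_rate: float,
                 seed: int = 0) -> ProbabilityMap:
    """Reassign the probability mass of an exact fraction of pixels to a
    random wrong class (one-hot); rows keep summing to 1."""
    if not 0 <= flip_rate < 1:
        raise ValueError("flip_rate must lie in [0, 1)")
    n = prob_map.probs.shape[0]
    k = prob_map.n_classes
    n_flip = int(round(flip_rate * n))
    probs = prob_map.probs.copy()
    if n_flip:
        rng = np.random.default_rng(seed)
        picks = rng.choice(n, size=n_flip, replace=False)
        current = np.argmax(probs[picks], axis=1)
        shift = rng.integers(1, k, size=n_flip)
        wrong = (current + shift) % k
        probs[picks] = 0.0
        probs[picks, wrong] = 1.0
    return replace(prob_map, probs=probs)


def make_transfer_pair(spec_train: SceneSpec, spec_infer: SceneSpec,
                       max_passes: int = 100) -> tuple[tuple[HyperCube, LabelMap],
                                                       tuple[HyperCube, LabelMap]]:
    """Two scenes whose class signatures are mutually separated, for
    fixed-parameter cross-scene transfer with training-disjoint classes."""
    if spec_infer.open_set_classes < 1:
        raise ValueError("spec_infer must declare at least one open-set class")
    target = max(_separation_target(spec_train), _separation_target(spec_infer))
    rng_a = np.random.default_rng(spec_train.seed)
    sig_a = _draw_signatures(rng_a, spec_train)
    rng_b = np.random.default_rng(spec_infer.seed)
    sig_b = _draw_signatures(rng_b, spec_infer)
    for _ in range(max_passes):
        dists = np.linalg.norm(sig_b[:, None, :] - sig_a[None, :, :], axis=2)
        if dists.min() >= target:
            break
        # push each too-close inference signature away from its nearest
        # training signature along the separating direction
        for bi in range(sig_b.shape[0]):
            ai = int(np.argmin(dists[bi]))
            gap = dists[bi, ai]
            if gap >= target:
                continue
            direction = sig_b[bi] - sig_a[ai]
            norm = np.linalg.norm(direction)
            if norm == 0:
                direction = gaussian_filter1d(
                    rng_b.standard_normal(spec_infer.d),
                    sigma=max(spec_infer.signature_smoothness, 1e-6),
                    mode="reflect")
                norm = np.linalg.norm(direction)
            sig_b[bi] = sig_a[ai] + direction / norm * target
        sig_b = _enforce_separation(sig_b, _separation_target(spec_infer))
    else:
        raise ValueError("could not separate transfer-pair signatures")
    scene_a = _render(spec_train, sig_a, rng_a)
    scene_b = _render(spec_infer, sig_b, rng_b)
    return scene_a, scene_b
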