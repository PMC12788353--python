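"""Iterative spectral-spatial label refinement.

The seed probability map from the pixel-wise classifier is refined by
sequentially assigning each pixel the class of lowest neighborhood energy,
where the energy trades spectral similarity against spatial nearness:

* spatial nearness kernel ``S``: Gaussian in pixel-grid offset,
  ``S(u, v) = exp(-(u^2 + v^2) / (2 sigma_s^2))``, center excluded;
* spectral similarity kernel ``W``: Gaussian in feature distance,
  ``W_ij = exp(-||f_i - f_j||^2 / (2 sigma_w^2))``, computed on the
  mirror-padded feature raster so border pixels keep full neighborhoods.

Two algebraic forms of the per-class energy are available (they differ in
where the trade-off weight ``beta`` sits):

* ``eq11_grouped`` (default)::

      E_i(k) = - sum_{j in N(i)} [ (1-beta) W_ij P_j(k)
                                   + beta (S_ij P_j(k) + I(k, w_j)) ]

* ``eq9``::

      E_i(k) = - sum_{j in N(i)} [ (1-beta) (W_ij + S_ij) P_j(k)
                                   + beta I(k, w_j) ]

with ``I(k, w_j) = +1`` if neighbor j currently carries label k, else -1.
Neighbor terms falling on background pixels contribute 0.  After each full
sweep the conditional probabilities are re-expressed through a stabilized
softmax of the negated energies, and the outer loop stops once their total
L1 change between iterations drops below ``epsilon``.

``P_j`` in the energy is, by default, the *seed* probability map for every
outer iteration (``prob_update="anchored"``): the pixel classifier's output
acts as a fixed data term, labels alone evolve between sweeps, and the loop
reaches an exact fixed point once labels stop changing.  The alternative
``prob_update="iterated"`` feeds each iteration's softmax back into the
energy; it is offered for comparison but erodes class boundaries as
iterations accumulate and rarely meets a tight ``epsilon``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import LabelMap, ProbabilityMap

__all__ = [
    "RefineParams",
    "KernelStack",
    "RefineState",
    "spatial_kernel",
    "spectral_kernel",
    "build_kernels",
    "class_energies",
    "class_energy",
    "icm_sweep",
    "update_probabilities",
    "refine",
    "weak_label_feedback",
]

POTENTIAL_FORMS = ("eq11_grouped", "eq9")

#: Fixed transfer parameter set: carried unchanged across scenes, leaving
#: only the SVM cost (and optionally its kernel width) to re-tune.
TRANSFER_PARAMS = {"r": 4, "sigma_w": 1.3, "sigma_s": 1.3, "beta": 0.4}


@dataclass
class RefineParams:
    """Knobs of the refinement energy and its outer loop."""

    r: int = 4
    sigma_s: float = 1.3
    sigma_w: float = 1.3
    beta: float = 0.4
    epsilon: float = 1e-4
    max_outer: int = 20
    potential_form: str = "eq11_grouped"
    prob_update: str = "anchored"

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("neighborhood radius r must be >= 1")
        if self.sigma_s <= 0 or self.sigma_w <= 0:
            raise ValueError("kernel widths must be positive")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_outer < 1:
            raise ValueError("max_outer must be >= 1")
        if self.potential_form not in POTENTIAL_FORMS:
            raise ValueError(f"potential_form must be one of {POTENTIAL_FORMS}")
        if self.prob_update not in ("anchored", "iterated"):
            raise ValueError("prob_update must be 'anchored' or 'iterated'")


@dataclass
class KernelStack:
    """Precomputed neighborhood weights.

    ``S`` is the ``(2r+1, 2r+1)`` spatial offset grid with the center entry
    zeroed (the reference pixel is not its own neighbor); ``W`` holds the
    per-pixel spectral weights, shape ``(M, N, 2r+1, 2r+1)``.
    """

    S: np.ndarray
    W: np.ndarray
    r: int

    def __post_init__(self) -> None:
        w = 2 * self.r + 1
        if self.S.shape != (w, w):
            raise ValueError(f"S must be ({w}, {w})")
        if self.W.ndim != 4 or self.W.shape[2:] != (w, w):
            raise ValueError(f"W must be (M, N, {w}, {w})")


@dataclass
class RefineState:
    """Labels + probabilities tracked across outer iterations.

    ``labels`` is the full raster with external class ids (0 background);
    it is the argmax decision of the most recent sweep, not of ``probs``.
    """

    labels: np.ndarray
    probs: ProbabilityMap
    iteration: int = 0
    delta_history: list[float] = field(default_factory=list)
    converged: bool = False


def spatial_kernel(r: int, sigma_s: float, exclude_center: bool = True) -> np.ndarray:
    """Gaussian weight grid over pixel offsets ``(u, v) in [-r, r]^2``."""
    if r < 1:
        raise ValueError("r must be >= 1")
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    u = np.arange(-r, r + 1, dtype=np.float64)
    d2 = u[:, None] ** 2 + u[None, :] ** 2
    s = np.exp(-d2 / (2.0 * sigma_s**2))
    if exclude_center:
        s[r, r] = 0.0
    return s


def spectral_kernel(padded_features: np.ndarray, r: int, sigma_w: float) -> np.ndarray:
    """Per-pixel Gaussian similarity to each neighbor offset.

    ``padded_features`` is the ``(M+2r, N+2r, d)`` mirror-padded feature
    raster.  Returns ``W`` of shape ``(M, N, 2r+1, 2r+1)`` with
    ``W[i, j, r+u, r+v] = exp(-||f_ij - f_(i+u)(j+v)||^2 / (2 sigma_w^2))``.
    """
    padded_features = np.asarray(padded_features, dtype=np.float64)
    if padded_features.ndim == 2:
        padded_features = padded_features[:, :, None]
    if sigma_w <= 0:
        raise ValueError("sigma_w must be positive")
    if not np.all(np.isfinite(padded_features)):
        raise ValueError("features must be finite")
    mp, np_, _ = padded_features.shape
    m, n = mp - 2 * r, np_ - 2 * r
    if m < 1 or n < 1:
        raise ValueError("padded raster too small for the given radius")
    center = padded_features[r:r + m, r:r + n, :]
    w = np.empty((m, n, 2 * r + 1, 2 * r + 1), dtype=np.float64)
    inv = 1.0 / (2.0 * sigma_w**2)
    for du in range(-r, r + 1):
        for dv in range(-r, r + 1):
            nb = padded_features[r + du:r + du + m, r + dv:r + dv + n, :]
            d2 = np.einsum("ijk,ijk->ij", nb - center, nb - center)
            w[:, :, r + du, r + dv] = np.exp(-d2 * inv)
    return w


def build_kernels(features_raster: np.ndarray, params: RefineParams) -> KernelStack:
    """Pad the feature raster and assemble both kernels."""
    features_raster = np.asarray(features_raster, dtype=np.float64)
    if features_raster.ndim == 2:
        features_raster = features_raster[:, :, None]
    padded = np.pad(features_raster, ((params.r, params.r),) * 2 + ((0, 0),),
                    mode="symmetric")
    return KernelStack(S=spatial_kernel(params.r, params.sigma_s),
                       W=spectral_kernel(padded, params.r, params.sigma_w),
                       r=params.r)


# ---------------------------------------------------------------------------
# internal raster bookkeeping


def _reflect_index(n: int, r: int) -> np.ndarray:
    """Length ``n + 2r`` map from padded positions to in-raster indices,
    matching edge-including symmetric reflection."""
    return np.pad(np.arange(n), r, mode="symmetric")


class _Grid:
    """Raster-form views of a RefineState shared by the energy routines."""

    def __init__(self, state: RefineState, kernels: KernelStack):
        pm = state.probs
        self.class_ids = pm.class_ids
        self.k = len(self.class_ids)
        self.m, self.n = state.labels.shape
        self.r = kernels.r
        coords = pm.pixel_coords
        self.valid = np.zeros((self.m, self.n), dtype=bool)
        self.valid[coords[:, 0], coords[:, 1]] = True
        self.p_raster = np.zeros((self.m, self.n, self.k))
        self.p_raster[coords[:, 0], coords[:, 1], :] = pm.probs
        # internal labels: column index into class_ids, -1 for background
        lab = np.full((self.m, self.n), -1, dtype=np.int32)
        ext = state.labels[self.valid]
        pos = np.searchsorted(self.class_ids, ext)
        if np.any(pos >= self.k) or np.any(self.class_ids[np.minimum(pos, self.k - 1)] != ext):
            raise ValueError("state labels contain ids outside the seed class set")
        lab[self.valid] = pos
        self.labels_int = lab
        self.row_map = _reflect_index(self.m, self.r)
        self.col_map = _reflect_index(self.n, self.r)

    def coefficients(self, kernels: KernelStack, params: RefineParams) -> np.ndarray:
        """Per-offset weight on the neighbor probability term."""
        if params.potential_form == "eq11_grouped":
            return (1.0 - params.beta) * kernels.W + params.beta * kernels.S
        return (1.0 - params.beta) * (kernels.W + kernels.S)

    def prob_support(self, kernels: KernelStack, params: RefineParams) -> np.ndarray:
        """``A[i, k] = -sum_j coef_ij P_j(k)`` over valid neighbors."""
        r, m, n, k = self.r, self.m, self.n, self.k
        coef = self.coefficients(kernels, params)
        pv = self.p_raster * self.valid[:, :, None]
        ppad = np.pad(pv, ((r, r), (r, r), (0, 0)), mode="symmetric")
        a = np.zeros((m, n, k))
        for du in range(2 * r + 1):
            for dv in range(2 * r + 1):
                if du == r and dv == r:
                    continue
                a -= coef[:, :, du, dv, None] * ppad[du:du + m, dv:dv + n, :]
        return a

    def neighbor_index_table(self) -> np.ndarray:
        """Flat in-raster index of each neighbor, shape ``(M*N, nn)``."""
        r = self.r
        offsets = [(du, dv) for du in range(2 * r + 1) for dv in range(2 * r + 1)
                   if not (du == r and dv == r)]
        rows = np.arange(self.m)[:, None]
        cols = np.arange(self.n)[None, :]
        tables = []
        for du, dv in offsets:
            nr = self.row_map[rows + du]
            nc = self.col_map[cols + dv]
            tables.append((nr * self.n + nc).ravel())
        return np.stack(tables, axis=1).astype(np.int64)

    def indicator_energy(self, labels_int: np.ndarray, beta: float) -> np.ndarray:
        """Vectorized ``-beta sum_j I(k, w_j)`` over valid neighbors."""
        r, m, n, k = self.r, self.m, self.n, self.k
        onehot = np.zeros((m, n, k))
        vi = labels_int >= 0
        onehot[vi, labels_int[vi]] = 1.0
        opad = np.pad(onehot, ((r, r), (r, r), (0, 0)), mode="symmetric")
        vpad = np.pad(vi.astype(np.float64), r, mode="symmetric")
        counts = np.zeros((m, n, k))
        nvalid = np.zeros((m, n))
        for du in range(2 * r + 1):
            for dv in range(2 * r + 1):
                if du == r and dv == r:
                    continue
                counts += opad[du:du + m, dv:dv + n, :]
                nvalid += vpad[du:du + m, dv:dv + n]
        # sum_j I(k, w_j) = counts_k - (nvalid - counts_k)
        return beta * (nvalid[:, :, None] - 2.0 * counts)


def class_energies(state: RefineState, kernels: KernelStack,
                   params: RefineParams) -> np.ndarray:
    """Energy of every (pixel, class) pair under the current state.

    Returns an ``(M, N, K)`` array; rows at background pixels are computed
    but carry no meaning.
    """
    grid = _Grid(state, kernels)
    return grid.prob_support(kernels, params) + grid.indicator_energy(
        grid.labels_int, params.beta)


def class_energy(state: RefineState, pixel: tuple[int, int], class_id: int,
                 kernels: KernelStack, params: RefineParams) -> float:
    """Energy of assigning ``class_id`` to one pixel (scalar convenience)."""
    grid = _Grid(state, kernels)
    ks = np.searchsorted(grid.class_ids, class_id)
    if ks >= grid.k or grid.class_ids[ks] != class_id:
        raise ValueError(f"unknown class id {class_id}")
    i, j = pixel
    r = grid.r
    coef = grid.coefficients(kernels, params)
    e = 0.0
    for du in range(-r, r + 1):
        for dv in range(-r, r + 1):
            if du == 0 and dv == 0:
                continue
            ni = grid.row_map[i + du + r]
            nj = grid.col_map[j + dv + r]
            if not grid.valid[ni, nj]:
                continue
            e -= coef[i, j, du + r, dv + r] * grid.p_raster[ni, nj, ks]
            ind = 1.0 if grid.labels_int[ni, nj] == ks else -1.0
            e -= params.beta * ind
    return float(e)


def icm_sweep(state: RefineState, kernels: KernelStack, params: RefineParams,
              clamp_mask: np.ndarray | None = None) -> RefineState:
    """One full pass of lowest-energy reassignment in raster order.

    Labels of earlier-visited pixels are already updated when later pixels
    are evaluated (Gauss-Seidel); probabilities stay fixed for the whole
    sweep.  Ties go to the smallest class id.  Pixels under ``clamp_mask``
    keep their labels but still influence their neighbors.
    """
    grid = _Grid(state, kernels)
    beta = params.beta
    a_flat = grid.prob_support(kernels, params).reshape(-1, grid.k)
    nbr_idx = grid.neighbor_index_table()
    labels_flat = grid.labels_int.ravel().copy()
    visit = np.nonzero(grid.valid.ravel())[0]
    if clamp_mask is not None:
        clamp_flat = np.asarray(clamp_mask, dtype=bool).ravel()
        visit = visit[~clamp_flat[visit]]
    for p in visit:
        lab = labels_flat[nbr_idx[p]]
        lab = lab[lab >= 0]
        counts = np.bincount(lab, minlength=grid.k)
        e = a_flat[p] + beta * lab.size - 2.0 * beta * counts
        labels_flat[p] = int(np.argmin(e))
    new_int = labels_flat.reshape(grid.m, grid.n)
    new_ext = np.zeros((grid.m, grid.n), dtype=np.int32)
    new_ext[grid.valid] = grid.class_ids[new_int[grid.valid]]
    return dataclasses.replace(state, labels=new_ext)


def update_probabilities(state: RefineState, kernels: KernelStack,
                         params: RefineParams) -> ProbabilityMap:
    """Softmax of the negated class energies, stabilized per pixel."""
    energies = class_energies(state, kernels, params)
    coords = state.probs.pixel_coords
    e = energies[coords[:, 0], coords[:, 1], :]
    logits = -(e - e.min(axis=1, keepdims=True))
    expv = np.exp(logits)
    probs = expv / expv.sum(axis=1, keepdims=True)
    return dataclasses.replace(state.probs, probs=probs)


def _init_state(seed: ProbabilityMap, shape: tuple[int, int],
                labels_known: np.ndarray | None) -> tuple[RefineState, np.ndarray | None]:
    labels = seed.to_label_map(shape).labels
    clamp = None
    if labels_known is not None:
        known = labels_known.labels if isinstance(labels_known, LabelMap) \
            else np.asarray(labels_known, dtype=np.int32)
        if known.shape != shape:
            raise ValueError("labels_known shape must match the raster")
        clamp = known > 0
        labels = labels.copy()
        labels[clamp] = known[clamp]
    return RefineState(labels=labels, probs=seed), clamp


def refine(seed: ProbabilityMap, features_raster: np.ndarray,
           labels_known: LabelMap | np.ndarray | None = None,
           params: RefineParams | None = None,
           kernels: KernelStack | None = None) -> RefineState:
    """Run sweep + probability-update outer iterations to convergence.

    Stops when the summed L1 probability change drops to ``epsilon`` or
    after ``max_outer`` iterations; non-convergence is reported through the
    ``converged`` flag, never raised.
    """
    params = params or RefineParams()
    features_raster = np.asarray(features_raster, dtype=np.float64)
    if features_raster.ndim == 2:
        features_raster = features_raster[:, :, None]
    shape = features_raster.shape[:2]
    if kernels is None:
        kernels = build_kernels(features_raster, params)
    state, clamp = _init_state(seed, shape, labels_known)
    history: list[float] = []
    converged = False
    prev = seed.probs
    for n in range(params.max_outer):
        if params.prob_update == "anchored":
            state = dataclasses.replace(state, probs=seed)
        state = icm_sweep(state, kernels, params, clamp_mask=clamp)
        new_probs = update_probabilities(state, kernels, params)
        delta = float(np.abs(new_probs.probs - prev).sum())
        prev = new_probs.probs
        state = dataclasses.replace(state, probs=new_probs, iteration=n + 1)
        history.append(delta)
        if delta <= params.epsilon:
            converged = True
            break
    return dataclasses.replace(state, delta_history=history, converged=converged)


def weak_label_feedback(result: RefineState, features_raster: np.ndarray,
                        params: RefineParams | None = None, n_runs: int = 1,
                        labels_known: LabelMap | np.ndarray | None = None) -> RefineState:
    """Feed the refined probability map back as the seed, ``n_runs`` times."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    params = params or RefineParams()
    features_raster = np.asarray(features_raster, dtype=np.float64)
    if features_raster.ndim == 2:
        features_raster = features_raster[:, :, None]
    kernels = build_kernels(features_raster, params)
    state = result
    for _ in range(n_runs):
        state = refine(state.probs, features_raster, labels_known=labels_known,
                       params=params, kernels=kernels)
    return state
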