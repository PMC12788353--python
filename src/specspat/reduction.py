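"""Linear spectral dimensionality reduction by explained-variance threshold."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import PixelTable

__all__ = ["SpectralProjection", "fit_projection", "project"]

#: Default cumulative explained-variance ratio used throughout the pipeline.
DEFAULT_EVR_THRESHOLD = 0.92
#: Default cap on retained components; classification accuracy saturates
#: well before the variance curve does.
DEFAULT_D_CAP = 18


@dataclass
class SpectralProjection:
    """Principal-subspace projection ``z = Ud^T (x - mean)``.

    ``components`` holds the leading ``d`` orthonormal eigenvectors of the
    feature covariance as columns; ``eigenvalues`` is the full nonincreasing
    spectrum so the explained-variance curve can be audited after fitting.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    d: int
    evr_threshold: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.components = np.asarray(self.components, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64).ravel()
        if self.components.shape != (self.mean.size, self.d):
            raise ValueError("components must be (D, d)")
        gram = self.components.T @ self.components
        if not np.allclose(gram, np.eye(self.d), atol=1e-8):
            raise ValueError("projection columns must be orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be nonincreasing")

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, mean=self.mean, components=self.components,
                            eigenvalues=self.eigenvalues, d=self.d,
                            evr_threshold=self.evr_threshold)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SpectralProjection":
        with np.load(path, allow_pickle=False) as npz:
            return cls(mean=npz["mean"], components=npz["components"],
                       eigenvalues=npz["eigenvalues"], d=int(npz["d"]),
                       evr_threshold=float(npz["evr_threshold"]))


def _as_matrix(table: PixelTable | np.ndarray) -> np.ndarray:
    if isinstance(table, PixelTable):
        return table.features
    return np.asarray(table, dtype=np.float64)


def fit_projection(table: PixelTable | np.ndarray,
                   evr_threshold: float = DEFAULT_EVR_THRESHOLD,
                   d_cap: int | None = None) -> SpectralProjection:
    """Fit the principal subspace retaining the smallest ``d`` whose
    cumulative explained-variance ratio reaches ``evr_threshold``.

    ``d_cap``, if given, clips ``d`` after threshold selection.
    """
    x = _as_matrix(table)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    if not 0 < evr_threshold <= 1:
        raise ValueError("evr_threshold must lie in (0, 1]")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / (x.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(eigvecs.shape[1])])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    total = eigvals.sum()
    if total <= 0:
        d = 1
    else:
        cum = np.cumsum(eigvals) / total
        d = int(np.searchsorted(cum, evr_threshold - 1e-12) + 1)
        d = min(d, len(eigvals))
    if d_cap is not None:
        if d_cap < 1:
            raise ValueError("d_cap must be >= 1")
        d = min(d, d_cap)
    return SpectralProjection(mean=mean, components=eigvecs[:, :d],
                              eigenvalues=eigvals, d=d,
                              evr_threshold=evr_threshold)


def project(projection: SpectralProjection,
            table: PixelTable | np.ndarray) -> np.ndarray:
    """Project features onto the fitted subspace: ``(X - mean) @ Ud``."""
    x = _as_matrix(table)
    if x.shape[-1] != projection.mean.size:
        raise ValueError(
            f"feature dimension {x.shape[-1]} does not match projection "
            f"dimension {projection.mean.size}"
        )
    return (x - projection.mean) @ projection.components
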