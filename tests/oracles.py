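"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain index-by-index loops with explicit
boundary reflection, deliberately sharing no code with the package's
vectorized paths.
"""

from __future__ import annotations

import numpy as np


def reflect_index(x: int, n: int) -> int:
    """Edge-including symmetric reflection of an out-of-range index."""
    while x < 0 or x >= n:
        if x < 0:
            x = -x - 1
        if x >= n:
            x = 2 * n - x - 1
    return x


def mirror_pad_oracle(arr: np.ndarray, r: int) -> np.ndarray:
    m, n = arr.shape[:2]
    out = np.empty((m + 2 * r, n + 2 * r) + arr.shape[2:], dtype=arr.dtype)
    for i in range(-r, m + r):
        for j in range(-r, n + r):
            out[i + r, j + r] = arr[reflect_index(i, m), reflect_index(j, n)]
    return out


def spectral_kernel_oracle(features: np.ndarray, r: int, sigma_w: float) -> np.ndarray:
    """Per-pair loop over the *unpadded* raster with explicit reflection."""
    m, n = features.shape[:2]
    w = np.empty((m, n, 2 * r + 1, 2 * r + 1))
    for i in range(m):
        for j in range(n):
            fi = features[i, j]
            for du in range(-r, r + 1):
                for dv in range(-r, r + 1):
                    fj = features[reflect_index(i + du, m), reflect_index(j + dv, n)]
                    d2 = float(np.sum((fi - fj) ** 2))
                    w[i, j, du + r, dv + r] = np.exp(-d2 / (2.0 * sigma_w**2))
    return w


def energy_oracle(labels_int: np.ndarray, p_raster: np.ndarray,
                  valid: np.ndarray, w: np.ndarray, s: np.ndarray,
                  beta: float, form: str, r: int,
                  i: int, j: int, k: int) -> float:
    """Energy of assigning class column ``k`` to pixel (i, j)."""
    m, n = labels_int.shape
    e = 0.0
    for du in range(-r, r + 1):
        for dv in range(-r, r + 1):
            if du == 0 and dv == 0:
                continue
            ni = reflect_index(i + du, m)
            nj = reflect_index(j + dv, n)
            if not valid[ni, nj]:
                continue
            wij = w[i, j, du + r, dv + r]
            sij = s[du + r, dv + r]
            pj = p_raster[ni, nj, k]
            ind = 1.0 if labels_int[ni, nj] == k else -1.0
            if form == "eq11_grouped":
                e -= (1 - beta) * wij * pj + beta * (sij * pj + ind)
            elif form == "eq9":
                e -= (1 - beta) * (wij + sij) * pj + beta * ind
            else:
                raise ValueError(form)
    return e


def all_energies_oracle(labels_int, p_raster, valid, w, s, beta, form, r):
    m, n = labels_int.shape
    k = p_raster.shape[2]
    out = np.zeros((m, n, k))
    for i in range(m):
        for j in range(n):
            for kk in range(k):
                out[i, j, kk] = energy_oracle(labels_int, p_raster, valid, w, s,
                                              beta, form, r, i, j, kk)
    return out


def sweep_oracle(labels_int, p_raster, valid, w, s, beta, form, r):
    """Raster-order lowest-energy reassignment with live label updates."""
    lab = labels_int.copy()
    m, n = lab.shape
    k = p_raster.shape[2]
    for i in range(m):
        for j in range(n):
            if not valid[i, j]:
                continue
            energies = [energy_oracle(lab, p_raster, valid, w, s, beta, form,
                                      r, i, j, kk) for kk in range(k)]
            lab[i, j] = int(np.argmin(energies))
    return lab


def confusion_oracle(truth: np.ndarray, pred: np.ndarray, class_ids) -> np.ndarray:
    k = len(class_ids)
    idx = {c: i for i, c in enumerate(class_ids)}
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(truth.ravel(), pred.ravel()):
        if t > 0:
            counts[idx[t], idx[p]] += 1
    return counts
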