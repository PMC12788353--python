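"""Band-subset ensembling: split bands, run the pipeline per subset, vote."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabelMap

__all__ = ["FeaturePartition", "split_features", "majority_vote"]


@dataclass
class FeaturePartition:
    """Mutually exclusive, collectively exhaustive band-index subsets."""

    subsets: list[list[int]]
    seed: int

    def __post_init__(self) -> None:
        flat = sorted(b for s in self.subsets for b in s)
        if len(flat) != len(set(flat)):
            raise ValueError("subsets must be pairwise disjoint")


def split_features(d: int, n_subsets: int = 4, seed: int = 0) -> FeaturePartition:
    """Randomly partition band indices ``1..d`` into ``n_subsets`` groups
    whose sizes differ by at most one.  Deterministic given ``seed``."""
    if d < n_subsets:
        raise ValueError(f"cannot split {d} bands into {n_subsets} subsets")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(d) + 1  # 1-based band ids
    sizes = np.full(n_subsets, d // n_subsets)
    sizes[: d % n_subsets] += 1
    subsets = []
    start = 0
    for size in sizes:
        subsets.append(sorted(int(b) for b in perm[start:start + size]))
        start += size
    return FeaturePartition(subsets=subsets, seed=seed)


def majority_vote(maps: list[LabelMap | np.ndarray],
                  probs: list[np.ndarray] | None = None,
                  class_ids: np.ndarray | None = None) -> LabelMap:
    """Per-pixel modal label over voter maps.

    Ties are broken by the highest mean probability across voters (when
    ``probs`` — a list of ``(M, N, K)`` rasters over a shared ``class_ids``
    vocabulary — is supplied), then by the smallest class id.
    """
    if not maps:
        raise ValueError("majority_vote needs at least one map")
    arrays = [m.labels if isinstance(m, LabelMap) else np.asarray(m) for m in maps]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all voter maps must share the same shape")
    stack = np.stack(arrays, axis=0)  # (V, M, N)
    vocab = np.unique(stack)
    votes = np.zeros(stack.shape[1:] + (len(vocab),), dtype=np.int32)
    for ci, c in enumerate(vocab):
        votes[:, :, ci] = (stack == c).sum(axis=0)
    top = votes.max(axis=2)
    is_top = votes == top[:, :, None]
    mean_probs = None
    if probs is not None:
        if class_ids is None:
            raise ValueError("probs requires class_ids")
        class_ids = np.asarray(class_ids)
        mp = np.mean(np.stack(probs, axis=0), axis=0)  # (M, N, K)
        # align probability columns with the vote vocabulary; labels with no
        # probability column (e.g. background) get -inf so they never win ties
        mean_probs = np.full(votes.shape, -np.inf)
        for ci, c in enumerate(vocab):
            hit = np.nonzero(class_ids == c)[0]
            if hit.size:
                mean_probs[:, :, ci] = mp[:, :, hit[0]]
    if mean_probs is not None:
        # rank tied candidates by mean probability, then by smaller class id
        score = np.where(is_top, mean_probs, -np.inf)
        best = score.max(axis=2)
        tie_top = is_top & ((score == best[:, :, None]) | ~np.isfinite(best)[:, :, None])
    else:
        tie_top = is_top
    winner_idx = tie_top.argmax(axis=2)  # first True -> smallest class id
    return LabelMap(vocab[winner_idx].astype(np.int32))
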