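"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (triple loops, exhaustive searches)
so they cannot share bugs with the vectorised implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from segsat import LabelVolume


def random_label_volume(
    seed: int,
    shape: tuple[int, int, int] = (8, 8, 8),
    n_labels: int = 3,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelVolume:
    rng = np.random.default_rng(seed)
    voxels = rng.integers(0, n_labels, size=shape).astype(np.int32)
    return LabelVolume(voxels=voxels, spacing=spacing, source_id=f"rand{seed}")


@pytest.fixture
def rng_volume_pair():
    """Factory for comparable random volume pairs."""

    def make(seed: int, **kwargs):
        return random_label_volume(seed, **kwargs), random_label_volume(
            seed + 10_000, **kwargs
        )

    return make


# ---------------------------------------------------------------- oracles


def oracle_counts(ref: LabelVolume, pred: LabelVolume, label: int):
    """Triple-loop TP/FP/FN count."""
    tp = fp = fn = 0
    ni, nj, nk = ref.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                r = ref.voxels[i, j, k] == label
                p = pred.voxels[i, j, k] == label
                tp += r and p
                fp += (not r) and p
                fn += r and (not p)
    return tp, fp, fn


def oracle_boundary(mask: np.ndarray):
    """Boundary voxel list: mask voxels with a 6-neighbour outside the mask
    (the grid edge counts as outside)."""
    pts = []
    ni, nj, nk = mask.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                if not mask[i, j, k]:
                    continue
                for di, dj, dk in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0),
                    (0, -1, 0), (0, 0, 1), (0, 0, -1),
                ):
                    a, b, c = i + di, j + dj, k + dk
                    outside = not (0 <= a < ni and 0 <= b < nj and 0 <= c < nk)
                    if outside or not mask[a, b, c]:
                        pts.append((i, j, k))
                        break
    return pts


def oracle_msd(ref: LabelVolume, pred: LabelVolume, label: int):
    """Exhaustive nearest-boundary-voxel symmetric mean surface distance."""
    ba = oracle_boundary(np.asarray(ref.mask(label)))
    bb = oracle_boundary(np.asarray(pred.mask(label)))
    if not ba or not bb:
        return None
    sp = ref.spacing

    dst_arr = {
        "a": np.array(ba, dtype=float) * sp,
        "b": np.array(bb, dtype=float) * sp,
    }

    def directed(src, dst_key):
        # exhaustive: distance of every source point to EVERY destination
        # point, then the minimum — no spatial indexing involved
        dst = dst_arr[dst_key]
        total = 0.0
        for p in src:
            q = np.asarray(p, dtype=float) * sp
            total += math.sqrt(((dst - q) ** 2).sum(axis=1).min())
        return total / len(src)

    return 0.5 * (directed(ba, "b") + directed(bb, "a"))


def oracle_majority(votes, tie_lowest=True, background=0):
    """Exhaustive-count modal label with explicit tie handling."""
    counts = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    tied = sorted(lab for lab, c in counts.items() if c == top)
    if tie_lowest:
        return tied[0]
    return background if background in tied else tied[0]


def all_vote_combinations(labels=(0, 1, 2), k=5):
    return list(itertools.product(labels, repeat=k))
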