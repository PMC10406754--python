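"""Per-voxel majority-vote fusion of cross-validation fold predictions.

The ensemble prediction at each voxel is the most common label across the K
fold models.  With five voters and three labels, 2-2-1 ties occur; the tie
rule is explicit and deterministic:

``lowest_label``
    the numerically smallest tied label wins (with the conventional
    background/kidney/tumor = 0/1/2 map this prefers background — the
    conservative choice);
``background_wins``
    the background label wins any tie it participates in; otherwise the
    lowest tied label wins.  Identical to ``lowest_label`` whenever the
    background value is the numerically smallest label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .label_volumes import LabelVolume, check_comparable

__all__ = ["EnsembleInput", "majority_vote", "TIE_RULES"]

TIE_RULES = ("lowest_label", "background_wins")


@dataclass(frozen=True)
class EnsembleInput:
    """K >= 1 pairwise-comparable fold predictions plus a tie rule."""

    predictions: Sequence[LabelVolume] = field(default_factory=list)
    tie_rule: str = "lowest_label"
    background: int = 0

    def __post_init__(self) -> None:
        if not self.predictions:
            raise ValueError("ensemble needs at least one prediction")
        if self.tie_rule not in TIE_RULES:
            raise ValueError(f"tie_rule must be one of {TIE_RULES}, got {self.tie_rule!r}")
        first = self.predictions[0]
        for other in self.predictions[1:]:
            check_comparable(first, other)


def majority_vote(ensemble: EnsembleInput | Sequence[LabelVolume]) -> LabelVolume:
    """Fuse K fold predictions into one volume by per-voxel modal label.

    Permutation-invariant and idempotent; with K=1 returns a copy of the
    single input.  Output spacing equals the input spacing.
    """
    if not isinstance(ensemble, EnsembleInput):
        ensemble = EnsembleInput(predictions=list(ensemble))
    volumes = ensemble.predictions
    first = volumes[0]
    if len(volumes) == 1:
        return LabelVolume(
            voxels=first.voxels.copy(), spacing=first.spacing, source_id=first.source_id
        )

    labels = np.unique(np.concatenate([np.unique(v.voxels) for v in volumes]))
    # counts[i] = votes for labels[i] at each voxel; labels ascending, so
    # argmax already implements the lowest-label tie break.
    counts = np.zeros((len(labels),) + first.shape, dtype=np.int16)
    for vol in volumes:
        for i, lab in enumerate(labels):
            counts[i] += vol.voxels == lab
    winner_idx = np.argmax(counts, axis=0)
    if ensemble.tie_rule == "background_wins":
        bg_pos = np.nonzero(labels == ensemble.background)[0]
        if bg_pos.size:
            bg_i = int(bg_pos[0])
            max_count = np.max(counts, axis=0)
            bg_tied = counts[bg_i] == max_count
            winner_idx = np.where(bg_tied, bg_i, winner_idx)
    fused = labels[winner_idx].astype(first.voxels.dtype)
    return LabelVolume(voxels=fused, spacing=first.spacing, source_id=first.source_id)
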