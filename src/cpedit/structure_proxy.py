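"""Hydropathy-based transmembrane-segment calling.

A transparent heuristic for comparing edited vs non-edited protein forms:
Kyte-Doolittle residue hydropathy, centred moving average (window 19,
truncated at the termini), segments = maximal runs above 1.6 of length
>= 15. This is a windowed-mean proxy for membrane-helix propensity, not an
HMM topology predictor; segment coordinates are comparative indicators
(did editing add/extend hydrophobic stretches?), not structure predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError

# Kyte & Doolittle hydropathy scale
KD_SCALE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class TmMap:
    """Candidate transmembrane segments of one protein.

    ``segments`` are 1-based inclusive residue intervals, sorted and
    non-overlapping; ``profile`` is the per-residue windowed hydropathy.
    """

    protein_id: str
    length: int
    segments: tuple[tuple[int, int], ...]
    profile: np.ndarray = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.segments:
            if not (1 <= start <= end <= self.length) or start <= prev_end:
                raise InputError(f"bad segment ({start}, {end})")
            prev_end = end

    def covered(self) -> np.ndarray:
        mask = np.zeros(self.length, dtype=bool)
        for start, end in self.segments:
            mask[start - 1 : end] = True
        return mask


def hydropathy_profile(protein: str, window: int = 19) -> np.ndarray:
    """Centred moving average of Kyte-Doolittle values.

    Terminal residues use truncated (shorter) windows. Unknown residues
    (X, *, ...) contribute 0 with a warning.
    """
    if window < 5 or window % 2 == 0:
        raise InputError("window must be odd and >= 5")
    if len(protein) < window:
        raise InputError(
            f"protein of length {len(protein)} shorter than window {window}"
        )
    unknown = sorted({aa for aa in protein if aa not in KD_SCALE})
    if unknown:
        warnings.warn(f"unknown residues {unknown} treated as hydropathy 0")
    vals = np.array([KD_SCALE.get(aa, 0.0) for aa in protein])
    half = window // 2
    ones = np.ones(window)
    sums = np.convolve(vals, ones, mode="same")
    counts = np.convolve(np.ones_like(vals), ones, mode="same")
    return sums / counts


def call_tm_segments(
    profile: np.ndarray,
    threshold: float = 1.6,
    min_len: int = 15,
    protein_id: str = "",
) -> TmMap:
    """Maximal runs of profile > threshold with length >= min_len."""
    profile = np.asarray(profile, dtype=float)
    above = profile > threshold
    segments = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                segments.append((start + 1, i))
            start = None
    if start is not None and len(above) - start >= min_len:
        segments.append((start + 1, len(above)))
    return TmMap(
        protein_id=protein_id,
        length=len(profile),
        segments=tuple(segments),
        profile=profile,
    )


@dataclass(frozen=True)
class TmDiff:
    """Interval-algebra diff of two TM maps of the same protein length."""

    gained: tuple[tuple[int, int], ...]
    lost: tuple[tuple[int, int], ...]
    extended: tuple[tuple[int, int], ...]
    shrunk: tuple[tuple[int, int], ...]

    @property
    def is_empty(self) -> bool:
        return not (self.gained or self.lost or self.extended or self.shrunk)


def _seg_len(seg: tuple[int, int]) -> int:
    return seg[1] - seg[0] + 1


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def compare_tm_maps(before: TmMap, after: TmMap) -> TmDiff:
    """Classify segment changes between the unedited and edited forms.

    ``after`` segments with no overlap in ``before`` are gained; those
    overlapping a before-segment but longer than the longest overlapped one
    are extended. Symmetric logic yields lost/shrunk.
    """
    if before.length != after.length:
        raise InputError("TM maps compare only at equal protein length")

    gained, extended = _one_way(after.segments, before.segments)
    lost, shrunk = _one_way(before.segments, after.segments)
    return TmDiff(
        gained=tuple(gained), lost=tuple(lost), extended=tuple(extended), shrunk=tuple(shrunk)
    )


def _one_way(
    segs: Sequence[tuple[int, int]], others: Sequence[tuple[int, int]]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    fresh, longer = [], []
    for s in segs:
        overlapping = [o for o in others if _overlaps(s, o)]
        if not overlapping:
            fresh.append(s)
        elif _seg_len(s) > max(_seg_len(o) for o in overlapping):
            longer.append(s)
    return fresh, longer
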