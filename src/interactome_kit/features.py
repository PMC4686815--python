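"""Per-protein disorder and low-complexity sequence features.

Intrinsic disorder is consumed as an externally produced per-residue
score track (e.g. IUPred output); a residue is disordered when its
score exceeds 0.4.  Compositional complexity is the Shannon entropy
(bits) of the amino-acid composition in a +/-10 residue window around
each position; positions below 3 bits are low complexity.  Both
features are summarised as per-protein fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResidueScoreTrack",
    "FeatureSummary",
    "disorder_fraction",
    "windowed_entropy",
    "low_complexity_fraction",
]


@dataclass
class ResidueScoreTrack:
    """Externally produced per-residue disorder scores in [0, 1]."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be a one-dimensional track")


@dataclass
class FeatureSummary:
    protein_id: str
    fraction_disordered: float
    fraction_low_complexity: float

    def __post_init__(self) -> None:
        for f in (self.fraction_disordered, self.fraction_low_complexity):
            if not 0.0 <= f <= 1.0:
                raise ValueError("feature fractions must lie in [0, 1]")


def disorder_fraction(track: ResidueScoreTrack, threshold: float = 0.4) -> float:
    """Fraction of residues with disorder score strictly above ``threshold``."""
    if track.scores.size == 0:
        raise ValueError(f"empty score track for {track.protein_id!r}")
    return float(np.mean(track.scores > threshold))


def windowed_entropy(sequence: str, halfwidth: int = 10) -> np.ndarray:
    """Shannon entropy (bits) of the residue composition around each position.

    The window at position i spans [i - halfwidth, i + halfwidth]
    intersected with the sequence (truncated at the ends, no padding);
    the focal residue is part of its own window.  Any letters present
    are treated as ordinary symbols; a terminal '*' is stripped.
    """
    seq = sequence.rstrip("*").upper()
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    codes, alphabet = _encode(seq)
    # cumulative symbol counts -> O(L * |alphabet|) window composition
    onehot = np.zeros((L + 1, len(alphabet)), dtype=np.int32)
    onehot[np.arange(1, L + 1), codes] = 1
    csum = np.cumsum(onehot, axis=0)
    lo = np.maximum(np.arange(L) - halfwidth, 0)
    hi = np.minimum(np.arange(L) + halfwidth + 1, L)
    win = csum[hi] - csum[lo]
    sizes = (hi - lo).astype(float)
    p = win / sizes[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def _encode(seq: str) -> tuple[np.ndarray, list[str]]:
    alphabet = sorted(set(seq))
    lut = {s: i for i, s in enumerate(alphabet)}
    return np.fromiter((lut[s] for s in seq), dtype=np.int64, count=len(seq)), alphabet


def low_complexity_fraction(
    sequence: str, halfwidth: int = 10, bits_threshold: float = 3.0
) -> float:
    """Fraction of positions whose window entropy is strictly below threshold."""
    H = windowed_entropy(sequence, halfwidth=halfwidth)
    return float(np.mean(H < bits_threshold))
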