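"""Cross-sectional fluorescence line-profile analysis.

Given a multi-channel intensity profile sampled along a line drawn across an
organelle interface (e.g. a MOM marker, an ER marker, and a query signal),
the analysis min-max normalizes each channel, locates each channel's peak
after light smoothing, and asks whether the query channel's peak lies
between the two flanking marker peaks — the readout used to place an
interaction signal at a membrane contact interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d


class ProfileError(ValueError):
    """A line profile violates its contract (bad shape, constant channel, ...)."""


@dataclass(frozen=True)
class LineProfile:
    """Positions along the line plus per-channel intensities.

    ``positions`` must be strictly increasing; every channel array has the
    same length.  ``normalized`` holds min-max normalized intensities (each
    channel spanning [0, 1]) once :func:`normalize_profile` has run.
    """

    positions: np.ndarray
    channels: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        if pos.ndim != 1 or len(pos) < 2:
            raise ProfileError("positions must be a 1D array with >= 2 samples")
        if not np.all(np.diff(pos) > 0):
            raise ProfileError("positions must be strictly increasing")
        chans = {k: np.asarray(v, float) for k, v in self.channels.items()}
        for name, arr in chans.items():
            if arr.shape != pos.shape:
                raise ProfileError(
                    f"channel {name!r}: length {arr.shape} != positions {pos.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ProfileError(f"channel {name!r}: non-finite intensities")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "channels", chans)


@dataclass(frozen=True)
class PeakLocation:
    position: float
    tied: bool


def read_profile_csv(path) -> LineProfile:
    """Read a profile CSV: a ``position`` column followed by one column per channel."""
    df = pd.read_csv(path)
    if "position" not in df.columns:
        raise ProfileError(f"{path}: missing 'position' column")
    channels = {c: df[c].to_numpy(float) for c in df.columns if c != "position"}
    if not channels:
        raise ProfileError(f"{path}: no channel columns")
    return LineProfile(df["position"].to_numpy(float), channels)


def normalize_profile(profile: LineProfile) -> LineProfile:
    """Min-max normalize each channel to [0, 1].

    A constant channel carries no positional information and is an error.
    """
    if any(len(v) < 3 for v in profile.channels.values()):
        raise ProfileError("need >= 3 samples per channel to normalize")
    normalized = {}
    for name, arr in profile.channels.items():
        lo, hi = float(arr.min()), float(arr.max())
        if hi == lo:
            raise ProfileError(f"channel {name!r} is constant; cannot normalize")
        normalized[name] = (arr - lo) / (hi - lo)
    return replace(profile, normalized=normalized)


def locate_peaks(profile: LineProfile, smooth_window: int = 3
                 ) -> dict[str, PeakLocation]:
    """Per-channel peak position after centered moving-average smoothing.

    Operates on normalized intensities (normalizing on the fly if needed;
    peak position is invariant under the positive affine rescaling anyway).
    Exact ties for the maximum are broken by first occurrence and flagged.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ProfileError("smooth_window must be a positive odd integer")
    if not profile.normalized:
        profile = normalize_profile(profile)
    peaks = {}
    for name, arr in profile.normalized.items():
        smoothed = (uniform_filter1d(arr, smooth_window, mode="nearest")
                    if smooth_window > 1 else arr)
        idx = int(np.argmax(smoothed))
        tied = bool(np.sum(np.isclose(smoothed, smoothed[idx], rtol=0, atol=0)) > 1)
        peaks[name] = PeakLocation(float(profile.positions[idx]), tied)
    return peaks


def betweenness_test(peaks: Mapping[str, PeakLocation | float], query: str,
                     flank_a: str, flank_b: str
                     ) -> tuple[bool, float, float]:
    """Does the query channel's peak lie between the two flanking peaks?

    Order-agnostic in the flanks; boundary-inclusive.  Returns the verdict
    plus the signed offsets ``query − flank_a`` and ``query − flank_b``.
    """
    def _pos(name: str) -> float:
        if name not in peaks:
            raise ProfileError(f"channel {name!r} missing from peak map")
        p = peaks[name]
        return p.position if isinstance(p, PeakLocation) else float(p)

    q, a, b = _pos(query), _pos(flank_a), _pos(flank_b)
    verdict = min(a, b) <= q <= max(a, b)
    return bool(verdict), q - a, q - b
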