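"""Circular tuning-channel bases for inverted encoding models.

A basis is a set of k idealized channels evenly spaced on a circular
feature dimension (polar-angle location, period 360°, or bar orientation,
period 180°).  Each channel's tuning curve is a half-wave-rectified
sinusoid raised to a power, scaled so one half-cycle spans the full
feature period: the activation of channel j for feature value f is

    max(0, cos(pi * d_j / period)) ** p,

where d_j is the signed circular difference between f and the channel's
center.  The curve is 1 at the center and falls to 0 at half a period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import LOCATION_BASE, ORIENTATION_BASE, circular_difference

__all__ = ["ChannelBasis", "channel_response", "ideal_channel_matrix"]


@dataclass(frozen=True)
class ChannelBasis:
    """Evenly spaced rectified-sinusoid channels on a circular feature axis."""

    period: float
    centers: tuple
    exponent: int

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 1 or len(c) < 2:
            raise ValueError("need at least two channel centers")
        spacing = np.diff(c)
        if np.any(spacing <= 0) or not np.allclose(spacing, spacing[0]):
            raise ValueError("centers must be strictly increasing and equally spaced")
        if not np.isclose(spacing[0] * len(c), self.period):
            raise ValueError("spacing must equal period / n_channels")
        if self.exponent < 1:
            raise ValueError("exponent must be >= 1")

    @classmethod
    def location(cls) -> "ChannelBasis":
        """9 channels at 20°…340°, period 360°, power 8."""
        return cls(period=360.0, centers=tuple(map(float, LOCATION_BASE)), exponent=8)

    @classmethod
    def orientation(cls) -> "ChannelBasis":
        """6 channels at 15°…165°, period 180°, power 6."""
        return cls(period=180.0, centers=tuple(map(float, ORIENTATION_BASE)), exponent=6)

    @property
    def n_channels(self) -> int:
        return len(self.centers)

    @property
    def spacing(self) -> float:
        return self.period / self.n_channels

    @property
    def zero_position(self) -> int:
        """Index where the 0°-offset channel sits after recentering.

        Chosen so the offset axis (center_j − center_zero, wrapped) covers
        (−period/2, period/2]: index 4 for 9 location channels (offsets
        −160…160) and index 2 for 6 orientation channels (−60…90).
        """
        return (self.n_channels - 1) // 2

    @property
    def offsets(self) -> np.ndarray:
        """Channel offsets (degrees) relative to the recentered 0° channel."""
        return (np.arange(self.n_channels) - self.zero_position) * self.spacing

    def nearest_channel(self, features) -> np.ndarray:
        """Index of the channel center circularly nearest each feature."""
        f = np.atleast_1d(np.asarray(features, dtype=float))
        d = np.abs(circular_difference(f[:, None], np.asarray(self.centers), self.period))
        return np.argmin(d, axis=1)

    def as_dict(self) -> dict:
        return {
            "period": self.period,
            "centers": list(self.centers),
            "exponent": self.exponent,
        }


def channel_response(basis: ChannelBasis, feature: float) -> np.ndarray:
    """Idealized k-vector of channel activations for one feature value."""
    f = np.asarray(feature, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("feature value must be finite")
    d = circular_difference(f, np.asarray(basis.centers), basis.period)
    return np.maximum(0.0, np.cos(np.pi * d / basis.period)) ** basis.exponent


def ideal_channel_matrix(basis: ChannelBasis, labels) -> np.ndarray:
    """Idealized channel responses for each trial, k channels × n trials."""
    labels = np.atleast_1d(np.asarray(labels, dtype=float))
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    if not np.all(np.isfinite(labels)):
        raise ValueError("labels must be finite")
    d = circular_difference(
        labels[None, :], np.asarray(basis.centers)[:, None], basis.period
    )
    return np.maximum(0.0, np.cos(np.pi * d / basis.period)) ** basis.exponent
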