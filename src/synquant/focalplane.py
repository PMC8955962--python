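"""Focal-plane (best Z slice) selection.

The synapse sits on the planar lipid bilayer, so the slice where the tumor
antigen (channel 3) accumulates most strongly marks the focal plane.  "Most
strongly" is read as the maximum per-slice *mean* intensity: a per-slice
maximum-pixel criterion would be dominated by single bright impurity
speckles, while the mean tracks the overall in-focus signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stackio import ImageStack

__all__ = ["FocalPlane", "slice_mean_profile", "select_focal_slice"]


@dataclass(frozen=True)
class FocalPlane:
    z_index: int
    profile: np.ndarray  # per-slice mean intensity of the probed channel


def slice_mean_profile(stack: ImageStack, channel: int) -> np.ndarray:
    """Mean intensity of each Z slice of one channel."""
    sub = stack.channel(channel)
    if sub.size == 0:
        raise ValueError("empty stack")
    return sub.reshape(sub.shape[0], -1).mean(axis=1)


def select_focal_slice(stack: ImageStack, channel: int = 3) -> FocalPlane:
    """Pick the slice with maximal mean intensity (ties -> lowest index)."""
    profile = slice_mean_profile(stack, channel)
    return FocalPlane(z_index=int(np.argmax(profile)), profile=profile)
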