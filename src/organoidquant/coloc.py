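"""Thresholded-volume-of-colocalization (TVC) analysis on 3D stacks.

Each stack carries a *target* channel (e.g. β-catenin), a *nuclear* channel
(DAPI) and a *neuronal* channel (NeuN).  Channels are binarized — per-channel
Otsu by default, or a fixed threshold — and colocalization between channels A
and B is reported as the percentage of A's supra-threshold volume that also
lies in B::

    TVC(A, B) = 100 · |A ∩ B| / |A|

The measure is deliberately asymmetric; both orientations are emitted for the
neuronal comparison since the denominator convention is a modelling choice.
Group comparison across region labels uses the one-way ANOVA + Tukey chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .roi import OTSU_BINS, DegenerateRegionError
from .stats import stats_report

__all__ = ["VolumeStack", "TVCResult", "threshold_channel", "tvc", "coloc_report"]

CHANNEL_ROLES = ("target", "nuclear", "neuronal")


@dataclass
class VolumeStack:
    """Multi-channel 3D raster; 2D images are accepted as single-slice volumes."""

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: str = ""

    def __post_init__(self) -> None:
        fixed = {}
        shape = None
        for name, arr in self.channels.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim == 2:
                a = a[np.newaxis, ...]
            if a.ndim != 3:
                raise ValueError(f"channel {name!r} must be 2D or 3D")
            if a.min() < 0 or not np.all(np.isfinite(a)):
                raise ValueError(f"channel {name!r} must be finite and non-negative")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError("all channels must share one shape")
            fixed[name] = a
        self.channels = fixed

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class TVCResult:
    region: str
    channel_a: str
    channel_b: str
    percent: float
    n_a: int
    n_intersection: int
    threshold_a: float | None = None
    threshold_b: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.percent <= 100):
            raise ValueError("TVC percent must lie in [0, 100]")


def threshold_channel(
    stack: VolumeStack, channel: str, method: str = "otsu", value: float | None = None
) -> tuple[np.ndarray, float]:
    """Binarize one channel; returns (supra-threshold volume, threshold used).

    ``method`` is ``"otsu"`` (256-bin histogram over the whole volume) or
    ``"fixed"`` with an explicit ``value``; voxels >= threshold are foreground
    for Otsu, > threshold for fixed (so ``fixed(0)`` keeps every positive voxel).
    """
    if channel not in stack.channels:
        raise KeyError(f"channel {channel!r} not in stack")
    vol = stack.channels[channel]
    if method == "otsu":
        if np.ptp(vol) == 0:
            raise DegenerateRegionError(f"constant channel {channel!r}: Otsu undefined")
        t = float(threshold_otsu(vol, nbins=OTSU_BINS))
        return vol >= t, t
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        return vol > value, float(value)
    raise ValueError(f"unknown thresholding method {method!r}")


def tvc(
    vol_a: np.ndarray,
    vol_b: np.ndarray,
    region: str = "",
    channel_a: str = "A",
    channel_b: str = "B",
    threshold_a: float | None = None,
    threshold_b: float | None = None,
) -> TVCResult:
    """Percent of A's thresholded volume overlapping B: 100·|A∩B|/|A|."""
    a = np.asarray(vol_a, dtype=bool)
    b = np.asarray(vol_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("volumes must share a shape")
    n_a = int(a.sum())
    if n_a == 0:
        raise DegenerateRegionError("empty thresholded volume A: TVC undefined")
    n_ab = int((a & b).sum())
    return TVCResult(
        region=region,
        channel_a=channel_a,
        channel_b=channel_b,
        percent=100.0 * n_ab / n_a,
        n_a=n_a,
        n_intersection=n_ab,
        threshold_a=threshold_a,
        threshold_b=threshold_b,
    )


def _stack_tvcs(stack: VolumeStack, method: str, fixed: Mapping[str, float] | None) -> list[TVCResult]:
    masks: dict[str, tuple[np.ndarray, float]] = {}
    for role in CHANNEL_ROLES:
        if role not in stack.channels:
            raise KeyError(f"stack {stack.label!r} lacks required channel {role!r}")
        if fixed and role in fixed:
            masks[role] = threshold_channel(stack, role, "fixed", fixed[role])
        else:
            masks[role] = threshold_channel(stack, role, method)
    (tgt, t_tgt), (nuc, t_nuc), (neu, t_neu) = (masks[r] for r in CHANNEL_ROLES)
    rows = [
        tvc(tgt, nuc, stack.label, "target", "nuclear", t_tgt, t_nuc),
        tvc(tgt, neu, stack.label, "target", "neuronal", t_tgt, t_neu),
        # reverse orientation for the neuronal comparison — denominator
        # convention is ambiguous, so both are reported
        tvc(neu, tgt, stack.label, "neuronal", "target", t_neu, t_tgt),
    ]
    return rows


def coloc_report(
    stacks_by_region: Mapping[str, Sequence[VolumeStack]],
    method: str = "otsu",
    fixed_thresholds: Mapping[str, float] | None = None,
) -> dict:
    """Per-stack TVC table plus cross-region ANOVA/Tukey statistics.

    Statistics are computed independently for each channel-pair orientation;
    with fewer than two regions (or fewer than two stacks in a region) the
    table is still emitted but statistics are skipped with a warning.
    """
    rows: list[TVCResult] = []
    for region, stacks in stacks_by_region.items():
        for stack in stacks:
            stack.label = region
            rows.extend(_stack_tvcs(stack, method, fixed_thresholds))

    report: dict = {
        "table": [r.__dict__ for r in rows],
        "statistics": {},
    }
    pairs = sorted({(r.channel_a, r.channel_b) for r in rows})
    can_test = len(stacks_by_region) >= 2 and all(
        len(s) >= 2 for s in stacks_by_region.values()
    )
    if not can_test:
        warnings.warn("fewer than 2 regions or 2 stacks per region: statistics skipped", stacklevel=2)
        return report
    for a, b in pairs:
        groups = {
            region: [r.percent for r in rows if r.region == region and (r.channel_a, r.channel_b) == (a, b)]
            for region in stacks_by_region
        }
        report["statistics"][f"{a}_in_{b}"] = stats_report(groups)
    return report
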