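"""Per-cell fluorescence quantification and population statistics.

Instance masks derived from the F-actin channel at the focal slice are
applied unchanged to channels 1-4 (the DIC channel is never quantified);
the total fluorescence intensity (TFI) of a cell in a channel is the raw
sum of gray values under its mask, split into border and interior parts.
No background subtraction or normalization is applied by default — the
statistics operate on raw integrated intensities.

Population comparisons use the two-sided pooled-variance Student t test
(two independent, identically distributed samples; Welch's correction is
available as an option), with histograms and the empirical CDF as the
distributional summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .focalplane import FocalPlane
from .segment import CellInstance
from .stackio import ImageStack

__all__ = [
    "GroupStats",
    "TTestResult",
    "total_fluorescence_intensity",
    "per_cell_channel_table",
    "summarize",
    "ttest_two_sided",
    "distribution_summaries",
    "compare_groups",
    "QUANTIFIED_CHANNELS",
]

QUANTIFIED_CHANNELS = (1, 2, 3, 4)


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float
    variance: float  # unbiased sample variance (0 when n == 1)
    sem: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float


def total_fluorescence_intensity(
    channel_slice: np.ndarray, instance: CellInstance, image_id: str = "", channel: int = 0
) -> dict:
    """One TFI record: masked sum plus its border/interior decomposition."""
    img = np.asarray(channel_slice, np.float64)
    if img.shape != instance.mask.shape:
        raise ValueError("slice and mask frames differ")
    if not instance.mask.any():
        raise ValueError("empty mask")
    border = float(img[instance.border_pixels].sum())
    interior = float(img[instance.interior_pixels].sum())
    return {
        "image_id": image_id,
        "cell_id": instance.cell_id,
        "channel": channel,
        "area_px": instance.area,
        "tfi": border + interior,
        "border_intensity": border,
        "interior_intensity": interior,
    }


def per_cell_channel_table(
    stack: ImageStack,
    z: FocalPlane | int,
    instances: list[CellInstance],
    image_id: str = "",
) -> list[dict]:
    """TFI records for every instance in channels 1-4 at the focal slice."""
    z_index = z.z_index if isinstance(z, FocalPlane) else int(z)
    records = []
    for inst in instances:
        for ch in QUANTIFIED_CHANNELS:
            records.append(
                total_fluorescence_intensity(
                    stack.plane(ch, z_index), inst, image_id=image_id, channel=ch
                )
            )
    return records


def summarize(values) -> GroupStats:
    """Sample mean, unbiased variance and SEM (n == 1 -> variance 0)."""
    v = np.asarray(values, np.float64)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    var = float(v.var(ddof=1)) if v.size > 1 else 0.0
    return GroupStats(
        n=int(v.size),
        mean=float(v.mean()),
        variance=var,
        sem=float(np.sqrt(var / v.size)),
    )


def ttest_two_sided(a, b, welch: bool = False) -> TTestResult:
    """Two-sided independent two-sample t test (pooled variance by default).

    Degenerate zero-variance inputs: equal means -> (t=0, p=1); unequal
    means -> infinite t with p = 0 sentinel.
    """
    a = np.asarray(a, np.float64)
    b = np.asarray(b, np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    df = a.size + b.size - 2 if not welch else None
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, df=float(a.size + b.size - 2))
        return TTestResult(
            t=float(np.sign(a.mean() - b.mean()) * np.inf), p=0.0, df=float(a.size + b.size - 2)
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=float(res.df))


def distribution_summaries(values, n_bins: int = 20):
    """Histogram (counts, edges) and empirical CDF (x, F(x)) of a sample.

    The ECDF is the right-continuous step function F(x) = #{v <= x} / n
    evaluated at the sorted sample points; counts sum to n and F ends at 1.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    v = np.asarray(values, np.float64)
    if v.size == 0:
        raise ValueError("empty sample")
    counts, edges = np.histogram(v, bins=n_bins)
    xs = np.sort(v)
    ecdf = np.arange(1, v.size + 1) / v.size
    return (counts, edges), (xs, ecdf)


def _channel_tfi(table: pd.DataFrame, channel: int) -> np.ndarray:
    sel = table[table["channel"] == channel]["tfi"].to_numpy(np.float64)
    if sel.size == 0:
        raise ValueError(f"no records for channel {channel}")
    return sel


def compare_groups(
    table_a: pd.DataFrame, table_b: pd.DataFrame, channel: int, welch: bool = False
) -> tuple[GroupStats, GroupStats, TTestResult]:
    """Compare the per-cell TFI of one channel between two populations."""
    a = _channel_tfi(table_a, channel)
    b = _channel_tfi(table_b, channel)
    return summarize(a), summarize(b), ttest_two_sided(a, b, welch=welch)
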