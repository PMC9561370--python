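"""Summary statistics and 2D breathing histograms in reporting conventions.

Scalar series (Rg, contact counts) are reported as the median with the 5th
and 95th percentiles in brackets, "median (p5–p95)", using
linear-interpolation (type-7) percentiles. Breathing-angle ensembles are
summarized as 2D (gamma1, gamma2) histograms with 1° bins and contour
levels at 1 and 100 counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SeriesSummary",
    "GammaHistogram2D",
    "summarize_series",
    "format_summary",
    "parse_summary",
    "gamma_histogram2d",
]

CONTOUR_LEVELS = (1, 100)


@dataclass(frozen=True)
class SeriesSummary:
    median: float
    p5: float
    p95: float
    n: int

    def __post_init__(self) -> None:
        if not (self.p5 <= self.median <= self.p95):
            raise ValueError("percentiles out of order")

    def __str__(self) -> str:
        return format_summary(self)


def summarize_series(values) -> SeriesSummary:
    """Median and 5/95 percentiles (linear interpolation) of a series."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    p5, med, p95 = np.percentile(v, [5, 50, 95], method="linear")
    return SeriesSummary(median=float(med), p5=float(p5), p95=float(p95),
                         n=int(v.size))


def format_summary(s: SeriesSummary, precision: int = 1) -> str:
    """Format as ``median (p5–p95)`` with an en-dash, e.g. ``49.2 (48.3–51.0)``."""
    fmt = f"%.{precision}f"
    return f"{fmt % s.median} ({fmt % s.p5}–{fmt % s.p95})"


_SUMMARY_RE = re.compile(
    r"^\s*(-?[\d.]+)\s*\(\s*(-?[\d.]+)\s*[–—-]\s*(-?[\d.]+)\s*\)\s*$"
)


def parse_summary(text: str, n: int = 0) -> SeriesSummary:
    """Parse a ``median (p5–p95)`` cell back into a :class:`SeriesSummary`."""
    m = _SUMMARY_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse summary cell {text!r}")
    med, p5, p95 = (float(g) for g in m.groups())
    return SeriesSummary(median=med, p5=p5, p95=p95, n=n)


@dataclass(frozen=True)
class GammaHistogram2D:
    """2D histogram of (gamma1, gamma2) samples, possibly per ensemble."""

    edges1: np.ndarray
    edges2: np.ndarray
    #: ensemble label -> count grid of shape (len(edges1)-1, len(edges2)-1)
    grids: dict[str, np.ndarray]
    contour_levels: tuple[int, ...] = CONTOUR_LEVELS

    @property
    def counts(self) -> np.ndarray:
        """Pooled count grid over all ensembles."""
        return sum(self.grids.values())

    def to_dataframe(self) -> pd.DataFrame:
        c1 = 0.5 * (self.edges1[:-1] + self.edges1[1:])
        c2 = 0.5 * (self.edges2[:-1] + self.edges2[1:])
        frames = []
        for label, grid in self.grids.items():
            g1, g2 = np.meshgrid(c1, c2, indexing="ij")
            frames.append(pd.DataFrame({
                "ensemble": label,
                "gamma1_deg": g1.ravel(),
                "gamma2_deg": g2.ravel(),
                "count": grid.ravel().astype(int),
            }))
        return pd.concat(frames, ignore_index=True)


def gamma_histogram2d(samples, bin_width: float = 1.0,
                      range1: tuple[float, float] = (-180.0, 180.0),
                      range2: tuple[float, float] = (-180.0, 180.0),
                      contour_levels: tuple[int, ...] = CONTOUR_LEVELS,
                      ) -> GammaHistogram2D:
    """Histogram (gamma1, gamma2) samples on a fixed 1°-bin grid.

    ``samples`` is either an (n, 2) array of angle pairs (degrees) or a
    mapping of ensemble label -> such an array (for free-vs-bound
    overlays); per-ensemble grids are kept separate. NaN pairs (undefined
    projections) are dropped.
    """
    if bin_width <= 0:
        raise ValueError("zero-width bins")
    if not isinstance(samples, dict):
        samples = {"ensemble": samples}
    edges1 = np.arange(range1[0], range1[1] + bin_width / 2, bin_width)
    edges2 = np.arange(range2[0], range2[1] + bin_width / 2, bin_width)
    grids = {}
    for label, arr in samples.items():
        arr = np.asarray(arr, dtype=float).reshape(-1, 2)
        arr = arr[~np.isnan(arr).any(axis=1)]
        grid, _, _ = np.histogram2d(arr[:, 0], arr[:, 1],
                                    bins=[edges1, edges2])
        grids[label] = grid
    return GammaHistogram2D(edges1=edges1, edges2=edges2, grids=grids,
                            contour_levels=tuple(contour_levels))
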