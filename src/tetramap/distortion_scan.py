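"""Segregation-distortion-region scanning along linkage groups.

Per-marker chi-square p-values against 1:1 segregation are transformed
to -log10(p), LOESS-smoothed along the genetic map of each linkage
group, and regions are called where the smoothed curve exceeds a
threshold (default 3, i.e. p < 0.001 on the smoothed scale) across a
run of at least three consecutive markers that are individually
distorted (p below a cutoff) and skewed in the same direction.

Smoothing is degree-1 LOESS with tricube weights over the span
fraction of nearest neighbours, one pass (no robustness iterations),
matching common plotting defaults; statsmodels' lowess provides the
smoother.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ScanConfig",
    "DistortionRegion",
    "loess_smooth",
    "call_regions",
    "scan_map",
]


@dataclasses.dataclass(frozen=True)
class ScanConfig:
    loess_span: float = 0.3
    curve_threshold: float = 3.0  # -log10(p) scale
    min_consecutive: int = 3
    p_cut: float = 0.001

    def __post_init__(self) -> None:
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must lie in (0, 1]")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")


@dataclasses.dataclass(frozen=True)
class DistortionRegion:
    """A called segregation-distortion region.

    ``markers`` lists every marker under the above-threshold stretch of
    the smoothed curve; ``core_markers`` is the qualifying run of
    consecutive, individually distorted (p < p_cut), same-direction
    markers inside it.
    """

    linkage_group: str
    start_cM: float
    end_cM: float
    direction: str
    peak: float
    markers: tuple[str, ...]
    core_markers: tuple[str, ...]

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def loess_smooth(
    positions: Sequence[float], values: Sequence[float], span: float = 0.3
) -> np.ndarray:
    """LOESS-smooth values along sorted positions, evaluated at each position.

    Fewer than three points cannot support a local linear fit; the
    input is returned unchanged with a warning.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y):
        raise ValueError("positions and values length mismatch")
    if (np.diff(x) < 0).any():
        raise ValueError("positions must be sorted")
    if len(x) < 3:
        warnings.warn("fewer than 3 points; returning input unsmoothed", stacklevel=2)
        return y.copy()
    # a local linear fit needs >= 3 neighbours; widen the span on tiny groups
    frac = max(span, min(1.0, 3.0 / len(x)))
    # co-located markers (zero adjacent recombination) would give zero-width
    # windows; an epsilon ramp keeps positions strictly increasing
    x_fit = x + np.arange(len(x)) * 1e-9
    return lowess(y, x_fit, frac=frac, it=0, return_sorted=False)


def call_regions(
    table: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
    linkage_group: str = "",
) -> list[DistortionRegion]:
    """Call distortion regions on one linkage group's marker table.

    ``table`` needs columns marker, cM, p, direction, smoothed, sorted
    by cM. A region is a maximal stretch of markers where the smoothed
    curve exceeds ``curve_threshold`` that contains at least
    ``min_consecutive`` consecutive markers individually distorted
    (p < p_cut) in a shared skew direction; bounds are the first and
    last positions of the stretch, and the qualifying run is reported
    as the region core. With several qualifying runs in one stretch the
    longest (first on ties) sets the region direction.
    """
    above = table["smoothed"].to_numpy() > config.curve_threshold
    distorted = table["p"].to_numpy() < config.p_cut
    directions = table["direction"].to_numpy(dtype=object)
    regions: list[DistortionRegion] = []
    i, n = 0, len(table)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        # longest run of consecutive same-direction distorted markers inside [i, j]
        best_run: tuple[int, int] | None = None
        k = i
        while k <= j:
            if not distorted[k]:
                k += 1
                continue
            m = k
            while m + 1 <= j and distorted[m + 1] and directions[m + 1] == directions[k]:
                m += 1
            if best_run is None or (m - k) > (best_run[1] - best_run[0]):
                best_run = (k, m)
            k = m + 1
        if best_run is not None and best_run[1] - best_run[0] + 1 >= config.min_consecutive:
            stretch = table.iloc[i : j + 1]
            core = table.iloc[best_run[0] : best_run[1] + 1]
            regions.append(
                DistortionRegion(
                    linkage_group=linkage_group,
                    start_cM=float(stretch["cM"].iloc[0]),
                    end_cM=float(stretch["cM"].iloc[-1]),
                    direction=str(directions[best_run[0]]),
                    peak=float(stretch["smoothed"].max()),
                    markers=tuple(stretch["marker"]),
                    core_markers=tuple(core["marker"]),
                )
            )
        i = j + 1
    return regions


def scan_map(
    map_table: pd.DataFrame,
    sda_table: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every linkage group of a map for distortion regions.

    ``map_table`` has columns (parent, linkage_group, marker,
    position_cM); ``sda_table`` is the screen output indexed by marker
    (columns p, neglog10p, direction). Returns (regions, plot table):
    regions with one row per detected region, and a tidy per-marker
    table (parent, linkage_group, marker, cM, neglog10p, smoothed,
    in_region) ready for plotting.
    """
    missing = set(map_table["marker"]) - set(sda_table.index)
    if missing:
        raise KeyError(f"markers absent from the SDA table: {sorted(missing)[:5]} ...")
    region_rows, plot_rows = [], []
    for (parent, lg), sub in map_table.groupby(["parent", "linkage_group"], sort=True):
        sub = sub.sort_values("position_cM")
        stats_sub = sda_table.loc[sub["marker"]]
        tab = pd.DataFrame(
            {
                "marker": sub["marker"].to_numpy(),
                "cM": sub["position_cM"].to_numpy(),
                "p": stats_sub["p"].to_numpy(),
                "neglog10p": stats_sub["neglog10p"].to_numpy(),
                "direction": stats_sub["direction"].to_numpy(),
            }
        )
        tab["smoothed"] = loess_smooth(
            tab["cM"], tab["neglog10p"], config.loess_span
        ) if len(tab) >= 3 else tab["neglog10p"].to_numpy()
        regions = call_regions(tab, config, linkage_group=lg) if len(tab) >= config.min_consecutive else []
        in_region = np.zeros(len(tab), dtype=bool)
        for reg in regions:
            in_region |= tab["marker"].isin(reg.markers).to_numpy()
            region_rows.append(
                {
                    "parent": parent,
                    "linkage_group": lg,
                    "start_cM": reg.start_cM,
                    "end_cM": reg.end_cM,
                    "direction": reg.direction,
                    "peak": reg.peak,
                    "n_markers": reg.n_markers,
                    "markers": ";".join(reg.markers),
                    "core_markers": ";".join(reg.core_markers),
                }
            )
        tab.insert(0, "linkage_group", lg)
        tab.insert(0, "parent", parent)
        tab["in_region"] = in_region
        plot_rows.append(tab)
    regions_df = pd.DataFrame(
        region_rows,
        columns=[
            "parent",
            "linkage_group",
            "start_cM",
            "end_cM",
            "direction",
            "peak",
            "n_markers",
            "markers",
            "core_markers",
        ],
    )
    plot_df = (
        pd.concat(plot_rows, ignore_index=True)
        if plot_rows
        else pd.DataFrame(
            columns=[
                "parent",
                "linkage_group",
                "marker",
                "cM",
                "p",
                "neglog10p",
                "direction",
                "smoothed",
                "in_region",
            ]
        )
    )
    return regions_df, plot_df


def plot_scan(plot_df: pd.DataFrame, path, threshold: float = 3.0) -> None:
    """Render the distortion scan: -log10(p) points with LOESS curves per LG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(plot_df.groupby(["parent", "linkage_group"]))
    ncol = 4
    nrow = max(1, int(np.ceil(len(groups) / ncol)))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False)
    for ax, ((parent, lg), sub) in zip(axes.ravel(), groups):
        ax.scatter(sub["cM"], sub["neglog10p"], s=6, alpha=0.6)
        ax.plot(sub["cM"], sub["smoothed"], color="crimson")
        ax.axhline(threshold, ls="--", color="gray", lw=0.8)
        ax.set_title(f"{parent} {lg}", fontsize=8)
    for ax in axes.ravel()[len(groups) :]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
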