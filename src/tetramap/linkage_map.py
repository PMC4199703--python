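"""Pseudo-testcross linkage mapping from single-dose presence/absence data.

Each parent's SDA markers behave like backcross markers: per progeny a
marker is present (1) or absent (0), and two markers on the same
homolog are in coupling, so the recombination fraction between them is
the mismatch fraction over pairwise-complete progeny. Markers on
different homologs (repulsion) show mismatch fractions >= 0.5 and are
treated as unlinked, which is what makes each linkage group at a high
LOD threshold correspond to a single homolog — four groups per
chromosome, named A-D by descending marker count.

Pipeline: pairwise recombination fraction + LOD -> single-linkage
grouping at a LOD threshold (connected components) -> per-group
seriation minimising the sum of adjacent recombination fractions (SARF;
greedy seeding and insertion followed by 2-opt reversals) -> cumulative
Kosambi distances.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MapConfig",
    "PairwiseLinkage",
    "pairwise_rf",
    "pairwise_rf_matrix",
    "group_markers",
    "order_group",
    "kosambi_cm",
    "kosambi_inverse",
    "map_positions",
    "name_homologs",
    "build_parent_map",
]

LOG10_2 = float(np.log10(2.0))
_UNLINKED_PENALTY = 0.5  # SARF contribution of a non-qualifying adjacency


@dataclasses.dataclass(frozen=True)
class MapConfig:
    """Grouping/ordering thresholds: LOD 14 single-linkage grouping,
    ordering restricted to pairs with LOD >= 1.0 and rf <= 0.35,
    Kosambi map function."""

    group_lod: float = 14.0
    order_min_lod: float = 1.0
    max_rf: float = 0.35
    min_group_size: int = 2

    def __post_init__(self) -> None:
        if self.group_lod <= 0:
            raise ValueError("group_lod must be > 0")
        if not 0 < self.max_rf < 0.5:
            raise ValueError("max_rf must lie in (0, 0.5)")


@dataclasses.dataclass(frozen=True)
class PairwiseLinkage:
    rf: float
    lod: float
    n_informative: int


def pairwise_rf(m1: Sequence[float], m2: Sequence[float]) -> PairwiseLinkage:
    """Recombination fraction and LOD between two presence vectors.

    Vectors contain 1 (present), 0 (absent) and NaN (missing); only
    pairwise-complete progeny are used. With R mismatches among n
    informative progeny: rf = R/n and
    LOD = R log10(rf) + (n-R) log10(1-rf) + n log10 2 (0 log 0 = 0).
    Mismatch fractions above 0.5 (repulsion-like) are truncated to
    rf = 0.5, LOD = 0.
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no progeny typed at both markers")
    r = int((a[ok] != b[ok]).sum())
    return _rf_lod_from_counts(r, n)


def _rf_lod_from_counts(r: int, n: int) -> PairwiseLinkage:
    rf = r / n
    if rf >= 0.5:
        return PairwiseLinkage(0.5, 0.0, n)
    lod = n * LOG10_2 + (n - r) * np.log10(1 - rf)
    if r > 0:
        lod += r * np.log10(rf)
    return PairwiseLinkage(float(rf), float(lod), n)


def pairwise_rf_matrix(
    presence: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs recombination fractions for a markers x progeny matrix.

    Returns (rf, lod, n_informative) DataFrames. Pairs with zero
    informative progeny get rf = NaN, lod = 0, n = 0.
    """
    x = presence.to_numpy(dtype=float)
    valid = (~np.isnan(x)).astype(float)
    ones = np.nan_to_num(x) * valid
    zeros = (1.0 - np.nan_to_num(x)) * valid
    n = valid @ valid.T
    mismatches = ones @ zeros.T + zeros @ ones.T
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = mismatches / n
        lod = n * LOG10_2 + (n - mismatches) * np.log10(1.0 - np.minimum(rf, 0.5))
        contrib = np.where(mismatches > 0, mismatches * np.log10(np.maximum(rf, 1e-300)), 0.0)
        lod = lod + contrib
    unlinked = rf >= 0.5
    rf = np.where(unlinked, 0.5, rf)
    lod = np.where(unlinked | (n == 0), 0.0, lod)
    rf = np.where(n == 0, np.nan, rf)
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, 0.0)
    idx = presence.index
    return (
        pd.DataFrame(rf, index=idx, columns=idx),
        pd.DataFrame(lod, index=idx, columns=idx),
        pd.DataFrame(n.astype(int), index=idx, columns=idx),
    )


def group_markers(
    presence: pd.DataFrame,
    config: MapConfig = MapConfig(),
    lod: pd.DataFrame | None = None,
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage grouping: connected components of the LOD graph.

    Edges join marker pairs with LOD >= ``config.group_lod``. Returns
    (groups, unplaced); groups have >= ``min_group_size`` markers, are
    sorted by descending size then first marker id, and are internally
    sorted by marker id. Components below the size floor are unplaced.
    """
    if presence.empty:
        return [], []
    if lod is None:
        _, lod, _ = pairwise_rf_matrix(presence)
    adj = (lod.to_numpy() >= config.group_lod).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    markers = np.asarray(presence.index, dtype=object)
    groups, unplaced = [], []
    for c in range(n_comp):
        members = sorted(markers[labels == c])
        if len(members) >= config.min_group_size:
            groups.append(members)
        else:
            unplaced.extend(members)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups, sorted(unplaced)


def _distance_matrix(
    group: Sequence[str],
    rf: pd.DataFrame,
    lod: pd.DataFrame,
    config: MapConfig,
) -> np.ndarray:
    """Ordering distances: rf where the pair qualifies (LOD >= order_min_lod
    and rf <= max_rf), else a flat unlinked penalty."""
    sub_rf = rf.loc[group, group].to_numpy()
    sub_lod = lod.loc[group, group].to_numpy()
    qual = (sub_lod >= config.order_min_lod) & (sub_rf <= config.max_rf)
    qual &= ~np.isnan(sub_rf)
    d = np.where(qual, sub_rf, _UNLINKED_PENALTY)
    np.fill_diagonal(d, 0.0)
    return d


def _sarf(order: Sequence[int], d: np.ndarray) -> float:
    o = np.asarray(order)
    return float(d[o[:-1], o[1:]].sum())


def _two_opt(order: list[int], d: np.ndarray) -> list[int]:
    """Best-improvement 2-opt segment reversals to a local SARF optimum."""
    n = len(order)
    improved = True
    while improved:
        improved = False
        best_delta, best_ij = 0.0, None
        for i in range(n - 1):
            a = order[i - 1] if i > 0 else -1
            for j in range(i + 1, n):
                b = order[j + 1] if j + 1 < n else -1
                old = new = 0.0
                if a >= 0:
                    old += d[a, order[i]]
                    new += d[a, order[j]]
                if b >= 0:
                    old += d[order[j], b]
                    new += d[order[i], b]
                delta = new - old
                if delta < best_delta - 1e-12:
                    best_delta, best_ij = delta, (i, j)
        if best_ij is not None:
            i, j = best_ij
            order[i : j + 1] = order[i : j + 1][::-1]
            improved = True
    return order


def order_group(
    group: Sequence[str],
    rf: pd.DataFrame,
    lod: pd.DataFrame,
    config: MapConfig = MapConfig(),
) -> list[str]:
    """Deterministic seriation of one linkage group.

    Minimises the sum of adjacent recombination fractions: seed with the
    farthest qualifying pair, grow by inserting (nearest-first) each
    remaining marker at the SARF-optimal position, then polish with
    2-opt reversals. Output orientation is normalised so the first
    marker id sorts before the last. Input order never matters: markers
    are canonicalised by id first and every tie breaks by id.
    """
    markers = sorted(group)
    if len(markers) == 1:
        return list(markers)
    d = _distance_matrix(markers, rf, lod, config)
    if not (d[np.triu_indices(len(markers), 1)] < _UNLINKED_PENALTY).any():
        warnings.warn(
            "no marker pair passes the ordering filters; falling back to id order",
            stacklevel=2,
        )
        return markers
    n = len(markers)
    # farthest qualifying pair seeds the backbone ends
    masked = np.where(d < _UNLINKED_PENALTY, d, -1.0)
    np.fill_diagonal(masked, -1.0)
    i, j = np.unravel_index(np.argmax(masked), masked.shape)
    order = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in order]
    # nearest-first insertion, SARF-optimal position
    while remaining:
        dist_to_placed = [d[k, order].min() for k in remaining]
        k = remaining[int(np.argmin(dist_to_placed))]
        remaining.remove(k)
        best_pos, best_cost = 0, None
        for pos in range(len(order) + 1):
            cand = order[:pos] + [k] + order[pos:]
            cost = _sarf(cand, d)
            if best_cost is None or cost < best_cost - 1e-12:
                best_cost, best_pos = cost, pos
        order.insert(best_pos, k)
    order = _two_opt(order, d)
    result = [markers[k] for k in order]
    if result[0] > result[-1]:
        result.reverse()
    return result


def kosambi_cm(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centimorgans."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_inverse(d: float) -> float:
    """Inverse Kosambi: r = (e^(d/25) - 1) / (2 (e^(d/25) + 1)) = tanh(d/50)/2."""
    if d < 0:
        raise ValueError("map distance must be >= 0")
    return float(0.5 * np.tanh(d / 50.0))


def map_positions(
    ordered: Sequence[str],
    rf: pd.DataFrame,
    n_informative: pd.DataFrame | None = None,
    max_rf_for_distance: float = 0.4999,
) -> pd.Series:
    """Cumulative Kosambi positions along an ordered group (first at 0).

    Each adjacent interval uses the pairwise rf of its endpoints. If
    that estimate is unusable (no shared progeny, or truncated at 0.5),
    the shortest marker pair spanning the interval with a usable rf
    supplies the distance, spread evenly over the spanned intervals.
    """
    m = len(ordered)
    pos = np.zeros(m)
    sub = rf.loc[list(ordered), list(ordered)].to_numpy()

    def usable(a: int, b: int) -> bool:
        v = sub[a, b]
        return bool(np.isfinite(v) and v < 0.5)

    gaps = np.full(m - 1, np.nan)
    for k in range(m - 1):
        if usable(k, k + 1):
            gaps[k] = kosambi_cm(min(sub[k, k + 1], max_rf_for_distance))
    for k in np.flatnonzero(np.isnan(gaps)):
        found = False
        for span in range(2, m):
            for a in range(max(0, k + 1 - span), min(k, m - 1 - span) + 1):
                b = a + span
                if usable(a, b):
                    share = kosambi_cm(min(sub[a, b], max_rf_for_distance)) / span
                    gaps[k] = share
                    found = True
                    break
            if found:
                break
        if not found:
            warnings.warn(
                f"no recombination estimate spans interval {k}; assigning 0 cM",
                stacklevel=2,
            )
            gaps[k] = 0.0
    pos[1:] = np.cumsum(gaps)
    return pd.Series(pos, index=list(ordered), name="position_cM")


def name_homologs(
    groups_by_chromosome: Mapping[str, Sequence[Sequence[str]]],
) -> dict[str, list[str]]:
    """Label each chromosome's linkage groups A-D by descending marker count.

    Ties break by the lexicographically smallest member marker id. More
    than four groups on one chromosome is flagged and the extras get
    letters E, F, ...
    """
    out: dict[str, list[str]] = {}
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for chrom, groups in groups_by_chromosome.items():
        ranked = sorted(groups, key=lambda g: (-len(g), min(g)))
        if len(ranked) > 4:
            warnings.warn(
                f"{chrom}: {len(ranked)} linkage groups (> 4 homologs)", stacklevel=2
            )
        for letter, g in zip(letters, ranked):
            out[f"{chrom}_{letter}"] = list(g)
    return out


def build_parent_map(
    presence: pd.DataFrame,
    parent: str,
    config: MapConfig = MapConfig(),
) -> tuple[pd.DataFrame, list[str]]:
    """Group, order and place one parent's SDA markers.

    Returns (map table, unplaced markers). The map table has one row per
    mapped marker with columns parent, linkage_group (LG01, LG02, ... by
    descending size; chromosome naming happens after synteny
    assignment), marker, position_cM.
    """
    rf, lod, n_inf = pairwise_rf_matrix(presence)
    groups, unplaced = group_markers(presence, config, lod=lod)
    rows = []
    for gi, group in enumerate(groups):
        ordered = order_group(group, rf, lod, config)
        positions = map_positions(ordered, rf, n_inf)
        for marker in ordered:
            rows.append(
                {
                    "parent": parent,
                    "linkage_group": f"LG{gi + 1:02d}",
                    "marker": marker,
                    "position_cM": float(positions[marker]),
                }
            )
    return pd.DataFrame(rows), unplaced
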