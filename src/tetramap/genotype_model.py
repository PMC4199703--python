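"""Binomial read-depth genotype model and rule-based caller for
autotetraploid biallelic SNPs.

For a SNP with alleles A/B in a tetrasomic individual of true genotype
G (AAAA, AAAB, AABB, ABBB or BBBB) and total depth N, the A-read count
X_A is binomial with success probability

    1 - alpha, 3/4, 1/2, 1/4, alpha

respectively, where alpha is the per-read sequencing error rate. Only
the two homozygote classes include alpha; heterozygote classes use
their exact dosage fractions.

The caller collapses this model into deterministic rules that limit
missing data while avoiding the dominant miscall mode (a triplex
heterozygote read only for its major allele):

* one allele observed: homozygote if N >= 11 (the smallest depth at
  which (3/4)^N < 0.05), else missing;
* both alleles observed: heterozygote if the minor allele has >= 2
  reads AND minor-allele frequency > 0.10, else missing;
* N = 0: missing.

Heterozygote dosage classes are never emitted by the caller (separating
AAAB/AABB/ABBB reliably needs ~60x depth); they exist only in the
likelihoods and in simulation truth.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReadCountMatrix

__all__ = [
    "HOM_A",
    "HOM_B",
    "HET",
    "MISSING",
    "DOSAGE_CLASSES",
    "CallModel",
    "genotype_likelihood",
    "min_homozygote_depth",
    "call_genotype",
    "call_matrix",
    "marker_missingness",
    "merge_parent_replicates",
    "filter_by_missingness",
    "missingness_tier_report",
]

HOM_A = "AA"
HOM_B = "BB"
HET = "AB"
MISSING = "NA"

DOSAGE_CLASSES = ("AAAA", "AAAB", "AABB", "ABBB", "BBBB")


@dataclasses.dataclass(frozen=True)
class CallModel:
    """Thresholds of the rule-based caller.

    alpha is carried for likelihood reporting; the calling rules
    themselves are threshold-based and do not consume it.
    """

    alpha: float = 0.005
    min_hom_depth: int = 11
    min_het_reads: int = 2
    min_het_maf: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 0.5):
            raise ValueError("alpha must lie in [0, 0.5)")
        if self.min_hom_depth < 1:
            raise ValueError("min_hom_depth must be >= 1")
        if not (0 <= self.min_het_maf < 0.5):
            raise ValueError("min_het_maf must lie in [0, 0.5)")


def _success_probability(g: str, alpha: float) -> float:
    table = {
        "AAAA": 1.0 - alpha,
        "AAAB": 0.75,
        "AABB": 0.5,
        "ABBB": 0.25,
        "BBBB": alpha,
    }
    try:
        return table[g]
    except KeyError:
        raise ValueError(f"unknown dosage class {g!r}; expected one of {DOSAGE_CLASSES}")


def genotype_likelihood(x_a: int, n: int, g: str, alpha: float = 0.0) -> float:
    """P(X_A = x_a | G = g; N = n, alpha) under the binomial read model."""
    if not (0 <= alpha < 0.5):
        raise ValueError("alpha must lie in [0, 0.5)")
    if not 0 <= x_a <= n:
        raise ValueError("require 0 <= x_a <= n")
    p = _success_probability(g, alpha)
    return float(stats.binom.pmf(x_a, n, p))


def min_homozygote_depth(p_threshold: float = 0.05) -> int:
    """Smallest depth N at which a triplex heterozygote (AAAB) yields only
    A-reads with probability below ``p_threshold``: min N with (3/4)^N < p.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    n = 1
    while 0.75**n >= p_threshold:
        n += 1
    return n


def call_genotype(x_a: int, x_b: int, model: CallModel = CallModel()) -> str:
    """Call one (marker, individual) cell from its allele depths."""
    if x_a < 0 or x_b < 0:
        raise ValueError("read counts must be non-negative")
    n = x_a + x_b
    if n == 0:
        return MISSING
    if x_b == 0:
        return HOM_A if n >= model.min_hom_depth else MISSING
    if x_a == 0:
        return HOM_B if n >= model.min_hom_depth else MISSING
    minor = min(x_a, x_b)
    if minor >= model.min_het_reads and minor / n > model.min_het_maf:
        return HET
    return MISSING


def call_matrix(reads: ReadCountMatrix, model: CallModel = CallModel()) -> pd.DataFrame:
    """Vectorised elementwise genotype calling.

    Returns a markers x individuals DataFrame with values AA/BB/AB/NA.
    """
    xa = reads.x_a.to_numpy(dtype=np.int64)
    xb = reads.x_b.to_numpy(dtype=np.int64)
    if xa.shape != xb.shape:
        raise ValueError("allele depth matrices have mismatched shapes")
    n = xa + xb
    minor = np.minimum(xa, xb)
    out = np.full(xa.shape, MISSING, dtype=object)

    only_a = (xb == 0) & (xa > 0)
    only_b = (xa == 0) & (xb > 0)
    out[only_a & (n >= model.min_hom_depth)] = HOM_A
    out[only_b & (n >= model.min_hom_depth)] = HOM_B
    both = (xa > 0) & (xb > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(n > 0, minor / np.maximum(n, 1), 0.0)
    out[both & (minor >= model.min_het_reads) & (maf > model.min_het_maf)] = HET
    return pd.DataFrame(out, index=reads.markers, columns=reads.individuals)


def marker_missingness(
    calls: pd.DataFrame, individuals: Iterable[str] | None = None
) -> pd.Series:
    """Fraction of MISSING calls per marker over the given individuals."""
    sub = calls if individuals is None else calls[list(individuals)]
    return (sub == MISSING).mean(axis=1)


def merge_parent_replicates(
    reads: ReadCountMatrix, replicate_map: Mapping[str, str]
) -> ReadCountMatrix:
    """Pool parental replicate columns by summing allele depths.

    ``replicate_map`` maps replicate column label -> merged column label
    (e.g. ``{"mother_rep1": "mother", ...}``). Columns not mentioned are
    passed through unchanged; merged columns are appended after them.
    """
    unknown = [c for c in replicate_map if c not in reads.individuals]
    if unknown:
        raise KeyError(f"unknown replicate columns: {unknown}")
    keep = [c for c in reads.individuals if c not in replicate_map]
    xa = reads.x_a[keep].copy()
    xb = reads.x_b[keep].copy()
    merged: dict[str, list[str]] = {}
    for rep, parent in replicate_map.items():
        merged.setdefault(parent, []).append(rep)
    for parent, reps in merged.items():
        xa[parent] = reads.x_a[reps].sum(axis=1)
        xb[parent] = reads.x_b[reps].sum(axis=1)
    return ReadCountMatrix(xa, xb)


def consensus_parent_calls(
    reads: ReadCountMatrix,
    replicate_map: Mapping[str, str],
    model: CallModel = CallModel(),
) -> pd.DataFrame:
    """Call all columns, then collapse parental replicates by majority vote.

    Each replicate is called at its own depth and the parent's genotype
    is the majority state among non-missing replicate calls (ties and
    all-missing give NA). Compared with depth pooling this is robust at
    high total depth, where a homozygote's pooled reads almost surely
    include a sequencing error and the single-allele rule can no longer
    fire. Returns the full call matrix with replicate columns replaced
    by one consensus column per parent (appended last).
    """
    unknown = [c for c in replicate_map if c not in reads.individuals]
    if unknown:
        raise KeyError(f"unknown replicate columns: {unknown}")
    calls = call_matrix(reads, model)
    by_parent: dict[str, list[str]] = {}
    for rep, parent in replicate_map.items():
        by_parent.setdefault(parent, []).append(rep)
    keep = [c for c in calls.columns if c not in replicate_map]
    out = calls[keep].copy()
    states = np.array([HOM_A, HOM_B, HET], dtype=object)
    for parent, reps in by_parent.items():
        sub = calls[reps].to_numpy(dtype=object)
        votes = np.stack([(sub == s).sum(axis=1) for s in states])  # 3 x markers
        order = np.sort(votes, axis=0)
        top, runner_up = order[-1], order[-2]
        winner = states[np.argmax(votes, axis=0)]
        consensus = np.where((top == 0) | (top == runner_up), MISSING, winner)
        out[parent] = consensus
    return out


def filter_by_missingness(
    calls: pd.DataFrame,
    cutoff: float,
    individuals: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Retain markers whose missing fraction among progeny is <= cutoff."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    miss = marker_missingness(calls, individuals)
    return calls.loc[miss <= cutoff]


def missingness_tier_report(
    calls: pd.DataFrame, individuals: Iterable[str] | None = None
) -> pd.DataFrame:
    """Marker counts and mean missingness for NA10..NA90 cutoff tiers.

    Tier NAx retains markers with at most x% missing genotype calls;
    the "All" row is the unfiltered set.
    """
    miss = marker_missingness(calls, individuals)
    rows = []
    for tier in range(10, 100, 10):
        sel = miss[miss <= tier / 100.0]
        rows.append(
            {
                "dataset": f"NA{tier}",
                "n_markers": int(sel.size),
                "mean_missing_pct": float(sel.mean() * 100) if sel.size else float("nan"),
            }
        )
    rows.append(
        {
            "dataset": "All",
            "n_markers": int(miss.size),
            "mean_missing_pct": float(miss.mean() * 100) if miss.size else float("nan"),
        }
    )
    return pd.DataFrame(rows)
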