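"""Single-dose-allele (SDA) screening and per-marker segregation tests.

In a two-way pseudo-testcross on an autotetraploid F1, a mapping-usable
marker is heterozygous in exactly one parent (configurations AB x AA /
AA x AB). A single-dose (simplex) allele then segregates 1:1
presence:absence among progeny, while a double-dose (duplex) allele
segregates 5:1 under random chromosome segregation. The two hypotheses
are equally supported (equal chi-square goodness of fit) at a
presence:absence ratio of sqrt(5) ~ 2.24:1, so markers with observed
ratio below 2:1 and fewer than 50% missing calls are kept as SDA
markers.

Distortion of each SDA marker from the 1:1 expectation is measured by a
one-degree-of-freedom chi-square test without continuity correction.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_model import HET, HOM_A, HOM_B, MISSING

__all__ = [
    "SDAConfig",
    "MarkerSegregation",
    "DistortionStat",
    "classify_parental_configuration",
    "segregation_counts",
    "is_sda",
    "equal_evidence_ratio",
    "distortion_test",
    "screen_markers",
    "presence_matrix",
]

MATERNAL_ONLY = "maternal_only"
PATERNAL_ONLY = "paternal_only"
BOTH = "both"
NEITHER = "neither"
UNUSABLE = "unusable"


@dataclasses.dataclass(frozen=True)
class SDAConfig:
    max_ratio: float = 2.0
    max_missing: float = 0.5
    distortion_alpha: float = 0.001

    def __post_init__(self) -> None:
        if self.max_ratio <= 1:
            raise ValueError("max_ratio must be > 1")
        if not 0 < self.max_missing <= 1:
            raise ValueError("max_missing must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class MarkerSegregation:
    marker: str
    parent_of_origin: str  # "maternal" or "paternal"
    n_present: int
    n_absent: int
    n_missing: int

    @property
    def n_progeny(self) -> int:
        return self.n_present + self.n_absent + self.n_missing

    @property
    def ratio(self) -> float:
        """Presence:absence ratio; inf when nothing is absent."""
        if self.n_absent == 0:
            return float("inf")
        return self.n_present / self.n_absent


@dataclasses.dataclass(frozen=True)
class DistortionStat:
    chi2: float
    p: float
    neglog10p: float
    direction: str  # "excess_presence" or "excess_absence"


def classify_parental_configuration(maternal_call: str, paternal_call: str) -> str:
    """Classify a marker by its merged parental genotype calls.

    maternal_only = AB x homozygote (pseudo-testcross usable for the
    maternal map); paternal_only the mirror image; both = double
    simplex (AB x AB, excluded); neither = no segregation expected;
    unusable = a parent call is missing.
    """
    if maternal_call == MISSING or paternal_call == MISSING:
        return UNUSABLE
    m_het = maternal_call == HET
    p_het = paternal_call == HET
    if m_het and p_het:
        return BOTH
    if m_het:
        return MATERNAL_ONLY
    if p_het:
        return PATERNAL_ONLY
    return NEITHER


def segregation_counts(
    progeny_calls: Iterable[str],
    configuration: str,
    homozygous_parent_call: str,
    marker: str = "",
) -> MarkerSegregation:
    """Count presence/absence of the segregating allele among progeny.

    The segregating (single-dose) allele is the allele absent from the
    homozygous parent; presence = progeny carrying it (HET or its
    homozygote, the latter possible only through miscalls), absence =
    progeny homozygous for the common allele.
    """
    if configuration not in (MATERNAL_ONLY, PATERNAL_ONLY):
        raise ValueError(
            f"segregation counts require a one-parent configuration, got {configuration!r}"
        )
    if homozygous_parent_call not in (HOM_A, HOM_B):
        raise ValueError("homozygous parent call must be AA or BB")
    hom_sda = HOM_A if homozygous_parent_call == HOM_B else HOM_B
    calls = list(progeny_calls)
    n_present = sum(c in (HET, hom_sda) for c in calls)
    n_absent = sum(c == homozygous_parent_call for c in calls)
    n_missing = sum(c == MISSING for c in calls)
    if n_present + n_absent == 0:
        raise ValueError(f"marker {marker or '<unnamed>'}: no typed progeny")
    parent = "maternal" if configuration == MATERNAL_ONLY else "paternal"
    return MarkerSegregation(marker, parent, n_present, n_absent, n_missing)


def is_sda(seg: MarkerSegregation, config: SDAConfig = SDAConfig()) -> bool:
    """Single-dose screen: ratio < max_ratio and missingness < max_missing.

    Both bounds are strict. A marker with no absent progeny (infinite
    ratio) fails. There is no lower bound on the ratio: a presence
    deficit stays an SDA candidate and is flagged by the distortion
    test instead.
    """
    if seg.n_absent == 0:
        return False
    miss_frac = seg.n_missing / seg.n_progeny if seg.n_progeny else 1.0
    return seg.ratio < config.max_ratio and miss_frac < config.max_missing


def _chi2_stat(x: float, expected: tuple[float, float]) -> float:
    """1-df goodness-of-fit statistic per observation for observed
    proportions (x, 1-x) against expected proportions."""
    p, q = expected
    return (x - p) ** 2 / p + ((1 - x) - q) ** 2 / q


def equal_evidence_ratio(
    expected_simplex: tuple[float, float] = (0.5, 0.5),
    expected_duplex: tuple[float, float] = (5 / 6, 1 / 6),
) -> float:
    """Presence:absence ratio at which the chi-square goodness-of-fit
    statistics against the two expectations coincide.

    The statistic is scale-free in the presence fraction, so the
    crossover ratio does not depend on sample size. For the 1:1 vs 5:1
    expectations the crossover is at presence fraction
    (1 + sqrt(5)) / (2 + 6/sqrt(5)), i.e. ratio sqrt(5) ~ 2.236,
    conventionally printed 2.24. Identical expectations return 1.0 by
    convention.
    """
    p1 = float(expected_simplex[0])
    p2 = float(expected_duplex[0])
    for pair in (expected_simplex, expected_duplex):
        if not (0 < pair[0] < 1) or abs(sum(pair) - 1) > 1e-9:
            raise ValueError(f"degenerate expectation {pair}")
    if abs(p1 - p2) < 1e-12:
        return 1.0
    lo, hi = sorted((p1, p2))
    f = lambda x: _chi2_stat(x, expected_simplex) - _chi2_stat(x, expected_duplex)
    x = optimize.brentq(f, lo + 1e-12, hi - 1e-12)
    return x / (1 - x)


def distortion_test(n_present: int, n_absent: int) -> DistortionStat:
    """Chi-square (1 df, no continuity correction) against 1:1."""
    n = n_present + n_absent
    if n == 0:
        raise ValueError("no typed progeny")
    chi2 = (n_present - n_absent) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    direction = "excess_presence" if n_present >= n_absent else "excess_absence"
    with np.errstate(divide="ignore"):
        neglog = float(-np.log10(p)) if p > 0 else float("inf")
    return DistortionStat(chi2=float(chi2), p=p, neglog10p=neglog, direction=direction)


def screen_markers(
    calls: pd.DataFrame,
    mother: str,
    father: str,
    config: SDAConfig = SDAConfig(),
) -> pd.DataFrame:
    """Full SDA screen over a genotype-call matrix (vectorised).

    ``calls`` must contain one merged column per parent plus the progeny
    columns. Returns one row per marker with the parental configuration,
    segregation counts, ratio, distortion statistics and the ``is_sda``
    flag (False whenever the configuration is not single-parent or no
    progeny are typed).
    """
    for col in (mother, father):
        if col not in calls.columns:
            raise KeyError(f"parent column {col!r} missing from call matrix")
    progeny_cols = [c for c in calls.columns if c not in (mother, father)]
    m_call = calls[mother].to_numpy(dtype=object)
    f_call = calls[father].to_numpy(dtype=object)
    sub = calls[progeny_cols].to_numpy(dtype=object)
    n_markers, n_prog = sub.shape

    conf = np.full(n_markers, NEITHER, dtype=object)
    m_het, f_het = m_call == HET, f_call == HET
    conf[m_het & ~f_het] = MATERNAL_ONLY
    conf[f_het & ~m_het] = PATERNAL_ONLY
    conf[m_het & f_het] = BOTH
    conf[(m_call == MISSING) | (f_call == MISSING)] = UNUSABLE

    single = (conf == MATERNAL_ONLY) | (conf == PATERNAL_ONLY)
    # common-allele homozygote call of the non-segregating parent
    common_hom = np.where(conf == MATERNAL_ONLY, f_call, m_call)
    # a single-parent configuration whose homozygous parent is HET is impossible;
    # treat non-homozygous "common" calls as unusable
    bad_hom = single & ~np.isin(common_hom, (HOM_A, HOM_B))
    conf[bad_hom] = UNUSABLE
    single &= ~bad_hom
    sda_hom = np.where(common_hom == HOM_B, HOM_A, HOM_B)

    present = (sub == HET) | (sub == sda_hom[:, None])
    absent = sub == common_hom[:, None]
    missing = sub == MISSING
    n_present = np.where(single, present.sum(axis=1), 0)
    n_absent = np.where(single, absent.sum(axis=1), 0)
    n_missing = np.where(single, missing.sum(axis=1), 0)
    typed = n_present + n_absent
    conf[single & (typed == 0)] = UNUSABLE
    single &= typed > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            single & (n_absent > 0), n_present / np.maximum(n_absent, 1), np.inf
        )
        chi2 = np.where(single, (n_present - n_absent) ** 2 / np.maximum(typed, 1), np.nan)
        p = stats.chi2.sf(chi2, df=1)
        neglog = -np.log10(p)
    ratio = np.where(single, ratio, np.nan)
    miss_frac = n_missing / max(n_prog, 1)
    sda = single & np.isfinite(ratio)
    sda &= np.where(sda, ratio < config.max_ratio, False)
    sda &= miss_frac < config.max_missing
    direction = np.where(
        single,
        np.where(n_present >= n_absent, "excess_presence", "excess_absence"),
        "",
    )
    parent = np.select(
        [conf == MATERNAL_ONLY, conf == PATERNAL_ONLY],
        ["maternal", "paternal"],
        default="",
    )
    return pd.DataFrame(
        {
            "configuration": conf,
            "parent": parent,
            "n_present": n_present,
            "n_absent": n_absent,
            "n_missing": n_missing,
            "ratio": ratio,
            "chi2": np.where(single, chi2, np.nan),
            "p": np.where(single, p, np.nan),
            "neglog10p": np.where(single, neglog, np.nan),
            "direction": direction,
            "is_sda": sda,
        },
        index=calls.index,
    )


def presence_matrix(
    calls: pd.DataFrame,
    sda_table: pd.DataFrame,
    parent: str,
    mother: str,
    father: str,
) -> pd.DataFrame:
    """Presence/absence (1/0/NaN) matrix of one parent's SDA markers.

    Presence means the progeny carries the segregating allele (HET or
    its homozygote); absence means homozygous for the common allele;
    anything else (missing call) is NaN.
    """
    if parent not in ("maternal", "paternal"):
        raise ValueError("parent must be 'maternal' or 'paternal'")
    sel = sda_table[(sda_table["is_sda"]) & (sda_table["parent"] == parent)]
    progeny_cols = [c for c in calls.columns if c not in (mother, father)]
    hom_parent_col = father if parent == "maternal" else mother
    sub = calls.loc[sel.index, progeny_cols].to_numpy(dtype=object)
    common_hom = calls.loc[sel.index, hom_parent_col].to_numpy(dtype=object)
    sda_hom = np.where(common_hom == HOM_B, HOM_A, HOM_B)
    out = np.full(sub.shape, np.nan)
    out[(sub == HET) | (sub == sda_hom[:, None])] = 1.0
    out[sub == common_hom[:, None]] = 0.0
    return pd.DataFrame(out, index=sel.index, columns=progeny_cols)
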