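"""Synthetic autotetraploid F1 populations under tetrasomic inheritance.

The generator emulates a GBS experiment on an outbred autotetraploid
F1 cross (two heterozygous parents, e.g. an alfalfa mapping population):

* each parent carries four homologs per chromosome; mapping-informative
  markers are *simplex* (allele A on exactly one homolog of one parent,
  absent from the other parent), with optional *duplex* decoys (A on two
  homologs of one parent) that a single-dose screen should reject;
* meiosis is tetrasomic with random bivalent pairing: the four homologs
  pair uniformly at random into two bivalents (three equally likely
  pairings), each bivalent recombines as a no-interference Poisson
  crossover process (Haldane; 1 event per 100 cM) and contributes one
  product to the gamete. Double reduction is assumed absent (random
  chromosome, not chromatid, segregation), which yields the classical
  1:1 simplex and 5:1 duplex presence:absence expectations;
* read depth per marker per individual is negative-binomial (heavily
  overdispersed by default, reproducing GBS-like missingness), and the
  A-allele read count is binomial with success probability
  ``(d/4)(1-alpha) + (1-d/4)alpha`` for true dosage d and sequencing
  error rate alpha;
* optional viability loci thin carriers at conception (rejection
  sampling until the target number of progeny survives), implanting
  segregation-distortion regions around the selected locus.

Everything downstream of per-allele tag counts is emulated; tag
discovery from raw reads is out of scope.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ReadCountMatrix

__all__ = [
    "ChromosomeModel",
    "SimulatedParent",
    "SimConfig",
    "TruthSet",
    "make_parents",
    "meiosis",
    "simulate_gametes",
    "make_progeny",
    "simulate_reads",
    "parent_read_columns",
    "expected_gamete_dosage_distribution",
    "expected_presence_absence_ratio",
    "synthetic_hit_table",
    "write_truth_tsv",
    "write_true_map_tsv",
]

_BIVALENT_PAIRINGS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)


@dataclasses.dataclass(frozen=True)
class ChromosomeModel:
    """Genetic model of one chromosome: name, length and marker positions.

    Marker coordinates are shared across the four homologs; which
    homolog(s) carry the A allele at a marker lives in the parents'
    haplotypes, not here.
    """

    name: str
    length_cM: float
    marker_ids: tuple[str, ...]
    positions_cM: np.ndarray  # shape (n_markers,), strictly increasing

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cM, dtype=float)
        object.__setattr__(self, "positions_cM", pos)
        if len(self.marker_ids) != len(pos):
            raise ValueError("marker_ids and positions_cM length mismatch")
        if len(pos) == 0:
            raise ValueError(f"chromosome {self.name}: zero markers")
        if (pos < 0).any() or (pos > self.length_cM).any():
            raise ValueError(f"chromosome {self.name}: positions outside [0, length]")
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"chromosome {self.name}: duplicate or unsorted positions")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError(f"chromosome {self.name}: duplicate marker ids")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclasses.dataclass
class SimulatedParent:
    """Four phased homolog haplotypes per chromosome.

    ``haplotypes[chrom]`` is a (4, n_markers) 0/1 array; row h gives the
    A-allele indicator along homolog h.
    """

    name: str
    haplotypes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, h in self.haplotypes.items():
            h = np.asarray(h, dtype=np.uint8)
            if h.ndim != 2 or h.shape[0] != 4:
                raise ValueError(f"{chrom}: expected 4 homologs, got shape {h.shape}")
            self.haplotypes[chrom] = h

    def dosage(self, chrom: str) -> np.ndarray:
        """Parental allele dosage (0-4) per marker on one chromosome."""
        return self.haplotypes[chrom].sum(axis=0)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cross.

    Defaults mirror a 384-progeny autotetraploid F1 GBS experiment:
    eight chromosomes, 25 simplex markers per homolog per parent plus a
    handful of duplex decoys, overdispersed read depth and a small
    sequencing error rate.

    Parameters
    ----------
    n_progeny : surviving F1 individuals (384).
    n_chromosomes : chromosomes per genome (8).
    markers_per_homolog : simplex markers per homolog per parent (25).
    n_duplex_per_chrom : duplex decoy markers per chromosome (4),
        alternately assigned to the two parents.
    chrom_length_cM : genetic length of every chromosome (70 cM, the
        typical per-homolog map length in tetraploid alfalfa).
    depth_mean : expected reads per marker per individual.
    depth_dispersion : within-locus negative-binomial size parameter k
        (var = m + m^2/k per cell); small k = strong overdispersion.
    depth_locus_shape : shape of the mean-1 gamma factor multiplying
        depth_mean per locus, emulating the unequal distribution of
        GBS reads across loci (restriction-fragment and PCR bias);
        small shape = strong between-locus inequality and a broad
        per-marker missingness spectrum under the read-depth caller.
    alpha : per-read sequencing error rate, in [0, 0.5).
    viability_loci : (marker_id, survival) pairs; carriers of the A
        allele at the locus survive conception with that probability.
    double_reduction : rate hook; only 0 (pure random chromosome
        segregation) is implemented.
    parent_replicates : GBS library replicate columns emitted per
        parent (maternal, paternal).
    """

    n_progeny: int = 384
    n_chromosomes: int = 8
    markers_per_homolog: int = 25
    n_duplex_per_chrom: int = 4
    chrom_length_cM: float = 70.0
    depth_mean: float = 30.0
    depth_dispersion: float = 2.0
    depth_locus_shape: float = 1.2
    alpha: float = 0.001
    viability_loci: tuple[tuple[str, float], ...] = ()
    double_reduction: float = 0.0
    parent_replicates: tuple[int, int] = (5, 7)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.markers_per_homolog < 1 and self.n_duplex_per_chrom < 1:
            raise ValueError("at least one marker per chromosome is required")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        if self.depth_locus_shape <= 0:
            raise ValueError("depth_locus_shape must be > 0")
        if not (0 <= self.alpha < 0.5):
            raise ValueError("alpha must lie in [0, 0.5)")
        for marker, s in self.viability_loci:
            if not (0 <= s <= 1):
                raise ValueError(f"survival probability for {marker} outside [0, 1]")
        if self.double_reduction != 0:
            raise NotImplementedError(
                "only double_reduction=0 (random chromosome segregation) is implemented"
            )
        if min(self.parent_replicates) < 1:
            raise ValueError("each parent needs >= 1 replicate column")


@dataclasses.dataclass
class TruthSet:
    """Latent truth for recovery tests.

    Attributes
    ----------
    marker_info : DataFrame indexed by marker id with columns
        ``chromosome, cM, origin`` (``maternal``/``paternal``),
        ``homologs`` (tuple of carrier homolog indices in the origin
        parent) and ``type`` (``simplex``/``duplex``).
    dosage : markers x progeny DataFrame of true allele dosage 0-4.
    maternal_gametes, paternal_gametes : per chromosome, (n, 2, M)
        arrays of the inherited homolog products per progeny.
    """

    marker_info: pd.DataFrame
    dosage: pd.DataFrame
    maternal_gametes: dict[str, np.ndarray]
    paternal_gametes: dict[str, np.ndarray]
    chromosomes: dict[str, ChromosomeModel]
    mother: SimulatedParent
    father: SimulatedParent

    @property
    def progeny(self) -> pd.Index:
        return self.dosage.columns

    def true_map(self) -> pd.DataFrame:
        """Long-format true map of simplex markers: one row per marker.

        Columns: parent ('maternal'/'paternal'), chromosome, homolog
        (A-D by homolog index), marker, cM.
        """
        rows = []
        letters = "ABCD"
        for marker, info in self.marker_info.iterrows():
            if info["type"] != "simplex":
                continue
            (h,) = info["homologs"]
            rows.append(
                {
                    "parent": info["origin"],
                    "chromosome": info["chromosome"],
                    "homolog": letters[h],
                    "linkage_group": f"{info['chromosome']}_{info['origin']}_{letters[h]}",
                    "marker": marker,
                    "cM": info["cM"],
                }
            )
        return pd.DataFrame(rows)


def _marker_layout(config: SimConfig) -> tuple[dict[str, ChromosomeModel], pd.DataFrame]:
    """Lay out simplex and duplex marker positions along each chromosome.

    Marker sets (4 maternal homologs, 4 paternal homologs, duplex
    decoys) are interleaved on an even grid with a per-set offset so no
    two markers collide and every homolog's markers span the chromosome.
    """
    n_sets = 9  # 4 maternal + 4 paternal + 1 duplex track
    chromosomes: dict[str, ChromosomeModel] = {}
    info_rows = []
    k = config.markers_per_homolog
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        entries: list[tuple[float, str, str, tuple[int, ...], str]] = []
        step = config.chrom_length_cM / max(k, 1)
        for parent_idx, origin in enumerate(("maternal", "paternal")):
            for h in range(4):
                set_idx = parent_idx * 4 + h
                for i in range(k):
                    pos = i * step + (set_idx + 1) * step / (n_sets + 1)
                    mid = f"{chrom}_{origin[0]}{h}_{i + 1:03d}"
                    entries.append((pos, mid, origin, (h,), "simplex"))
        if config.n_duplex_per_chrom:
            dstep = config.chrom_length_cM / config.n_duplex_per_chrom
            for i in range(config.n_duplex_per_chrom):
                origin = "maternal" if (c + i) % 2 == 0 else "paternal"
                pos = (i + 0.61) * dstep  # offset off the simplex grid
                mid = f"{chrom}_dx_{i + 1:03d}"
                entries.append((pos, mid, origin, (0, 1), "duplex"))
        entries.sort(key=lambda e: (e[0], e[1]))
        positions = np.array([e[0] for e in entries])
        # guard against collisions from the duplex track
        for j in range(1, len(positions)):
            if positions[j] <= positions[j - 1]:
                positions[j] = np.nextafter(positions[j - 1], np.inf) + 1e-6
        positions = np.minimum(positions, config.chrom_length_cM)
        for j in range(1, len(positions)):  # re-assert monotonicity after clipping
            if positions[j] <= positions[j - 1]:
                positions[j] = positions[j - 1] + 1e-6
        ids = tuple(e[1] for e in entries)
        chromosomes[chrom] = ChromosomeModel(
            name=chrom,
            length_cM=float(max(config.chrom_length_cM, positions.max())),
            marker_ids=ids,
            positions_cM=positions,
        )
        for pos, mid, origin, homologs, mtype in zip(
            positions, ids, (e[2] for e in entries), (e[3] for e in entries), (e[4] for e in entries)
        ):
            info_rows.append(
                {
                    "marker": mid,
                    "chromosome": chrom,
                    "cM": pos,
                    "origin": origin,
                    "homologs": homologs,
                    "type": mtype,
                }
            )
    marker_info = pd.DataFrame(info_rows).set_index("marker")
    return chromosomes, marker_info


def make_parents(
    config: SimConfig,
) -> tuple[SimulatedParent, SimulatedParent, dict[str, ChromosomeModel], pd.DataFrame]:
    """Construct the two heterozygous parents of the cross.

    Returns (mother, father, chromosome models, marker_info). A simplex
    marker has allele A on exactly one homolog of its origin parent and
    nowhere in the other parent; a duplex decoy has A on two homologs
    of its origin parent. The layout is deterministic given the config
    (parental phase carries no randomness; all randomness is meiotic
    and sequencing noise).
    """
    chromosomes, marker_info = _marker_layout(config)
    mother_h: dict[str, np.ndarray] = {}
    father_h: dict[str, np.ndarray] = {}
    for chrom, model in chromosomes.items():
        m = np.zeros((4, model.n_markers), dtype=np.uint8)
        f = np.zeros((4, model.n_markers), dtype=np.uint8)
        for j, mid in enumerate(model.marker_ids):
            info = marker_info.loc[mid]
            target = m if info["origin"] == "maternal" else f
            for h in info["homologs"]:
                target[h, j] = 1
        mother_h[chrom] = m
        father_h[chrom] = f
    mother = SimulatedParent("mother", mother_h)
    father = SimulatedParent("father", father_h)
    return mother, father, chromosomes, marker_info


def _recombinant_product(
    hap_a: np.ndarray, hap_b: np.ndarray, positions: np.ndarray, length_cM: float, rng
) -> np.ndarray:
    """One meiotic product of a bivalent: a Haldane mosaic of two homologs."""
    n_xo = rng.poisson(length_cM / 100.0)
    start = rng.integers(0, 2)
    if n_xo == 0:
        return hap_a if start == 0 else hap_b
    points = np.sort(rng.uniform(0.0, length_cM, size=n_xo))
    phase = (start + np.searchsorted(points, positions, side="right")) % 2
    return np.where(phase == 0, hap_a, hap_b).astype(np.uint8)


def meiosis(
    parent: SimulatedParent,
    chromosomes: Mapping[str, ChromosomeModel],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw one gamete: two recombinant homologs per chromosome.

    The four homologs pair uniformly at random into two bivalents (three
    equally likely pairings); each bivalent contributes one Haldane
    recombinant product. No double reduction.
    """
    gamete: dict[str, np.ndarray] = {}
    for chrom, model in chromosomes.items():
        haps = parent.haplotypes[chrom]
        pairing = _BIVALENT_PAIRINGS[rng.integers(0, 3)]
        products = [
            _recombinant_product(
                haps[a], haps[b], model.positions_cM, model.length_cM, rng
            )
            for a, b in pairing
        ]
        gamete[chrom] = np.stack(products)
    return gamete


def simulate_gametes(
    parent: SimulatedParent,
    chromosomes: Mapping[str, ChromosomeModel],
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw n gametes; returns per chromosome an (n, 2, M) uint8 array."""
    out = {
        chrom: np.empty((n, 2, model.n_markers), dtype=np.uint8)
        for chrom, model in chromosomes.items()
    }
    for chrom, model in chromosomes.items():
        haps = parent.haplotypes[chrom]
        pos = model.positions_cM
        length = model.length_cM
        pairing_idx = rng.integers(0, 3, size=n)
        buf = out[chrom]
        for i in range(n):
            pairing = _BIVALENT_PAIRINGS[pairing_idx[i]]
            for b, (a1, a2) in enumerate(pairing):
                buf[i, b] = _recombinant_product(haps[a1], haps[a2], pos, length, rng)
    return out


def expected_gamete_dosage_distribution(parent_dosage: int) -> dict[int, float]:
    """Exact gamete dosage distribution under random bivalent pairing.

    Enumerates the three equally likely pairings of four homologs
    carrying ``parent_dosage`` copies of allele A and, per bivalent, the
    two equally likely transmitted homologs — 12 equiprobable outcomes.
    For a duplex parent this yields {0: 1/6, 1: 2/3, 2: 1/6}; for a
    simplex parent {0: 1/2, 1: 1/2}.
    """
    if not 0 <= parent_dosage <= 4:
        raise ValueError("parent dosage must be in 0..4")
    homologs = [1] * parent_dosage + [0] * (4 - parent_dosage)
    counts: dict[int, int] = {}
    total = 0
    for (a1, a2), (b1, b2) in _BIVALENT_PAIRINGS:
        for pick1, pick2 in itertools.product((a1, a2), (b1, b2)):
            d = homologs[pick1] + homologs[pick2]
            counts[d] = counts.get(d, 0) + 1
            total += 1
    return {d: c / total for d, c in sorted(counts.items())}


def expected_presence_absence_ratio(parent_dosage: int) -> float:
    """Expected presence:absence ratio of allele A among F1 progeny of a
    ``parent_dosage``-plex by nulliplex cross (ratio : 1).

    Simplex gives 1.0 (1:1); duplex gives 5.0 (5:1).
    """
    dist = expected_gamete_dosage_distribution(parent_dosage)
    p_absent = dist.get(0, 0.0)
    if p_absent in (0.0, 1.0):
        raise ValueError("degenerate cross: allele always or never transmitted")
    return (1.0 - p_absent) / p_absent


def make_progeny(
    mother: SimulatedParent,
    father: SimulatedParent,
    chromosomes: Mapping[str, ChromosomeModel],
    marker_info: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> TruthSet:
    """Cross the parents and return the latent truth for n_progeny survivors.

    Each progeny is the union of one maternal and one paternal gamete.
    Viability loci act at conception by rejection sampling: a conceptus
    carrying allele A at the locus survives with the configured
    probability, and conception is repeated until n_progeny survive.
    """
    chrom_names = list(chromosomes)
    marker_order = [m for c in chrom_names for m in chromosomes[c].marker_ids]
    # map viability marker -> (chrom, column index within chrom)
    via_lookup = []
    for mid, s in config.viability_loci:
        if mid not in marker_info.index:
            raise KeyError(f"viability locus {mid!r} is not a simulated marker")
        chrom = marker_info.loc[mid, "chromosome"]
        j = chromosomes[chrom].marker_ids.index(mid)
        via_lookup.append((chrom, j, s))

    kept_m: dict[str, list[np.ndarray]] = {c: [] for c in chrom_names}
    kept_p: dict[str, list[np.ndarray]] = {c: [] for c in chrom_names}
    n_kept = 0
    while n_kept < config.n_progeny:
        batch = max(config.n_progeny - n_kept, 32)
        gm = simulate_gametes(mother, chromosomes, batch, rng)
        gp = simulate_gametes(father, chromosomes, batch, rng)
        survive = np.ones(batch, dtype=bool)
        for chrom, j, s in via_lookup:
            dose = gm[chrom][:, :, j].sum(axis=1) + gp[chrom][:, :, j].sum(axis=1)
            carrier = dose >= 1
            survive &= ~carrier | (rng.random(batch) < s)
        take = np.flatnonzero(survive)[: config.n_progeny - n_kept]
        for chrom in chrom_names:
            kept_m[chrom].append(gm[chrom][take])
            kept_p[chrom].append(gp[chrom][take])
        n_kept += len(take)

    maternal = {c: np.concatenate(kept_m[c], axis=0) for c in chrom_names}
    paternal = {c: np.concatenate(kept_p[c], axis=0) for c in chrom_names}
    progeny_ids = [f"F1_{i + 1:03d}" for i in range(config.n_progeny)]
    dosage_blocks = [
        (maternal[c].sum(axis=1) + paternal[c].sum(axis=1)).T for c in chrom_names
    ]
    dosage = pd.DataFrame(
        np.concatenate(dosage_blocks, axis=0).astype(np.int8),
        index=marker_order,
        columns=progeny_ids,
    )
    return TruthSet(
        marker_info=marker_info.loc[marker_order],
        dosage=dosage,
        maternal_gametes=maternal,
        paternal_gametes=paternal,
        chromosomes=dict(chromosomes),
        mother=mother,
        father=father,
    )


def _reads_from_dosage(
    dosage: np.ndarray,
    locus_mean: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    k = config.depth_dispersion
    m = np.broadcast_to(locus_mean[:, None], dosage.shape)
    p_nb = k / (k + m)
    n_total = rng.negative_binomial(k, p_nb, size=dosage.shape)
    p_a = (dosage / 4.0) * (1.0 - config.alpha) + (1.0 - dosage / 4.0) * config.alpha
    x_a = rng.binomial(n_total, p_a)
    return x_a, n_total - x_a


def simulate_reads(
    truth: TruthSet, config: SimConfig, rng: np.random.Generator
) -> ReadCountMatrix:
    """GBS-like read depths for every progeny plus parent replicate columns.

    Each locus draws a mean-1 gamma factor scaling its expected depth
    (shared by progeny and parent replicates: a poorly cut or poorly
    amplified fragment is shallow in everyone); given the locus mean,
    depth is negative-binomial per cell (zero allowed) and the A-read
    count is binomial with success probability
    (d/4)(1-alpha)+(1-d/4)alpha. Parent replicates are independent
    depth draws from the same true parental dosages, emulating repeated
    library entries of one DNA.
    """
    d_prog = truth.dosage.to_numpy(dtype=float)
    s = config.depth_locus_shape
    locus_mean = config.depth_mean * rng.gamma(s, 1.0 / s, size=d_prog.shape[0])
    xa, xb = _reads_from_dosage(d_prog, locus_mean, config, rng)
    columns = list(truth.dosage.columns)
    blocks_a, blocks_b = [xa], [xb]

    for parent, n_rep, label in (
        (truth.mother, config.parent_replicates[0], "mother"),
        (truth.father, config.parent_replicates[1], "father"),
    ):
        dose = np.concatenate(
            [parent.dosage(c) for c in truth.chromosomes], axis=0
        ).astype(float)
        dose_mat = np.tile(dose[:, None], (1, n_rep))
        pa, pb = _reads_from_dosage(dose_mat, locus_mean, config, rng)
        blocks_a.append(pa)
        blocks_b.append(pb)
        columns += [f"{label}_rep{r + 1}" for r in range(n_rep)]

    x_a = pd.DataFrame(
        np.concatenate(blocks_a, axis=1), index=truth.dosage.index, columns=columns
    )
    x_b = pd.DataFrame(
        np.concatenate(blocks_b, axis=1), index=truth.dosage.index, columns=columns
    )
    return ReadCountMatrix(x_a, x_b)


def parent_read_columns(config: SimConfig) -> dict[str, list[str]]:
    """Replicate-column labels emitted by :func:`simulate_reads` per parent."""
    return {
        "mother": [f"mother_rep{r + 1}" for r in range(config.parent_replicates[0])],
        "father": [f"father_rep{r + 1}" for r in range(config.parent_replicates[1])],
    }


def simulate_cross(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[TruthSet, ReadCountMatrix]:
    """Convenience wrapper: parents -> progeny -> reads for one config."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mother, father, chromosomes, marker_info = make_parents(config)
    truth = make_progeny(mother, father, chromosomes, marker_info, config, rng)
    reads = simulate_reads(truth, config, rng)
    return truth, reads


def synthetic_hit_table(
    true_map: pd.DataFrame,
    rng: np.random.Generator,
    bp_per_cM: float = 5e5,
    bp_noise_sd: float = 1e5,
    noise_frac: float = 0.05,
    n_chromosomes: int | None = None,
) -> pd.DataFrame:
    """Fabricate a BLAST-outfmt6-like hit table consistent with a true map.

    Each marker gets one strong hit on its true chromosome at a physical
    position proportional to its cM position (plus Gaussian jitter), and
    a ``noise_frac`` fraction of markers additionally receive a weak
    spurious hit on a uniformly random chromosome. Spurious hits carry
    e-values passing a loose 1e-5 cutoff but failing a strict 1e-20 one,
    so cutoff tightening removes exactly the noise.
    """
    chroms = sorted(true_map["chromosome"].unique())
    if n_chromosomes is not None:
        chroms = [f"chr{c + 1:02d}" for c in range(n_chromosomes)]
    max_cM = float(true_map["cM"].max())
    rows = []
    for _, r in true_map.iterrows():
        bp = max(1, int(r["cM"] * bp_per_cM + rng.normal(0, bp_noise_sd)))
        rows.append(
            {
                "qseqid": r["marker"],
                "sseqid": r["chromosome"],
                "pident": 98.0,
                "length": 64,
                "mismatch": 1,
                "gapopen": 0,
                "qstart": 1,
                "qend": 64,
                "sstart": bp,
                "send": bp + 63,
                "evalue": 10.0 ** rng.uniform(-45, -30),
                "bitscore": float(rng.integers(110, 130)),
            }
        )
        if rng.random() < noise_frac:
            rows.append(
                {
                    "qseqid": r["marker"],
                    "sseqid": chroms[rng.integers(0, len(chroms))],
                    "pident": 85.0,
                    "length": 50,
                    "mismatch": 7,
                    "gapopen": 1,
                    "qstart": 1,
                    "qend": 50,
                    "sstart": int(rng.uniform(1, max_cM * bp_per_cM)),
                    "send": int(rng.uniform(1, max_cM * bp_per_cM)),
                    "evalue": 10.0 ** rng.uniform(-12, -6),
                    "bitscore": float(rng.integers(40, 60)),
                }
            )
    return pd.DataFrame(rows)


def write_truth_tsv(truth: TruthSet, path) -> None:
    """Long-format dosage truth: columns marker, individual, dosage."""
    long = truth.dosage.stack().rename("dosage").reset_index()
    long.columns = ["marker", "individual", "dosage"]
    long.to_csv(path, sep="\t", index=False)


def write_true_map_tsv(truth: TruthSet, path) -> None:
    truth.true_map().to_csv(path, sep="\t", index=False)
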