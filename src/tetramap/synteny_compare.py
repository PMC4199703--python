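"""Synteny between a genetic map and a reference physical map.

Consumes precomputed sequence-similarity hits (BLAST tabular outfmt-6
dialect) of marker tag sequences against a reference genome. Per marker
the best hit (highest bitscore) under an e-value cutoff is kept; each
linkage group is assigned to the reference chromosome carrying the
majority of its markers' hits; and a dotplot table (genetic cM vs
physical bp) with per-group Spearman collinearity scores supports
visual inspection of inversions and translocations. Structural events
are described (rank discordance, cross-chromosome dot patterns), not
formally modelled.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SyntenyConfig",
    "BLAST_COLUMNS",
    "read_blast_table",
    "filter_best_hits",
    "assign_chromosomes",
    "dotplot_table",
]

BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclasses.dataclass(frozen=True)
class SyntenyConfig:
    evalue_cutoff: float = 1e-5  # strict alternative: 1e-20
    min_votes: int = 3
    ambiguity_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")


def read_blast_table(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column BLAST tabular file; malformed rows are skipped
    with a warning naming their line numbers."""
    rows, bad_lines = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                bad_lines.append(lineno)
                continue
            try:
                rows.append(
                    {
                        "qseqid": parts[0],
                        "sseqid": parts[1],
                        "pident": float(parts[2]),
                        "length": int(parts[3]),
                        "mismatch": int(parts[4]),
                        "gapopen": int(parts[5]),
                        "qstart": int(parts[6]),
                        "qend": int(parts[7]),
                        "sstart": int(parts[8]),
                        "send": int(parts[9]),
                        "evalue": float(parts[10]),
                        "bitscore": float(parts[11]),
                    }
                )
            except ValueError:
                bad_lines.append(lineno)
    if bad_lines:
        warnings.warn(
            f"skipped {len(bad_lines)} malformed hit rows (lines {bad_lines[:10]}"
            + ("...)" if len(bad_lines) > 10 else ")"),
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def filter_best_hits(
    hits: pd.DataFrame, config: SyntenyConfig = SyntenyConfig()
) -> pd.DataFrame:
    """One best hit per marker under the e-value cutoff.

    Best = highest bitscore; ties break by lowest e-value, then lowest
    subject position. Markers with no qualifying hit are dropped. The
    result gains a ``position`` column = min(sstart, send).
    """
    if hits.empty:
        return hits.assign(position=pd.Series(dtype=int)).iloc[0:0]
    qual = hits[hits["evalue"] < config.evalue_cutoff].copy()
    if qual.empty:
        return qual.assign(position=pd.Series(dtype=int))
    qual["position"] = qual[["sstart", "send"]].min(axis=1)
    qual = qual.sort_values(
        ["qseqid", "bitscore", "evalue", "position"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = qual.drop_duplicates("qseqid", keep="first").reset_index(drop=True)
    return best


def assign_chromosomes(
    map_table: pd.DataFrame,
    best_hits: pd.DataFrame,
    config: SyntenyConfig = SyntenyConfig(),
) -> pd.DataFrame:
    """Assign each linkage group to a reference chromosome by majority vote.

    One row per (parent, linkage_group) with columns chromosome,
    n_votes, vote_fraction, status (assigned / ambiguous / unassigned).
    Ambiguous = winning fraction below the ambiguity threshold;
    unassigned = fewer hit-bearing markers than ``min_votes``.
    """
    hit_chrom = best_hits.set_index("qseqid")["sseqid"]
    rows = []
    for (parent, lg), sub in map_table.groupby(["parent", "linkage_group"], sort=True):
        chroms = hit_chrom.reindex(sub["marker"]).dropna()
        if len(chroms) < config.min_votes:
            rows.append(
                {
                    "parent": parent,
                    "linkage_group": lg,
                    "chromosome": "",
                    "n_votes": int(len(chroms)),
                    "vote_fraction": float("nan"),
                    "status": "unassigned",
                }
            )
            continue
        counts = chroms.value_counts()
        top = counts.index[0]
        frac = counts.iloc[0] / counts.sum()
        tie = len(counts) > 1 and counts.iloc[0] == counts.iloc[1]
        status = "ambiguous" if (frac < config.ambiguity_fraction or tie) else "assigned"
        rows.append(
            {
                "parent": parent,
                "linkage_group": lg,
                "chromosome": str(top) if not tie else "",
                "n_votes": int(counts.sum()),
                "vote_fraction": float(frac),
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def dotplot_table(
    map_table: pd.DataFrame,
    best_hits: pd.DataFrame,
    assignments: pd.DataFrame,
    restrict_to_assigned: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dotplot-ready table and per-LG Spearman collinearity scores.

    The table holds (parent, linkage_group, marker, cM, chromosome, bp)
    for every mapped marker with a best hit; with
    ``restrict_to_assigned`` only hits on the LG's assigned chromosome
    are retained (the unrestricted table shows translocation-like
    cross-chromosome patterns). The score per LG is the Spearman rank
    correlation between cM and bp on the assigned chromosome; its sign
    is arbitrary (group orientation is arbitrary), so |rho| is the
    collinearity score.
    """
    bh = best_hits.set_index("qseqid")
    assign_key = assignments.set_index(["parent", "linkage_group"])
    rows = []
    for _, r in map_table.iterrows():
        if r["marker"] not in bh.index:
            continue
        hit = bh.loc[r["marker"]]
        rows.append(
            {
                "parent": r["parent"],
                "linkage_group": r["linkage_group"],
                "marker": r["marker"],
                "cM": float(r["position_cM"]),
                "chromosome": hit["sseqid"],
                "bp": int(hit["position"]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["parent", "linkage_group", "marker", "cM", "chromosome", "bp"]
    )
    score_rows = []
    for (parent, lg), sub in table.groupby(["parent", "linkage_group"], sort=True):
        try:
            assigned = assign_key.loc[(parent, lg), "chromosome"]
        except KeyError:
            assigned = ""
        on_chrom = sub[sub["chromosome"] == assigned] if assigned else sub.iloc[0:0]
        if len(on_chrom) >= 3:
            rho = stats.spearmanr(on_chrom["cM"], on_chrom["bp"]).statistic
        else:
            rho = float("nan")
        score_rows.append(
            {
                "parent": parent,
                "linkage_group": lg,
                "chromosome": assigned,
                "n_markers": int(len(on_chrom)),
                "spearman_rho": float(rho) if rho == rho else float("nan"),
                "collinearity": abs(float(rho)) if rho == rho else float("nan"),
            }
        )
    if restrict_to_assigned and not table.empty:
        keep = []
        for i, r in table.iterrows():
            try:
                assigned = assign_key.loc[(r["parent"], r["linkage_group"]), "chromosome"]
            except KeyError:
                assigned = ""
            keep.append(bool(assigned) and r["chromosome"] == assigned)
        table = table[np.asarray(keep)]
    return table.reset_index(drop=True), pd.DataFrame(score_rows)
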