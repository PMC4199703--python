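"""Shared fixtures: small simulated crosses and pipeline helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tetramap import genotype_model, linkage_map, sda_screen, simulate


def run_calling(cfg: simulate.SimConfig, truth, reads) -> pd.DataFrame:
    """Progeny calls plus consensus parent columns ('mother'/'father')."""
    rep_map = {
        col: parent
        for parent, cols in simulate.parent_read_columns(cfg).items()
        for col in cols
    }
    return genotype_model.consensus_parent_calls(reads, rep_map)


def run_pipeline(cfg: simulate.SimConfig):
    """simulate -> call -> screen -> both parent maps; returns a dict."""
    truth, reads = simulate.simulate_cross(cfg)
    calls = run_calling(cfg, truth, reads)
    sda = sda_screen.screen_markers(calls, "mother", "father")
    maps = []
    for parent in ("maternal", "paternal"):
        presence = sda_screen.presence_matrix(calls, sda, parent, "mother", "father")
        table, unplaced = linkage_map.build_parent_map(presence, parent)
        maps.append(table)
    map_table = pd.concat(maps, ignore_index=True)
    return {
        "config": cfg,
        "truth": truth,
        "reads": reads,
        "calls": calls,
        "sda": sda,
        "map": map_table,
    }


def truth_presence(truth: simulate.TruthSet, parent: str) -> pd.DataFrame:
    """Perfectly typed presence/absence (1/0) of one parent's simplex markers.

    For a simplex marker of the given parent the other parent carries no
    A allele, so progeny dosage >= 1 iff the segregating allele was
    transmitted.
    """
    info = truth.marker_info
    sel = info[(info["type"] == "simplex") & (info["origin"] == parent)].index
    return (truth.dosage.loc[sel] >= 1).astype(float)


def truth_distortion_table(truth: simulate.TruthSet, parent: str) -> pd.DataFrame:
    """Per-marker 1:1 distortion statistics from perfectly typed progeny,
    shaped like the screen output (indexed by marker)."""
    pres = truth_presence(truth, parent)
    rows = {}
    for marker, row in pres.iterrows():
        n_present = int(row.sum())
        n_absent = int(len(row) - n_present)
        d = sda_screen.distortion_test(n_present, n_absent)
        rows[marker] = {
            "n_present": n_present,
            "n_absent": n_absent,
            "p": d.p,
            "neglog10p": d.neglog10p,
            "direction": d.direction,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SimConfig:
    """Two-chromosome cross kept small enough for subsecond pipelines."""
    return simulate.SimConfig(
        n_chromosomes=2, markers_per_homolog=12, n_duplex_per_chrom=2, seed=11
    )


@pytest.fixture(scope="session")
def small_cross(small_cfg):
    truth, reads = simulate.simulate_cross(small_cfg)
    return truth, reads


@pytest.fixture(scope="session")
def small_calls(small_cfg, small_cross):
    truth, reads = small_cross
    return run_calling(small_cfg, truth, reads)


@pytest.fixture(scope="session")
def small_sda(small_calls):
    return sda_screen.screen_markers(small_calls, "mother", "father")
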