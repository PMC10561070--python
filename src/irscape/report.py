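"""Result exports: score tables, BedGraph tracks, summaries, profiles.

The summary mirrors the per-chromosome layout of the enrichment analysis
(one row per chromosome with the window count and percent of enriched
windows per length class, plus "Global %" and "Mean cv" rows).  Profile
tables give, for one window, the observed pair count m(d) next to its
expectation n(d)p(d) — the data behind per-window length-distribution
plots; by convention one exports the windows with the highest total S, the
highest mid-length-class S and the lowest total S of each chromosome.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .counting import DistanceSpectrum, pair_count_spectrum
from .enrichment import CriticalValueTable, summarize
from .genome_io import MaskedChromosome, Window, region_label
from .markov import PairProbability

__all__ = [
    "write_scores",
    "write_bedgraph",
    "write_summary",
    "heatmap_matrix",
    "window_profile",
    "select_profile_windows",
]


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(scores: pd.DataFrame, label: str, path: str | Path) -> None:
    """One BedGraph track of S values for a single length class."""
    col = f"S_{label}"
    if col not in scores.columns:
        raise KeyError(f"no scores for class {label!r}")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="S_{label}"\n')
        for row in scores.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{getattr(row, col):.6g}\n")


def write_summary(calls: pd.DataFrame, cvtable: CriticalValueTable, path: str | Path) -> pd.DataFrame:
    table = summarize(calls, cvtable)
    table.round(1).to_csv(path, sep="\t")
    return table


def heatmap_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Windows x classes matrix of S values (rows labelled chrom:start:end)."""
    labels = [c for c in scores.columns if c.startswith("S_")]
    idx = [
        region_label(r.chrom, r.start, r.end) for r in scores.itertuples()
    ]
    mat = scores[labels].copy()
    mat.columns = [c[2:] for c in labels]
    mat.index = pd.Index(idx, name="window")
    return mat


def window_profile(spectrum: DistanceSpectrum, pp: PairProbability) -> pd.DataFrame:
    """Per-distance profile of one window: d, m, n and expected = n(d)p(d)."""
    if spectrum.k != pp.k or spectrum.d_max != pp.d_max:
        raise ValueError("spectrum and pair probability index ranges differ")
    return pd.DataFrame(
        {
            "d": spectrum.d,
            "m": spectrum.m,
            "n": spectrum.n,
            "expected": spectrum.n * pp.p,
        }
    )


def select_profile_windows(
    scores: pd.DataFrame, total_label: str = "I_t", mid_label: str = "I_5"
) -> pd.DataFrame:
    """Per chromosome: highest S(total), highest S(mid class), lowest S(total).

    Returns rows of ``scores`` with an added ``criterion`` column.
    """
    picks = []
    for _, grp in scores.groupby("chrom", sort=False):
        for crit, col, fn in (
            (f"highest_{total_label}", f"S_{total_label}", "idxmax"),
            (f"highest_{mid_label}", f"S_{mid_label}", "idxmax"),
            (f"lowest_{total_label}", f"S_{total_label}", "idxmin"),
        ):
            if col not in grp.columns:
                continue
            row = grp.loc[getattr(grp[col], fn)()].copy()
            row["criterion"] = crit
            picks.append(row)
    return pd.DataFrame(picks).reset_index(drop=True)
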