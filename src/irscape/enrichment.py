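"""Enrichment statistics: z-scores, class scores S, critical values, calls.

Under the null, the observed pair count M(d) in a window is modelled as
binomial B(n(d), p(d)), giving the z-score

    Z(d) = (M(d) - n(d) p(d)) / sqrt(n(d) p(d) (1 - p(d))).

T(d) is the ambiguity-adjusted variant: n(d) is the mask-aware count of
possible pair positions, and distances with no information (n(d) = 0, or a
degenerate null probability) contribute T(d) = 0.  The enrichment
statistic for a distance interval is the inclusive sum

    S[d1, d2] = sum_{d = d1}^{d2} T(d),

and a window is called enriched for a length class when its S strictly
exceeds the empirical critical value — the 0.95 nearest-rank quantile of S
over all windows of a control genome simulated from the fitted null.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import DistanceSpectrum
from .genome_io import Window
from .markov import PairProbability

__all__ = [
    "LengthClass",
    "EnrichmentResult",
    "CriticalValueTable",
    "default_length_classes",
    "zscore",
    "adjusted_zscores",
    "class_score",
    "class_scores",
    "empirical_critical_value",
    "call_enrichment",
    "summarize",
]


@dataclass(frozen=True)
class LengthClass:
    """Inclusive distance interval [d1, d2] labelling a repeat-length class."""

    label: str
    d1: int
    d2: int

    def __post_init__(self) -> None:
        if self.d2 < self.d1:
            raise ValueError(f"class {self.label}: d2 < d1")


def default_length_classes(k: int, d_max: int, n_classes: int = 8) -> list[LengthClass]:
    """The total class I_t = [k, d_max] plus n equal-width numbered classes.

    With k = 7, d_max = 4000 this yields I_1 = [7, 500], I_2 = [501, 1000],
    ... I_8 = [3501, 4000]; at other scales the same geometry is kept
    (class 1 starts at k, boundaries at multiples of d_max / n_classes).
    """
    if d_max % n_classes:
        raise ValueError("d_max must be divisible by the number of classes")
    w = d_max // n_classes
    if w < k:
        raise ValueError("class width below k; reduce n_classes")
    classes = [LengthClass("I_t", k, d_max)]
    for j in range(1, n_classes + 1):
        d1 = k if j == 1 else (j - 1) * w + 1
        classes.append(LengthClass(f"I_{j}", d1, j * w))
    return classes


def zscore(M, n, p):
    """Binomial z-score (M - n p) / sqrt(n p (1 - p)); 0 where n = 0."""
    M = np.asarray(M, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (M - n * p) / np.sqrt(n * p * (1 - p))
    z = np.where(n > 0, z, 0.0)
    return float(z) if z.ndim == 0 else z


def adjusted_zscores(spectrum: DistanceSpectrum, pp: PairProbability) -> np.ndarray:
    """T(d): the z-score with mask-aware n(d); 0 where n = 0 or the null degenerates."""
    if spectrum.k != pp.k or spectrum.d_max != pp.d_max:
        raise ValueError("spectrum and pair probability index ranges differ")
    T = zscore(spectrum.m, spectrum.n, pp.p)
    return np.where(pp.degenerate, 0.0, T)


def class_score(T: np.ndarray, cls: LengthClass, k: int) -> float:
    """S[d1, d2]: inclusive sum of T(d) over the class interval."""
    lo, hi = cls.d1 - k, cls.d2 - k + 1
    if lo < 0 or hi > T.size:
        raise ValueError(f"class {cls.label} [{cls.d1},{cls.d2}] outside spectrum range")
    return float(T[lo:hi].sum())


def class_scores(T: np.ndarray, classes: list[LengthClass], k: int) -> dict[str, float]:
    return {c.label: class_score(T, c, k) for c in classes}


@dataclass
class EnrichmentResult:
    """Per-window T spectrum, class scores and (optional) enrichment flags."""

    window: Window
    T: np.ndarray
    S: dict[str, float]
    flags: dict[str, bool] = field(default_factory=dict)
    informative: bool = True  # False when n(d) = 0 everywhere (fully masked)


def empirical_critical_value(values, alpha: float = 0.05) -> float:
    """Nearest-rank upper quantile: element at rank ceil((1 - alpha) N), 1-based.

    alpha = 0 returns the maximum.  Conservative and always an observed
    value.
    """
    values = np.sort(np.asarray(values, dtype=np.float64))
    N = values.size
    if N == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    rank = N if alpha == 0 else math.ceil((1 - alpha) * N)
    rank = min(max(rank, 1), N)
    return float(values[rank - 1])


@dataclass
class CriticalValueTable:
    """Empirical thresholds per (scope, class); scope is a chromosome or 'global'."""

    alpha: float
    cv: dict[str, dict[str, float]]
    window_counts: dict[str, int]
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def lookup(self, chrom: str, label: str) -> float:
        scope = chrom if chrom in self.cv else "global"
        if scope not in self.cv:
            raise KeyError(f"no critical values for scope {chrom!r} or 'global'")
        return self.cv[scope][label]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "format": "irscape-cv",
            "version": 1,
            "alpha": self.alpha,
            "replicates": self.replicates,
            "seed": self.seed,
            "window_counts": self.window_counts,
            "cv": self.cv,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CriticalValueTable":
        obj = json.loads(Path(path).read_text())
        if obj.get("format") != "irscape-cv":
            raise ValueError(f"{path}: not an irscape critical-value file")
        return cls(
            alpha=obj["alpha"],
            cv=obj["cv"],
            window_counts={s: int(n) for s, n in obj["window_counts"].items()},
            replicates=int(obj.get("replicates", 1)),
            seed=obj.get("seed"),
        )


def call_enrichment(scores: pd.DataFrame, cvtable: CriticalValueTable) -> pd.DataFrame:
    """Flag windows whose S strictly surpasses the critical value.

    ``scores`` is a tidy frame with one row per window: columns ``chrom``,
    ``window``, ``start``, ``end``, ``informative`` and one ``S_<label>``
    column per class.  Returns the frame with added ``enriched_<label>``
    boolean columns; uninformative (fully masked) windows are never
    flagged.
    """
    labels = [c[2:] for c in scores.columns if c.startswith("S_")]
    out = scores.copy()
    for label in labels:
        cv = scores["chrom"].map(lambda ch: cvtable.lookup(ch, label))
        out[f"enriched_{label}"] = (scores[f"S_{label}"] > cv) & scores["informative"]
    return out


def summarize(calls: pd.DataFrame, cvtable: CriticalValueTable) -> pd.DataFrame:
    """Per-chromosome percent of enriched windows per class, plus summary rows.

    Mirrors the layout of a per-chromosome results table: one row per
    chromosome with the window count ("Wins") and the percentage of flagged
    windows in each class (fully masked windows stay in the denominator),
    then a "Global %" row over all windows and a "Mean cv" row — the
    window-count-weighted mean of the per-scope critical values.
    """
    labels = [c[9:] for c in calls.columns if c.startswith("enriched_")]
    rows = {}
    for chrom, grp in calls.groupby("chrom", sort=False):
        row = {"Wins": len(grp)}
        for label in labels:
            row[label] = 100.0 * grp[f"enriched_{label}"].sum() / len(grp)
        rows[chrom] = row
    total = len(calls)
    rows["Global %"] = {"Wins": total} | {
        label: 100.0 * calls[f"enriched_{label}"].sum() / total for label in labels
    }
    scopes = [s for s in cvtable.cv if s in set(calls["chrom"])] or list(cvtable.cv)
    weights = np.array([cvtable.window_counts[s] for s in scopes], dtype=float)
    rows["Mean cv"] = {"Wins": int(weights.sum())} | {
        label: float(
            np.average([cvtable.cv[s][label] for s in scopes], weights=weights)
        )
        for label in labels
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "Chr"
    return df
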