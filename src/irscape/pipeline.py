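"""Pipeline orchestration: configuration, scanning, control-scenario cv.

The full procedure for one genome:

1. fit one order-k Markov model per chromosome (or one global model);
2. compute p(d) once per model and share it across that model's windows;
3. per window, count the pair spectrum, form T(d) and the class scores S;
4. simulate a control genome (same lengths, same N-mask) from the fitted
   models, score it identically, and take per-scope nearest-rank 0.95
   quantiles of its S values as critical values;
5. flag real windows whose S strictly exceeds the critical value.

Randomness: a single run seed; per-(chromosome, replicate) child seeds are
derived with ``numpy.random.SeedSequence(run_seed, [crc32(name), rep])`` so
results do not depend on processing order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome_io import MaskedChromosome, Window, make_windows
from .counting import DistanceSpectrum, pair_count_spectrum
from .markov import MarkovModel, PairProbability, fit_markov, pair_probability, simulate_sequence
from .enrichment import (
    CriticalValueTable,
    EnrichmentResult,
    LengthClass,
    adjusted_zscores,
    call_enrichment,
    class_scores,
    default_length_classes,
    empirical_critical_value,
)

__all__ = [
    "RunConfig",
    "child_seed",
    "fit_models",
    "scan_genome",
    "simulate_control",
    "critical_values_from_scores",
    "simulate_cv",
    "run_scan_and_call",
]


@dataclass
class RunConfig:
    """Run parameters; the defaults are the genome-scale analysis settings
    (word length 7, distances up to 4000 nt, 100-kb windows, 5% level)."""

    k: int = 7
    d_max: int = 4000
    window_size: int = 100_000
    alpha: float = 0.05
    cv_scope: str = "chromosome"      # "chromosome" | "global"
    horizon: int = 50
    replicates: int = 1
    n_classes: int = 8
    seed: int = 0
    overhang: bool = False
    hard_mask_lower: bool = False
    classes: list[tuple[int, int]] | None = None  # explicit [d1, d2] list

    def __post_init__(self) -> None:
        if self.cv_scope not in ("chromosome", "global"):
            raise ValueError("cv_scope must be 'chromosome' or 'global'")
        if self.window_size < self.d_max + 2 * self.k:
            import warnings

            warnings.warn(
                "window_size below d_max + 2k: spectrum truncation dominates",
                stacklevel=2,
            )

    def length_classes(self) -> list[LengthClass]:
        if self.classes:
            return [LengthClass(f"{d1}:{d2}", d1, d2) for d1, d2 in self.classes]
        return default_length_classes(self.k, self.d_max, self.n_classes)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        if obj.get("classes"):
            obj["classes"] = [tuple(c) for c in obj["classes"]]
        return cls(**obj)


def child_seed(seed: int, *keys: int | str) -> int:
    """Deterministic, order-independent child seed below 2^31."""
    parts = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        if isinstance(key, str):
            key = zlib.crc32(key.encode())
        parts.append(int(key) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(parts)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def fit_models(
    chroms: list[MaskedChromosome], k: int, scope: str = "chromosome"
) -> dict[str, MarkovModel]:
    """One model per chromosome, or a single pooled 'global' model."""
    if scope == "global":
        return {"global": fit_markov(chroms, k, source="global")}
    return {ch.name: fit_markov(ch, k, source=ch.name) for ch in chroms}


def _model_for(models: dict[str, MarkovModel], chrom: str) -> MarkovModel:
    if chrom in models:
        return models[chrom]
    if "global" in models:
        return models["global"]
    raise KeyError(f"no model for chromosome {chrom!r} and no global model")


def scan_genome(
    chroms: list[MaskedChromosome],
    models: dict[str, MarkovModel],
    cfg: RunConfig,
    pair_probs: dict[str, PairProbability] | None = None,
    spectra_out: list[DistanceSpectrum] | None = None,
    keep_T: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[EnrichmentResult]]:
    """Score every window of a genome; returns a tidy per-window frame.

    Columns: chrom, window, start, end, informative, and one ``S_<label>``
    per length class.  ``pair_probs`` may carry precomputed p(d) (they are
    computed once per model otherwise).  With ``keep_T`` the full
    per-window results (including T spectra) are returned as well.
    """
    classes = cfg.length_classes()
    if pair_probs is None:
        pair_probs = {}
    rows = []
    results: list[EnrichmentResult] = []
    for chrom in chroms:
        model = _model_for(models, chrom.name)
        key = model.source
        if key not in pair_probs:
            pair_probs[key] = pair_probability(model, cfg.d_max, cfg.horizon)
        pp = pair_probs[key]
        for win in make_windows(chrom, cfg.window_size):
            sp = pair_count_spectrum(chrom, win, cfg.k, cfg.d_max, overhang=cfg.overhang)
            T = adjusted_zscores(sp, pp)
            S = class_scores(T, classes, cfg.k)
            informative = bool(sp.n.any())
            rows.append(
                {
                    "chrom": win.chrom,
                    "window": win.index,
                    "start": win.start,
                    "end": win.end,
                    "informative": informative,
                }
                | {f"S_{label}": s for label, s in S.items()}
            )
            if spectra_out is not None:
                spectra_out.append(sp)
            if keep_T:
                results.append(EnrichmentResult(win, T, S, informative=informative))
    df = pd.DataFrame(rows)
    return (df, results) if keep_T else df


def simulate_control(
    chroms: list[MaskedChromosome],
    models: dict[str, MarkovModel],
    seed: int,
    replicate: int = 0,
) -> list[MaskedChromosome]:
    """One control-scenario genome: same sizes and N-masks, null sequence."""
    out = []
    for ch in chroms:
        model = _model_for(models, ch.name)
        out.append(simulate_sequence(model, ch, child_seed(seed, ch.name, replicate)))
    return out


def critical_values_from_scores(
    scores: pd.DataFrame,
    alpha: float,
    scope: str = "chromosome",
    replicates: int = 1,
    seed: int | None = None,
) -> CriticalValueTable:
    """Nearest-rank quantiles of control S values, per chromosome or globally."""
    labels = [c[2:] for c in scores.columns if c.startswith("S_")]
    cv: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    if scope == "global":
        groups = [("global", scores)]
    else:
        groups = list(scores.groupby("chrom", sort=False))
    for name, grp in groups:
        cv[name] = {
            label: empirical_critical_value(grp[f"S_{label}"].to_numpy(), alpha)
            for label in labels
        }
        counts[name] = len(grp)
    return CriticalValueTable(alpha, cv, counts, replicates=replicates, seed=seed)


def simulate_cv(
    chroms: list[MaskedChromosome],
    models: dict[str, MarkovModel],
    cfg: RunConfig,
    seed: int | None = None,
    pair_probs: dict[str, PairProbability] | None = None,
) -> CriticalValueTable:
    """Critical values from ``cfg.replicates`` simulated control genomes."""
    seed = cfg.seed if seed is None else seed
    pooled = []
    for rep in range(cfg.replicates):
        control = simulate_control(chroms, models, seed, replicate=rep)
        pooled.append(scan_genome(control, models, cfg, pair_probs=pair_probs))
    scores = pd.concat(pooled, ignore_index=True)
    return critical_values_from_scores(
        scores, cfg.alpha, cfg.cv_scope, replicates=cfg.replicates, seed=seed
    )


def run_scan_and_call(
    chroms: list[MaskedChromosome], cfg: RunConfig
) -> tuple[pd.DataFrame, CriticalValueTable, dict[str, MarkovModel]]:
    """End-to-end convenience: fit, scan, simulate cv, call enrichment."""
    model_scope = "global" if cfg.cv_scope == "global" else "chromosome"
    models = fit_models(chroms, cfg.k, model_scope)
    pair_probs: dict[str, PairProbability] = {}
    scores = scan_genome(chroms, models, cfg, pair_probs=pair_probs)
    cvtable = simulate_cv(chroms, models, cfg, pair_probs=pair_probs)
    calls = call_enrichment(scores, cvtable)
    return calls, cvtable, models
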