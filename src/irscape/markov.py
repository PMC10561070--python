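"""Order-k Markov null model: fitting, pair probabilities, simulation.

The null for a chromosome is a Markov chain of order k over {A,C,G,T},
estimated from the chromosome's unambiguous runs (ambiguous symbols
terminate dependence, so word and transition counts never straddle an N
gap).  The model serves two purposes:

* computing ``p(d)``, the probability that a word occurrence at some
  position is followed at start-to-start distance d by its reverse
  complement — the expectation entering the binomial z-score; and
* simulating control genomes of identical length and N-mask, from which
  empirical critical values for the enrichment statistic are drawn.

For the chain of order k the state after emitting k symbols *is* those k
symbols, so the probability that the k symbols emitted after a gap of
``g = d - k`` steps spell a given word u starting from state w is simply
``(A^d)[w, u]`` where A is the word-level transition operator.  Hence

    p(d) = sum_w pi(w) * (A^d)[w, rc(w)]      for g <= horizon,

and beyond the horizon the chain is taken to have mixed, giving the flat
stationary tail ``p_inf = sum_w pi(w) * (pi A^k)[rc(w)]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy import sparse

from .genome_io import AMBIG, MaskedChromosome, segment_runs
from .counting import word_codes

EPS = 1e-12
_BASES = "ACGT"

__all__ = [
    "MarkovModel",
    "PairProbability",
    "fit_markov",
    "pair_probability",
    "simulate_sequence",
    "rc_permutation",
    "word_to_string",
    "string_to_word",
]


def word_to_string(w: int, k: int) -> str:
    return "".join(_BASES[(w >> (2 * (k - 1 - j))) & 3] for j in range(k))


def string_to_word(s: str) -> int:
    w = 0
    for ch in s:
        w = (w << 2) | _BASES.index(ch)
    return w


def rc_permutation(k: int) -> np.ndarray:
    """Permutation sending each word index to its reverse complement's index."""
    idx = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(idx)
    tmp = idx.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


@dataclass
class MarkovModel:
    """Order-k word probabilities pi and word->base transition probabilities."""

    k: int
    pi: np.ndarray            # shape (4**k,)
    trans: np.ndarray         # shape (4**k, 4)
    source: str = "global"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        self.trans = np.asarray(self.trans, dtype=np.float64)
        if self.pi.shape != (4**self.k,) or self.trans.shape != (4**self.k, 4):
            raise ValueError("pi/trans shapes inconsistent with order k")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("word probabilities must sum to 1")
        rowsum = self.trans.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-9):
            raise ValueError("every transition row must sum to 1")
        if self.pi.min() < 0 or self.trans.min() < 0:
            raise ValueError("probabilities must be non-negative")

    def base_marginal(self) -> np.ndarray:
        """Single-base marginal implied by pi (last-base margin of the word law)."""
        return self.pi.reshape(-1, 4).sum(axis=0)

    def to_dict(self) -> dict:
        """Versioned sparse representation (words written as ACGT strings)."""
        k = self.k
        uniform = np.full(4, 0.25)
        return {
            "format": "irscape-markov",
            "version": 1,
            "k": k,
            "source": self.source,
            "pi": {
                word_to_string(w, k): self.pi[w]
                for w in np.nonzero(self.pi)[0]
            },
            "trans": {
                word_to_string(w, k): self.trans[w].tolist()
                for w in range(4**k)
                if not np.allclose(self.trans[w], uniform)
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, obj: dict) -> "MarkovModel":
        if obj.get("format") != "irscape-markov":
            raise ValueError("not an irscape Markov model object")
        k = int(obj["k"])
        pi = np.zeros(4**k)
        for s, v in obj["pi"].items():
            pi[string_to_word(s)] = v
        trans = np.full((4**k, 4), 0.25)
        for s, row in obj["trans"].items():
            trans[string_to_word(s)] = row
        return cls(k, pi, trans, obj.get("source", "global"))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkovModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_markov(
    chroms: list[MaskedChromosome] | MaskedChromosome,
    k: int,
    source: str | None = None,
) -> MarkovModel:
    """Estimate pi and the transition matrix from unambiguous runs.

    Word counts pool every k-mer start position across runs; transition
    counts pool every (word, next base) adjacency, counted within runs
    only.  Words never observed get pi = 0 and a uniform transition row.
    """
    if isinstance(chroms, MaskedChromosome):
        chroms = [chroms]
    nwords = 4**k
    pi_counts = np.zeros(nwords, dtype=np.int64)
    tr_counts = np.zeros(nwords * 4, dtype=np.int64)
    longest = 0
    for ch in chroms:
        for r in ch.runs:
            longest = max(longest, r.length)
            if r.length < k:
                continue
            seg = np.asarray(ch.codes[r.start : r.end], dtype=np.int64)
            w = word_codes(seg, k)
            pi_counts += np.bincount(w, minlength=nwords)
            if r.length > k:
                idx = w[:-1] * 4 + seg[k:]
                tr_counts += np.bincount(idx, minlength=nwords * 4)
    if longest <= k:
        raise ValueError(f"no unambiguous run longer than k={k}; cannot fit model")
    pi = pi_counts / pi_counts.sum()
    tr = tr_counts.reshape(nwords, 4).astype(np.float64)
    rowsum = tr.sum(axis=1)
    seen = rowsum > 0
    tr[seen] /= rowsum[seen, None]
    tr[~seen] = 0.25
    if source is None:
        source = chroms[0].name if len(chroms) == 1 else "global"
    return MarkovModel(k, pi, tr, source)


@dataclass
class PairProbability:
    """p(d) for d in [k, d_max]; constant stationary tail past k + horizon."""

    k: int
    d_max: int
    horizon: int
    p: np.ndarray
    degenerate: np.ndarray = field(default=None)  # p clipped at 0/1: null uninformative

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(self.p.size, dtype=bool)

    @property
    def d(self) -> np.ndarray:
        return np.arange(self.k, self.d_max + 1)


def _word_operator(model: MarkovModel) -> sparse.csr_matrix:
    """Sparse word-level transition operator A[w, shift(w, b)] = trans[w, b]."""
    k, nwords = model.k, 4**model.k
    rows = np.repeat(np.arange(nwords), 4)
    bases = np.tile(np.arange(4), nwords)
    cols = (rows % (4 ** (k - 1))) * 4 + bases
    return sparse.csr_matrix(
        (model.trans.ravel(), (rows, cols)), shape=(nwords, nwords)
    )


def pair_probability(model: MarkovModel, d_max: int, horizon: int = 50) -> PairProbability:
    """Expected pair probability p(d), d = k .. d_max, under the fitted chain.

    Exact state propagation up to gap = ``horizon`` steps, then the flat
    pi-averaged tail.  Values are clipped to [EPS, 1-EPS]; distances whose
    raw value lies outside (0, 1) are flagged degenerate so downstream
    z-scores can be zeroed.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    k = model.k
    if d_max < k:
        raise ValueError("d_max must be >= k")
    nwords = 4**k
    rc = rc_permutation(k)
    A = _word_operator(model)
    # M = A^k: probability of emitting each word over the next k steps
    M = A.toarray()
    for _ in range(k - 1):
        M = M @ A
    q = model.pi @ M                      # emission law from the pi-average
    p_inf = float(model.pi @ q[rc])
    rows = np.arange(nwords)
    p = np.empty(d_max - k + 1)
    gmax = min(horizon, d_max - k)
    for g in range(gmax + 1):
        if g > 0:
            M = M @ A
        p[g] = float(model.pi @ M[rows, rc])
    if gmax < d_max - k:
        p[gmax + 1 :] = p_inf
    degenerate = (p <= EPS) | (p >= 1 - EPS)
    return PairProbability(k, d_max, horizon, np.clip(p, EPS, 1 - EPS), degenerate)


@njit(cache=False)
def _fill_runs(out, starts, lengths, cum_pi, cum_trans, cum_marg, k, seed):  # pragma: no cover
    np.random.seed(seed)
    kpow1 = 4 ** (k - 1)
    nwords = cum_pi.size
    for r in range(starts.size):
        s = starts[r]
        L = lengths[r]
        if L < k:
            for t in range(L):
                u = np.random.random()
                b = np.searchsorted(cum_marg, u, side="right")
                if b > 3:
                    b = 3
                out[s + t] = b
        else:
            u = np.random.random()
            w = np.searchsorted(cum_pi, u, side="right")
            if w >= nwords:
                w = nwords - 1
            tmp = w
            for j in range(k - 1, -1, -1):
                out[s + j] = tmp & 3
                tmp >>= 2
            for t in range(k, L):
                u = np.random.random()
                row = cum_trans[w]
                b = 0
                while b < 3 and u >= row[b]:
                    b += 1
                out[s + t] = b
                w = (w % kpow1) * 4 + b


def simulate_sequence(
    model: MarkovModel, template: MaskedChromosome, seed: int
) -> MaskedChromosome:
    """Simulate a chromosome with the template's exact length and N-mask.

    Each unambiguous run is generated independently: the first k symbols
    are a word drawn from pi, later symbols follow the transition law; runs
    shorter than k are filled i.i.d. from the base marginal of pi.  The
    chain restarts at every run boundary.  Identical seeds give identical
    output.
    """
    if model.pi.sum() <= 0 or not np.isfinite(model.pi).all():
        raise ValueError("model has no usable word probabilities")
    out = np.full(template.length, AMBIG, dtype=np.uint8)
    starts = np.array([r.start for r in template.runs], dtype=np.int64)
    lengths = np.array([r.length for r in template.runs], dtype=np.int64)
    if starts.size:
        _fill_runs(
            out,
            starts,
            lengths,
            np.cumsum(model.pi),
            np.cumsum(model.trans, axis=1),
            np.cumsum(model.base_marginal()),
            model.k,
            int(seed) & 0xFFFFFFFF,
        )
    return MaskedChromosome(template.name, out, list(template.runs))
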