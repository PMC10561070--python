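"""Inverted-repeat pair spectra.

An inverted repeat is a k-nt word followed downstream by its reverse
complement; ``d``, the difference of the two start positions, equals the
stem length plus the loop length, and ``d = k`` means the words are
adjacent.  Per window this module counts ``m(d)``, the number of ordered
word/reverse-complement pairs at every distance ``d`` in ``[k, d_max]``,
and ``n(d)``, the number of positions where such a pair could sit.  Both
words and the enclosed loop must lie inside a single unambiguous run, so
masked (``N``) positions act as separators and never contribute.

The counter groups word occurrences by k-mer code and histograms the
start-position differences between each word's occurrences and its reverse
complement's, which is exact and runs in roughly O(L log L + pairs) per
window instead of O(L * d_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import AMBIG, MaskedChromosome, UnambiguousRun, Window, clip_runs

__all__ = [
    "DistanceSpectrum",
    "reverse_complement",
    "word_codes",
    "rc_word_codes",
    "pair_count_spectrum",
    "valid_pair_counts",
    "write_spectra",
]


def reverse_complement(word: np.ndarray) -> np.ndarray:
    """Reverse-complement a word of symbol codes (A<->T, C<->G).

    An involution: applying it twice returns the input.  Ambiguous codes
    are rejected — reverse complementation is only defined over {A,C,G,T}.
    """
    word = np.asarray(word)
    if word.size and word.max() >= AMBIG:
        raise ValueError("cannot reverse-complement an ambiguous symbol")
    return (3 - word)[::-1]


def word_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of every k-mer start position (MSB = first base)."""
    codes = np.asarray(codes, dtype=np.int64)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    w = np.zeros(n, dtype=np.int64)
    for j in range(k):
        w = w * 4 + codes[j : j + n]
    return w


def rc_word_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 code of the reverse complement of every k-mer."""
    codes = np.asarray(codes, dtype=np.int64)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    w = np.zeros(n, dtype=np.int64)
    # rc reverses position order, so the first base of the k-mer becomes the
    # least-significant digit of the rc code
    for j in range(k - 1, -1, -1):
        w = w * 4 + (3 - codes[j : j + n])
    return w


@dataclass
class DistanceSpectrum:
    """Observed (m) and possible (n) pair counts for one window, d in [k, d_max]."""

    k: int
    d_max: int
    m: np.ndarray
    n: np.ndarray
    window: Window | None = None

    @property
    def d_min(self) -> int:
        return self.k

    @property
    def d(self) -> np.ndarray:
        return np.arange(self.k, self.d_max + 1)

    def __post_init__(self) -> None:
        expect = self.d_max - self.k + 1
        if self.m.size != expect or self.n.size != expect:
            raise ValueError("spectrum arrays must span d = k .. d_max inclusive")


def valid_pair_counts(
    runs: list[UnambiguousRun],
    k: int,
    d_max: int,
    first_word_limit: int | None = None,
) -> np.ndarray:
    """Possible pair positions n(d) = sum over runs of max(0, L_run - d - k + 1).

    Both words and the enclosed loop must fit in one run.  With
    ``first_word_limit`` (exclusive genome coordinate) the first word must
    additionally end at or before the limit; this supports counting with a
    right overhang where partners may extend past a window edge.
    """
    d = np.arange(k, d_max + 1, dtype=np.int64)
    n = np.zeros(d.size, dtype=np.int64)
    for r in runs:
        last_start = r.end - d - k  # last admissible first-word start
        if first_word_limit is not None:
            last_start = np.minimum(last_start, first_word_limit - k)
        n += np.maximum(0, last_start - r.start + 1)
    return n


def pair_count_spectrum(
    chrom: MaskedChromosome,
    window: Window,
    k: int,
    d_max: int,
    overhang: bool = False,
) -> DistanceSpectrum:
    """Count inverted-repeat pairs by distance inside one window.

    Every ordered pair of positions (i, i + d) with word(i) equal to the
    reverse complement of word(i + d) counts, provided the whole span
    [i, i + d + k) is unambiguous and inside the window.  With ``overhang``
    the first word must still start in the window but the partner may
    extend up to ``d_max + k`` nt past the window's right edge (never past
    the chromosome).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if d_max < k:
        raise ValueError("d_max must be >= k")
    right = min(window.end + d_max + k, chrom.length) if overhang else window.end
    limit = window.end if overhang else None
    runs = clip_runs(chrom.runs, window.start, right)
    n = valid_pair_counts(runs, k, d_max, first_word_limit=limit)
    n_d = d_max - k + 1
    m = np.zeros(n_d, dtype=np.int64)
    if not runs:
        return DistanceSpectrum(k, d_max, m, n, window)

    # Remap run-local coordinates onto one axis with > d_max of dead space
    # between runs so cross-run differences always exceed d_max.
    w_keys, rc_keys = [], []
    offset = 0
    for r in runs:
        L = r.length
        if L >= k:
            seg = chrom.codes[r.start : r.end]
            pos = np.arange(L - k + 1, dtype=np.int64) + offset
            wc = word_codes(seg, k)
            rcc = rc_word_codes(seg, k)
            if limit is not None:
                keep = pos - offset + r.start + k <= limit
                w_keys.append((wc[keep], pos[keep]))
            else:
                w_keys.append((wc, pos))
            rc_keys.append((rcc, pos))
        offset += L + d_max + 1
    if not w_keys:
        return DistanceSpectrum(k, d_max, m, n, window)

    big = offset + d_max + 2  # position stride; keeps word blocks disjoint
    a = np.sort(np.concatenate([wc * big + pos for wc, pos in w_keys]))
    b = np.sort(np.concatenate([wc * big + pos for wc, pos in rc_keys]))
    lo = np.searchsorted(b, a + k)
    hi = np.searchsorted(b, a + d_max + 1)
    counts = hi - lo
    total = int(counts.sum())
    if total:
        group = np.repeat(np.arange(a.size), counts)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        idx = np.arange(total) - starts[group] + lo[group]
        diffs = b[idx] - a[group]
        m = np.bincount(diffs - k, minlength=n_d)[:n_d].astype(np.int64)
    return DistanceSpectrum(k, d_max, m, n, window)


def write_spectra(spectra: list[DistanceSpectrum], path) -> None:
    """Dump spectra as TSV: chrom, window, d, m, n — one row per distance."""
    with open(path, "w") as fh:
        fh.write("chrom\twindow\td\tm\tn\n")
        for sp in spectra:
            chrom = sp.window.chrom if sp.window else "?"
            widx = sp.window.index if sp.window else -1
            for d, m, n in zip(sp.d, sp.m, sp.n):
                fh.write(f"{chrom}\t{widx}\t{d}\t{m}\t{n}\n")
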