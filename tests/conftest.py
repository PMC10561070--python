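"""Shared fixtures and independent oracles.

The brute-force spectrum oracle re-derives m(d)/n(d) by the definition —
a double loop over all position pairs — and deliberately shares no code
with the production counter.
"""

from __future__ import annotations

import numpy as np
import pytest

from irscape.genome_io import MaskedChromosome, encode_sequence


def brute_force_spectrum(codes, k, d_max, wstart=0, wend=None):
    """Naive m(d), n(d) over a window by enumerating every (i, d) pair.

    A pair at (i, i + d) qualifies when the whole span [i, i + d + k) lies
    inside [wstart, wend) and contains no ambiguous symbol; it is observed
    when word(i) equals the reverse complement of word(i + d).
    """
    codes = np.asarray(codes)
    if wend is None:
        wend = codes.size
    m = np.zeros(d_max - k + 1, dtype=np.int64)
    n = np.zeros(d_max - k + 1, dtype=np.int64)
    for i in range(wstart, wend):
        for d in range(k, d_max + 1):
            j = i + d
            if j + k > wend:
                continue
            span = codes[i : j + k]
            if (span >= 4).any():
                continue
            n[d - k] += 1
            w1 = codes[i : i + k]
            w2 = codes[j : j + k]
            if np.array_equal(w1, (3 - w2)[::-1]):
                m[d - k] += 1
    return m, n


def random_masked_codes(rng, length, n_frac=0.15):
    """Random code array over {0..4} with i.i.d. N placement."""
    codes = rng.integers(0, 4, size=length).astype(np.uint8)
    mask = rng.random(length) < n_frac
    codes[mask] = 4
    return codes


@pytest.fixture
def toy_chrom():
    return MaskedChromosome("chr_toy", encode_sequence("ACGTNNAC"))


@pytest.fixture
def rng():
    return np.random.default_rng(20230725)
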