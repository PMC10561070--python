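# Methods

## Model and procedure

A chromosome is a string over {A, C, G, T, N}; every non-ACGT IUPAC symbol
is treated as N.  Ambiguous positions act as *separators*: they split the
sequence into maximal unambiguous runs, and no counted quantity ever
crosses a run boundary — neither the two words of an inverted-repeat pair
nor the loop between them, nor the adjacencies used to fit the Markov
chain, nor the simulated chain itself (which restarts at every run).

An inverted repeat at distance `d` is an ordered pair of positions
`(i, i + d)` whose `k`-words satisfy `word(i) = rc(word(i + d))`; `d` is
the difference of start positions, so `d = k` means adjacent words and a
stem-`k`/loop-`g` hairpin sits at `d = k + g`.  Per window (fixed tiling,
trailing partial window included and analysed) we count

* `m(d)` — observed pairs, every qualifying pair, not only nearest
  neighbours; both words inside the window and one run;
* `n(d) = Σ_runs max(0, L_run − d − k + 1)` — possible pair positions.

Counting is exact and runs in `O(L log L + pairs)`: word codes and
reverse-complement word codes are computed per run, runs are laid out on
one axis with more than `d_max` of dead space between them, and the pair
histogram is a distance-limited difference histogram between each word's
occurrence list and its reverse complement's (composite word×position
keys, one `searchsorted` pass, ragged gather, `bincount`).  A brute-force
double loop over all position pairs serves as the independent oracle in
the tests and never shares code with this path.

### Null model and p(d)

The null for a chromosome is an order-`k` Markov chain estimated from its
runs: `π(w)` is the relative frequency of word `w` over all word
positions; transition rows are conditional frequencies of the next base;
words never observed get `π = 0` and a uniform row.  The model doubles as
the control-genome simulator (runs shorter than `k` are filled i.i.d.
from the single-base marginal of `π`; the first `k` bases of longer runs
are a word drawn from `π`).

For the pair probability we use the identity that the chain's state after
`d` steps *is* the last `k` emitted bases, hence

    p(d) = Σ_w π(w) · (A^d)[w, rc(w)],

where `A` is the sparse word-level transition operator.  This is computed
by dense-matrix propagation for gaps `g = d − k` up to a mixing horizon
(default 50 steps; DNA chains mix long before that — at the default
horizon the propagated value and the tail agree to < 1e-6), and by the
flat π-averaged stationary value beyond.  `horizon = 0` degenerates to
the independence approximation.  Values are clipped to
`[1e-12, 1 − 1e-12]`; distances clipped at either end are flagged
degenerate and force `T(d) = 0`.  The propagation cost is
`O(4^{2k} · (k + horizon))`; it is paid once per chromosome, not per
window (at `k = 7` this is the expensive step, minutes and ~2 GB, which
is why the per-chromosome pair probabilities are shared by all windows).

### Scores, critical values, calls

`T(d)` is the binomial z-score with the mask-aware `n(d)`; windows
contribute `T(d) = 0` wherever `n(d) = 0`.  Class scores are inclusive
sums; the numbered classes partition `[k, d_max]`, so `S(I_t)` equals the
sum of `S(I_1..I_8)` exactly (asserted to 1e-9).

Critical values are **nearest-rank** upper quantiles of the control-
scenario `S` values — sort ascending, take the element at 1-based rank
`ceil((1 − α) N)` — per chromosome by default, globally on request.
Nearest-rank is conservative and always an observed value.  Enrichment
requires *strictly* exceeding the critical value; fully masked windows
are never flagged but stay in every denominator (window counts come from
ceiling division of chromosome length, which includes them).  One control
replicate is the default; `replicates > 1` pools windows for tighter
quantiles.

A deliberately documented small-sample property: with only `N` control
windows per scope, the nearest-rank construction gives an independent
window an exceedance probability of `(N + 1 − r)/(N + 1)`, e.g. ≈9.5%
rather than 5% at `N = 20`.  At genome scale (hundreds to thousands of
windows per chromosome) the distortion is negligible; at toy scales it is
visible in calibration experiments and is a property of the estimator,
not a bug.

### Overdispersion

`Var(T(d)) ≈ 0.8–1` per distance, but the per-window `S` over the full
range has variance several times the number of distances: sampling
fluctuations of a window's word composition shift `m(d)` coherently
across all `d`, inducing small positive cross-distance correlations that
dominate `Var(S)`.  This is precisely why thresholds are taken from the
simulated control (which reproduces the effect) instead of from a
Gaussian `S ~ N(0, #distances)` approximation, and it is the mechanism
behind the heavy right tails of real-genome `S` distributions.

## Randomness

One integer run seed.  Child seeds for every (chromosome, purpose,
replicate) triple are derived via `SeedSequence([seed, crc32(name), ...])`
— deterministic, below 2^31, and independent of processing order.  The
control simulator is a numba kernel seeded per chromosome; identical
seeds give byte-identical genomes.

## Synthetic genomes

The generator emulates the study conditions at a desk scale chosen to run
in seconds-to-minutes on one CPU: 4 chromosomes × 2 Mb, 100-kb windows,
`k = 3`, `d_max = 1000` (the genome-scale configuration `k = 7`,
`d_max = 4000` is the library default but is not exercised by the test
suite at full size).

* **Mask.**  Alternating unambiguous runs (exponential, mean 150 nt,
  minimum 20) and N runs (mean 100 nt, minimum 10), ≈40% masked.  The
  fragmentation matters: it is what makes `n(d)` decay with `d` inside
  windows and hence the dispersion of `S` decrease from short- to
  long-distance classes, as in hard-masked assemblies.  With long
  unbroken runs, equal-width classes would have equal dispersion.
* **Background.**  i.i.d. base composition A = T = 0.3, C = G = 0.2
  (≈40% GC) expressed as an order-`k` model, or any fitted model.
* **Plants.**  A directive overwrites non-overlapping positions of one
  window with stem + loop + rc(stem); stems are drawn from the background
  word distribution so the enrichment is pairing structure, not
  composition.  Loops can be fixed, uniform in a range, or drawn from a
  periodic set.  The default intensity — 7000 loop-less stems, i.e. 6-nt
  palindromes at `k = 3` — was sized by a power analysis against the
  *measured* null sd of `S` (≈70, see overdispersion above) so that the
  planted excess (≈340 from the direct pairs, more from incidental
  cross-plant pairs) clears the expected maximum of 19 null windows with
  a ≈2.7-sd margin; it models a severely exaggerated short-repeat region.
  Placement walks the window's runs left to right with multinomially
  drawn slack, so plants never overlap each other or an N run (an
  impossible directive raises).

What the generator does **not** emulate: the composition heterogeneity,
isochore structure and residual repeat content of real chromosomes, or
realistic RepeatMasker run-length distributions.  Passing tests therefore
demonstrate the statistics and the machinery, not that any particular
real genome is enriched.

## Numerical and interface choices

* Coordinates 0-based half-open everywhere; 1-based inclusive only in
  display labels (`chrX:53000001:53100000` style).
* Pairs never cross window edges; with `d_max ≪ window`, the edge loss is
  bounded by ≈`d_max/window` (4% at defaults) and is a documented bias.
  An `overhang` mode lets the partner word extend up to `d_max + k` past
  the right edge for users who want unclipped counts.
* Soft-masked lowercase is upper-cased by default (`hard_mask_lower`
  flips this); any non-ACGT IUPAC code separates runs.
* Model files are versioned JSON with words as ACGT strings; critical
  values are JSON keyed by scope × class; scores/summary/heatmap/profile
  tables are TSV; per-class tracks are BedGraph.

## Problem sizes used by the tests

Unit tests run on strings and ≤0.5-Mb sequences; the end-to-end suites
use the desk scale above (a full calibration experiment — genome, two
control replicates, 160 windows scored — takes a few seconds; the
20-genome planted-recovery sweep tens of seconds).

## Known limitations

* Exact-match stems only; mismatched or degenerate stems are out of scope.
* `p(d)` propagation memory grows as `16^k`; practical up to `k = 7`.
* The binomial variance model understates `Var(S)` (see overdispersion);
  any user bypassing the empirical critical values should not interpret
  `S` on a Gaussian scale.
* Per-chromosome critical values at very small window counts carry the
  finite-sample exceedance bias quantified above.
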