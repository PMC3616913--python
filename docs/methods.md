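# Methods

`meiochip` analyses meiotic ChIP-chip experiments in budding yeast in which
a crossover-designation factor (Zip3, a ZMM-group SUMO E3 ligase) is mapped
genome-wide alongside a DSB map (ssDNA in *dmc1Δ*, or Spo11-bound signal in
*rad50S*). The package has five analysis layers — signal processing, peak
calling, experiment comparison, hotspot classification, tetrad genetics —
plus a synthetic-data generator that provides ground truth for all of them.

## Signal model and processing chain

A tiling array reports one IP/whole-cell ratio per probe (~300 bp spacing
on a 44k yeast array). Ratios are strictly positive and multiplicatively
noisy, so all modelling is done in log space.

1. **Decile normalization.** Every probe is divided by the mean of the
   lowest 10% of ratios on the whole array (all chromosomes pooled — one
   hybridization, one background). After normalization the lowest-decile
   mean is exactly 1, so values at or below ~1 read as background. The
   operation is idempotent and invariant to rescaling the input; the
   lowest-decile set is the smallest `max(1, n // 10)` values.
2. **Denoising.** The upstream literature cites a denoising step without
   specifying it; this package defines it as isolated-spike removal. A
   probe is a spike when it exceeds `spike_factor` (default 3) times the
   median of the `neighbor_span` (default 5) probes on each side *and*
   neither immediate neighbor exceeds that bound; spikes are replaced by
   that flanking median. The two-sided neighbor condition guarantees a
   genuine multi-probe enrichment is never flattened. Chromosome-end
   probes are left untouched.
3. **Smoothing.** A genomic-distance moving average: each probe becomes
   the mean of all probes within `window_bp / 2` (inclusive) on the same
   chromosome. Windows are position-based, not probe-count-based, so
   irregular spacing and missing probes need no imputation; edge windows
   are truncated, never padded. Default `window_bp` = 2000 (2 kb); 1 kb is
   used for display-style profiles and 300 bp suits sharp axis-protein
   maps. Singleton windows return the input bit-exactly.

## Peak calling and comparison

Peaks are local maxima of the smoothed track with height ≥ `threshold`
(default 2.0, i.e. twice background on a decile-normalized track; very hot
datasets may need 5). A run of equal maximal values yields one summit at
the run's midpoint probe, so an exactly flat track yields no peaks. Maxima
closer than `min_separation` (default = the smoothing window, 2000 bp) are
merged keeping the higher. Peaks are ranked 1..k by descending height,
ties broken by chromosome order then position, so ranks are deterministic.

Two experiments are compared by (a) greedy nearest-first one-to-one summit
matching within `match_dist` — the matched-pair count is symmetric in the
two lists — and (b) the Pearson correlation of the two processed tracks on
their common probe grid. `match_dist` defaults to the smoothing window
(2000 bp) since "coincident" peaks cannot be resolved more finely than the
smoothing scale; overlap tables should be read alongside a scan of this
parameter.

## Hotspot classification

DSB hotspots are taken as the `n_top` (default 400) strongest DSB peaks
after removing peaks within `cen_excl` (default 10 kb) of a centromere,
re-ranked 1..n_top. Each hotspot is matched to the nearest Zip3 peak
within `match_dist` and labelled by rank difference
`Δ = zip3_rank − dsb_rank` (positive = Zip3 peak weaker):

- **high**: matched and `|Δ| < 50`;
- **low**: unmatched, or `Δ ≥ 100`;
- **intermediate**: everything else.

The partition is exhaustive and exclusive by construction. The stricter
variant used for *set1Δ*-style data (200 strongest DSBs, low cutoff 150) is
pure parameterization, not a code path. Per-site features — distance to
the nearest centromere or axis site (Rec8/Red1 peak), and the
Zip3-per-DSB signal ratio (max smoothed signal within `radius` of the
site, target over reference, NaN on zero denominator) — feed the group
statistics.

Group comparisons report notched-boxplot summaries (median, quartiles,
whiskers at the most extreme point within 1.5×IQR, notch half-width
`1.58·IQR/√n`) and a two-sided Wilcoxon rank-sum p-value: exact
permutation enumeration of the midrank statistic when both groups have ≤ 8
observations, otherwise the normal approximation with tie and continuity
correction. Distance-binned analyses use half-open bins `[e_i, e_{i+1})`
with per-bin means and pairwise rank-sum tests; p-values are reported raw
(an optional Benjamini–Hochberg column is available but never drives
headline outputs). Category-overlap questions (e.g. low-Zip3 ∩ low-rad50S)
use a 2×2 Pearson chi-square without continuity correction, with the
expected overlap `|A||B|/|U|` reported alongside.

## Tetrad genetics

For two linked markers, tetrads are scored PD/NPD/T and the map distance
estimated by the Perkins formula `cM = 100·(T/2 + 3·NPD)/n`. Since the
estimator is a linear functional of the multinomial class proportions with
coefficients `(0, 3, ½)`, its standard error has the closed delta-method
form `100·sqrt((Σc_i²p_i − (Σc_i p_i)²)/n)`; a seeded multinomial
bootstrap (10,000 resamples) is provided as a cross-check and agrees to a
few percent. Estimates above 50 cM are reported unclamped with a warning —
the formula leaves its quasi-linear regime there.

Strain comparisons use the likelihood-ratio G-test on the 2×3
strain-by-class table (`G = 2ΣO·ln(O/E)`, convention `0·ln0 = 0`), df = 2,
dropping any class empty in both strains (df reduced). Simulation shows
the test is well calibrated (~5% type-I at α = 0.05) when all three
classes have adequate expected counts; with expected NPD counts below ~5
it becomes mildly anticonservative, as is generic for G-tests.

The CO-per-DSB ratio for an interval is `(cM × 2)/(DSB% × 4)`: twice the
genetic distance is the percentage of cells with a crossover (a CO
involves 2 of 4 chromatids), and the measured per-chromatid DSB frequency
times 4 chromatids is the percentage of cells with a break, assuming at
most one chromatid per cell is cut in the interval.

## Synthetic-data generator

**Tracks.** Probes at `probe_spacing` (default 300 bp, matching a 44k
array over a ~12 Mb genome) starting at position 1. Expected log-signal is
`log(baseline)` plus, per planted feature, a Gaussian bump
`log(s)·exp(−(x−pos)²/2σ²)` with `σ = kernel_width/2` (defaults: 1500 bp
for DSB/axis features, 4000 bp for centromere enrichment, shapes
comparable to 2 kb-smoothed real profiles). Noise is multiplicative
log-normal with sd `noise_sigma` (default 0.1) — ratios are positive, so a
log-scale Gaussian is the natural convention; the real arrays' noise model
is unknown and these parameters are conventions, not estimates. Two
channels share one feature list: *reference* (the DSB map) uses each
feature's full `strength`; *target* (the Zip3 IP) replaces a DSB feature's
strength by `max(strength × zip3_propensity, 1)` — the floor keeps a
zero-propensity hotspot at background rather than depleted, and keeps the
log finite. The RNG stream derives from `(seed, channel)`, so a
seed+config pair gives bit-identical output.

**Default study conditions.** Two 1 Mb chromosomes, 50 DSB hotspots with
strengths uniform in [4, 10] and bimodal propensity {0, 3}, 30 axis sites
(strength [2, 5]), centromere enrichment 6, features ≥ 12 kb apart and
≥ 10 kb from ends/centromeres so planted summits stay resolvable after
2 kb smoothing. These sizes keep a full pipeline run under a few seconds
while leaving every stage statistically exercisable.

**Tetrads.** Per meiosis the crossover count is Poisson(`m`); each
crossover exchanges the distal-marker alleles of a uniformly chosen
non-sister chromatid pair (no chromatid interference — the simplest model
consistent with Perkins estimation). Scoring the four chromatids gives
PD (0 recombinant), T (2) or NPD (4). The analytic counterpart is the
classical ditype/tetratype Markov chain (PD→T; T→PD,T,NPD with ¼,½,¼;
NPD→T) mixed over the Poisson count, shipped as
`expected_tetrad_frequencies` / `expected_perkins_cM`.

An important consequence: the Perkins estimator is *biased* under this
model because it corrects exactly only for double crossovers. Its
expectation is 4.99 cM at a nominal 5 (`m = 0.1`), 19.37 at 20, 32.17
at 35. Calibration checks (law-of-large-numbers convergence, 2·SE
coverage) therefore target the closed-form expectation, which is what the
estimator converges to; targeting the nominal `50·m` would conflate SE
calibration with estimator bias.

**What the generator does not emulate.** Probe-specific response and GC
bias, spatially correlated noise, missing/flagged probes, replicate
dye-swap structure, chromosome-size effects on crossover rates, crossover
interference, and meiotic time-course dependence (each time point would be
an independent feature mixture). Passing tests therefore demonstrate the
correctness and calibration of the algorithms under a clean generative
model, not performance on real arrays; real-data runs should scan
`threshold` and `match_dist` as described above.

## Numerical and design choices

- 1-based inclusive coordinates everywhere (SGD convention); conversion to
  0-based half-open formats only at the BED boundary. No strand handling:
  all features are strandless positions.
- Track values written to 12 significant digits; round-trips preserve
  order, grid, ranks and processing-state flags.
- `signal_at` uses a strict radius (`|pos − site| < r`) and reports sites
  with no probe in range as missing (NaN), never imputed.
- Distance to the nearest feature is `inf` when the peak's chromosome
  carries none.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; identical config + seed reproduces every output byte
  for byte.

## Limitations

- Peak heights are smoothed signal values, not deconvolved occupancies;
  closely spaced real peaks closer than the smoothing window merge.
- Greedy nearest-first matching is not guaranteed to find a maximum
  bipartite matching in adversarial geometries (it does in the
  configurations that arise at realistic peak spacing).
- The exact rank-sum path enumerates all C(n_a+n_b, n_a) assignments and
  is limited to n ≤ 8 per group by design.
- The G-test's chi-square reference is asymptotic; with expected class
  counts below ~5 it rejects slightly more than nominal.
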