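# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. It is the maintainer-facing companion to the
README.

## Data model and transformation

A record is a strictly time-ordered (oldest first) table of samples × element
measurements for one core: XRF core-scanner intensities in counts per second
and, where available, total organic C and N in dry-weight percent. Ages are
calibrated calendar years CE produced by a published age–depth model; age
modelling is outside this package's scope and depth is never used in
computation. Values must be non-negative and complete; missing cells are an
error by default, with an explicit `drop_incomplete` switch that removes
incomplete samples and logs it. C and N default to the *organic* class,
K, Si, Al, Mn, Fe, Ti, Zr, V, Sr and Ca to *terrigenous*; a sidecar metadata
CSV can override this.

Every element series is square-root transformed, then min–max rescaled to
[0, 1]. The square root damps the dominance of high-count elements (Fe or Si
cps run 10³–10⁵ while N is &lt; 1 wt %); the min–max step puts all elements on
one relative scale so Euclidean geometry treats them evenly. Two consequences
worth keeping in mind:

- **Scaling is per element within one record, never across records.** XRF
  intensities are instrument- and matrix-specific; pooling cores before
  rescaling would let one core's dynamic range distort another's geometry.
  When several records share a multivariate space, each is transformed
  independently and then restricted to the ordered common-element list
  (C, N, K, Fe, Mn, Ti, Zr, V, Si, Sr, Ca when all are present).
- **Constant (degenerate) series are mapped to all-zeros and flagged**, not
  NaN, so distances downstream remain defined. They are excluded from the
  element-series clustering.

Because both steps are strictly monotone, within-element rank order is
preserved — a property the tests assert directly.

Relationships among elements are summarized by Ward/Euclidean hierarchical
clustering of the element time-series (elements as observations, samples as
dimensions), delegated to `scipy.cluster.hierarchy.linkage` and verified in
the tests against a naive Lance–Williams implementation.

## Zonation (CONISS)

CONISS is agglomerative clustering under a stratigraphic constraint: only
adjacent clusters may merge, and each step takes the merge with the smallest
increase in total within-cluster sum of squares. The implementation keeps
prefix sums of the transformed matrix so each candidate cost is O(elements),
giving O(n²) overall; the test oracle is an independent O(n³) version that
recomputes every cluster dispersion from scratch. Numerical conventions:

- dispersion is computed on the transformed values, with no further
  standardization inside the clustering;
- equal-cost ties merge the stratigraphically uppermost (oldest) pair, so
  output is deterministic (a strict `<` with a 10⁻¹⁵ guard keeps the first
  minimum);
- merge heights are reported both as increments and cumulative sums; the
  final cumulative sum equals the total dispersion about the grand mean
  (asserted to 10⁻⁹).

Cutting the tree at *k* undoes the last *k* − 1 merges, yielding contiguous
zones labelled 1..k downcore. Breakpoints are emitted as the age interval
between the two boundary samples rather than an interpolated midpoint — an
interval honestly represents the dating resolution. *k* is a user choice,
matched in practice to independent phase schemes; `broken_stick` compares
each merge-cost increment against the broken-stick expectation for the
corresponding ranked share of total dispersion and suggests the largest *k*
reached before the first non-exceedance (total dispersion below 10⁻¹⁰ is
treated as zero signal → k = 1).

Two cut zonations on the same grid are compared by greedily pairing
breakpoints by absolute age offset (interval midpoints) and by the Rand index
of the zone labelings (via `sklearn.metrics.rand_score`).

## Moving windows and trajectory metrics

Window width is W = ⌊fraction × (age_max − age_min)⌋ whole years, fraction
0.30 by default. Flooring to whole years is the convention consistent with
the published per-lake widths that can be checked against their printed
spans. One window per sample, centered on the sample's year, membership
|age − center| ≤ W/2; edge windows keep the nominal W but hold fewer samples.
Windows with fewer than `min_window_n` (default 4) members are flagged and
their metrics reported as missing; each metric additionally applies its own
hard minimum (turnover and speed n ≥ 2, directionality n ≥ 3) so turnover can
still be reported where directionality cannot.

- **Turnover** BD = SS_total/(n−1). The algebraic identity with the mean
  squared pairwise distance is asserted to 10⁻¹² and is the basis of an
  acceptance check. The percentile bootstrap resamples window rows with
  replacement (N = 999); resamples with fewer than two distinct rows
  legitimately contribute BD = 0 and are retained. The generator is seeded
  from the analysis config, so CIs are bit-reproducible.
- **Directionality** averages the angle at the middle point over *all*
  ordered triplets of window members (the convention of the community
  trajectory-analysis literature), cosine clamped to [−1, 1] before arccos.
  Triplets containing a zero-length segment are skipped, not scored 0°:
  coincident compositions carry no direction, and scoring them as reversals
  would bias duplicated samples downward.
- **Speed** defaults to *path* mode (summed consecutive-segment distance per
  year) — the natural reading of "speed of change" — with *net* and
  *mean_segment* selectable because the verbal definitions in circulation
  admit those readings too. The chosen mode is echoed in all outputs. Speed
  rows are assigned the mean year of the window's members, which is why the
  speed series' ages differ slightly from the turnover/directionality series
  on irregular grids.

## Shape metrics

PCA is computed by SVD of the centered (not re-scaled — the data are already
on [0, 1]) matrix; variance fractions are taken over all axes and therefore
sum to 1, and each axis is oriented so its largest-magnitude loading is
positive. Explored area uses the normal-theory ellipse
π · χ²₂(level) · √det(S) on a record's first-two-axis scores from the pooled
ordination; the χ² form has a closed-form test value, while the
multivariate-t variant (2(n−1)/(n−2) · F(level; 2, n−2)), which some plotting
ecosystems default to, is available behind `kind="t"` — at fixed n the two
differ by a scalar factor only. Collinear score sets have no ellipse and
return NaN. The three-centroid length deliberately uses the full element
space, not the 2-D scores: it measures separation of compositional states,
not of their projection; `chronological` mode (c₁→c₂→c₃) is the default and
`all_pairs` adds d(c₁,c₃).

## Synthetic records

The generator emulates the statistical shape of dated lake-core element
data: 10–16 positive series over spans of several centuries to two
millennia, 50–300 samples, piecewise compositional regimes with abrupt or
linearly ramped transitions at known ages, optional within-zone linear
drift, and multiplicative lognormal noise — multiplicative because cps and
wt % are positive and their measurement error scales with the signal. The
lognormal mean identity E[value] = level · exp(σ²/2) is Monte-Carlo-checked
at 1 %. Ground truth (boundary ages, per-sample labels) is emitted as a
sidecar table so recovery experiments treat the generator as a black box.

Presets fix realistic scenario parameters once: `shallow_small` (70 samples,
700 y, three regimes with factor ≈ 2 shifts in terrigenous input and
organic content, noise σ = 0.10 — a small shallow lake reacting strongly),
`deep_large` (120 samples, 1650 y, muted ramped transitions — a deep lake
buffering the same forcings), `drift_only` (one regime, slow monotone drift
from terrigenous-rich to organic-rich, σ = 0.05) and `stationary` (pure
noise about one composition, σ = 0.10). Recovery and robustness experiments
in the tests and the acceptance script run at these condition sizes (e.g.
100 replicates of a 50-sample, 8-element, 3-zone record with factor-2 steps,
i.e. log-scale steps ≈ 7× the noise σ), which keeps the full suite and the
acceptance script in the level of minutes on one CPU.

What the synthetic data does *not* emulate: age–model uncertainty, data
hiatuses, autocorrelated (red) noise, closed-sum compositional effects, and
element-specific detection limits. Passing recovery tests therefore shows the
algorithms behave correctly under the stated generative model, not that real
cores will be zoned this cleanly — real XRF noise is autocorrelated and
transitions are rarely synchronous across all elements.

## Pipeline and reproducibility

A single YAML/JSON config drives `transform → zones → metrics → shapes`
(plus the full-vs-XRF-only comparison). All CSVs are written with `%.12g`
formatting, so identical config + inputs reproduce byte-identical outputs;
the JSON manifest (config echo, input SHA-256, package version, seed,
per-stage row counts) is written only when every requested stage succeeds.
The XRF-only comparison re-runs zonation and metrics with C/N dropped before
transformation (per-element transforms are independent, so this equals
deleting the columns afterwards) and reports breakpoint offsets, Rand
agreement, and per-window metric deltas.

## Known limitations

- Turnover windows with highly uneven occupancy have CIs of uneven quality;
  the occupancy n is reported per row for exactly this reason.
- Directionality is O(n³) in window occupancy; records of thousands of
  samples with wide windows will feel it.
- The broken-stick suggestion is a heuristic; it is intentionally advisory
  and never applied automatically.
- Explored areas computed from per-record rather than pooled ordinations are
  not comparable across records; the pooled route is the default for
  multi-record analyses.
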