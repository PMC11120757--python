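# Methods

## Data model and preprocessing

The unit of analysis is a condition (e.g. normal tissue, tumor, a cell
line) profiled on `r` biological replicas, with `r = 4` the canonical small
design and `r ≥ 3` required (the variability estimate needs at least two
degrees of freedom). Spot-level input carries per-spot foreground and
background intensities and a spot→gene map, with possibly several redundant
probes per gene.

Preprocessing order:

1. **Validity filter.** A spot is eliminated from *every* array of the
   experiment if its foreground is below twice its background on at least
   one array. The filter removes spots, not spot–array cells, because the
   downstream statistics need complete replica vectors. By default the
   filter is applied jointly across all conditions' arrays; `joint=False`
   filters each condition against its own arrays only (which of the two the
   original pipelines used is usually not stated, so it is configurable).
2. **Per-array spot normalization** to the median of the array's valid
   spots.
3. **Probe summarization.** Redundant probes are collapsed to the gene by
   the arithmetic mean of the normalized spot values (the mean preserves
   the linearity of the average expression level); the probe count per gene
   is retained.
4. **Per-array gene-level renormalization** to the median gene, so that
   expression is measured in "median gene" units. Step 2 makes the spot
   universe comparable across arrays for filtering; step 4 defines the
   final unit after averaging has slightly shifted the median. Genes absent
   from any condition are dropped everywhere, since every between-condition
   measure requires both conditions.

## Per-gene characteristics within a condition

With replica values `x_1..x_r` of one gene (mean `m`, sample SD `s`):

* `AVE = m`.
* `REV = 100 · (s/m) · ½ [√((r−1)/χ²_{0.975,r−1}) + √((r−1)/χ²_{0.025,r−1})]`
  percent — the coefficient of variation corrected by the mid-point of its
  chi-square confidence interval. At `r = 4` the factor is 2.1475, so a 10%
  replicate CV reads as REV ≈ 21.5%. The correction widens the estimate to
  acknowledge how poorly a 4-replica SD is determined; it is deliberately
  an interval midpoint, not an unbiasing factor. REV is scale-invariant.
* `COR(i, j)` — Pearson correlation of two genes' replica vectors; p-value
  from the t-transform with `r − 2` degrees of freedom. Classes:
  synergistic (`COR > 0.950` and `p < 0.05`), antagonistic (`COR < −0.950`
  and `p < 0.05`), independent (`|COR| < 0.050`), otherwise unclassified.
  At `r = 4` the two-tailed 5% critical value is exactly 0.9500 (3 d.p.),
  so the numeric thresholds and the t-test coincide for synergism and
  antagonism; the independence band is a literal numeric criterion with no
  conventional p-value. Zero-variance genes have undefined COR and are
  excluded from classification. No multiple-testing correction is applied
  across pairs: the classes are defined per pair at `p < 0.05`, and the
  expected null synergistic rate (~2.5%) is itself used as a calibration
  check.
* `REC = 100 · (median(REV)/REV − 1)` percent, the median taken over all
  quantified genes of the condition. The median (not the mean) is the
  reference because REV is strongly right-skewed at small `r`. `REC` of a
  zero-REV gene is undefined (flagged NaN rather than infinite).
* `COORD = 100 · (#synergistic + #antagonistic partners)/(G − 1)` percent
  over a universe of `G` genes — by default the whole quantified
  transcriptome; a pathway subset can be passed instead (both readings of a
  pathway-level coordination figure are defensible, so the universe is a
  parameter). Independent partners do not count toward COORD: it measures
  established coordination, not established independence.

Pairwise correlation over large universes is computed blockwise from
row-standardized matrices, so the dense G×G matrix is never materialized;
only classified pairs are persisted as edge lists.

## Regulation against a reference condition

* Signed ratio `x = AVE_c/AVE_ref` if ≥ 1, else `−AVE_ref/AVE_c`.
* `p` from the two-tailed Welch (unequal-variance) t-test on the
  normalized replicas — the conservative choice when nothing guarantees
  equal variances between, say, tissue and culture. Degenerate
  zero-variance pairs resolve to `p = 1` (equal means) or `p = 0`.
* `CUT = 1 + √((REV_ref/100)² + (REV_c/100)²)` — the gene's own
  fold-change cut-off, combining the replicate variability of both
  conditions in quadrature. A gene is **up** if `x > CUT` and `p < 0.05`,
  **down** if `x < −CUT` and `p < 0.05`, otherwise not-regulated.
* `WIR = AVE_ref · (|x| − 1) · sign(x) · (1 − p)` — expression change in
  median-gene units, discounted by statistical confidence. It reproduces
  the reference behaviour, e.g. `WIR(18.11, −27.91, 0) = −487.3`.
* `ΔREC`, `ΔCOORD` — condition minus reference, over the identical gene
  universe (enforced).
* `TD = √(WIR² + ΔREC² + ΔCOORD²)` — Euclidean distance in the
  three-component alteration space; per-pathway TD is the mean over
  quantified members.

All expression values stay on the linear scale throughout: AVE has a
physical unit (expression of the median gene) that log transforms would
destroy, and the signed-ratio convention already symmetrizes up/down.

## Pathways and networks

Gene sets are plain GMT files; sets may overlap and a gene contributes to
every set that contains it. Percentages of up/down genes use quantified
members as denominator; unquantified members are reported, not imputed.
Coordination networks keep one undirected edge per classified pair
(synergistic / antagonistic / independent); unclassified pairs are missing
edges, meaning "no significant evidence", which is deliberately distinct
from independence ("significant evidence of no coordination"). Network
comparison reports edges gained, lost, flipped (synergism ↔ antagonism)
and reclassified (to or from independence), plus each gene's change in
significant degree. Regulation status is attached to nodes as a purely
decorative attribute — edge classification never reads it, and a test
asserts this independence.

## Synthetic data generator

The generator emulates the structure of a replicated two-channel
microarray study and returns the full ground truth with every dataset:

* true mean expression per gene, log-normal around the median gene with
  ln-scale SD 1.8 (spanning roughly 0.01–100 median-gene units, matching
  the dynamic range replicated platforms report), floored at 0.05 so every
  planted gene is detectable;
* per-gene replicate CVs, drawn from a configurable range (default
  0.05–0.35, i.e. REV roughly 10–75% at r = 4, the range typical of
  replicated tissue experiments) or fixed/planted per gene;
* signed fold changes (≥ 1 up, division by |fold| down) per non-reference
  condition;
* correlation blocks via replica-level latent factors:
  `z = √(1−ρ)·ε + sign·√ρ·f` on the log scale, giving pairwise correlation
  ±ρ between members — exactly the across-replica correlation COR
  measures; negative loadings produce antagonistic members;
* redundant probes (spot value = gene value × multiplicative technical
  noise, default CV 5%) and per-spot uniform backgrounds; a configured
  fraction of spots is forced below the 2× background threshold on one
  random array, and valid spots are floored just above the threshold so
  the planted invalid set and the filter's removal set coincide exactly;
* one seeded RNG drives everything: a fixed seed gives bit-identical
  output, and with CV → 0 sample statistics equal the planted parameters
  exactly.

**CV scale.** With r = 4 the sample SD underestimates the population SD
(`E[s] = c₄(r)·σ`, `c₄(4) ≈ 0.921`), so a generator planting population
CVs produces data whose measured replicate CVs sit ~8% below nominal — a
bias of the estimator, not of the implementation. Because the planted CV
is meant to be the value replicate-based estimators recover (it is what a
simulator calibrated against real replicate tables would match), the
default `cv_scale="sample"` calibrates the log-normal width by a seeded
internal Monte Carlo so that the expected r-replica sample CV equals the
planted value (accurate to ~0.1%). `cv_scale="population"` keeps the
literal mapping `σ² = ln(1 + CV²)`.

What the generator does **not** emulate: dye effects, spatial array
artifacts, probe-sequence biases, heavy-tailed outliers, or correlated
technical batch structure. Passing recovery tests therefore demonstrates
the statistics are implemented and calibrated correctly, not that real
microarray data meet these assumptions.

A relevant measured artifact: dividing by a per-array median computed from
a finite gene universe injects a small common-mode component into all
genes of that array. At 700 genes this raises the null synergistic pair
rate from the nominal 0.025 to ~0.027 and slightly attenuates planted
anticorrelation; it shrinks with the universe size. Tests that probe
planted correlation structure in tiny universes use the generator's
unnormalized output for this reason.

## Validation experiments (tests and acceptance script)

Problem sizes were chosen to keep each experiment's Monte-Carlo error
well inside its tolerance: 2000 genes × 4 replicas for REV/AVE recovery
and regulation recall (100 planted genes, folds ±2); 700 genes
(244,650 pairs) for the null edge density; REC recovery with 2.5% of
2000 genes planted at half the background CV, summarized by the median
REC of planted genes (the mean is heavy-tail biased upward by the 1/REV
transform) and averaged over 20 independent simulations — the small
planted fraction keeps the condition-wide median REV, which is REC's
reference point, essentially unaffected by the planted genes themselves.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] before the t-transform; |r| = 1
  maps to p = 0.
* Zero-variance replica vectors: REV = 0, COR undefined (excluded),
  Welch test resolved explicitly (see above).
* REC of REV = 0 genes is NaN and propagates to ΔREC/TD as NaN (flagged,
  never silently dropped except where means require `dropna`).
* Ties in the validity filter (foreground exactly 2× background) pass;
  the generator's validity floor sits 0.1% above the threshold.
* Blockwise pair scanning uses 512-gene blocks (≈ 2 MB of doubles per
  block at G = 20,000), a memory ceiling rather than a speed choice.

## Known limitations

* The independence band |COR| < 0.050 is a numeric convention; at r = 4 a
  sample correlation that small is compatible with a wide range of true
  correlations.
* REC at r = 4 is noisy (the SD estimate has 3 degrees of freedom); REC
  differences below a few tens of percent are not individually meaningful,
  which is why pathway-level averages and the TD aggregate are the
  intended readouts.
* GEO series-matrix support covers the plain-text table (ID_REF × GSM);
  probe-to-symbol annotation must be supplied by the caller.
* The pipeline assumes equal replica counts within a condition and at
  least 3 replicas; unbalanced designs are rejected rather than
  approximated.
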