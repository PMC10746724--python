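# Methods

This note records the statistical model, the conventions every module
follows, what the synthetic-data generator does and does not emulate, and
the known limitations. It is the reference for anyone auditing the numbers
the pipeline produces.

## 1. Input data model

The central input is a **variability table**: one row per
(MAG, contig, position, sample) with integer read counts for A, C, G, T.
Rows with zero total coverage are invalid. An alternative `anvio` dialect
(`split_name`/`pos` headers, extra columns ignored) is accepted on read.
Sample metadata rows carry site, trench system, realm (`abyssal`/`hadal`),
water depth, core, horizon interval in cm, and geochemical zone
(`oxic`/`nitrogenous`/`ferruginous`); horizons within one core must not
overlap.

## 2. SNV profiling

- **Consensus** at a position in a sample is the base with the highest
  count; ties resolve to the alphabetically first base (A < C < G < T) so
  results are order-independent.
- **Departure from consensus** = (coverage − consensus count) / coverage,
  bounded by 0.75.
- A position is an **SNV record** in a sample when coverage ≥ 10 **and**
  departure ≥ 0.1. *All* coverage-style thresholds in the package are
  inclusive (≥); the single exception is the detection rule below, which is
  strict by convention. SNV calling is idempotent: re-filtering its own
  output changes nothing.
- **Detection** of a MAG in a sample is the fraction of genome positions
  with ≥ 1 read. Mean coverage is reported as an abundance proxy only when
  detection > 0.7 (strictly), else 0 — near-threshold detections are too
  easily driven by conserved-region cross-mapping.
- **Core positions** of a sample group are the positions covered ≥ 10× in
  *every* sample of the group. SNV density (SNVs per kb) is reported over
  the core-position support of the comparison group by default, so coverage
  differences cannot masquerade as variability differences.
- MAG selection for analysis: ≥ 10× coverage in ≥ 40 samples, with a
  fallback tier at ≥ 20 samples (intended for clades absent from half the
  design, e.g. confined to one realm).

## 3. F_ST estimator

For a sample pair (x, y), with per-site allele-frequency 4-vectors:

    pi_x  = 1 − Σ_a f_a²            (within-sample heterozygosity)
    pi_xy = 1 − Σ_a x_a y_a         (between-sample heterozygosity)
    F_ST  = 1 − (mean pi_x + mean pi_y) / (2 · mean pi_xy)

a **ratio of averages** over the pair's usable site set, not an average of
per-site ratios. Two site policies exist:

- `snv-union` (pipeline default): sites covered ≥ 10× in both samples with
  an SNV record in at least one. This matches how real variability data are
  reported.
- `all-covered`: every site covered ≥ 10× in both. Used by the recovery
  experiments, because the Balding–Nichols identity E[F_ST] = F is over all
  segregating sites; SNV ascertainment is a reporting convention the
  identity does not model.

Conventions and provable properties:

- A pair with an empty site set has no defined F_ST: the matrix builder
  either raises (default, required before clustering) or records NaN.
- If the denominator is zero (all usable sites monomorphic and identical),
  F_ST is defined as 0.
- Between two samples the estimator cannot be negative: per site,
  2·pi_xy − pi_x − pi_y = Σ_a (x_a − y_a)² ≥ 0, and summing preserves the
  inequality. No clamping is applied anywhere.
- Sites that are identically monomorphic in both samples contribute zero to
  every sum, so including them (all-covered) does not change the value —
  the two policies differ only through sites variable somewhere, or fixed
  for *different* alleles (departure 0 in both samples, hence not SNVs,
  yet maximal pi_xy; only all-covered sees them).
- **Bias**: plugin frequencies from finite read depth inflate within- and
  between-sample heterozygosity unequally; with no n/(n−1) correction the
  estimator overshoots by roughly (1 − F)/coverage. At the validation
  conditions (50×) this is visible and accepted: truth 0.05 is estimated
  ≈ 0.068, truth 0.4 ≈ 0.406, all within the ±0.03 acceptance band, and
  the ordering of divergence levels is preserved, which is what the
  downstream analyses consume.

**Clustering** uses Ward linkage in the Ward.D2 convention (scipy `ward` on
the F_ST distances directly). Newick export places leaves at height 0 and
each internal node at its merge height, a branch's length being the drop to
its parent: two leaves merging at height h render `(a:h,b:h);`. The tests
verify scipy's linkage against a hand-rolled O(n³) Lance–Williams
agglomerator via cophenetic distances.

## 4. Shared-variant statistics

For a sample pair, SNV sets are first restricted to the pair's core
positions (covered ≥ 10× in both). Then:

- **shared-SNV fraction** = |X ∩ Y| / |X ∪ Y| (Jaccard; `min` and `mean`
  denominators available),
- **same-consensus fraction** = fraction of shared positions where both
  samples call the same consensus base (0 by convention when the
  intersection is empty),
- pairs are classified **inter-core** (same site and horizon, different
  core), **intra-core** (same core, different horizon), or **other**.

The inter- vs intra-core contrast is tested with Kruskal–Wallis (scipy,
tie-corrected; an all-tied input returns H = 0, p = 1), and F_ST is
regressed on each shared-variant fraction by OLS over inter-core pairs
pooled across horizons, with adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2).

## 5. PERMANOVA

Anderson's one-factor decomposition on the distance matrix:
SS_total = Σ_{i<j} d²_ij / n, SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g,
pseudo-F = (SS_between/(k−1)) / (SS_within/(n−k)). Significance by random
label permutations with the add-one rule p = (1 + #{F_perm ≥ F_obs}) /
(1 + n_permutations), bounding p below by 1/(n_permutations + 1). Distances
are floored at 0 before squaring (relevant only for matrices from other
estimators; this package's F_ST cannot be negative), and the flooring is
logged. Post-hoc structure for ≥ 3 groups uses one PERMANOVA per group pair
with Benjamini–Hochberg adjustment across pairs — a deliberate substitute
for parametric post-hoc tests, which assume Euclidean responses that a
bounded distance like F_ST does not satisfy.

## 6. Synthetic-data generator

Scope: the generator produces ground truth for *estimator validation*, not
a biological simulation of sediment communities.

- Each MAG gets `n_variable_sites` biallelic positions; the two segregating
  bases are drawn per site, the ancestral minor-allele frequency
  ~ Uniform(maf_low, maf_high) (default 0.05–0.5).
- Frequencies cascade realm → trench → site → core by Balding–Nichols
  draws: daughter ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so E = p and
  Var = F·p(1−p); F = 0 copies the parent exactly and fixed sites stay
  fixed.
- **Selection**: each cell (core × horizon) frequency is pulled toward the
  derived (minor) allele — a beneficial variant rising at its niche — by
  f_cell = (1 − s·w)·f_core + s·w with w = exp(−|rank − optimum|/τ). s = 1
  at the optimum fixes the allele in every core, making inter-core F_ST
  exactly 0 there.
- **Coverage**: λ(horizon) = floor + (peak − floor)·w, read depth per site
  ~ Poisson(λ), counts ~ Multinomial with error ε moving each true base to
  the other three uniformly (observed frequency f(1−ε) + (ε/3)(1−f)).
  Monomorphic genome positions enter the aggregate coverage/detection
  summaries (total depth Poisson, presence Bernoulli per position) without
  being materialized row by row.
- Reproducibility: one seed drives three separated RNG streams
  (frequencies, counts, reference FASTA) via `SeedSequence` spawn keys;
  the same config yields byte-identical output bundles.

Not modeled: linkage between sites, recombination, strain mixtures with
haplotype structure, mapping bias or conserved-region cross-mapping, indels
or structural variants, time dynamics.

## 7. Validation experiments (what the acceptance suite pins)

All experiments live in `magpop.validation` and are shared verbatim by the
tests and the reproducibility script. Conditions were fixed before running:

1. **Exact arithmetic**: the F_ST code path agrees with an exact-rational
   (Fraction) reimplementation to 1e−12 on random count tables.
2. **Recovery**: two demes at F ∈ {0.05, 0.1, 0.2, 0.4}, 10⁴ sites, 50×,
   all-covered policy: each estimate within ±0.03 of truth, monotone in F.
3. **Null**: panmictic samples at 100×/5,000 sites give |F_ST| < 0.05;
   PERMANOVA type-I error over 1,000 panmictic replicates is in
   [0.03, 0.07] at α = 0.05. The type-I experiment uses 16 samples per
   replicate: with markedly fewer (e.g. 10, where a half/half grouping has
   only C(10,5) = 252 distinct partitions), sampled permutations tie the
   observed statistic often enough under the ≥ convention to bias the
   measured level visibly below α — an artifact of the experiment's
   discreteness, not of the test.
4. **Structure**: realm F = 0.1 over site F = 0.02 — the Ward tree's first
   bipartition is the realm split in ≥ 18/20 replicates.
5. **Niche signature**: s = 0.6 at one horizon, τ = 0.5, core F = 0.05 —
   minimum inter-core F_ST, maximum shared-SNV fraction and maximum
   same-consensus fraction all land on the configured optimal horizon in
   ≥ 15/20 replicates, with negative OLS slopes. τ is deliberately short:
   a slow decay pulls several adjacent horizons' frequencies to
   intermediate values, saturating the Jaccard fraction at exactly 1 across
   those horizons and leaving its maximum undefined; and without core-level
   drift there is nothing for convergent selection to visibly homogenize.

## 8. Numerical conventions

- TSV round-trips write floats with `%.17g` (distance matrices) and read
  them back with exact round-trip parsing, so write → read is lossless.
- Derived RNG sub-seeds are reduced mod 2³¹ for portability.
- Tie-breaking (consensus base, argmax) is deterministic and documented.
- p-values from permutation tests are never 0 (add-one rule).

## 9. Limitations

- The F_ST bias (§3) means absolute values at low coverage should not be
  compared across studies with different depths; within-study contrasts
  (the package's purpose) are ordered correctly.
- PERMANOVA tests location differences but is sensitive to dispersion
  heterogeneity; no PERMDISP companion test is included.
- The intra- vs inter-core Kruskal–Wallis contrast has low power when
  selection is confined to a narrow depth band (most intra-core pairs then
  compare two effectively neutral horizons); it is reported, but the
  per-horizon profile (§4) is the sensitive readout.
- Shared-SNV fractions depend on the SNV ascertainment threshold; they are
  comparable only between pairs filtered identically, which the pipeline
  enforces by restricting to pairwise core positions.
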