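# Methods

## Analysis model

The pipeline analyses a two-genotype (WT / KO) × two-fraction (total
nuclear RNA / RNP immunoprecipitate) bead-array design with biological
replicates. Its chain is:

1. **Quantile normalization** of background-corrected linear intensities,
   jointly across all arrays. Every column is mapped onto the reference
   distribution (the row-wise mean of the per-column sorted values);
   within-column ties receive the mean of their block of reference
   positions, so tied inputs stay tied. The transform is idempotent and
   rank-preserving per column.
2. **log2 transform** with a floor (default 1.0 intensity unit) guarding
   non-positive background-corrected values.
3. **Detection filter.** A probe is *detected in a condition* — a
   (genotype, fraction) cell — when its detection p-value is ≤ 0.01 in at
   least half (rounded up) of that cell's replicates; probes detected in
   no condition are removed. The majority rule makes the call robust to
   one failed replicate in a triplicate design. The same rule restricted
   to one genotype's two fractions later decides whether a gene is
   *absent* in that genotype.
4. **Annotation filter.** Probes without a RefSeq transcript id are
   removed.
5. **Gene collapse.** Per gene symbol, the probe with the highest mean
   log2 intensity across all arrays represents the gene (ties break to the
   lexicographically smallest probe id). Max-mean rather than averaging
   keeps genotype-specific absent/present contrasts sharp: averaging a
   strong probe with a failed one would blur exactly the cases the
   detection logic is meant to expose.
6. **Statistics.** Differential expression (KO vs WT totals) and IP
   enrichment (IP vs totals, per genotype) both use the pooled-variance
   two-sided Student's t-test; with triplicate groups measured under one
   protocol, equal variance is the conventional reading, and Welch can be
   substituted by computing a different statistic on the same group
   selectors. Zero-pooled-variance degenerate rows (possible in tiny or
   noiseless fixtures) resolve to p = 1 when the means agree and p = 0
   with a ±∞ statistic when they differ. Multiple testing uses the
   Benjamini–Hochberg step-up (q = min over higher ranks of p·m/rank),
   computed within genotype for the enrichment analyses, since the two
   genotypes' IP experiments are independent; for differential expression
   it runs across all genes surviving preprocessing, not only nominally
   significant ones.
7. **Calling rules.** All cutoffs are strict and configurable, with
   defaults: raw p < 0.05, q < 0.05, fold / enrichment > 2 (a gene at
   exactly 2.0 is not called), detection α = 0.01, association band
   [0.70, 1.40] closed (a ratio exactly on a boundary is *unchanged*),
   GO α = 0.01. The association ratio KO/WT is computed for every gene in
   the union of the target sets whenever the gene is detected in both
   genotypes — including sub-threshold enrichments, so a gene whose
   expression and IP abundance move together is correctly read as
   unchanged association; genes detected in only one genotype get a
   one-sided class (wt_only / ko_only) and no ratio. The band is *not*
   reciprocal-symmetric (1/0.70 ≈ 1.43 > 1.40); the literal band is
   applied as configured.
8. **Venn bookkeeping.** Exclusive percentages are each genotype's
   exclusive count over its own target-set size, rounded half-up to an
   integer; the platform share of a target list is reported to one
   decimal percent of the configured platform transcript count.
9. **GO over-representation.** Plain hypergeometric upper tail
   P[X ≥ k] via the survival function, evaluated per GMT term after
   intersecting the term with the universe (default universe: all genes
   surviving preprocessing; a full-platform universe can be passed
   instead). Terms with fewer than two universe members are dropped
   (singleton terms give unstable p). No DAG propagation and no
   correction beyond the fixed α — the printed cutoff is the contract.
10. **Hierarchical clustering** for heat-map ordering: average linkage on
    Euclidean distances of log2 enrichments, rows pre-sorted by symbol so
    leaf order is deterministic under ties; undefined entries are imputed
    as 0 (ratio-neutral) for clustering only and flagged in the output.
11. **qPCR relative standard curve.** Per amplicon, OLS of Ct on
    log₁₀(relative quantity) over ≥ 3 dilution points; efficiency
    E = 10^(−1/slope) − 1; a positive slope or r² below 0.98 flags the
    curve invalid. Quantities are computed per well and averaged within a
    biological replicate (technical wells → experiment value), then
    summarized as mean ± sd across replicates — per-well inversion first
    preserves the variance structure that Ct-averaging would hide.
    Normalization divides by the reference transcript's quantity in the
    same sample, which cancels per-sample template scale; IP enrichment
    and KO/WT expression fold follow from the normalized values, with
    replicates paired by index. An undetected Ct propagates as an
    undetected quantity and ultimately an `undetected` ratio with a
    reason, never a number; an undetected *reference* is fatal. No-RT
    controls must not amplify; amplification logs a warning rather than
    aborting.

## Synthetic data: what it emulates and what it does not

The generator plants, per gene: a base log2 abundance (clipped normal,
mean 8.5, sd 1.5 on [5.5, 13.5] — bell-shaped like real array intensity
distributions, dense enough in the tail that quantile normalization
behaves as it does on real data), an optional KO expression shift
(|Δlog2| ~ U[1.5, 3], random sign; 40 genes), an IP enrichment per
genotype (100 target genes at U[2.5, 5], drawn independently per genotype
so association ratios span roughly the published 0.38–3.5 range), five
KO-only transcripts absent from WT (background-level signal and detection
p > 0.01 there), and a housekeeping control planted at enrichment exactly
1.0 in both genotypes at base 11.0. Replicate noise is Gaussian on the
log2 scale (sd 0.25, n = 3 per condition — the study's replication level);
heavier-tailed noise can be substituted by the caller. About 45% of genes
carry a second, one-log2-unit-dimmer probe (the platform's ≈1.5
probes-per-transcript ratio) and 20 decoy probes lack RefSeq annotation.
Detection p-values are generated from signal versus a background
threshold; only their position relative to the 0.01 cutoff matters
downstream, so no bead-level model is attempted. Everything is
deterministic per seed.

Not emulated: bead-level noise, spatial/batch artifacts, probe
cross-hybridization, intensity-dependent variance. Passing tests
therefore demonstrate the pipeline's correctness and calibration under a
log-additive Gaussian model, not robustness to platform-specific
artifacts.

One measured property of the model worth knowing: joint quantile
normalization across fractions slightly shrinks planted enrichments
(about −0.15 log2 on average at these settings), because the IP arrays'
upper tail genuinely differs from the totals'. This is a property of the
normalization itself, visible in the noiseless-limit tests (which
therefore check planting against raw generated signals), and it is why
recovered enrichments sit a little below planted truth.

## Recovery metric

Recovery of planted targets is scored on the **union target list** across
genotypes — the object the downstream association analysis consumes: a
planted target counts as recovered when called in at least one genotype,
and a call is false when the gene was planted in neither. At the default
conditions (25 seeds), mean union recall ≥ 0.90 with empirical FDP 0. A
per-genotype recall would be substantially lower (≈ 0.8) for a structural
reason: with triplicates, the pooled t has 4 degrees of freedom, and a
true 2.5-fold enrichment yields p ≈ 3·10⁻³ in expectation — right at the
adaptive BH cutoff when ~5% of 2,000 genes are true. That is the
operating characteristic of this design, not an implementation defect,
and it motivates scoring the pipeline on its actual output list.

## Numerical and interface choices

- Outputs are TSV with a header, floats at six significant digits, fixed
  sort orders (targets by descending enrichment, GO by ascending p), so
  reruns diff cleanly; every CLI stage writes a manifest echoing seed,
  thresholds and configuration, and stagewise runs are byte-identical to
  the monolithic `all` run.
- The probe-profile dialect is one header line with `<sample>.AVG_Signal`
  / `<sample>.Detection_Pval` column pairs plus PROBE_ID / SYMBOL /
  REFSEQ / DEFINITION annotation columns; matrix column order always
  follows the design table, not the file.
- Detection α = 1 is accepted as the degenerate everything-detected
  identity; α = 0 is rejected.
- The hypergeometric tail, t CDF, BH adjustment, OLS fit and linkage
  clustering are delegated to scipy/statsmodels; quantile normalization
  and the calling logic are implemented here and verified against
  independent brute-force oracles in the test suite.
- Single-threaded throughout; results never depend on parallelism.

## Known limitations

- Probe→gene collapse keeps one probe per symbol; splice-variant-specific
  probes are collapsed away.
- The IgG background that a bead-level control would provide is out of
  scope (the motivating design discards IgG-control RNA as below array
  input requirements); the housekeeping contaminant bound is the only
  negative control.
- GO scoring treats GMT annotations as flat sets.
- The qPCR module implements the relative standard curve method only; no
  ΔΔCt, melting-curve or efficiency-correction variants.
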