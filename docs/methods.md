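# Methods

## Scope and data model

The package operationalizes a three-layer analysis: (1) transwell
chemotaxis of immune subsets (cDC1, cDC2, B cells, CD4/CD8 T cells,
monocytes, pDCs) toward conditioned media, quantified by flow cytometry
with counting beads; (2) targeted proteomics of the same media as
log2-scale normalized protein expression (NPX) with per-protein limits of
detection (LOD); (3) bulk expression of a small immunotherapy cohort
scored against gene-set signatures. NPX values are comparable across
samples within a protein but never between proteins, so all secretome
analyses are per-protein.

## Migration quantification and calling

Absolute counts use standard counting-bead arithmetic: a known bead
quantity is spiked per sample, so `count = events x beads_added /
bead_events`. Wells with zero acquired bead events are unquantifiable and
rejected rather than imputed.

Donor QC excludes a donor (per subset) when the ratio of migration toward
the positive-control chemokine mix over the negative control (medium only)
is below 2.5; a ratio of exactly 2.5 passes, and a zero negative control
with nonzero positive migration passes (the ratio diverges). Donors with
both controls at zero are excluded with a warning.

Induction: an attractant is called active for a subset when its mean
absolute count strictly exceeds `mean + 2 x SD` of the matched negative
control replicates. The SD is the sample standard deviation (n-1): the
negative-control replicate sets are small (typically 4 wells), so the
unbiased estimator is the defensible choice. With SD = 0 the rule
degenerates to a strict mean comparison. The rule is scale-equivariant and
monotone in the attractant counts.

Pooling across donors: induction is computed on absolute bead-scaled
counts pooled across QC-passing donors, with negative controls pooled from
the same donors. This keeps the call and its threshold on a single scale
(the call invariant `induced iff mean > threshold` holds exactly) and is
conservative: between-donor variation inflates the pooled negative-control
SD and therefore the threshold. Normalized percentages, by contrast, are
computed within donor (each donor's own positive-control mean defines
100 %) and then averaged, because donors differ systematically in overall
migratory capacity. `donor_pooling: separate` emits per-donor rows
instead, since published figures sometimes plot donors individually; the
package does not assert which convention a given figure used.

## Nonparametric tests

All tests are written directly rather than delegated, because the
exact/approximate switch and tie conventions are load-bearing for small
assay samples; scipy serves only as an independent cross-check in the test
suite.

* **Fisher 2x2**: two-sided p sums hypergeometric point probabilities (of
  all tables with the observed margins) not exceeding the observed one,
  within relative tolerance 1e-12; computed with exact integer binomials.
* **Mann-Whitney / Wilcoxon signed-rank**: exact by full enumeration
  (all group assignments / all sign patterns over midranks) up to the
  configured thresholds (8 per group; 12 nonzero differences). The
  two-sided exact p counts outcomes at least as extreme in
  |statistic − null mean|. Beyond the thresholds, a midrank,
  tie-variance-corrected normal approximation with continuity correction
  is used; the signed-rank version carries a one-term Edgeworth kurtosis
  refinement (the sign-flip null has excess kurtosis
  −2·Σr⁴/(Σr²)², noticeable just above the enumeration threshold), which
  keeps the approximation within ~0.002 of exact down to n = 9.
* **Kruskal-Wallis / Friedman**: tie-corrected statistics against
  chi-square(k−1); Friedman additionally enumerates all within-row rank
  permutations when `n·k ≤ 12`. All-constant input returns the degenerate
  result (statistic 0, p = 1) instead of erroring, so batch screens do not
  abort.
* **Dunn post hoc**: pooled-midrank z statistics with the tie term
  `Σ(t³−t)/(12(N−1))`; the paired variant uses Friedman mean ranks with
  `SE = sqrt(k(k+1)/(6n))`. Two-sided p-values are multiplied by the
  number of *requested* comparisons (capped at 1) — published figures
  typically compare selected pairs rather than all pairs; passing all
  pairs recovers the classical correction.
* **BH FDR**: step-up q-values, monotone and order-equivariant.

## Secretome semantics

Below-LOD NPX values are stored as reported but flagged; analyses
substitute the per-protein LOD (standard NPX convention; half-LOD and raw
modes available). "Detected" means above LOD in at least one TME sample
(configurable via `min_detected_samples`) — a deliberately liberal
reading, since detection counts in such studies are rarely operationally
defined. The presence contrast requires below-LOD in **all** cell-line
profiles and detection in a strict majority (> 50 %) of TME profiles;
exactly half fails. The contrast is monotone in TME detection and every
passing protein is by construction detected.

## Correlation screen and candidate selection

Migration enters the screen as the mean absolute migrated count per TME
sample (averaged over replicates and donors), correlated against NPX by
Pearson across samples (n ≥ 3 required). BH correction is applied within
each subset's protein family (the per-subset display convention of
correlation heatmaps); a global family is available by flag. Significance
thresholds the corrected q by default, with an `--uncorrected` switch
because legends of the form "* p < 0.05 (BH-corrected)" are ambiguous
about which scale the star refers to. Constant proteins or constant
migration yield degenerate records excluded from the BH family.
Candidates for the anchor subset (default cDC1) are significant records
with r > 0 — positivity is enforced at selection, not screening — that
also pass the presence contrast.

## Signature scoring

Each gene is z-scored across the cohort (sample SD); a sample's score for
a signature is the mean z over the signature's genes present in the
matrix. This is the most common reading of "signature Z-score" and makes
scores invariant to per-gene affine transforms; per-signature cohort means
are 0 by construction. Zero-variance genes contribute z = 0; absent genes
are dropped and reported via `n_genes_used`. Composite signatures resolve
to de-duplicated unions of their components (cycles rejected). Response
comparison is a two-sided rank-sum test, exact whenever the assignment
count is tractable (always at the 3-vs-13 design scale, where the minimum
two-sided p is 2/C(16,3) ≈ 0.0036). Gene lists are supplied as GMT plus a
composite-mapping TSV and are never hard-coded.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated; defaults are fixed to the motivating design and are not tuning
knobs.

**Secretome.** Each protein has a background (assay floor) NPX drawn once
per panel. The per-protein LOD is `floor + z_q · noise_sd` with
`lod_quantile = 0.9999` — i.e. the upper quantile of the background-noise
distribution, an assay property analogous to how proteomics LODs are
derived from blank measurements. Background proteins split into ~30 %
"absent" (floor everywhere, hence below LOD — reproducing the observed
pattern of roughly 65 of 92 panel proteins detectable in tumor media) and
~70 % "ubiquitous" (2-8 NPX units above floor, running up to 2 units
higher in TME media). The four planted chemokines sit at floor in every
cell line and `stromal_level = 4` log2 units above floor in TME media,
modulated by a shared per-sample stromal-activity factor (SD 0.8 log2),
a per-protein deviation (SD 0.4) and an anatomical-site shift (laryngeal
−0.5, hypopharyngeal +0.5). The shared factor models co-secretion by the
same stromal compartment and yields migration-NPX correlations around
0.8-0.9, the regime reported for strong chemokine associations.

**Migration.** Expected counts are
`baseline_k x donor_effect x multiplier`, with lognormal donor effects
(σ = 0.3, capturing PBMC donor variability), negative-binomial sampling
(size 10), and multipliers of 1 (negative control), 6 (chemokine mix),
`1 + 4 · w_k · drive_j` for TME media (weights 1 for cDC1/cDC2, 0.5 for
B cells, 0.3 for monocytes, 0 for T cells — the central negative finding
that tumor secretomes do not recruit T cells), and an HPV-dependent cDC2
attraction for cell lines (HPV-negative lines lognormal around 5x,
HPV-positive none). Bead acquisition fractions are drawn per well
(30-90 %) so counting-bead arithmetic inverts the true count within
sampling noise.

**Expression.** 2,000 Gaussian genes (SD 1) over 16 samples; eight
disjoint 25-gene signatures; responders (3 samples) receive +1 SD on all
genes of the six designated "up" signatures (chemokine, DC programs,
myCAF, iCAF); eCAF and pericyte stay flat.

Determinism: every layer is a pure function of `(config, seed)`; the
layers draw from independent streams (`default_rng([seed, stream])`) so
regenerating one never perturbs another.

**What the generator does not emulate:** compositional correlations among
background proteins, batch effects and plate-level LOD variation,
donor-subset interactions beyond a multiplicative effect, heavy-tailed
count contamination, and expression covariance structure (genes are
independent given the planted shifts). Passing tests therefore demonstrate
correctness of the decision rules and statistics under a faithful but
idealized generative model, not robustness to all failure modes of real
assay data.

## Problem sizes used in validation

End-to-end validation runs the full default design (28 TME media, 11 cell
lines, 92 proteins, 2 donors x 2 replicates) over 100 simulated studies
for candidate recovery, 60-100 for null calibration, and 200 expression
cohorts for signature power — sizes at which the recovery and error-rate
estimates have standard errors of a few percent.

## Known limitations

* The exact rank tests enumerate; for samples just above the thresholds
  the Edgeworth-corrected approximation is accurate to ~0.002, but exact
  enumeration can be forced with larger thresholds at exponential cost.
* Dataset-dependent counts from any particular real study (which proteins
  pass, how many correlate) depend on that study's data and are not
  reproduced by the synthetic generator; only the decision rules and
  their operating characteristics are.
* The pipeline's staleness rule is mtime-based; clock skew across file
  systems can cause unnecessary re-runs (never silently stale results,
  since `--force` re-runs everything).
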