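# Methods

## Model

`coreg` assumes that disease genes share regulatory programs with the genes
already annotated to the disease's phenotype terms, and that those programs
are visible as principal components of the gene–gene correlation matrix of
a large, heterogeneous expression compendium. Everything downstream is a
statement about a gene's *eigenvector coefficients* — its loadings on the
retained components.

**Component space.** The gene–gene Pearson correlation matrix (genes ×
genes) is eigendecomposed (`scipy.linalg.eigh`); an economy path takes the
SVD of the row-standardized data instead and yields identical leading
eigenvectors. Eigenvalues below −10⁻⁸ (relative) reject the input as
non-PSD; small negative values are clipped to zero. Eigenvector sign is
arbitrary, so each column's largest-magnitude coefficient is forced
positive; all results are invariant to consistent sign flips (the
prioritization correlation multiplies two sign flips together).

**Component reliability.** A component is only useful if it reflects
reproducible co-regulation rather than sampling noise. Reliability is
estimated split-half: samples are randomly partitioned into two halves,
each half's correlation matrix is decomposed, each full-data component is
matched to the most similar component in each half (maximal absolute
loading correlation), and the absolute correlation between the two matched
half-eigenvectors is Spearman–Brown corrected (2r/(1+r)) and averaged over
`n_splits` partitions (default 5, seeded). Retention uses a prefix rule —
stop at the first component below the 0.7 gate — so the retained space is
always the nested top-variance one. The reliability estimator is a single
function; an alternative formula can replace it without touching the rest
of the pipeline.

**Term profiles and prioritization Z.** For a gene set, each retained
component gets a signed Z from a Student's (optionally Welch's) two-sample
*t*-test of in-set vs background coefficients, where the background is
every gene in the space outside the (possibly leave-one-out-reduced) set.
All p→Z conversions are signed two-sided probits computed from the log
tail probability (`scipy.special.ndtri_exp`), exact to |Z| = 40 where they
are capped with an explicit flag. A gene's prioritization Z for a term is
the probit of the p-value of the Pearson correlation between its
coefficient vector and the term profile, via t = r√(k−2)/√(1−r²) with
k−2 degrees of freedom.

**Leave-one-out.** Annotated genes are scored against the profile
recomputed with the gene excluded (the gene joins the background). This is
the load-bearing detail: without it a gene's own coefficients enter the
profile and known annotations trivially score high. The exclusion must be
exact — the per-gene moment updates are indexed by set-member order, and a
dedicated null-calibration test guards the property (annotated-gene Z
under random sets is standard normal).

**Term gating and fallback.** Per term: AUC = U/(n₁n₂) from the
Mann–Whitney U of annotated LOO scores vs background (midranks,
tie-corrected normal approximation, one-sided), Bonferroni correction over
the database's eligible (≥ 10 gene) terms, significance at corrected
p ≤ 0.05. Insignificant query terms resolve to their *minimal significant
ancestors* in the `is_a` DAG: significant ancestors with no significant
descendant that is also an ancestor of the query, root excluded, ordered
by distance. All minimal ancestors are used (each as one term in the
combination); ties across queried terms are deduplicated.

**Combination and ranking.** Combined Z = Σz/√m over the used terms; terms
without a usable score for a gene are skipped and m shrinks; genes with no
usable term are reported unscored rather than imputed at zero. Ties share
the average rank. Combined Z ≥ 5 (p ≈ 5.7 × 10⁻⁷) flags strong candidates.
The optional annotation floor raises every known (gene, term) cell to
Z = 3 before combination; annotated cells that could not be scored at all
(LOO set below 2 genes) also receive the floor, since the annotation
itself is known.

**Predictability.** Per gene and database, the bias-adjusted
Fisher–Pearson skewness (g₁ · √(n(n−1))/(n−2)) of the gene's prioritization
Z over the database's *significant* terms only (insignificant terms are
noise by construction); the overall score is the unweighted mean across
databases. Undefined (constant or < 3 values) database entries are NaN and
excluded from the mean.

## Synthetic studies

The generator produces the statistical structure the method consumes, not
realistic RNA-seq: X = L·F + E with disjoint blocks of genes loading one
standard-normal factor each, noise scaled to a per-factor signal-to-noise
ratio (SNR = signal variance / noise variance for loaded genes), plus
annotation sets sampled from blocks with optional label noise, a
three-level toy ontology (root → per-factor umbrella → leaf terms, with
annotations propagated to umbrellas), and a disease catalog whose causal
genes are held out of every training set.

Two generator choices matter and are deliberate:

- **Block sizes follow a geometric ladder** (e.g. 13·1.12^f). Equal-size,
  equal-SNR blocks give a near-degenerate eigenvalue spectrum whose
  eigenvectors mix arbitrarily between sample halves — split-half
  reliability then correctly reports the components as unstable, and
  nothing is retained. This is a true property of PCA, not an artifact;
  real compendia have a decaying spectrum because real co-expression
  modules vary widely in size. The ladder makes the planted components
  identifiable.
- **Heterogeneity where a correlation is measured.** The contamination and
  subsampling analyses report correlations *across terms/diseases*; these
  are only meaningful when terms differ. Those studies therefore vary SNR
  across factors (geomspace 0.3–6) and/or annotation quality across terms
  (label noise 0–0.6), emulating the spread of real annotation databases.
  The planted-recovery benchmark keeps SNR fixed at 5.

Fixed study sizes (chosen once, as the package's study conditions): the
`small` preset uses 300 genes (10 factors of 13–36 genes), 1 500 samples,
SNR 5, three 10-gene terms plus one 3-gene "rare" term per factor, 3
held-out causal genes and 3 diseases per factor (30 diseases, 50 decoys
per patient). The robustness studies use 600 genes, 12 factors (25–71
genes), 1 500 samples. The null-calibration study uses a 300 × 1 500
pure-noise compendium with the top 10 components selected directly (a
truly unstructured null cannot pass a reliability gate, and should not).

What passing these tests does *not* show: robustness to library-size and
count-distribution effects, batch structure, overlapping/pleiotropic
modules, or annotation biases of real databases — the generator plants
none of these.

## Numerical choices

- Correlation inputs are used as given; `--log2` and `--center-scale` are
  caller-opted preprocessing.
- Zero-variance gene rows are dropped with a logged warning before
  correlation; constant coefficient vectors yield Z = 0 with a warning.
- Both-groups-constant-and-equal t-tests return Z = 0; zero pooled
  variance with unequal means returns the capped ±40.
- AUC p-values are clamped to (tiny, 1]; |Z| is capped at 40 everywhere.
- Term-profile clustering uses average linkage on distance 1 − r
  (configurable); profiles are correlated over all matrix genes, not just
  a patient's candidates.
- The permutation null redraws each disease's genes uniformly from the
  universe excluding genes annotated to any of the disease's terms (retry
  cap 1000). Because exactly the top-ranking genes are excluded, permuted
  ranks are uniform over the *eligible pool*, not the full universe — the
  test suite asserts the former.
- All stochastic steps take an explicit seed (default 42); generators are
  pure functions of (parameters, seed).

## Limitations

- Split-half reliability is one reasonable operationalisation of component
  stability; other reliability coefficients may gate differently near the
  0.7 threshold.
- The prefix retention rule discards reliable components that sit after an
  unreliable one; with a strongly decaying spectrum this is what you want,
  but it is conservative on spectra with interleaved noise.
- With few retained components (k ≈ 10 in the desk-scale studies) the
  prioritization correlation is coarse; the method's discrimination grows
  with k, and desk-scale ranks should be read as a structural, not
  quantitative, analogue of compendium-scale performance.
- Genes whose expression carries no co-regulation signal are genuinely
  unpredictable; the predictability score diagnoses but does not fix this.
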