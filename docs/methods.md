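# Methods

## Data model

The experimental unit is a peptide spot measurement with coordinates
(sample, peptide, chip, array index 1–4, series, technical replicate,
inhibitor condition) and two values: raw fluorescence and local array
background. Chips carry up to four arrays; a sample's with-inhibitor
arrays must be paired with without-inhibitor arrays of the same sample on
the same chip — this pairing is what licenses chip-level log-fold
changes, and the validator rejects experiments that break it. BRAF/NRAS
co-mutation is reported as a warning, not an error: the two are mutually
exclusive in melanoma cohorts, but a data table asserting otherwise
should be surfaced, not silently rejected.

## Preprocessing

Net signal is raw minus local background and may be negative. Before the
log2 transform, non-positive nets are replaced by a floor of 0.01
(arbitrary fluorescence units); positive values below the floor pass
through unchanged — the floor exists only to make the logarithm defined,
and flooring positives would silently bias genuinely tiny signals. A
consequence worth knowing: the transform is *not* monotone on the open
interval (0, 0.01), where values map below log2(0.01); it is monotone
everywhere else. In practice real spot intensities sit orders of
magnitude above the floor.

Basal profiles average the floored log2 replicate values per
(sample, peptide) within each experimental series, subtract each
peptide's across-sample series mean (centering, which removes
batch-level offsets), and average the centered values over the series a
sample appears in. Within-series contrasts between samples are untouched
by construction.

Inhibition profiles are computed per chip — replicate-mean log2 without
minus replicate-mean log2 with inhibitor — then averaged over the
sample's chips. No series centering or other normalization is applied to
LFC values: chip and batch offsets are shared by the two paired
conditions and cancel in the difference. Positive LFC means the
inhibitor reduced phosphorylation.

## Differential testing and FDR

Each peptide is tested independently with a two-tailed two-sample t-test
on the chosen matrix (inhibition profiles for the BRAF contrast). The
default is the pooled-variance Student statistic, df = n₁+n₂−2, matching
the historical default of array-analysis environments; Welch with
Satterthwaite df is a config switch. Groups with zero variance and equal
means are reported as degenerate with p = 1 rather than NaN. Selection is
at raw P < α (default 0.05) with no multiplicity adjustment — faithful
to the analysis being reproduced, which selects raw and discusses FDR
post hoc. The plug-in estimate m·α/k (all features assumed null) is the
headline; the (m−k)·α/k variant (only non-discoveries null) is also
reported. For m = 144, k = 40, α = 0.05 these give 18% and 13%
respectively. Benjamini–Hochberg adjusted p-values are available as a
clearly separate extra.

Samples with undetermined BRAF status are excluded from the two-group
contrast and from cross-validated accuracy, with a log notice.

## PCA and PLS-DA

PCA is the SVD of the column-centered matrix with a deterministic
reflection (largest-magnitude loading element positive per component).

PLS-DA is implemented from scratch as NIPALS PLS1: classes are coded
−1 (wild-type) / +1 (V600E), X columns and y are mean-centered, and per
component the weight vector is Xᵀy normalized to unit length, scores
t = Xw, loadings p = Xᵀt/tᵀt, q = yᵀt/tᵀt, with deflation of X and y.
The regression vector B = W(PᵀW)⁻¹q maps a centered profile to its
continuous prediction score; the overall training mean scores exactly 0.
Class rule: score > 0 → V600E, score ≤ 0 → wild-type (ties fall to the
reference class). Two latent components by default — the minimal choice
consistent with score plotting and common PLS-DA practice; the component
count is config-exposed and no inner selection loop is run, keeping the
outer cross-validation honest. Columns are centered but not autoscaled
by default, because LFC values already share the log2 scale; autoscaling
is a config switch. All linear algebra is deterministic, so identical
inputs give bit-identical models.

Leave-one-out cross-validation refits everything — centering, scaling if
enabled, the full NIPALS decomposition — on the n−1 retained samples for
every fold; the held-out profile influences nothing about the model that
scores it (asserted by a construction test). Folds whose training set
degenerates to a single class are marked invalid and excluded from the
accuracy denominators. A fold may train with a singleton class (2-vs-1
at n = 4); the fit only refuses single-class input.

## Clustering

Agglomerative clustering runs on a condensed distance matrix
(scipy linkage) after canonically sorting items by label, which makes
the dendrogram invariant to input row order and gives ties a
deterministic resolution. Defaults are 1−Pearson distance with average
linkage, the customary heat-map choice; Euclidean and complete linkage
are config switches. One caveat the defaults cannot see: correlation
distance is invariant to uniform scaling of a profile, so a class effect
that only rescales the signature profile (exactly the structure of the
synthetic generator's V600E effect) is invisible to it — cluster-purity
claims on such data use Euclidean distance. Correlation distance over a
single-peptide restriction is undefined; the heat-map ordering falls
back to Euclidean rows there.

## Packaged tables

Three CSV fixtures ship in `kinarray/data/`: the cohort table
(26 melanoma + 4 normal-skin samples; 10 V600E, 15 wild-type, 1
undetermined BRAF; 6 NRAS Q61), the 80-substrate significance-flag table
whose melanoma-tissue column defines the 40-substrate vemurafenib
signature with cell-line overlap flags (20 shared with the
resistant-line contrast, 8 with the sensitive-line contrast), and the
14-row EGFR/PDGFRβ/RAF p-value table. In the cohort table only the
totals are authoritative; the per-sample assignment of free-form
covariates (age, sex, site) is a synthetic reconstruction consistent
with those totals, and nothing computed from the fixtures depends on it.
Prevalences are reported exactly (10/26 = 38.46%, 6/26 = 23.08%); the
display helper rounds to the nearest half point (38.5, 23).

## Synthetic generator

The generator emulates the study's design: 144 peptides, three technical
replicates, two series, paired conditions on shared chips, 26 tumors
(10/15/1) and 4 normal-skin donors. On the log2 scale, signals are
peptide baseline b_j ~ N(7, 1.5²) plus a tumor effect, series offsets
N(0, 0.3²) per (series, peptide), chip effects N(0, 0.15²) and replicate
noise N(0, 0.25²) — lognormal noise on the linear scale, standard for
fluorescence. Tumor effects are U(0, log2 5) (up to 5-fold) for 85% of
peptides; the remainder are mildly depressed (−U(0, log2(5)/4)) rather
than exactly zero, so the observed fraction of tumor-elevated peptides
emulates the 80–90% seen on real arrays instead of drifting to ~92%
under coin-flip ties. Inhibition subtracts
w(b_j)·(1.0 + 1.0·[V600E ∧ signature]) log2 units, where
w(b) = 1/(1+e^(−1.5(b−5))) is a logistic attenuation making low-basal
peptides resist inhibition (direction taken from the data being
emulated; the logistic form is this package's choice). The base depth of
1.0 log2 gives the ~50% median signal reduction of the study; the
signature set (default 40 peptides) is drawn uniformly from the panel.
One seeded generator drives all sampling in a documented draw order, so
identical seeds give bit-identical experiments.

What the generator does **not** emulate: per-cycle kinetic reads,
spatial spot artifacts, sample-level biological heterogeneity within a
class (all wild-type tumors share one expected inhibition profile), or
cross-peptide correlation beyond shared effects. Passing recovery tests
therefore demonstrate correctness of the computations under the assumed
model, not expected performance on real tumor arrays — in particular
LOOCV accuracy saturates at 1.0 here, whereas heterogeneous real cohorts
will sit lower.

## Problem sizes and numerics

The test suite runs the full pipeline on study-sized experiments
(≈24,000 measurement rows each); calibration suites use 1,000 pure-noise
panels of 144 peptides for the type-I rate (3 Monte-Carlo-SE tolerance
around α) and 100 label permutations for the LOOCV chance envelope
([0.35, 0.65] mean accuracy); recovery metrics average a 10-seed grid.
The acceptance script uses the same sizes and finishes in seconds.
Oracle comparisons are pinned at 1e-10 (t-test closed form), 1e-8 (PCA
vs SVD), 1e-6 (PLS-DA vs an independent PLS1 reference) and 1e-10
(average-linkage heights vs a brute-force agglomerator). Degenerate
inputs (empty series, unpaired chips, zero-variance columns, no
discoveries) raise typed errors listed per operation rather than
propagating NaNs.

## Known limitations

* No moderated/empirical-Bayes variance shrinkage; per-peptide tests use
  raw sample variances.
* Two-class PLS-DA only; no multi-class coding, sparse variants, or ROC
  analysis (the classification readout is thresholded accuracy).
* No ingestion of vendor-native array exports or MAGE-TAB archives; the
  long-format CSV schema is the interchange surface, and an adapter for
  deposited raw archives is future work.
* End-level signals only; no kinetic modeling of incubation cycles.
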