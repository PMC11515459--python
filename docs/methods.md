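# Methods

`bonepmi` re-implements, as a tested pipeline, an analysis strategy for
estimating late postmortem intervals (PMI, > 5 years) from bone
proteomes: characterize label-free-quantification (LFQ) protein
abundance tables from rib and tibia samples, explore them without
supervision (PCA, K-means, MCA), then train a resampling-stabilized
random-forest classifier and screen its variables down to a minimal
biomarker panel using Mean-Decrease-in-Gini importances and TreeSHAP
attributions.  Because the original LC–MS/MS data are not shipped with
the package, a synthetic study generator reproduces the statistical
structure the analysis assumes, giving every stage a ground truth.

## The abundance model and the synthetic study

An abundance table is samples × proteins; a cell is either a positive
MS1-based LFQ intensity or an explicit "not identified" state (NaN in
memory, blank in TSV).  Missingness is information — a protein absent
from a degraded sample is a finding, not a defect — so imputation is
always an explicit, named step (`zero_fill`) rather than something the
reader does silently.

`SyntheticSpec` describes one study: conditions (PMI class × bone),
replicates, a protein panel, per-(protein, PMI class) log10 mean
intensities, a common log10 standard deviation, per-(protein, PMI
class) detection probabilities, additive per-(protein, bone) log10
shifts, and a list of planted biomarkers.  A detected intensity is
drawn as `10 ** Normal(log10_mean + bone_effect, log10_sd)`; detection
is Bernoulli.  Intensities are log-normal because LFQ intensities are
positive and heavy-tailed with roughly multiplicative noise.
Generation is a pure function of the spec: the same spec yields a
bit-identical table.

The default study mirrors the design of a 25-sample bone collection:
five conditions (PMI < 1 yr rib; PMI 15 rib and tibia; PMI 20 rib and
tibia) × five biological replicates, over the 21 named representative
semitryptic proteins (albumin, prothrombin, fetuin-A, hemoglobins,
collagens I/III and biglycan, keratins, semenogelin, S100 proteins,
histones, GAPDH).  Its key parameters:

- **Planted biomarkers** PGS1, K1C13, CO3A1: class-conditional log10
  means separated by ≥ 2.5 log10 units (≥ 10 σ at σ = 0.25), in
  opposite directions for the keratin (declining with PMI) and the
  matrix proteins (relatively accumulating), always detected.  Their
  mean ± 3σ intervals — widened by the bone shift where it applies —
  are pairwise disjoint across PMI classes, which the spec validator
  enforces arithmetically and a test asserts on the generated output.
- **Noise proteins** (the other 18): identical means in every class.
  Detection probability 0.98 (PMI1) vs 0.88 (both late classes) — the
  early proteome is richer, but missingness carries no signal *between*
  the late classes, matching the nearly identical late-class
  consistent-proteome sizes reported for real bone and keeping the
  planted trio the only PMI15-vs-PMI20 signal.
- **Bone effect**: +2.0 log10 (tibia) on collagens I, +1.0 on CO3A1 and
  PGS1 — tibia retains matrix proteins better than rib.
- **σ = 0.25** log10 units, a typical between-replicate spread for
  label-free bone proteomics.

A second factory, `bone_dominant_spec`, generates the *variance regime*
of real proteomes instead: a strong tibia shift across the whole
matrix-associated half of the panel and an early-PMI enrichment of the
cellular/blood half.  Real proteomes have this broad correlated
structure, which is why a few principal components explain most of
their variance; the default (screening) study deliberately does not —
its 18 noise proteins must be independent for the planted trio to be
the unique answer — so the two regimes are provided as two specs rather
than squeezed into one.  This is also the honest statement of what the
generator does *not* emulate: real studies have both structures at
once, plus peptide-level effects, shared contaminants and batch
structure that no stage here models.

`generate_sequences` produces protein sequences with exact rounded
counts of acidic (D, E) and basic (K, R, H) residues at requested
percentages, for exercising the biochemical profiling stage with known
composition contrasts.

## Proteome sets and biochemical profiling

A protein is *identified* in a sample when its intensity is present;
the upstream one-unique-peptide criterion belongs to the search engine,
so users of real FragPipe/IonQuant exports should pre-filter
accordingly.  A condition's *consistent proteome* is the intersection
of identified sets over its replicates; the *representative set* of a
search type is the union of its per-condition consistent proteomes
(unions run within a search type by default — that convention
reproduces the published counts of 16 tryptic and 21 semitryptic
representative proteins).  Intersection signatures (the counts an UpSet
plot shows) are computed by exact per-protein membership enumeration.

Two-group comparisons use a normality gate: Shapiro–Wilk per group at
α = 0.05; Student's t-test if both groups pass, otherwise a two-sided
Mann–Whitney U.  A zero-variance group counts as non-normal
(Shapiro–Wilk is undefined on constant data).  Molecular weights are
averages (residue masses + one water, via Biopython); acidic/basic
fractions are simple residue percentages over the full supplied
sequence.  Histidine counts as basic by convention; the class sets are
arguments for users who disagree.  The early-vs-late contrast subtracts
the union of late proteomes from the early set and compares weight and
composition distributions between the early-exclusive and late groups.

## Ordination

`standardize` zero-fills, optionally log10-transforms (off by default),
and z-scores each protein with the population standard deviation;
constant columns are dropped with a warning.  PCA is the full SVD of
the standardized matrix; K-means (k-means++ seeding, 10 restarts,
seeded) runs on the component scores.  MCA uses the complete
disjunctive table — two indicator columns per protein — and the SVD of
the standardized residual matrix; single-state proteins are dropped,
and an all-constant matrix returns a flagged degenerate result rather
than an error.

## The random-forest protocol

All modelling uses scikit-learn's `RandomForestClassifier` on
zero-filled, **log10(1 + intensity)** features.  The log transform is a
numerical choice, not a statistical one: tree *fits* are invariant to
monotone transforms, but split thresholds are placed at arithmetic
midpoints of adjacent training values, and on a raw intensity scale
spanning eight decades those midpoints sit at the very top of any
between-class gap, so held-out samples near the lower edge of the upper
class are systematically misassigned.  On the log scale the midpoint of
a gap is its geometric mean — the natural "between" for intensities —
and planted-structure studies classify cleanly.

Hyperparameters come from a randomized search (default 50 candidates)
over the declared grid — `n_estimators` ∈ [100, 500), `max_depth` ∈
{5, 10, 15, 20}, `min_samples_split` = `min_samples_leaf` = 2,
`max_features` = sqrt — scored by stratified 3-fold cross-validated
accuracy on a stratified 60% training portion (3-fold is the largest
feasible CV at ten samples per stratum).  The published per-stratum
presets are shipped under `PRESETS`; the default is the
tibia/semitryptic block (448 trees, depth 15).  A second published
tibia block (158 trees, depth 30, `max_features` None) conflicts with
the declared grid and is kept as the explicitly named
`tibia-alternative` preset.

`resampled_evaluation` repeats, `n_iter` = 100 times: draw a stratified
80/20 train/test split, fit the forest, record test accuracy and
macro-averaged F1, the normalized Mean-Decrease-in-Gini importance
shares, and per-class SHAP values for the test samples.  Iteration *i*
seeds both split and forest with `base_seed + i`, so the full trace is
reproducible from one integer.  Splits are stratified because with five
samples per class an unstratified 80/20 split can produce single-class
training sets.  F1 is macro-averaged (classes are balanced by design,
so macro equals weighted here).  After the requested iterations the
protocol verifies that every sample appeared in at least one training
and one test set, appending reshuffled iterations (with a warning) if
not.

SHAP values are computed by an exact path-dependent TreeSHAP
implementation (`bonepmi.treeshap`) operating on the fitted sklearn
trees' class-probability outputs: the Shapley value of each feature
against the value function E[f(x) | x_S], with out-of-subset splits
averaged by training cover.  Per-tree attributions average across the
forest, so local accuracy — base value + Σ attributions =
`predict_proba` — holds to numerical precision and is asserted for
every iteration record.  The implementation is validated against a
brute-force subset-enumeration Shapley oracle on small trees.

## Variable screening

`minimal_biomarker_search` runs the screening loop:

1. **Round 0** — evaluate the full panel; average importances over the
   iterations; keep proteins with mean importance share strictly
   > 4% (the pre-filter is applied once, up front).
2. **Elimination rounds** — from each retrained round's per-class SHAP
   summaries, drop (at most `batch` = 2 per round, never the whole
   remaining panel) the proteins whose pooled SHAP median is near zero
   in *every* class and whose pooled minimum is negative in at least
   one class; a protein whose SHAP is identically zero everywhere also
   qualifies.  Summaries for class *c* pool the class-*c* SHAP values
   of test samples whose true label is *c* — the distribution of each
   protein's contribution toward recognising that class, which is what
   the per-class violin plots show.  (Pooled over *all* test samples,
   a strong feature's median would be ≈ 0 by symmetry and the rule
   would delete the best features first.)
3. **Termination** — when no protein qualifies: if mean *and* minimum
   accuracy and F1 across the iterations all reach the target (default
   1.0), the loop stops "sustained" and a leave-one-out pass certifies
   whether the set is *minimal* (no single protein removable without
   falling below target); otherwise the best-performing round's set is
   returned.  The candidate set strictly shrinks, so the loop is
   bounded by the panel size.

"Near zero" is a relative band: |median| ≤ ε · M with M the largest
absolute pooled SHAP value anywhere and ε = 0.25.  The band is
deliberately a quarter of the extreme value, not a few percent of it:
a median is a *typical* value and sits far below the distribution's
extremes even for uninformative proteins (measured ≲ 0.15 M, against
≳ 0.6 M for informative ones), so the default lies in the middle of
that empirical gap.

Minimality is reported, not enforced: on synthetic planted data each
planted biomarker separates the classes alone (disjoint supports), so
the certificate legitimately reports `minimal = False` for the
recovered trio; dropping certified-removable proteins is available
behind `loo_drop=True` for data where single features are insufficient.

### What recovery does and does not show

On the full default study (25 samples, three PMI classes) the screening
recovers exactly the planted trio stably (the stability property runs
20 seeded studies and requires ≥ 90% exact recovery; it uses 100-tree
forests and 20 iterations per round, the package's standard
reduced-size setting for multi-study properties).  On the *two-class,
ten-sample* tibia stratum alone, exact recovery is not a reasonable
expectation for any method: with 18 independent noise features and 5v5
samples, some noise feature rank-separates the two classes in roughly a
quarter of draws, and within that draw it is genuinely informative —
indistinguishable in principle from a planted signal.  Screening on
such a stratum still always *contains* the trio; small-cohort screening
results should be read with exactly this caveat.

## Pipeline and outputs

`run_pipeline` executes characterize → profile → ordinate → screen per
(bone, search) stratum from one `PipelineConfig` (JSON-serializable),
writing TSV stage outputs and a consolidated `report.json` that embeds
the config and seeds; a rerun with the same config reproduces the
outputs byte for byte.  The `bonepmi` CLI exposes `simulate`, `screen`
and `pipeline` subcommands.

## Numerical conventions and degenerate inputs

- Population (ddof = 0) standard deviation in standardization;
  explained-variance ratios from sample covariance eigenvalues.
- Ties in the randomized search resolve to the first-sampled candidate;
  ties in elimination ranking resolve alphabetically.
- Identical groups in `compare_groups` yield t = 0 or Mann–Whitney
  p = 1 (midrank convention).
- Empty early-exclusive or late groups (< 3 members) flag the contrast
  as degenerate instead of testing.
- All seeds are plain integers; every stochastic routine takes one
  explicitly and derives per-iteration seeds additively.

## Known limitations

- The generator starts at protein level: no peptides, spectra,
  retention times or FDR, and no correlation between dropout and
  abundance (in real LFQ, low-abundance proteins drop out first).
- Screening certifies internal resampling performance only; it cannot
  claim biological generality of a biomarker panel, and on ten-sample
  strata its output should be treated as hypothesis generation.
- MCA implements the indicator (complete disjunctive) formulation only;
  the Burt-matrix variant is out of scope.
- Molecular weights ignore post-translational modifications; no
  isoelectric point or hydropathy profiling.
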