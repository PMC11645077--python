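# Methods

## Model

The pipeline models the joint activity of `N` regions of interest at one
time point as a spin vector `σ ∈ {−1, +1}^N` (active/inactive relative to
each region's own temporal threshold).  The pairwise maximum-entropy model
(equivalently the Ising model / fully visible Boltzmann machine) assigns
state `V_k` the probability

    P(V_k) = exp(−E(V_k)) / Z,
    E(V_k) = − Σ_i h_i σ_i^(k) − (1/2) Σ_{i≠j} J_ij σ_i^(k) σ_j^(k),

with local fields `h` and symmetric zero-diagonal couplings `J`.  This is
the least-structured distribution reproducing the empirical first and
second spin moments.  The ±1 spin convention and the ½ double-counting
factor on the coupling term are stated explicitly because several
equivalent parameterisations circulate; all package outputs use this one.
States are encoded as integers with ROI 1 in the least significant bit and
may be labelled by their active-ROI positions (state 6 → "23").

Energy and probability are monotonically inverse by construction; the test
suite asserts exact rank inversion rather than assuming it.

## Fitting

`fit_mem` / `PairwiseMaxEnt.fit` maximise the exact log-likelihood by
gradient ascent on the moment residuals,

    Δh_i ∝ ⟨σ_i⟩_data − ⟨σ_i⟩_model,   ΔJ_ij ∝ ⟨σ_iσ_j⟩_data − ⟨σ_iσ_j⟩_model,

with model moments obtained by full enumeration of the `2^N` states (the
package targets small-N analyses; `N ≤ 20` is enforced, `N ≤ 15` is
practical, the canonical analysis uses `N = 8`).  The likelihood is
concave, so this converges to the global MLE.  Defaults: zero
initialisation (deterministic), learning rate 0.1, tolerance 1e−8 on the
max absolute moment residual, max 5·10⁵ iterations.  Non-convergence is
always reported via `FitDiagnostics.converged`.  Ridge shrinkage (`l2`) is
available for short recordings but off by default — an unregularised MLE
is the reference behaviour.  States never observed in a subject get
empirical probability zero; the model still assigns them positive
probability (no pseudocounts).

Fits are per subject by default (each subject has their own `2^N` energies
and probabilities); pooling subjects into one distribution is possible by
concatenating recordings before `empirical_distribution`.  `fit_many`
vectorises many per-subject fits through one batched gradient loop — it is
numerically identical to repeated `fit_mem` calls (shared update rule and
zero init) and exists so cohort-scale simulation studies (hundreds of
cohorts × ~120 subjects) run in seconds.  Simulation studies use tolerance
1e−6; at that tolerance the residual fitting error is orders of magnitude
below the between-subject variability the studies measure.

Sampling from a fitted or specified model is exact (enumeration +
inverse-CDF, i.i.d.) for `N ≤ 20`, or via a single-site-sweep Gibbs chain
(burn-in 1000 sweeps, thinning 5, both configurable) when enumeration is
undesirable.

## Landscape

Dynamics are idealised as steepest single-flip descent on the energy
surface over the `N`-dimensional hypercube.  A state is a local minimum
iff it is strictly lower than all `N` neighbours; basins are the attraction
regions of descent.  Exact energy ties are broken toward the lower state
index — ties have measure zero for continuous parameters but the rule
makes results bit-reproducible.  Basin depth of minimum `m` is the lowest
saddle to any other minimum minus `E(m)`, computed by threshold
percolation (states are inserted in ascending energy into a union-find;
the level at which `m`'s component first contains another minimum is its
saddle).  A single-minimum landscape is assigned depth `max E − E(m)` by
convention.  All three quantities are validated against exhaustive
brute-force search (neighbour comparison, literal path simulation,
Floyd-Warshall minimax saddles) on random instances with `N ≤ 4`.

## Group pipeline

**Binarization** thresholds each ROI at its temporal mean (median
optional).  Mean thresholding is the standard choice in the
energy-landscape literature; the threshold is invariant under positive
affine rescaling, so signal units are irrelevant.  Whether any further
standardisation precedes binarization is left to the caller; the synthetic
generator produces already-denoised series, and an optional zero-phase
Butterworth band-pass (default band 0.01–0.1 Hz) is provided for real
recordings.

**Per-state tests.**  For each state, per-subject model energies are
compared between groups with a Welch two-sample t-test (pooled-variance
optional), followed by Bonferroni correction with `m` defaulting to the
number of tested states.  The 5% usage-rate partition (below / near /
above a mean visit rate of 0.05, band ±0.005) and the
patient-only/control-only/shared occurrence sets are descriptive by
default; the usage partition can optionally pre-filter the tested states
but does not do so unless requested, since the choice is not forced by the
analysis logic.

**Paired states.**  "Complementary" state pairs are formed by
minimum-total-Hamming-weight matching over the significant states
(exhaustive over perfect matchings up to 12 states, greedy beyond), with a
deterministic lexicographic tie-break; an explicit user-supplied pairing
is always accepted, because the pairing convention is a judgement call in
the source analyses rather than a derivable rule.  Odd sets report the
unpaired leftover.  The per-pair statistic is the subject-level average of
the two states' empirical probabilities.

**Connectivity and SPC.**  Edge connectivity is `atanh` of Pearson
correlation (the weighted-GLM formulation used by CONN-style software
reduces to plain correlation for a single rectified resting condition —
implemented as such and documented as a simplification), with `r` clipped
to ±(1−1e−7).  Group contrasts are pooled-variance t maps (control = −1,
patient = +1; df = n1 + n2 − 2).  ROIs are ordered by complete-linkage
clustering with optimal leaf ordering on 1 − correlation of their mean-z
edge profiles (each pair's own columns excluded; an anatomical-distance
blend is available but defaults to purely functional, the anatomical
weighting being otherwise unconstrained).  Clusters are 4-connected
components of suprathreshold cells (|T| above the two-sided height-p
critical value, default 0.05) in the ordered upper triangle — the exact
connectedness rule used by the reference software is unpublished, so this
one is stated and tested.  Cluster mass is Σ|T|.  The null is group-label
permutation (subjects are the exchangeability unit; default 1000
permutations, seeded): per-permutation maximum masses give FWE p-values,
the pooled null mass distribution gives uncorrected p-values (with the
+1/(B+1) correction), and Benjamini–Hochberg across clusters gives FDR.
The "Score" cluster statistic reported by the reference software has no
published definition and is not implemented.  `n_possible_clusters` — the
Bonferroni denominator for ROI reduction — is defined here as the number
of unordered dendrogram-node block pairs, `(2N−1)·2N/2`, and is always
reported next to the results so the denominator is explicit.

**Summary-statistic tests.**  Demographic comparisons use
`ttest_ind_from_stats` (Welch or pooled) and Pearson χ² without Yates
correction (the printed sex χ² of the reference cohort is reproduced only
without it).  All p-values are two-sided.  Recomputation tolerance for
printed-table checks is ±0.05 absolute, reflecting two-decimal input
rounding.  Known discrepancies in the reference table (smoker χ², three of
the clinical-scale t values) are excluded from assertions: they cannot be
reproduced from the printed summaries by any of the standard formulas.

## Synthetic cohorts

`CohortConfig` defaults emulate the target study design: 8 ROIs, 63
controls vs 55 patients, 888 time points per subject.  (The acquisition
arithmetic of such protocols can imply more volumes than the analysis
matrix contains; `n_timepoints` is therefore a free parameter rather than
a hard-coded constant.)  Base parameters are `h = −0.2` (regions inactive
more often than active, as for sparse binarized BOLD) and a
nearest-neighbour coupling chain `J = 0.3` with one stronger link `J12 =
0.6`; `planted_cohort_config(delta=0.6)` removes that link in the patient
group, so the control-analogue group keeps the deeper co-activation basin
and the higher paired-state frequencies — the direction reported for
patient cohorts.  Per-subject jitter (sd 0.05 on `h` and `J`) supplies
inter-individual variability.  Continuous surrogates are spin amplitude
±1 plus Gaussian noise (sd 0.5, optional AR(1) smoothing); no hemodynamic
convolution or motion/physiological artefacts are simulated, so passing
tests demonstrate correctness of the analysis chain, not robustness to
scanner artefacts or preprocessing choices.  Behavioural covariates are
linear in the mean probability of designated target states plus Gaussian
noise and an optional group offset.  One seed drives everything through
`numpy.random.SeedSequence` spawning; cohorts are bit-reproducible given
(config, seed).

## Validation studies and problem sizes

`statescape.validation` runs the end-to-end studies the acceptance script
reports, at sizes chosen to give stable estimates on a single CPU:

- exact-distribution refit at `N = 3` (max parameter error ~1e−10) and
  sampled refit at `N = 8`, `T = 50,000` (truth-vs-fit correlation > 0.99);
- energy-probability rank inversion across 20 fitted models;
- landscape vs brute force on 100 random instances, `N ≤ 4`;
- per-state familywise error on 200 null cohorts (`N = 4`, 63/55 subjects,
  `T = 888`) — Bonferroni keeps the FWER at/below its binomial envelope
  around 0.05 (the per-state energies are strongly dependent across
  states, so Bonferroni is conservative here);
- SPC FWE validity on 100 null datasets (20/20 subjects, 8 ROIs,
  `T = 200`, 500 permutations);
- planted-effect power on 50 replicates of the 0.6-delta cohort at full
  study scale: detection of the two most-affected states (identified by
  enumerating both ground-truth Boltzmann distributions) and the sign of
  the control-minus-patient paired-state frequency contrast.

## Limitations

- Exact enumeration bounds the method to small-N analyses by design; no
  pseudo-likelihood or mean-field approximations are provided.
- The SPC connectedness rule, candidate-block count and cluster statistics
  are this package's stated definitions, not a reimplementation of any
  proprietary tool's internals; numbers are comparable across runs of this
  package, not across software.
- Synthetic cohorts validate the statistics, not the neuroscience: no
  claim about real patient/control separability follows from them.
- Preprocessing (realignment, normalisation, denoising) is out of scope;
  inputs are assumed to be analysis-ready ROI series.
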