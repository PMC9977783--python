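# Methods

## Scope and data flow

The package analyses peptide-level HDX-MS measurements of one protein in
two or more functional states. The unit of raw data is a centroid mass
(Da) for one peptide / state / timepoint / replicate, plus two controls
per peptide: an undeuterated centroid *m*₀ and a fully-deuterated (FD)
centroid *m*∞. Stages run in a fixed order — deuteration and uptake
curves, kinetic fits, fractional state differences, residue rigidity
labels, phenotype enrichment — with an independent structural-water
analysis over structure ensembles. All tabular interchange is CSV,
sequences are FASTA, ensembles are multi-model PDB.

## Deuteration and back-exchange correction

D(t) = max_protons · (m_t − m₀)/(m∞ − m₀), with
max_protons = length − 2 − (prolines at peptide positions ≥ 3). The FD
control is assumed to experience the same fractional back-exchange loss as
the timepoint samples, so the ratio cancels the per-peptide retention
factor exactly; the synthetic generator implements precisely this
single-multiplicative-factor model, which makes the correction an exact
inverse there. Replicate centroids are averaged per timepoint *before*
applying the correction; because the map is affine in *m_t* the order does
not bias the mean, and the replicate SD propagates through the same linear
scale factor. Deuteration values outside [0, max_protons] are retained
(clipping would bias downstream fits) and flagged when the excursion
exceeds 0.5 D. Degenerate controls (m∞ ≤ m₀) are a hard error.

The FD cohort summary reports mean and SD of per-peptide FD fractions as
percentages and the fraction of peptides at or below a 50% threshold with
explicit numerator/denominator, since low-retention peptides carry
little usable signal.

## Constrained uptake fitting

Model: D(t) = A(1−e^(−k₁t)) + B(1−e^(−k₂t)) + C(1−e^(−k₃t)), i.e.
max_protons − A e^(−k₁t) − B e^(−k₂t) − C e^(−k₃t) − NE with
A+B+C+NE = max_protons. Two constraints are built into the
parameterization rather than penalised:

- **Budget and non-negativity:** (A, B, C, NE) = max_protons ·
  softmax(φ₁, φ₂, φ₃, 0). The partition holds at every iterate, forcing
  D(0) = 0 and D(∞) = max_protons − NE.
- **Rate ordering:** k₁ = e^θ₁ (exponent clamped to ±25 to avoid
  overflow), k₂ = k₁·σ(θ₂), k₃ = k₂·σ(θ₃) with σ the logistic function,
  so k₁ > k₂ > k₃ > 0 exactly (up to float rounding when an amplitude is
  zero and the adjacent rate is unidentifiable).

A note on the budget constraint: stated literally as
max_protons = A+B+C+NE − 2 − num_prolines, the amplitude sum would exceed
the sequence-derived budget and force D(0) < 0; we read the "−2 −
prolines" term as the definition of max_protons from peptide length and
set the amplitude sum equal to that budget, which is the only reading
consistent with zero uptake at t = 0.

The loss is unweighted least squares on the replicate-mean curve
(Levenberg–Marquardt, `scipy.optimize.least_squares`). Exponential-sum
fitting is multi-modal, so the optimizer restarts from every strictly
ordered rate triple on a log-spaced grid over 1e−5–1 s⁻¹ with an even
amplitude split, keeping the best residual sum of squares. The default
grid has 5 points (10 ordered triples): with 4 points the optimizer
missed the global optimum on ~5% of noisy synthetic curves (found RSS
above the RSS at the generating parameters); with 5 points no misses were
observed over 200 curves. An essentially exact fit (RSS below
1e−16·n·max_protons²) ends the multi-start early — degenerate curves with
fewer kinetic phases than model terms would otherwise spend the whole
evaluation budget polishing an unidentifiable direction.

**Slow peptides:** when the replicate-mean uptake at the final timepoint
is below 0.5 D, the fast term is removed (A = 0, k₁ reported as NaN) and
the reduced model fit instead; with that little exchange the fast rate is
pure noise. Fits with fewer than 4 non-zero timepoints are flagged
`fit_ok = False`.

**Parameter uncertainty.** With nine timepoints, per-point SE ≈ 0.06 D
(0.1 D replicate noise, n = 3) and six free parameters, the Cramér–Rao
bound puts sd(A) ≈ 0.4 D and sd(ln k₁) up to ≈ 0.6 depending on the
amplitude pattern: adjacent amplitudes (fast/medium) trade off against
each other, and a fast rate of 0.1 s⁻¹ is constrained only by the first
three non-zero timepoints. Individual fitted parameters at this noise
level therefore carry substantial variance even when the optimizer finds
the global optimum; curve-level quantities (plateau, fractional
differences) are far better determined, which is why the differential
analysis uses the measured curves, not the fit parameters.

## Differential exchange and residue classification

ΔHX(t) = (D₁(t) − D₂(t)) / max_protons on the intersection of the two
states' timepoint grids; uncertainty is the standard error of a
difference of independent means, √(sd₁²/n₁ + sd₂²/n₂)/max_protons.
Peptides enter the comparison only if curated: ≥ 2 replicates at every
observed timepoint in every required state, plus an FD control.

A peptide qualifies for a state when |ΔHX| > threshold (default 0.20,
interpreted as a fraction of max_protons) in that state's favour at
≥ min_timepoints (default 3) timepoints. The comparison is strict but
guarded by a 1e−9 epsilon: planted class shifts can place a plateau
difference exactly on the threshold (e.g. one shifted residue in a
5-amide peptide), where round-off from the affine centroid arithmetic
must not decide the label. Residues inherit the direction of their
qualifying covering peptides; opposing directions give `ambiguous`
(excluded from enrichment denominators — the method refuses to rank
conflicting peptide evidence), covered-but-unqualified residues give
`none`, uncovered residues `no_data`.

Stringency is tunable via (threshold, min_timepoints). The monotone
object under increasing stringency is the per-direction *support* set
(labeled in that direction or ambiguous): supports only shrink. The
labeled sets themselves are not strictly monotone, because an ambiguous
residue legitimately resolves to a single direction once the opposing
peptide stops qualifying.

## Phenotype enrichment

Each residue carries one phenotype class (I_S, I_minus, other) and a
mutation-tolerance flag on `other`. For each rigidity group the table
reports the percentage of member residues per class with explicit
numerators and denominators; residues without a phenotype entry are
excluded from the denominator and counted separately; empty groups report
null percentages rather than dividing by zero. An optional residue-range
filter restricts the tabulation (e.g. to a core domain). No significance
test is attached — the output is the raw contingency table.

## Structural waters

A hydrogen bond is a water-oxygen-to-partner heavy-atom distance ≤ 3.2 Å
where the partner is any N or O atom of a non-water residue (protein or
ligand); no angle term — a deliberate simplification, since the input
ensembles place waters in hydrogen-bonding geometry by construction.
A *structural water* has ≥ 3 distinct such contacts ("three or four"
coordination; a distance-only count can exceed four, so the default
reading is ≥ 3 with an optional literal cap at 4). Waters are retained if
their oxygen lies within a closed 6 Å shell of any ligand atom. Per
residue, the reported probability is the exact count ratio: structures in
which the residue contacts a retained structural water, over ensemble
size. Neighbour search uses a k-d tree; tests pin its output to an
all-pairs brute-force scan. Water sets are matched between ensembles by
greedy nearest-neighbour bipartite matching (pairs accepted in order of
increasing distance, each water used once, tolerance 0.5 Å).

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes:

- **Kinetics:** each eligible residue (position ≥ 3, non-proline) carries
  one of four exchange classes per state — fast (0.1 s⁻¹), medium
  (1e−2 s⁻¹), slow (1e−4 s⁻¹), non (0) — chosen to be separable on the
  nine-timepoint grid (0, 30, 45, 60 s, 5, 25 min, 1, 2, 4 h). Peptide
  uptake is the sum of independent single-exponential saturations (EX2
  behaviour: gradual centroid drift of a single population; EX1 bimodal
  envelopes are deliberately not simulated).
- **State differences:** a configurable fraction of eligible residues
  (default 20%, exact count by construction) differs in class between the
  two designated states. Shifts are planted in contiguous blocks (default
  7 residues) with alternating direction, emulating the rigidification of
  whole secondary-structure elements; contiguity is also what makes
  shifts detectable through peptide-level averaging.
- **Digestion:** cut sites after F/W/Y/L/I, up to 2 missed cleavages
  (overlapping peptides), lengths 4–40.
- **Back-exchange:** one retention factor per peptide from a normal
  (mean 0.70, SD 0.157) truncated to (0, 1] — the distribution's shape
  beyond mean/SD is a modelling choice, not a claim of fidelity. The
  factor multiplies every timepoint and the FD control, so the FD
  correction inverts it exactly. An optional labeling-saturation factor
  (default 1.0) scales experimental rows but not FD controls, emulating
  labeling in diluted (e.g. 90%) D₂O buffer; the default keeps the
  noise-free round trip exact.
- **Noise:** additive Gaussian on each replicate centroid (default
  0.05 Da); control rows are noise-free.
- **Phenotypes:** residues in truth-rigidified regions receive the
  concordant class (I_S for the first state, I_minus for the second) with
  probability `p_concordant`; the remainder are `other` with a random
  tolerance flag. The default planting target is the region-level map
  obtained by applying the classification rule to the exact noise-free
  uptake curves — phenotype concordance is defined over rigidified
  *regions*, and peptide-level measurements resolve regions only to
  peptide footprints, so planting on raw per-residue shifts would make
  full concordance unreachable for any correct classifier.
- **Toy ensembles:** a three-atom ligand at the origin; planted waters on
  a staggered ring 5.2 Å from the ligand axis (inside the 6 Å shell,
  > 4 Å from every ligand atom, pairwise > 6.5 Å apart) each with three
  protein N/O partners at 2.8 Å; decoy waters either in-pocket with only
  two partners or fully coordinated outside the shell. All atoms jitter
  per structure inside a 0.15 Å ball, keeping every water within 0.5 Å of
  itself across structures while never crossing the 3.2 Å contact cutoff.

What the generator does *not* emulate — isotope envelopes, charge states,
chromatography, EX1 bimodality, peptide misidentification, correlated
(systematic) centroid error — bounds what passing tests show: they
validate the analysis logic under the stated statistical model, not
robustness to raw-spectra artefacts.

## Problem sizes and determinism

Default synthetic studies use a 120-residue protein (~75 peptides after
digestion, 2 states × 9 timepoints × 3 replicates), parameter-recovery
experiments use 200 peptides, classification oracle comparisons 50
randomized cases, and water analyses up to 100-structure ensembles —
sizes at which every stage completes in seconds to a couple of minutes on
one CPU while exercising all code paths. All randomness flows through
numpy Generators seeded from a single configured seed; fixed seed ⇒
byte-identical output tables and manifests.

## Known limitations

- Individual kinetic parameters are high-variance at realistic noise (see
  the Cramér–Rao discussion above); consumers should treat A/B/C/NE and
  rates as descriptive summaries, not precise estimates.
- The uncertainty attached to ΔHX is plain independent-means error
  propagation; it is not a calibrated hybrid significance test.
- The ≥ 3-contact water definition with no angle term over-counts
  hydrogen bonds in dense polar environments; results are intended for
  ensembles whose waters were placed in hydrogen-bonding geometry.
- Residue-level rigidity labels inherit peptide footprints; single-residue
  resolution is only as good as the overlap structure of the peptide pool.
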