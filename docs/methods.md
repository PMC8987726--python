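# Methods

This note documents the models, rules and numerical choices behind
camptomine, what the synthetic generators do and do not emulate, and the
known limitations.

## Mass arithmetic and formula prediction

Monoisotopic masses come from the NIST atomic-mass table shipped with
pyteomics; ion *m/z* treats printed ion formulas as formulas *of the ion*
(proton included) and corrects only for the electron mass
(m_e ≈ 0.000549 Da — at *m/z* 161 that is 3.4 ppm, the same order as the
5 ppm precursor tolerance, so it cannot be ignored).

Formula enumeration searches C ≤ 40, H ≤ 60, N ≤ 4, O ≤ 16, P ≤ 2, S ≤ 2
with ring-plus-double-bond equivalents (RDBE) in [0, 25].  These bounds
are a design choice — wide enough to cover every composition the fixture
contains with margin — not a literature constant.  Candidates are found
by depth-first search over the heavy elements with mass pruning; the
hydrogen count is solved arithmetically from the residual mass window, so
the full default space is searched in milliseconds.  Ranking is by |ppm
error| with lexicographic Hill-notation tie-break, making the output a
total, deterministic order.  The test suite checks the enumeration
against an exhaustive vectorized grid over the identical bounds.

## The fragmentation rule engine

**Loss graph.**  Edges connect every ion pair (precursor→fragment and
fragment→fragment) whose mass difference matches a catalog neutral loss.
The catalog holds the 22 losses the annotation rules use (2, 14, 16, 17,
18, 28, 29, 30, 32, 42, 44, 54, 56, 70, 80, 90, 96, 98, 124, 142,
162 Da); nominal 42 is deliberately ambiguous (propene C₃H₆ vs ketene
C₂H₂O) and the closer exact mass wins when attributing an edge.  Each
edge's step index is its BFS distance from the precursor.

**Matching modes.**  `exact_ppm` compares against exact loss masses; an
edge's tolerance is budgeted from *both* peaks
(tol·(m_parent + m_child)·10⁻⁶) because each peak carries its own
measurement error.  The default per-peak tolerance is 15 ppm: under a
5 ppm-per-peak noise model a pairwise difference has σ = √2·5 ppm, so a
10 ppm window would be ≈2σ (≥15 % of true edges lost per edge, fatal for
rules that require two specific losses), whereas 15 ppm gives ≥3σ.
`nominal` mode matches within ±0.5 Da of the integer loss mass and exists
for literature-transcribed spectra whose printed decimals are not
exact-mass reliable (the packaged fixture contains several typographical
outliers of 0.05–0.2 Da; all printed values remain consistent with their
stated formulas at integer-mass level, which the tests verify).

**Group rules.**  Each series needs its diagnostic ion (most intense peak
within tolerance of *m/z* 168, 158 or 144) plus loss evidence organised
as slots: CG = any of −56/−70; PG = both −70 and −96; SG = both −17 and
−70; VG = any of −70/−96; VC = any of −44 / (−56 or −42).  The evidence
score is the number of satisfied slots; labels are ordered by score then
by the fixed order CG > PG > SG > VG > VC, and all labels are retained
(the three series sharing diagnostic 144 legitimately co-label).  Two
asymmetries are intentional: SG demands *both* of its losses because the
−17 (ammonia) loss is what separates the open carboxylic-acid series from
the lactam series at the same diagnostic ion — otherwise a VG spectrum
showing only −70 would tie with SG and lose the fixed-order tie-break;
and VC accepts any slot because hybrid-series glucosides can show the
−44 route without the −56 step.

**Substituent tags** are read off the graph topology: glucosyl count is
the maximum number of 162 Da edges along any single root path (parallel
branches such as −162/−18 vs −18/−162 describe the same sugar and must
not double-count); hydroxy@step1 requires an 18 Da edge leaving the
precursor; methoxy a 32 Da edge within two steps; hydroxylated-core a
peak 16 Da above the diagnostic ion; dehydroxy-variant a VC match through
−42 with no −56 present.

**Novelty** is an identity claim: a classified compound is novel when no
registry compound of the *same* series has a theoretical ion *m/z* within
2 ppm of the observed precursor (isobars of a different series never
block novelty).  The identity tolerance is deliberately stricter than the
5 ppm formula-annotation tolerance — matching to a specific known
compound asserts more than matching to a composition, and well-calibrated
Orbitrap data resolves 2 ppm.  Known limitation: *m/z*-only matching
cannot separate same-series positional isomers of identical formula; on
real data retention time and fragmentation would be needed, and the
packaged fixture resolves such pairs only because observed and
theoretical masses differ measurably.

## Differential statistics

Metabolite intensities are log-transformed (ln(x+1)) before the two-sided
Welch *t*-test and autoscaled before PLS-DA; both transformations follow
common metabolomics practice, and the choice is recorded here because raw
*vs* log testing is a genuine degree of freedom.  PLS-DA is fitted with
scikit-learn's NIPALS-based `PLSRegression` on the centered class
indicator; VIP_j = √(p·Σ_a SS_a w_ja² / Σ_a SS_a) with unit-norm weight
columns, so Σ_j VIP_j² = p holds algebraically and is asserted on every
fit.  Zero-variance features are excluded with VIP 0.  Two presets exist
because two thresholds are in play: discriminating metabolites
(FC ≥ 2 or ≤ 0.5, VIP > 2, P < 0.05) and counted up/down lists
(VIP > 1, P < 0.05, direction by FC sign — no FC magnitude cut).

The gene screen substitutes Welch-on-log₂(x+1) + Benjamini–Hochberg for a
negative-binomial model: the package's contribution is the threshold rule
(|log₂FC| > 0, adjusted P < 0.05) and the downstream mining, and
externally computed per-gene statistics can be supplied through
`screen_from_stats`.  The substitute is *conservative at three
replicates*: for a two-fold effect at 20 % CV the noncentral-*t* power is
0.88 at raw P < 0.05 and lower after adjustment, so recovery benchmarks
use six replicates (power ≈ 0.99 after BH) — a deliberate design bound,
not a tuning artifact.

Enrichment requires the ratio criterion N_MPDM/N_DM > N_MPBM/N_BM and a
one-sided hypergeometric tail P < 0.05 (the standard choice for
membership-based pathway sets; recorded in output metadata).  2^−ΔΔCt is
computed exactly as defined, with the reference gene and calibrator
sample supplied by the caller.

## Co-expression network

Correlation is Pearson on log₂(FPKM+1); the network is unsigned
(a_ij = |cor|^β) at soft power β = 8, with a signed option.  TOM follows
the standard neighborhood-sharing form
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij).

**Module detection** clusters 1−TOM by average linkage, cuts the
dendrogram statically at dissimilarity 0.99, dissolves clusters below 30
genes to grey, and then refines by module eigengene: every gene joins the
module whose eigengene it best correlates with, provided |kME| ≥ 0.75,
iterated to stability (≤3 rounds).  The static height works because
module assembly completes below ≈0.95 while merges among unconnected
genes sit above 0.99 across all tested problem shapes; a merge-height
*quantile* is not usable here — its meaning inverts between matrices that
are mostly modules and matrices that are mostly noise.  The kME pass
matters at small sample counts: with 12 samples, average linkage lets
tens of noise genes attach to genuine modules, and eigengene correlation
is the cheapest consistent repair.  On planted data (2,000 genes × 12
samples, four modules of 60–150 genes at within-module correlation 0.7)
the detector reaches mean adjusted Rand ≈ 0.85 over seeds — which is the
statistical ceiling: an oracle given the true latent drivers scores the
same, because spurious |correlation| at n = 12 among ~1,500 background
genes is irreducible.  Individual seeds fluctuate by ±0.04, so the
recovery benchmark averages three seeded replicates.

**Eigengenes** are the first right singular vector of the module's
gene-standardized expression, unit-norm, sign-oriented so the mean member
correlation is positive.  **Merging** repeatedly fuses the closest module
pair while their eigengene dissimilarity 1−cor is below 0.25, recomputing
eigengenes after every merge; the count strictly decreases, so the loop
terminates.  Module labels follow the community color convention in
size-rank order (turquoise largest), making assignments invariant to gene
input order.

**Candidate mining** restricts to CYP450-annotated genes inside
bait-containing modules and scores each by (number of elicitor treatments
with significant upregulation) + (max |cor| with in-module baits); the
correlation term lies in [0,1], so upregulation dominates and correlation
orders within it, with gene-id tie-break.  No correlation cutoff is
applied by default (`min_bait_cor` is optional and off).

## Synthetic generators

`gen_spectra` builds each spectrum from a series scaffold ion formula,
optional substituent units (glucosyl/hydroxy/methoxy, which extend both
formula and loss chain), the series' diagnostic ion and an admissible
loss chain, then jitters all *m/z* by N(0, ppm_noise) and injects
spurious peaks at the stated per-peak rate.  Spurious peaks are resampled
until they form no catalog-compatible difference (±0.7 Da of any nominal)
with any other ion and avoid all diagnostic windows, so they test peak
clutter, not rule ambiguity.  Not emulated: collision-energy-dependent
intensities, isotope envelopes, co-isolation chimeras — recovery rates
near 1.0 therefore certify the matching logic under mass noise, not
performance on raw instrument data.

`gen_expression` plants co-expression modules as latent per-sample
drivers with gene loadings (default 0.8) plus log₂-normal noise (default
SD 0.25 ≈ 19 % CV, typical of RNA-seq biological replicates), on the
study's CK/MeJa/AgNO₃/PEG × 3 design.  Drivers are drawn mutually
orthogonal across samples (QR decomposition): at a dozen samples two
independent drivers can correlate above 0.6 by chance, which would make
planted modules genuinely inseparable and the benchmark meaningless.
Treatment effects apply per module (whole-pathway induction) or per gene.
Because the driver varies between replicates, it acts as biological
covariance in differential tests — detecting a 1.5-log₂ module induction
at n = 3 through the Welch+BH rule is genuinely hard, which mirrors the
real difficulty of DE testing on strongly co-regulated genes.

`gen_metabolites` plants symmetric log₂ effects in a lognormal
two-group table (default ln-SD 0.3 ≈ 30 % CV, typical of plant
metabolite replicates).

All generators are pure functions of (parameters, seed).

## Problem sizes

The shipped benchmarks run at desk scale by design: 500 simulated spectra
for rule-engine recovery, 2,000 genes × 12 samples for module recovery,
1,000 features for the false-positive-rate check, and a 600-gene demo
pipeline.  Dataset-scale outputs of the original study (tens of
thousands of genes, thousands of metabolites) require the raw archives
and are out of scope; the fixture and property checks are the
reproducible core.
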