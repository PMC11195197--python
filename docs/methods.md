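# Methods

## Element model and matching

Four degenerate element classes are matched exactly, position by
position, over the alphabet {A,C,G,U} with R = {A,G}, Y = {C,U} and
n = any base: `UGURnnAUn` (canonical, 9 nt), `UGURnAUn` (compact,
8 nt), `UGUYRnAUn` and `UGUnRnnAUn` (a\*-like, 9 and 10 nt). Every
class begins with the UGU anchor, which the constructor enforces.
Matching is single-strand, 5′→3′ only: CLIP peak sequences are
transcript-sense, so no reverse-complement search is wanted. Input is
normalized to uppercase RNA (T→U) so DNA-alphabet FASTA works
unchanged. The ambiguous base N never satisfies a literal or R/Y
symbol; letting it satisfy `n` is available but off by default, since
an exact-match search should not award credit for ambiguity. All
overlapping occurrences are reported, and a locus matching two classes
at the same start yields two distinct records — peak-level conclusions
are unaffected by this choice because a peak counts once however many
matches or pairs it holds.

Coordinates are 0-based half-open internally and 1-based inclusive in
every user-facing table (genomics reporting convention; the internal
arithmetic stays simple).

## Adjacency rule

A pair of element matches within one peak qualifies when (a) at least
one member is the canonical class (the other may be any of the four,
including a second canonical element) and (b) the spacing

    gap = start(3′-most) − start(5′-most) − length(5′-most)

lies in [1, 20] inclusive. Orientation does not matter; each unordered
pair is emitted once, oriented by start. Gap ≥ 1 automatically excludes
overlapping or abutting matches.

Two spacing conventions coexist for the *gld-1* FBEa–FBEa\* pair: the
core-element formula above gives 5 nt, while extending both elements 5′
through the affinity-relevant CA flank (11-nt and 12-nt element forms)
gives 3 nt. Both are genuine descriptions of the same arrangement, so
the package exposes the core convention as the scan default and a
`flank_inclusive_gap` utility (default 2-nt 5′ flank) for the other.

## Peak statistics

Group height comparisons use the unpaired two-sided t-test with pooled
variance (df = n_a + n_b − 2), via `scipy.stats.ttest_ind(equal_var=True)`;
a zero-pooled-variance comparison with equal means is defined as
t = 0, p = 1, and with unequal means is rejected as ill-posed.
Partnership-dependence categories (occupancy lower/higher/unchanged in
the Y479A mutant track) are consumed from the input table when present,
because the deposited labels were computed upstream of this package;
for synthetic data a symmetric 1.5-fold rule stands in. No
multiple-testing correction is applied — the analysis reports two
unadjusted tests.

## ITC one-set-of-sites model

The forward model is the standard single-site-class isotherm. With N
sites per cell molecule, association constant K = 1/K_d, and diluted
totals Mt (cell) and Xt (titrant), cumulative heat is

    Q = (N·Mt·ΔH·V0/2)·[A − √(A² − 4·Xt/(N·Mt))],
    A = 1 + Xt/(N·Mt) + 1/(N·K·Mt),

and the per-injection heat differences successive Q with the
half-displaced-volume correction ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V0)(Qᵢ+Qᵢ₋₁)/2.
The discriminant is provably nonnegative for valid inputs; it is
guarded anyway. Dilution follows the perfusion-cell convention
Mt = M0(1 − v/2)/(1 + v/2), Xt = X0·v/(1 + v/2) with v = cumulative
injected volume / V0. This convention is a deliberate, documented
dialect choice: vendor packages use closely related corrections, and
generator and fitter share it exactly, so round-trip recovery is a
clean test of the fitting machinery rather than of dilution bookkeeping.
The tests additionally verify the closed form against an independent
numeric equilibrium solver (brentq on the mass-action equation per
injection), so the isotherm is not self-certifying.

Fitting minimizes squared residuals over (N, log₁₀K_d, ΔH) with
`scipy.optimize.curve_fit`, initialized at N = 1, ΔH from the first
retained injection scaled to per-mole-of-injectant, and K_d at half the
cell concentration. The first injection is discarded by default
(standard practice, syringe-tip diffusion during equilibration);
irrelevant for noise-free data. Standard errors come from the
least-squares covariance and are labeled as such — the vendor fit's
error model is not reproduced. Units: molar and liters internally,
heats in µJ (a kJ/mol-of-injectant dialect is accepted and converted),
energies kJ/mol, default temperature 293.15 K with R = 8.314 J/(mol·K).

## EMSA, FRET, conversions

EMSA curves are fraction of trace RNA bound (5 nM default) vs total
protein, fit with B_max·x/(K_d + x) under the free≈total approximation;
an exact ligand-depletion quadratic solver is available when protein
and RNA concentrations are comparable. A fitted K_d above the highest
tested concentration is flagged and reported as a lower bound
(">5000"-style), since the data cannot localize it. Replicate summaries
report mean ± SEM (sample SD / √n). FRET efficiency is the acceptor
intensity fraction I_668/(I_668 + I_564). ΔG = RT ln K_d and
−TΔS = ΔG − ΔH convert fitted parameters to the thermodynamic columns;
reference-table consistency is asserted to one printed ulp because the
printed ΔG values derive from unrounded fitted K_d's and can disagree
with ΔG recomputed from the rounded K_d by slightly more than half an
ulp (worst observed: 0.07 kJ/mol).

## Expression profiles

Per-gonad line profiles are linearly interpolated onto a common 0–100 µm
grid at 1-µm steps (the original pixel-resolution profiles are an
image-domain object this package does not model; a physical grid is the
stand-in). Genotype means carry pointwise 95% t-intervals with
(n − 1) df; grid points outside a gonad's measured range are excluded
for that gonad. All genotypes are normalized by the wild-type mean's
maximum over the distal 100 µm, making the wild-type maximum exactly
1.0 and the operation idempotent and scale-invariant. Window
comparisons (defaults 0–10, 70–80, 90–100 µm) pool per-gonad window
means and apply the pooled t-test; stars follow the conventional
thresholds (*** < 0.001, ** < 0.01, * < 0.05), with no correction
across windows.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed) and serialize their
ground truth as a JSON sidecar.

**Peaks.** Background sequence is i.i.d. from a chosen composition
(uniform default; a U-rich preset A 0.30 / U 0.40 / C 0.15 / G 0.15
emulates 3′UTR composition). Planted elements are concrete realizations
of their class (degenerate positions uniform over allowed sets),
overwritten — not inserted — so peak length stays controlled; accidental
background matches are allowed and handled by oracle re-scans in tests,
mirroring real sequence statistics. Defaults: 80-nt peaks (a typical
narrow eCLIP peak width), lognormal heights with log-SD 1 and median
chosen so the background mean is ≈736 FPKM (the observed all-peak
average), and a 4-fold multiplicative height effect for planted-pair
peaks (the observed adjacent-vs-all contrast is ≈3.8-fold). Region
labels are drawn 3′UTR-heavy (0.90/0.04/0.05/0.01), reflecting where
FBF occupancy concentrates. The mutant-track heights multiply wild-type
heights by a lognormal factor centered at 0.5 for planted peaks
(partnership-dependent occupancy loss) and at 1 otherwise.

What the generator does **not** emulate: crosslink-induced sequence
biases, read-level peak shapes, transcript structure or shared 3′UTRs
across isoforms, conservation, and the real (unknown) rule behind the
deposited partnership categories. Passing tests therefore demonstrate
correctness of the scanning/statistics machinery under known truth, not
that real eCLIP data will show a particular effect size.

**Measurements.** ITC/EMSA/FRET/profile generators apply additive
Gaussian noise to the corresponding forward model (for ITC, σ is a
fraction of the largest injection heat; EMSA fractions are clipped to
[0, 1]). The germline shape is a logistic rise (amplitude 100 a.u.,
midpoint 50 µm, width 12 µm) plus a distally decaying baseline term
(decay length 25 µm) so a repression-defective mutant elevates the
distal end without moving the proximal plateau.

## Problem sizes

The shipped analyses and tests run at desk scale by design: 200-peak
sets (50 planted), 19-injection titrations, 12-point binding curves,
10 gonads per genotype; simulation-based checks use 100–1,000
repetitions (type-I error, power, false-positive calibration) and
200 seeds for noisy-fit medians. Scanning the full deposited eCLIP
peak set (2,702 peaks) uses the identical code path via `fbekit scan`;
the deposited table must be supplied by the user, as the package
includes no download client.

## Known limitations

- The ITC dilution convention is one documented dialect; comparisons
  with vendor-software fits can differ in the third significant figure.
- Two-site or sequential-site ITC models are out of scope (fitting two
  unconstrained binding events to a uniphasic curve is ill-posed).
- EMSA gel densitometry, image segmentation and peak calling are
  upstream of this package; it consumes intensities, profiles and peak
  sequences as given.
- The same-start multi-class match bookkeeping (retain both records,
  deduplicate at the unordered-pair level) is one of two defensible
  conventions; exact reproduction of published accession-scale counts
  may require toggling it.
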