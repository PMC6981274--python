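# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, in enough detail that a second implementation
could diff its assumptions against ours.

## Units and formats

q in Å⁻¹, lengths in Å, volumes in Å³, time in minutes, rates in min⁻¹.
Profiles are whitespace-delimited text (q, I, σ), `#` comments, the
de-facto `.dat` convention; 2-column files are accepted but any operation
needing uncertainties fails loudly rather than inventing them.  Profiles
recorded in nm⁻¹ must be declared (`--nm-units` rescales q by 0.1); no
unit auto-detection is attempted.  Structures are PDB/mmCIF via gemmi,
with author residue numbering preserved; residue intervals everywhere are
inclusive, 1-based, matching the "residues 3–151" style used in
crystallography.

## Guinier analysis

Weighted linear fit of ln I vs q² with var(ln I) = (σ/I)².  The window is
found self-consistently: fit, recompute the `q·R_g ≤ 1.3` cutoff from the
fitted R_g, refit until stable (1.3 is the community convention for
globular particles).  A second, curvature-based trim then shrinks the
window while a weighted quadratic in q² has a 3σ-significant q⁴ term:
on very precise data a straight line over the full 1.3-window is
measurably biased (an exact sphere gives R_g high by ~1.9%), and the trim
reduces that to ≲0.1% while leaving realistically noisy data untouched
(the curvature is then insignificant and the full window is kept).
Windows shorter than 5 points are an error, as is a non-negative slope
(non-Guinier data).

## Dimensionless Kratky

`y = (qR_g)² I(q)/I(0)` vs `x = qR_g`.  The globular reference point is
the analytic maximum of `x² e^(−x²/3)`: exactly `(√3, 3/e)`.  The curve
is invariant under intensity rescaling by construction.

## Moore P(r)

Representation: `p(r) = r·Σₙ aₙ sin(nπr/d_max)` on [0, d_max], so
p(0) = p(d_max) = 0 by construction.  Forward model per term (closed
form, with a = nπ/d_max):

    I_n(q) = 4π/q · (−1)^(n+1) · sin(q·d_max) · a/(a² − q²),

with the removable singularity at q = a evaluating to 2π·d_max/q.
Conventions, stated because P(r) normalisations differ between programs:
I(0) = 4π∫p dr and R_g² = ∫r²p dr / (2∫p dr), both computed analytically
from the coefficients.

Coefficients come from σ-weighted linear least squares.  The number of
terms (when not fixed by the caller) is chosen by an incremental F-test at
the 1% level: terms are added while each new sine term significantly
reduces the weighted residual, up to the Shannon count ⌈q_max·d_max/π⌉
plus 3, capped at 30.  This is the behaviour that matters in practice:
noisy data keep ~5 terms and a smooth P(r); near-noise-free data keep
enough terms to remove truncation bias.  A fixed Shannon count was tried
first and rejected — it left ~50% negative-area oscillations on noisy
curves and visible truncation error on exact ones.  Ill-conditioned
normal equations (condition number > 10¹²) raise with advice to reduce
terms or d_max.

## d_max estimation

For each candidate on a grid (default 2R_g to 5R_g in 0.1R_g steps) the
Moore fit is scored by

    score = χ²_fit + 10·(negativity fraction) + 10·|R_g(real)/R_g(Guinier) − 1|,

where negativity = ∫|min(p,0)|dr / ∫|p|dr.  The R_g-consistency term is
essential on short q-ranges: a truncated d_max can still reach χ² ≈ 1 at
1% noise, but it visibly compresses the real-space R_g.  Because extra
basis freedom means oversized d_max never fits worse, the selected value
is the *smallest* candidate within `best·1.05 + 0.05` of the best score
(the absolute floor handles noise-free data whose best score is ≈ 0).
On the synthetic open-state curve (true d_max ≈ 120 Å, q_max = 0.11 Å⁻¹,
1% noise) the estimate is stable at ≈ 108 Å across noise seeds — slightly
conservative because the P(r) tail carries little intensity at this
resolution.

## Porod volume

V_p = 2π²I(0)/Q with Q = ∫₀^q_cut q²I dq; the unmeasured [0, q_first]
gap is filled with the fitted Guinier model and the measured part is
integrated trapezoidally on its own grid.  q_cut defaults to 8/R_g
clipped to the measured range; the value used is echoed in every report.
On the one-bead-per-residue toy particles the absolute volume is biased
by the coarse-grained form factors, so only its relative apo-vs-complex
behaviour is meaningful there.

## Debye calculator

I(q) = Σᵢⱼ fᵢfⱼ sinc(q·rᵢⱼ), one bead per residue at its Cα.
`calpha-weighted` (default) assigns f from a built-in table of residue
heavy-atom electron counts (Gly 27 … Trp 88, MSE treated as Met + Se);
`calpha-uniform` sets f = 1 and is used in analytic tests.  The pairwise
sum is exact up to 5,000 beads (a Can1-sized chain is ~630); above that a
0.5 Å distance histogram is used, with per-bin *weighted mean* distances
rather than bin centres (this removes the leading binning bias; the toy
models agree with the exact sum to < 0.5%).  q = 0 is rejected —
I(0) = (Σf)² is available separately.  There is no hydration layer or
excluded-volume term: absolute χ² against real measured curves is
systematically offset relative to full atomic calculators, which is why
the pipeline's conclusions rest on *comparisons* between conformations
against the same data, where the offset cancels.

## Rigid-body sampling

Default decomposition (Can1 numbering): CARF dimer {3–151 ∪ 293–422} held
fixed as the frame of reference, nuclease-like domain {168–276}, nuclease
domain {429–638}; linkers 152–167, 277–292 and the hinge loop 423–428 are
unconstrained tethers.  (The hinge loop overlaps the nominal 426-start of
the nuclease domain; the tether takes precedence so it can flex.)

Restraints: for each group pair at ground-state centre-of-mass separation
d₀, the sampled separation must stay in
[max(0, d₀ − π/q_max), min(d_max, d₀ + π/q_max)] — π/q_max being the
nominal real-space resolution of the measurement, and d_max the P(r)
extent of the *measured* state.  `window:+-5A` / `window:+-10A` modes add
caps on each mobile group's COM displacement from its crystallographic
position, implemented as restraints to fixed anchors; `unconstrained`
drops the caps.  Whether such caps should apply to COM displacement or
all-atom RMSD is ambiguous; COM displacement is used and recorded in the
restraint provenance.

Sampler: every proposal rotates each mobile group about its COM by up to
15° and translates it up to 5 Å (uniform axis/angle, uniform in the
ball); a proposal is accepted iff all COM restraints hold, no inter-group
Cα pair is closer than 3.0 Å, and every linker's flanking-Cα gap stays
below 3.8 Å × (linker length + 1) × stretch factor (default 1.0).  There
is no energy function — all feasible states are equally probable and the
walk explores the feasible region uniformly; every 10th accepted state is
emitted.  Acceptance below 1% over 10⁴ proposals raises with advice to
loosen parameters.  Runs are bit-reproducible from the seed.

## Ensemble fitting

Scale c = Σ(I_e I_c/σ²)/Σ(I_c²/σ²) (the analytic weighted minimiser);
reduced χ² = Σ((I_e − cI_c)/σ)²/(N−1), one fitted scale, no constant
background by default (a flat background flag switches to a 2-parameter
fit normalised by N−2).  Calculated curves are interpolated onto the
experimental grid linearly in q.  Two-state fits enumerate all pairs
exactly and solve non-negative least squares per pair (weights are the
normalised NNLS coefficients; the overall scale is their sum); k > 2
grows greedily from the best pair.  For large pools an optional prefilter
restricts pair enumeration to the top members by single-state χ².

## Structure comparison

Kabsch superposition via SVD with reflection correction; degenerate
(collinear) inputs are rejected.  The sequence-independent correspondence
(standing in for full distance-matrix alignment) seeds from the best
gapless offsets of local Cα-distance profiles (descriptor: distances to
the next 8 residues; top 5 offsets are tried as restarts) and then
alternates Kabsch fitting with re-pairing until stable.  Re-pairing is an
LCS-style dynamic programme: the maximum sequence-order-preserving
matching with all paired distances ≤ d_cut (default 4.0 Å), ties broken
toward smaller summed distance.  Fewer than 10 final pairs raises
(non-homologous folds).  Because this is an approximation of
distance-matrix alignment, matched counts against published
DALI analyses should be read as approximate targets.

## Nicking kinetics

Lane normalisation: fraction cleaved = 1 − [SC/(SC+N+L)]ₜ /
[SC/(SC+N+L)]₀ — the within-lane supercoiled fraction first (cancelling
loading and scanner-gain differences), then normalisation to the
zero-time lane; a direct SC-vs-SC₀ alternative sits behind a flag.
Fit: f(t) = A(1 − e^(−kt)) to replicate means, weights 1/sd² when ≥ 2
replicates with positive spread, else unweighted; f(0) is fixed at 0
because reactions are quenched at the zero-time control (an offset flag
exists).  Initial guesses A₀ = max fraction, k₀ = ln2/t_half; standard
errors from the fit covariance.

## Synthetic data and what it does (not) show

The generator emulates the study conditions at toy scale: three random
dense bead clusters (120 beads uniform in 15 Å spheres, 4 Å clearance,
~360 beads total so the full scenario runs in ~2 minutes) packed along a
line; the open state translates the terminal domain 25 Å outward.  Noise
is multiplicative Gaussian with relative sd `noise_level·(1 + 5q/q_max)`
(default 1%), growing toward high q as in buffer-subtracted SAXS, and σ
is the true per-point sd — so χ² against the generating model calibrates
to ≈ 1 by construction.  Time courses are A(1−e^(−kt)) + N(0, 0.05),
clamped to [0,1], in triplicate, with k = 0.81 min⁻¹ as the reference
rate.  Not modelled: detector artefacts, buffer-subtraction errors,
interparticle interference, hydration effects, intra-domain flexibility.
Passing tests therefore demonstrate the *inference machinery* — that a
hinge opening of this magnitude is detectable and recoverable from data
of this quality — not the photon-level realism of the measurements.

Scenario problem sizes: the sampling scenario uses q up to 0.11 Å⁻¹ so
the π/q_max restraint half-width (28.6 Å) accommodates the 25 Å hinge —
the restraint window must always be wide enough to contain the motion
being tested for, which is a real experimental-design constraint, not a
software one.  Ensembles of 600 conformations suffice for the toy's
3-degree-of-freedom search (the library default of 2430 mirrors the scale
of the original study's ensemble).  Mixture recovery and χ² calibration
use the full 0.008–0.25 Å⁻¹ range, where the two states are well
separated and 0.6/0.4 weights come back within ±0.03 per realisation.

## Known limitations

* Coarse-grained form factors make absolute χ² and Porod volumes against
  real experimental curves systematically offset; conclusions should rest
  on model *comparisons* and relative invariants.
* The d_max estimate is mildly conservative at low resolution (tail mass
  below the noise floor is unrecoverable without priors).
* The sampler has no energetics: ensembles are feasibility samples, not
  Boltzmann ensembles, and loop/linker conformations are never built.
* The Cα correspondence is order-preserving only — circular permutations
  and large insertions that break sequence order are not matched.
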