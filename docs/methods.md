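# Methods

## Difference-function weights

An NDIS experiment prepares chemically identical solutions that differ only
in isotopic labelling and subtracts their diffraction patterns. For a
substituted hydrogen class *sub* the first-order difference is

ΔS(Q) = Σ_X A_X · (S_subX(Q) − 1),  A_X = 2 c_sub c_X (b_D − b_H) b_X,

with the self term A_sub = c_sub² (b_D² − b_H²). Atomic fractions c derive
from the mole ratios of the species and their per-formula-unit atom counts;
scattering lengths are coherent bound values (Sears compilation: H −3.739,
D 6.671, C 6.646, N 9.36, O 5.803, Cl 9.577 fm), packaged as a plain-text
table and overridable by the user. Coefficients are stored in mbarn
(1 fm² = 10 mbarn, fixed). Because each partial enters as S − 1, the
constant subtracted from the weighted sum equals the coefficient sum
exactly, a property tested for random compositions.

Isotope bookkeeping: water hydrogens are exchangeable and take the
solvent's isotope (D in D₂O samples, H in H₂O samples); aromatic ring
hydrogens and the substituted TMA hydrogens are non-exchangeable (ring
hydrogens are always protons; a phenol hydroxyl hydrogen, if present, would
be exchangeable and belong with the water-hydrogen class). All carbons and
all nitrogens are lumped into single classes, matching the resolution of
the measurement: the experiment cannot separate TMA-methyl from ring
carbons in a single difference function.

The second-order difference (D₂O set minus H₂O set) cancels every partner
term except the water-hydrogen one; the implementation verifies the
cancellation to 0.05 mbarn (the printed precision of the weights) and
returns w₂ = 2 c_sub c_HW (b_D − b_H)². For the bundled 2 m TMACl + 2 m
pyridine composition (mole ratios 55.508 : 2 : 2 : 2, identical for both
solvents since the solutions are chemically identical) the full-precision
value is 114.55 mbarn; published renderings round it both to 114.5 and to
114.6, and the package carries the unrounded number in provenance rather
than preferring either rounding. Similarly, the H₂O-set constant is 8.04
from unrounded coefficients (a rounded-coefficient sum gives 8.1);
comparisons use 0.1 mbarn tolerance, the printed precision.

`validate_charge_set` book-keeps electronic-continuum-correction (ECC)
charge scaling: scaling ionic charges by 1/√ε_∞ ≈ 0.75 in water embeds
electronic polarization in a nonpolarizable force field. The checker only
verifies that per-atom partial charges sum to the intended net charge
(e.g. +0.75 for a charge-scaled TMA, +1.00 for the full-charge set).

## RDF estimation and the transform pair

`compute_rdf` histograms minimum-image pair distances in orthorhombic
boxes (triclinic input is rejected) and normalises per frame by the
ideal-gas shell count 4πr²Δr·ρ_partner·N_ref. Pairs sharing a molecule id
are excluded by default: the comparison with experiment targets
intermolecular structure, and intramolecular correlations would otherwise
dominate the small-r region. Defaults: bin width 0.02 Å, r_max = half the
smallest box edge.

`rdf_to_sq` evaluates S(Q) − 1 = 4πρ₀ ∫ r²(g−1) sinc(Qr) w(r) dr as a
rectangle sum over the histogram bins (bin centres as nodes, Δr as cell
width). This makes each histogram bin one quadrature cell, so a single-bin
shell transforms *exactly* to its closed form — the basis of the
delta-shell oracle test — while for smooth profiles the midpoint rule is
second-order accurate (verified against a 10× finer grid to 1e−4). ρ₀ is
the **total** atomic number density, which is the convention under which
the Faber–Ziman partials combine with the prefactors above. The window w
is 1 (default) or the Lorch taper sin(πr/r_max)/(πr/r_max); no window is
applied by default because the appropriate choice depends on the noise and
truncation of the input, and the taper's damping of termination ripple is
covered by a dedicated test. Q grid default 0.05–25 Å⁻¹, step 0.025 Å⁻¹;
Q = 0 is excluded unless explicitly requested (the sinc limit handles it),
and sin(Qr)/(Qr) is evaluated through numpy's sinc, which is series-safe
near zero. A g(r) tail deviating from 1 by more than 5% over the last 10%
of the r range triggers a warning (truncation artefacts); a Q range ending
below 25 Å⁻¹ in the inverse transform flags the result metadata.

`sq_to_rdf` is the inverse Fourier–Bessel transform, provided for
round-trip verification; smooth profiles round-trip within 2% pointwise
away from r < 1 Å on the default grids.

## Difference assembly and the flatness check

`assemble_difference` is linear in the partials; `second_order` subtracts
the two first-order functions and also returns the extracted
S_HW = ΔΔS/w₂ + 1. On partials built from a single trajectory pushed
through both weight sets, the extraction reproduces the input S_HW to
machine precision — the algebraic content of the experimental
internal-consistency argument. `flatness_check` reports the mean, an
ordinary-least-squares slope (the simplest defensible trend detector for a
background check), and the rms deviation about the mean over Q ≥ Q_min
(default 0.5 Å⁻¹, reflecting that the lowest Q values are hard to measure);
"pass" means rms below a user threshold.

## Gaussian-process comparison

Kernel: k(q,q′) = s²·exp(−(q−q′)²/2ℓ²) + σ_n²·δ, hyperparameters optimised
in log space within [1e−6, 1e3] by scikit-learn's marginal-likelihood
optimiser with random restarts (default 10, default seed 20250627; fits are
deterministic given the seed). A jitter of 1e−10 is added to the kernel
diagonal for factorisation stability. The fitted σ_n estimates the white
noise on the data; on planted data (smooth curve + N(0, 0.037²), n = 800)
the median estimate over 20 seeds recovers the planted value within a few
percent. The noise bounds are exposed so that pinning σ_n² near zero
demonstrates the interpolation limit of GP conditioning. Predictions are
cross-checked in the tests against a dense-matrix evaluation of the
standard conditioning formulas, independent of scikit-learn.

Model scoring interpolates each model curve onto the training grid and
reports residuals against the GP mean, the fraction of points outside
mean ± 2σ_n (the band multiplicity is configurable; published uncertainty
bands do not always state theirs), and rms deviations split at
Q = 2.5 Å⁻¹ — the region below that split is where long-range density
correlations make force-field models differ most.

## Density maps

For every frame and every solute copy, the ring heavy atoms (made whole
across periodic boundaries) are superposed onto a canonical template —
ring plane = xy, heteroatom direction = +x, ring normal = +z — by
least-squares rigid-body fitting (Kabsch via scipy's rotation alignment;
proper rotations only, degenerate/collinear templates rejected). Target
atoms are mapped into that frame with the minimum-image convention relative
to the solute centroid and binned on a Cartesian grid, default 0.5 Å
spacing over ±8 Å: coarse enough for desk-scale memory, fine enough to
resolve the 3–5 Å cation–π contact region. Voxel values are normalised by
(voxel volume × accumulations × bulk density), with the bulk density of the
target class computed per frame as total count / box volume and averaged;
values are then multiples of bulk density, the scale on which such maps
are contoured (levels around 2–3× bulk). Optional mirror symmetrisation
across the ring plane and the heteroatom plane is off by default and
recorded in metadata. Because the heteroatom fixes the in-plane
orientation, the map distinguishes *face-on* binding (density on the
normal) from the *headphone* motif (density wrapping the heteroatom
in-plane).

`geometry_report` summarises the super-level set at a chosen iso-level:
voxel count, connected components (scipy.ndimage labelling), peak and
centroid positions, and the **axial fraction** — the share of super-level
voxels inside a 30° double cone about the ring normal. Because any voxel
whose count fluctuates above the iso-level joins the super-level set, the
report is only meaningful once the expected bulk count per voxel is well
above the Poisson tail at the chosen level; the planted-data tests
accumulate ~16 000 solute frames to reach that regime. There, face-on
generators give axial fractions above 0.9 with the peak on the axis, and
in-plane ("headphone") generators give fractions near zero.
Note that when the mapped class is the cation's methyl carbons and the
planted distance refers to the cation centre, the density maximum sits on
the axis within the methyl-carbon shell (planted distance ± the 1.5 Å
N–C bond length) rather than exactly at the planted distance.

Maps are written as OpenDX scalar fields and Gaussian cube files (plain
text, z-fastest ordering; cube lengths in bohr), both readable by standard
molecular viewers.

## Synthetic data

Generators are deterministic given their seed (one generator per artifact,
no global state) and attach their ground truth to the output. The planted
complex places rigid idealised molecules — a tetrahedral 4-methyl cation
(N + 4 C + 12 H), a planar hexagonal ring with one heteroatom and five
H-bearing carbons, 3-site waters, monatomic chlorides — with no force
field: geometry and bookkeeping, not energetics, are what the downstream
stages test. Each ring hosts a cation with the planted probability
(default 0.8), at the planted distance (default 4 Å) along the normal
(face-on) or in-plane at ±60° from the heteroatom direction (headphone),
with 0.15 Å Gaussian jitter; remaining cations, waters and chlorides are
uniform. Bound cations are oriented with one methyl face toward the ring
centre (the cation-pi contact orientation) with a random spin about the
contact axis; unbound cations are oriented uniformly at random. Default
stoichiometry keeps the 2-molal solution ratio of about
27.75 waters per cation at desk scale (10 cations / 10 rings / 278 waters
in a 21 Å box); analyses that do not involve water (e.g. density-map
statistics) use fewer waters and more frames to buy accumulation
statistics at fixed runtime. Because the generator has no repulsion or
hydration structure, its RDFs lack excluded-volume holes and solvation
shells, and bound cations deplete the far field slightly; passing tests
therefore certify the estimators and the algebra, not the realism of any
force field.

The noisy "experiment" generator adds white noise of known σ (default
0.037, a realistic noise floor for a reactor-source difference
measurement) to a smooth damped-oscillation curve on n = 800 points over
Q ∈ [0.5, 20] Å⁻¹.

## Problem sizes and numerical choices

Test and acceptance runs use reduced problem sizes chosen to keep the full
suite in the tens of minutes on one core: RDF checks at N ≈ 1000 over tens
of frames, density maps from ~1600 planted frames (16 000 accumulations,
enough to put the bulk Poisson tail well below the 2.3× iso-level), GP
recovery at n = 800 with 1 optimiser restart
(the default of 10 restarts is for production fits of real data).
Tolerances follow the source of error: printed-precision 0.1 mbarn for
weights, 1e−10 for algebraic identities, oracle-difference bounds (1e−4
to 1e−6) for quadrature, and sampling-statistics bands for stochastic
checks.

## Known limitations

- No instrument-side corrections (multiple scattering, absorption,
  vanadium normalisation, Placzek backgrounds): the package only *detects*
  residual background via the flatness check, as the experimental
  consistency argument does.
- Orthorhombic boxes only; no triclinic minimum image.
- The RDF estimator excludes intramolecular pairs by convention; published
  trajectory analyses do not always state theirs, so comparisons should
  check this flag.
- No MD engine, force-field evaluation, or isosurface rendering; density
  maps are exported for standard viewers instead.
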