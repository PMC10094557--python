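# Methods

`mrkit` solves the molecular-replacement (MR) problem: given measured
diffraction amplitudes |F(hkl)|, the unit cell and space group, the target
sequence(s), and the coordinates of a homologous search model, find the
rotations and fractional translations that place one or more copies of the
model in the target asymmetric unit (asu) so that the model's calculated
amplitudes reproduce the observations.

## Normalization and the working reflection set

Amplitudes are reduced to one asu representative per reflection class and
converted to normalized intensities E² = F² / (ε·⟨F²/ε⟩_shell) in
equal-population resolution shells (default 20, floor 1).  ε is the
symmetry-enhancement factor of the reflection class; without it, the zone
reflections common to the data and to *any* model orientation generate a
spurious baseline correlation in the rotation scores.

The working set drops reflections outside 7–2.5 Å (the low-resolution
cutoff is lifted when the model/target sequence identity SI < 0.5, because
poor models are informative mostly at low resolution), and |E| outliers
(|E| > 3.5 or |E| < 0.05).  The |E| < 0.05 floor is lifted for the
pseudo-translation score, which needs the weak class.

## Composition (NCHT / NMOD)

The number of chain sets per asu is the n minimizing |VOLAT(n) − T| with
VOLAT(n) = V_asu/(n·atoms) and a hard floor of 22 Å³/atom; T = 38 Å³
(protein), 34.5 (DNA), 44 (RNA).  A Matthews-style alternative picks the n
with chain volume fraction closest to 0.50, using a mass-dependent density
(1.50 g/cm³ at ≤7 kDa, 1.41 at ≥30 kDa, linear between; 1.35 when the mass
is unknown).  The copy count NMOD snaps NCHT to multiples of the model's
identical-chain count (ties round up) and disregards target chains shorter
than half the longest when the model covers only the long chain.

Recovery of the generating n from a synthetic composition is only
guaranteed near the target: for assemblies of n ≥ 3 the n→n+1 decision
boundary (e.g. 42.2 Å³ for n = 4 against protein's 38) lies within ±6 Å³
of the target, so ambiguity there is intrinsic to the rule, not an
implementation artifact.  The recovery suite therefore draws monomeric and
dimeric contents.

## Anisotropy correction

About 30 low-resolution "polar" directions (coprime indices, |h|≤2, unique
up to inversion and point symmetry, the three reciprocal axes always
included) are each assigned cone shells of equal population; the shell
means ⟨E²⟩(α) are fitted with M = A·exp(G cos 2α) by count-weighted least
squares on ln⟨E²⟩.  A positive G means slower intensity falloff along that
direction.  If max |G| > 0.2 the data are corrected by a crystal-system
ellipsoid O(hkl): axes are fixed by symmetry (none for cubic; a*/[1-20]/c*
shared pairs for trigonal-hexagonal and tetragonal; the reciprocal axes
for orthorhombic; [010] plus the best and most-perpendicular [h0l] pair
for monoclinic; three mutually near-perpendicular best-G directions for
triclinic, tolerance 15° widening to 30°).

Two implementation choices matter:

* the ellipsoid is evaluated on the log scale, ln O = Σ ln⟨E²⟩ᵢ cos²θᵢ.
  To first order this equals the plain weighted sum of ⟨E²⟩ values, but it
  is the form consistent with the exponential directional law and leaves
  no quartic residual for a Gaussian (overall anisotropic B) falloff;
* the axis ⟨E²⟩ values start from A·e^G at α = 0 and are refined by
  weighted least squares over all fitted directions, which is markedly less
  noisy than reading off two or three axes.

Corrected values E² ← E²/O are re-normalized within shells.  The ellipsoid
is a second-order directional model: very strong anisotropy (|G| ≳ 0.5)
leaves a percent-level directional residual that no axis-value choice can
remove.  The per-direction G estimate also carries a noise floor of
roughly N_shell^(-1/2); flattening below |G| = 0.05 needs a few thousand
reflections per cone shell set.

## Rotation search

The model, centered at its centroid, is Fourier-transformed once on the
reciprocal grid of a P1 box with edge four times the maximum molecular
dimension (floored at 10 Å for degenerate models).  Scattering factors are
single-Gaussian: f(s) = Z·exp(−b·s²/4) with a common width b = 12 Å² —
MR scoring ranks correlations, which are insensitive to the absolute
falloff shape.  Hydrogens are excluded.  Real and imaginary parts are
interpolated separately (cubic spline for accuracy-critical calls, a
trilinear fast path for bulk grid scoring); interpolating the modulus
directly is wrong near its zero-crossing cusps, where the error is
independent of grid density.

Orientations are sampled on a z-y-z Euler lattice of spacing dθ (default
5°, 10° in the test suite), either primitive or body-centered ("bcc":
the same lattice offset by (dθ/2,)³, doubling the points and reducing the
covering radius from √3/2·dθ ≈ 0.87 dθ to √5/4·dθ ≈ 0.56 dθ).  The grid is
reduced to one representative per orientation class under the crystal's
proper rotations via quaternion canonicalization.  Each orientation is
scored by RFOM: the Pearson correlation between corrected E² and the
per-reflection expectation |ΣF_located|² + Σ_s |F_ps|² (the incoherent
symmetry sum of interpolated transform amplitudes, divided by ε to match
the observed normalization).  The incoherent-sum expectation matrix does
not depend on located copies, so it is computed once per model and reused
across copies and carried solutions.  The 200 best orientations after
clustering (rotation-angle metric, radius dθ) proceed to translation.

## Translation search

For a fixed orientation, the product function

    S(t) = Σ_h w_h |Σ_s C_s(h) exp(2πi (R_sᵀh)·t)|²

is expanded into cross terms C_s C_s'* attached to index differences
h(R_s − R_s') and evaluated on the whole fractional-translation grid
(spacing d_min/4) by one inverse FFT; on-grid evaluation is exact because
index differences wrap modulo the grid.  The weights are w_h = E²_h
divided by the translation-averaged model intensity Σ_s |C_s(h)|² (+
|F_located|²); without that normalizer a few giant low-resolution model
terms dominate the sum and the argmax lands ångströms from the truth even
on exact data.  Up to two peaks survive per orientation after clustering
(1.5 grid steps, counting allowed-origin-shift copies as duplicates); in
polar space groups the free translation components of the first copy are
pinned to zero.

Candidates are ranked by TFOM = corr(|F|, |ΣF_placed|).  When a
sharpened-Patterson scan (E²−1 synthesis; non-origin peak above 20% of the
E² origin) flags pseudo-translational symmetry, the ranking switches to
the weak-reflection score 1 − ⟨|E_p|²⟩ over reflections with |E| < 0.3
(minimum 30, else fall back to the correlation).

## Refinement, multi-copy assembly, selection

The best candidates (10 per copy) are refined by Nelder–Mead downhill
simplex over the six pose parameters, maximizing TFOM; a refined pose is
never accepted if it scores below its start.  Solutions are scored by the
crystallographic R (scale k = Σ|Fo|/Σ|Fc|; this sum-matching convention is
what gives the classic R ≈ 0.586 between unrelated acentric structures)
and by CLASH, the fraction of reference atoms (Cα, or P/backbone-C/base-N
for nucleic acids) within 3.0 Å of a reference atom of another copy or any
symmetry mate.

The (n+1)th copy is accepted by three rules in order: R(n) − R(n+1) > 0.02
accepts without a clash check; CLASH > 0.35 or R(n+1) − R(n) > 0.15
rejects; otherwise accept iff (R(n)−R(n+1))/max(CLASH, 0.05) > 0.10.
Up to five solutions are carried between copies; before each new copy
search (and once for the final best solution) every placed pose is
re-refined against the others, approximating the loss of rigidity a
restrained-refinement stage would provide.  The search stops early when
the best TFOM of the next copy falls below the previous copy's, and the
final ranking is by minimum R.

At SI < 0.4 the search model is "alaninized" up front: the 80% of residues
with the highest mean B lose side-chain atoms beyond Cβ.  If the final R
still exceeds 0.50 at SI < 0.4, the run restarts once with a fully
alaninized model.  The expected coordinate error driving this strategy is
rmsd = 0.40·exp(1.87·(1 − SI)) Å — 1.23 Å at SI = 0.4.

No bulk-solvent model is applied, so absolute R values on real data will
run higher than on the synthetic fixtures.

## Synthetic fixtures

Test crystals are generated, not downloaded.  The protein model is a
helix-turn-helix: two ideal α-helical segments (rise 1.5 Å, twist
100°/residue, radius 2.3 Å, consecutive Cα–Cα = 3.83 Å) joined by a rigid
50° bend at the middle Cα, with Cβ/Cγ/Cδ stubs fanned at
residue-dependent azimuths and a B ladder from 10 to 30 Å².  A straight
ideal helix is deliberately avoided: its rotational self-similarity about
the helix axis makes orientations nearly degenerate for any rotation
function, which is a property of the object, not of the method.  The
nucleic-acid model is a single helical strand carrying P, primed-carbon
backbone atoms and base nitrogens so the clash rules are exercised.

The cell is shaped like the padded molecule (6 Å solvent margin) and
scaled so the volume per non-H atom at the true copy count sits at the
moltype target — except in P1 with one copy, where the minimal packable
cell already exceeds the target; composition is intrinsically
over-estimated there and the tests supply the copy count explicitly.
Copies are placed at random non-clashing poses (first copy pinned on polar
axes); amplitudes are |F| of the placed copies, optionally damped by
exp(−(β₁h²+β₂k²+β₃l²)), perturbed multiplicatively by Gaussian noise, and
the search model gets per-atom Gaussian coordinate noise (0.15 Å in the
recovery suite — small against the 0.6 Å accuracy tolerance but large
against the exact-data limit).  Everything derives from one integer seed.

What the fixtures do **not** emulate: side-chain rotamers, solvent
scattering, realistic B-factor distributions, measurement-error models
beyond fractional Gaussian noise, twinning, and realistic crystal packing
density in P1.  Passing the recovery suite shows the search machinery is
internally consistent at fixture scale; it does not bound performance on
real data with low sequence identity or many copies.

## Problem sizes and numerical choices

The test and acceptance runs use 10-residue polymers (~70 atoms), cells of
20–35 Å, ~300–700 unique reflections to 2.5 Å, and dθ = 10°; a pose
recovery run takes seconds to ~1.5 min per fixture on one core.  Ties in
candidate ranking break toward earlier (stable) order; the VOLAT tie
breaks toward smaller n; Euler wraparound is handled by comparing
orientations in the rotation-angle metric, never by Euler differences.
All randomness flows from a single integer seed; identical inputs give
bit-identical solution tables.
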