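# Methods

## Model

A weakly aligned molecule's residual dipolar couplings are governed by the
Saupe order matrix **S**: for a unit internuclear vector **b**,
D = **b**ᵀ**S b**, with **S** symmetric and traceless (5 degrees of
freedom). All couplings are expressed on the ¹⁵N–¹H normalized scale: a raw
coupling of type pq is multiplied by
W_pq = (|γ_N γ_H|/r_NH³)/(|γ_p γ_q|/r_pq³), computed from magnetogyric
ratios (γ_H = 26.752, γ_C = 6.728, γ_N = −2.713, ×10⁷ rad s⁻¹ T⁻¹) and
fixed effective distances (N–H 1.02 Å, Cα–Hα 1.09 Å, C′–N 1.329 Å,
Cα–C′ 1.525 Å, and effective two-bond distances C′–HN 2.05 Å,
C′–Hα 2.13 Å). The Cα–C′ factor comes out ≈ 5.4, i.e. that coupling's
dipolar constant is about five times smaller than the amide pair's.
Normalization with unit weights assumes measurement errors that scale with
the inverse dipolar constants; explicit per-record errors override this
with inverse-variance weights.

### Tensor conventions

Principal values are ordered by magnitude, |S_zz| ≥ |S_yy| ≥ |S_xx|;
Da = S_zz/2 (signed, Hz), so a bond along the principal z axis predicts
D = 2Da; Rh = (2/3)(S_xx − S_yy)/S_zz ∈ [0, 2/3]. The generalized
alignment strength G = {Da²(4 + 3Rh²)/5}^½ is rotation invariant and
satisfies G = ‖S‖_F/√7.5 — the closed form used as an independent oracle in
the tests. Principal-axis orientations are reported as z-y-z Euler angles.
Tensor averaging is element-wise on the 3×3 matrices (equivalently on the
5-vectors), never on (Da, Rh, angles).

### Fitting

The linear system D_k = **b**ₖᵀ**S b**ₖ is solved by SVD of the N×5 design
matrix with rows [b_z²−b_x², b_y²−b_x², 2b_xb_y, 2b_xb_z, 2b_yb_z] for
(S_zz, S_yy, S_xy, S_xz, S_yz); S_xx follows from the trace. Singular
values below 10⁻⁸ of the largest mark a rank-deficient design; the
minimum-norm solution is returned with a warning and the condition number
is reported. A fit needs ≥ 5 couplings; jackknifing needs ≥ 6; screening
requires ≥ 8 by default for robustness.

### Quality factors and jackknife uncertainties

Q = rms(D_pred − D_meas)/√{2Da²(4 + 3Rh²)/5} (the "powder" rms of
**b**ᵀ**S b** over isotropic **b**). The jackknifed
Q_jk = √{Σᵢ (Dᵢ_pred(−i) − Dᵢ_meas)² / (N·2·D_a,i²(4+3Rhᵢ²)/5)} evaluates
each omitted coupling against the fit that excluded it, using that fit's
(D_a,i, Rhᵢ); with this shared normalization Q_jk → Q for large N while
correctly penalizing overfitting at small N (empirically Q_jk ≥ Q for
N ≲ 25). The variant without the factor 2 in the denominator
(= √2 × Q_jk) is also reported as `Q_jk_norm1`, since both normalization
conventions circulate; published comparisons should state which is used.

From the N leave-one-out tensors Sᵢ and strengths Gᵢ:
ε(S) = √N·RMS{1 − P(Sᵢ, ⟨S⟩)} and ε(G) = √N·RMS(Gᵢ − ⟨G⟩)/⟨G⟩, with
⟨S⟩ the element-wise mean and ⟨G⟩ the mean of the Gᵢ (the all-data fit's G
is reported separately). Synthetic ensembles confirm the expected
≈ 1/√(N−5) decay of ε(G) with the number of couplings. Residue-level
jackknifing removes every coupling with an atom in a given residue's amide
plane (N-terminal plane of residue i: C′, O of i−1 plus N, H, Cα of i;
C-terminal plane defined symmetrically); this is the primitive behind
terminal culling.

## Idealized helices

Helices are built by internal-coordinate chain extension with exact
repetition of (φ, ψ, ω). Defaults: φ = −65°, ψ = −40°, ω = 180°, with
Engh–Huber-style bond lengths/angles (N–Cα 1.458, Cα–C′ 1.525, C′–N 1.329,
C′=O 1.231 Å; N–Cα–C′ 111.2°, Cα–C′–N 116.2°, C′–N–Cα 121.7°,
Cα–C′=O 120.8°). These are the canonical idealized-helix torsions, chosen
from within the canonical helical range (φ = −63 ± 6°, ψ = −42 ± 6°)
because they reproduce the standard benchmarks of α-helical geometry:
3.63 residues/turn, 1.54 Å rise/residue, and a mean N–H-to-axis angle of
15.6° (the accepted value is 15.8°, which anchors the sinusoidal
"dipolar wave" of sequential amide RDCs with ~3.6-residue period). The
parameter set is a plain dataclass/config block so an alternative ideal
geometry can be dropped in. Amide protons are placed in the
C′(i−1)–N–Cα plane on the external bisector at 1.02 Å; Hα on the
tetrahedral direction out of the N–Cα–C′ plane. The first residue of a
built helix has no amide H (no preceding carbonyl); for that reason the
ideal reference fitted to a segment is built with one extra N-terminal
residue, so the segment's first amide plane exists in the model.

Superposition onto the experimental backbone uses the least-squares
(Kabsch) rotation with det(R) = +1 enforced (no reflections), over the
segment's N, Cα, C′ atoms. The helix axis is the screw axis of the optimal
transform mapping Cα(i..last−1) onto Cα(i+1..last), oriented N→C.

## Screening and culling

Segments are split at prolines (a helix ends at the residue preceding a
Pro and restarts after it), fragments shorter than 5 residues or with
fewer than 8 attributable couplings are dropped with logged reasons.
Attribution: both atoms inside the segment, plus the sequential couplings
reaching back to the preceding carbonyl (the first residue's amide plane).
For each terminus independently, the fit is redone without that terminal
amide plane's couplings; the residue is culled when the relative Q_jk drop
is ≥ 20% (configurable; a single pass per terminus, so at most one residue
is removed from each end — iterative erosion is deliberately not
performed). A baseline Q_jk below 10⁻⁸ never culls.

## Diagnostics

**Sampling parameter Ξ.** Each unit bond vector probes one direction in the
5-dimensional space of tensor components, f(**b**) ∝ vec₅(**bb**ᵀ − I/3),
‖f‖ = 1. With M₅ = (1/N)Σ f f ᵀ, the package uses the D-optimality-style
normalized generalized variance

  Ξ = 1 − [5⁵ det(M₅)]^{1/5},

which is 0 for isotropic sampling (M₅ = I/5; e.g. icosahedron vertices, a
spherical 5-design), 1 when the design is singular (collinear vectors),
and is invariant under global rotations and per-vector sign flips. Since
the originally cited definition is not reproduced in the sources available
to this package, the implementation is calibrated against the published
benchmark values instead: helix N–H vectors alone give Ξ = 0.845
(benchmark ≈ 0.83, poor sampling), while the combined
{Cα–C′, N–C′, Cα–Hα, C′–HN, C′–Hα} set gives Ξ = 0.07 (benchmark ≤ 0.17,
excellent sampling); simpler second-moment-based candidates (0.75 / 0.89
for the N–H set) fail these benchmarks and were rejected.

**Histogram analysis.** For near-uniform vector sampling the normalized-RDC
distribution approaches the powder pattern with extrema
(2Da, −Da(1 ± (3/2)Rh)). The estimator reads D_zz as the extremum of
larger magnitude, D_yy as the opposite extremum, and closes D_xx by
tracelessness (the histogram mode is a noisier estimate of D_xx); then
Da = D_zz/2, Rh = (2/3)(D_xx − D_yy)/D_zz, clipped to [0, 2/3]. Expected
histograms sample D(θ, φ) with seeded, area-preserving (cos θ, φ) draws.
Extremum reading from finite samples is slightly biased inward; at ~10⁴
values the bias is within one bin.

**Dipolar wave.** D(i) = m + A·cos(2πi/T + φ) is fitted by a coarse grid
over T (2.5–6.0 residues, step 0.02, linear solve for the rest) followed by
bounded nonlinear refinement. Near-constant input (spread < 10⁻⁹ of scale)
is flagged `flat` with no period.

**Random-pair P.** Tensor pairs with Haar-random orientations and Rh
uniform on [0, 2/3] yield the reference distribution of P; the |P|
histogram on [0, 1] is reported (P is signed elsewhere), and its density
decreases roughly like cos(2α/π).

## Domain reorientation

`reorient_domain` rotates a residue range so the target tensor's principal
axes (matched to the reference's by eigenvalue-magnitude rank) coincide
with the reference's. The four proper sign combinations of paired axes all
produce the same rotated tensor, so the trial with the smallest rotation
angle is applied (about the selection's centroid). Near-axial tensors
(Rh < 0.02) are rejected — their transverse axes are undefined. A P near 1
after reorientation shows compatibility with *some* static relative
orientation, not the absence of interdomain motion; a low P before
reorientation establishes that the reference's relative domain orientation
is wrong on average.

## Synthetic data

The generator emulates the experimental setting: couplings are computed as
**b**ᵀ**S b** from helix coordinates, de-normalized to each type's raw
scale, and perturbed with Gaussian noise of sigma (NH-scale σ)/W_pq — so
the normalized data have homogeneous errors, matching the equal-weight
convention. Default two-domain fixture: two bundles of two helices
(12 + 10 residues each), per-domain tensors Da = 10 Hz, Rh = 0.3 rotated
60° apart (equal G ≈ 9.24 Hz — the flexibly-linked trap where equal
strength masquerades as rigidity), NH-scale noise 0.3 Hz (~1.5% of 2Da,
typical of good measurements), five coupling types per residue. Optional
controls: coordinate jitter (Å), and per-residue "outlier" rotations of an
amide plane's vectors to emulate a locally non-helical terminus for
culling tests. What the generator does *not* emulate: anisotropic
coordinate errors, internal dynamics (axially-symmetric order-parameter
scaling), type-specific systematic errors, or assignment mistakes — so
passing tests demonstrate correctness of the estimators under the stated
noise model, not robustness to every pathology of real data.

## Problem sizes and numerical choices

Test ensembles use 10–500 replicates with 8–200 couplings per fit; the
benchmark script uses an 18-residue helix (5 turns). Tensor validation
tolerances: symmetry/trace at 1e-9 relative (inputs are exactly
symmetrized/detraced after validation); vec₅ round trips are exact to
1e-12. The SVD rank cutoff is 1e-8 relative. All random draws flow from
explicit integer seeds through `numpy.random.default_rng`.

## Known limitations

- No multi-alignment (two-media) simultaneous fitting, no tensor
  prediction from molecular shape or paramagnetic models.
- Only α-helices; β-strands/loops and nucleic acids are out of scope, as
  is chemical-shift secondary-structure prediction (segments are input).
- Insertion-coded residues are rejected rather than handled; the first
  altloc is kept silently.
- The ideal-coordinate mode inherits the idealized geometry's ~0.2°-level
  departures from any specific published ideal parameter set; supply a
  custom `IdealHelixParams` to match another convention exactly.
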