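# helixfit

Alignment-tensor analysis of protein α-helices from residual dipolar
couplings (RDCs).

RDCs measured under weak molecular alignment report on the orientation of
internuclear vectors relative to the molecule's alignment frame: for a unit
bond vector **b** and Saupe order matrix **S** (3×3, symmetric, traceless),
the normalized coupling is D = **b**ᵀ**S b**. Because hydrogen-bonded
α-helices are geometrically highly regular, the backbone RDCs of a single
helix — ¹D_NH, ¹D_CαHα, ¹D_C′N, ¹D_CαC′ and the two-bond ²D_C′HN / ²D_C′Hα —
suffice to determine a well-conditioned local alignment tensor, even before a
structure is solved. Comparing per-helix tensors then distinguishes a single
well-ordered globular unit (all tensors agree) from flexibly linked domains
(tensors differ in orientation and/or magnitude).

`helixfit` implements this workflow:

- **Idealized helix geometry** — poly-alanine-like helices built from
  canonical torsions (φ = −65°, ψ = −40°) with standard bond geometry and
  in-plane amide protons, best-fit superimposed on the experimental backbone
  (N, Cα, C′), or direct use of the experimental (X-ray) coordinates.
- **SVD tensor fitting** — least-squares solution of D = **b**ᵀ**S b** over
  the five free tensor components, with all coupling types normalized to the
  ¹⁵N–¹H interaction strength via dipolar-constant ratios (γₐγ_b/r³), so
  e.g. ¹D_CαC′ is scaled up ~5× and all types carry equal weight (per-record
  errors, when given, supply inverse-variance weights). Exposed as
  scikit-learn-style estimators (`SaupeTensorFit`, `JackknifeSaupeFit`).
- **Jackknife statistics** — N leave-one-out refits give the jackknifed
  quality factor Q_jk (each omitted coupling predicted by the fit that
  excluded it; immune to the small-N optimism of the plain Q), the
  orientation/rhombicity spread ε(S) = √N·RMS{1 − P(Sᵢ, ⟨S⟩)}, and the
  fractional strength spread ε(G) = √N·RMS(Gᵢ − ⟨G⟩)/⟨G⟩, where
  G = {Da²(4 + 3Rh²)/5}^½ is the rotation-invariant alignment strength.
- **Screening and culling** — helix segments are split at prolines, dropped
  below 5 residues or 8 couplings, and terminal amide planes whose removal
  improves Q_jk by a configurable relative margin (default 20%) are culled.
- **Cross-helix comparison** — the normalized scalar product
  P(Sᵢ, Sⱼ) of the five-component tensor vectors
  [S_zz, (S_xx−S_yy)/√3, 2S_xy/√3, 2S_xz/√3, 2S_yz/√3] quantifies agreement
  between helices and against the pooled global tensor; a domain can be
  reoriented so two tensors' principal axes coincide.
- **Diagnostics** — the generalized sampling parameter Ξ of a bond-vector
  set (0 = optimal orientational sampling, 1 = collinear), powder-style
  histogram estimation of (Da, Rh), expected histograms for uniform
  orientations, dipolar-wave fitting, and the Monte-Carlo distribution of
  P for random tensor pairs.
- **Synthetic fixtures** — structures and RDC tables generated from known
  tensors (including a flexibly-linked two-domain scenario) so the entire
  pipeline is testable without any downloads.

## Worked example

Generate a two-domain synthetic data set (two helix bundles, equal alignment
strength G ≈ 9.24 Hz but tensors rotated 60° apart — the classic trap where
equal G does **not** imply rigidity) and analyse it:

```sh
$ helixfit simulate --seed 11 --noise 0.3
wrote synthetic.pdb/.tab/.segments/.truth.json

$ helixfit run --pdb synthetic.pdb --rdc synthetic.tab \
    --segments synthetic.segments --mode ideal --report report.json
H1 A:1-12
  ideal: N= 60  Da= 10.018 Hz  Rh=0.309  G= 9.275 Hz  Q_jk=0.025  eps(G)=0.004  eps(S)=0.000
H2 A:18-27
  ideal: N= 50  Da=  9.937 Hz  Rh=0.302  G= 9.187 Hz  Q_jk=0.024  eps(G)=0.005  eps(S)=0.000
H3 A:33-44
  ideal: N= 60  Da=  9.984 Hz  Rh=0.292  G= 9.212 Hz  Q_jk=0.026  eps(G)=0.004  eps(S)=0.000
H4 A:50-59
  ideal: N= 50  Da=  9.987 Hz  Rh=0.298  G= 9.226 Hz  Q_jk=0.025  eps(G)=0.005  eps(S)=0.000
P(S_i, S_j) vs global tensor:
  H1: 0.757
  H2: 0.752
  H3: 0.808
  H4: 0.811
```

Each helix recovers the generating parameters (Da ≈ 10 Hz, Rh ≈ 0.3,
G ≈ 9.24 Hz) with low Q_jk; helices within one domain agree (pairwise
P > 0.99 in `report.json`) while the fits against the *pooled* tensor sit
near 0.75–0.81 — the pooled tensor is a meaningless average of two distinct
alignments, exactly the signature of interdomain flexibility. The JSON
report contains the full per-helix blocks, the pairwise P matrix and the
global-fit block.

Library use mirrors the CLI:

```python
import helixfit as hf

fx = hf.make_two_domain_fixture(hf.SynthSpec(noise_sigma=0.3, seed=11))
cfg = hf.ScreenConfig(coordinate_mode="ideal")
reports = [hf.fit_helix(s, fx.rdcs, fx.structure, cfg) for s in fx.segments]
labels, P, P_global, global_fit = hf.cross_helix_matrix(reports)
```

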