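# Methods

## Dose-response models

Second-cancer induction is modelled per voxel through a risk equivalent
dose (RED). Two mechanistic families are used:

* **Carcinoma** — linear induction at low dose, attenuated at high dose
  by linear-quadratic cell kill and partially restored by inter-fraction
  repopulation/repair. The closed form is

      RED(D) = e^{-α'D}/(α'R) · (1 − 2R + R² e^{α'D} − (1−R)² e^{−α'RD/(1−R)})

  with `α' = α + (α/ρ)·d`, `ρ = α/β = 3 Gy`, and `d` the voxel's dose per
  fraction (total voxel dose divided by the number of fractions, so
  low-dose voxels see proportionally low per-fraction dose).

* **Sarcoma** (bone, soft tissue) — the same bracket with an extra
  `−α'RD` term, equivalently `RED_carc − D·e^{-α'D}`; it vanishes faster
  than linearly at low dose, reflecting the near-absence of sarcoma
  excess at survivor-study dose levels. Full tissue recovery (`R = 1`) is
  assumed for sarcoma tissues; `R` remains a config field for
  sensitivity work.

Organ risk follows `EAR_org = µ·β_EAR·(mean RED over the organ's
voxels)` in units of (10,000 person-years)⁻¹, and patient risk is the sum
over modelled organs. The age modifier
`µ = exp(γ_exp(t_exp−30) + γ_att·ln(t_att/70))` is exactly 1 at the
default operating point (exposure age 30, attained age 70); the γ
exponents are config inputs defaulting to 0 because the package is
calibrated at that operating point. A linear-no-threshold variant
(`RED = D`) is provided throughout as a robustness comparator; since the
cell-kill exponential never exceeds 1, mechanistic EAR never exceeds the
linear EAR.

### Numerical treatment

The carcinoma bracket is evaluated in the algebraically equivalent,
overflow-free form `[(1−2R)e^{-α'D} + R² − (1−R)²e^{-α'D/(1−R)}]/(α'R)`.
The expression is indeterminate at both ends of the repopulation domain,
so analytic limit branches are used for `R < 10⁻⁴` (→ `D·e^{-α'D}`) and
`R > 1−10⁻⁴` (→ `(1−e^{-α'D})/α'`); thyroid has `R = 0` exactly and
sarcoma tissues use `R = 1`, so both branches are exercised routinely,
not only in edge cases. Near the lower switch point the generic bracket
behaves as `D·e^{-α'D} + R/α' + O(R²)`, so the branch introduces an
absolute error bounded by about `10⁻⁴/α'` Gy — negligible against any
organ dose, though relatively large wherever `D·e^{-α'D}` is itself
astronomically small; the test suite therefore checks continuity at the
switch points in relative terms at moderate `α'D` and in absolute terms
at strong cell kill. Where `α'D` vanishes (zero dose or `α = 0`) the
exact linear limit `RED = D` is returned directly.

## Voxel model

Conventions: voxel-centre sampling, 0-based indices, axis order
(x, y, z), spacing in cm (default CT resolution
0.1055 × 0.1055 × 0.2500 cm³; coarser grids are used for desk-scale
work). Every in-patient voxel carries exactly one structure label; where
contours overlap, an explicit specificity ordering decides (defaults put
small structures — spinal cord, thyroid, pharynx — above the organs that
enclose them, then bone, then the soft-tissue body). Voxels inside no
contour are unlabelled and carry no risk; this is also how dose outside
the body contour is excluded. Dose is resampled to the label grid by
trilinear interpolation (exact for affine fields, convex so never
negative), with out-of-support voxels set to exactly 0 Gy — preserving
the zero-dose ⇒ zero-risk accounting. Proton dose is RBE-weighted by a
flat factor 1.1 once, guarded by a flag against double weighting. DICOM-RT
triplets (CT series, RTSTRUCT, RTDOSE) can be imported, with clinical
structure names mapped to library names through an alias table; a minimal
DICOM-RT writer exists for round-trip testing of synthetic plans.

## Tissue parameter library

One YAML record per organ: α (±σ), R (±σ), β_EAR (−σ/+σ), model kind.
The 13-structure roster is breast, oesophagus, heart, liver, lungs,
pharynx, spinal cord, spleen, stomach, thyroid, great vessels, bone, soft
tissue. Heart and vessels are `zero_risk` (their EAR is exactly 0 at any
dose); the spleen is *excluded* — its dose-response is considered too
uncertain to model — and is reported with the "–" sentinel rather than as
zero: exclusion and zero risk are semantically distinct. Absent-from-grid
organs are likewise reported as absent, never as zero. Two library
oddities are carried as printed rather than "corrected": the sarcoma
tissues list identical σ for β_EAR and α, and liver's α σ (0.905)
exceeds its mean (0.323).

## Uncertainty propagation

α, R and β_EAR are sampled from independent normal distributions per
organ (independence within and across organs is a modelling choice, not
an inference). Asymmetric β intervals are symmetrised to the larger σ —
a deliberate worst case that overestimates spread. Draws outside the
physical domains are **clipped** to the boundary and counted, rather than
rejection-sampled: clipping is deterministic, auditable, and does not
reshape the spread differently per organ. For liver α roughly a third of
draws clip at 0; that is expected, logged behaviour. A σ of 0 reproduces
the mean exactly in every draw (thyroid R).

The study is paired: a master seed spawns one independent substream per
patient, and every modality of that patient is evaluated with the same
draw sequence, so the same draw index means the same parameters for
every plan. Distribution summaries use sample moments (mean, ddof-1
standard deviation, CV = σ/|mean|); a constant sequence is reported with
σ exactly 0. Plan separation uses `z = |Δmean|/√(σ₁²+σ₂²)` with a
two-sided normal p-value; the significance gate is p < 0.001 (z ≈ 3.29),
with "three standard deviations" treated as the colloquial shorthand for
that gate. Two degenerate-σ distributions with equal means give z = 0;
with unequal means they are reported significant with p = 0.

Organ-level relative EAR is computed as the ratio of summed RED (β_EAR
and µ cancel algebraically, so they are never multiplied in and divided
back out); under the linear model that ratio is a ratio of summed doses
and therefore carries exactly zero variance across draws, while the
patient-level ratio — a ratio of β-weighted organ sums — retains a small
spread. This is the mechanism behind the paired design's variance
reduction: absolute EAR CVs of tens of percent shrink to a few percent
for similar-topology plan pairs, and a plan compared against itself gives
a ratio of exactly 1 with σ exactly 0.

## Synthetic plans

The generator builds a thorax-like phantom (all 13 roster structures as
axis-aligned boxes and ellipsoids, scaled to any grid) and analytic dose
fields: a Gaussian penumbra on the Euclidean distance to the PTV, plus a
sigmoid low-dose bath reaching a style-dependent fraction of the body,
plus a broad beam column for the 3DCRT style, and an exact-zero floor
(0.25 Gy) below which dose is zeroed. Style defaults encode the
modality contrasts the risk models are meant to detect: IMPT — minimal
bath (extent 0.15), most zero-dose voxels; IMRT/VMAT — bath over 90%/85%
of the body at 2.5/2.0 Gy; 3DCRT — full-dose column through the patient
with a 1 Gy bath over half the body. The default prescription is
30 Gy in 15 fractions; the PTV grows monotonically over stages 1–5,
emulating increasing disease extent. A small seeded multiplicative
ripple (2%) keeps fields from being perfectly analytic; everything is
deterministic under the spec's seed. An `equal_integral_pair` fixture
produces two fields with bitwise-equal integral dose but different
concentration, which the mechanistic model must — and does — assign
clearly different risk, demonstrating that integral dose is a poor risk
proxy.

What the generator does **not** emulate: beam transport, scatter and
penumbra physics, realistic organ shapes and inter-patient anatomy
variation, planning-constraint trade-offs, or delivered-vs-planned dose
differences. Passing tests on these phantoms validates the risk
mathematics and the paired statistics, not clinical dosimetry; absolute
EAR distributions here are broader than those of real Hodgkin-lymphoma
plans because the stylized dose fields place more of the sensitive
organs (breast, lungs) at high, uncertainty-dominated doses.

## Problem sizes

Default desk-scale grids are 40 × 40 × 30 voxels at 0.4 cm spacing
(tests use down to 20³-scale grids), with 1000 replicates for studies
and 100 for the self-comparison reference computation. These sizes were
chosen so a full 4-modality, 1000-draw study runs in seconds while every
organ of the roster keeps a non-trivial voxel count; the CT-resolution
grid is supported but not the default.

## Known limitations

* Parameters are sampled independently; any real correlation between α,
  R and β_EAR within an organ is ignored, which likely overstates
  absolute spread.
* Clipping at domain boundaries biases the effective sampling
  distribution for wide-σ parameters (liver α most of all).
* No neutron-dose contribution for proton plans, no
  chemotherapy/leukaemia risk, no background-incidence comparison.
* The separation statistic treats the two ratio distributions as
  independent normals; with paired draws they are correlated, so the
  reported significance is conservative in the usual case.
* Integral dose is volume-weighted (Gy·cm³), not mass-weighted; it is
  used only comparatively.
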