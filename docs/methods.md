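# Methods

## The problem

Fractional flow reserve (FFR) — the ratio of mean distal coronary pressure Pd
to mean aortic pressure Pa under maximal hyperemia — is the reference standard
for deciding whether a coronary stenosis causes ischemia; FFR ≤ 0.80 defines a
functionally significant lesion. Measuring it requires a pressure wire and a
hyperemic agent. *Virtual* FFR replaces the wire with a computation on
imaging-derived vessel geometry. `vffr` implements such a computation for an
unbranched coronary segment described by its lumen area profile A(s) (mm², as
a function of centerline arc length s in mm), together with the
diagnostic-statistics layer needed to evaluate any virtual index against
invasive FFR on a paired cohort.

## Geometry

Cross-sectional lumen area is the primitive measurement; diameters are
circular-equivalent, d(s) = 2·√(A(s)/π). The healthy-vessel taper ("reference"
diameter d_ref(s)) is an ordinary least-squares line through d(s) over the
non-lesion samples; the lesion is delimited as the contiguous run of pointwise
diameter stenosis DS%(s) = 100·(1 − d(s)/d_ref(s)) above a threshold (default
20%, configurable) containing the deepest narrowing. Anchoring at maximal
DS% rather than the global diameter minimum makes the delimitation robust on
tapered vessels, where the raw diameter minimum can sit at the distal end.
Lesion metrics follow catheter-lab convention: MLA/MLD at the area minimum
inside the lesion, RVD from the reference line at the MLA position,
DS% = 100·(1 − MLD/RVD), AS% = 100·(1 − MLA/RVA), and plaque burden
(EEM − MLA)/EEM where an external-elastic-membrane profile exists. For
circular cross-sections AS% = 100·(1 − (1 − DS/100)²) exactly, which the test
suite uses as an identity check. All profiles are resampled to a uniform
0.1 mm grid before hemodynamics.

The `VirtualFFR` model fits the reference in two passes by default (fit →
delimit lesion → refit excluding the lesion → re-delimit); a
`reference_segment_mm` window can pin the fit to an explicitly healthy
proximal segment instead, since no universal convention exists for which
"initial" segment defines the reference slope.

## Hyperemic flow

Hyperemic flow is modelled as v = k·d_ref², i.e. velocity proportional to the
square of the reference diameter, with Q = v·A_ref conserved along the
segment (side branches are ignored). The constant k (default 0.35/9 ≈ 0.0389
m·s⁻¹·mm⁻²) is calibrated so a 3.0 mm reference vessel carries 0.35 m/s —
typical adenosine-hyperemia velocity; the proportionality law itself carries
no published constant, so k is exposed as configuration. Alternatively the
velocity can come from a contrast frame-count transit measurement
(v = length / (n_frames/frame_rate)) or be imposed directly (`fixed` mode).
With v in m/s and A in mm², Q is in mL/s (1 m/s · 1 mm² = 1 mL/s).

## Pressure drop and FFR

The reduced-order pressure drop is the sum of two non-negative,
non-decreasing components:

* **Viscous (Poiseuille-profile) friction**, integrated pointwise:
  dP_v/ds = 8πμQ/A(s)², with μ = 0.0035 Pa·s and ρ = 1060 kg/m³ by default
  (standard blood properties, configurable). For a straight tube this
  reduces to ΔP = 8μLQ/(πr⁴).

* **Expansion (Borda–Carnot separation) loss** wherever the lumen re-expands
  distal to a throat: for each maximal contiguous area-increasing run,
  ΔP_e = k_e·(ρ/2)·Q²·(1/A_throat − 1/A_recovery)², with k_e = 1 (classical
  Borda–Carnot) by default. The loss is attributed across the run in
  proportion to the local change of 1/A, so the cumulative component is
  non-decreasing. Using the run's *endpoint* areas rather than per-grid-cell
  differences is deliberate: per-cell squared differences vanish under grid
  refinement on smooth profiles (Σδ² → 0), which would make the predicted
  drop resolution-dependent and smooth lesions spuriously lossless, whereas
  the endpoint form is grid-independent and coincides with the abrupt-
  expansion formula when the expansion occupies a single interval.
  Contractions are loss-free apart from friction, the standard reduced-order
  convention.

FFR(s) = (Pa − ΔP(s))/Pa with Pa = 90 mmHg by default (a typical mean aortic
pressure; per-patient values are configuration). The distal value is read at
the virtual sensor position (default: distal end of the profile). A drop
reaching Pa means the imposed-flow assumption has broken down — severe
lesions throttle real hyperemic flow — and raises a non-physical-regime
error rather than returning FFR ≤ 0. Unit conversion (1 mmHg = 133.322 Pa)
happens once, at the pressure-field boundary.

## 1D finite-volume solver

`solve_1d_steady` integrates the steady area-averaged 1D momentum balance
cell-by-cell on a uniform grid: Poiseuille-profile wall friction plus the
convective (Bernoulli) pressure change from the 1/A² gradient, with pressure
recovery on each expansion run capped by the same Borda–Carnot loss as the
reduced-order model. The two engines therefore share one physical contract
while discretising differently; their distal FFR values differ by the
unrecovered inlet-to-outlet Bernoulli term (taper) and by quadrature error,
which is what the cross-engine agreement tests measure. Mid-lesion the
solver's pressure dips below the reduced-order curve (recoverable kinetic
energy), so its cumulative drop is not monotone through a stenosis and its
convective component is stored signed. Friction uses midpoint quadrature;
observed convergence of the distal drop is better than first order on smooth
profiles.

Cross-engine verification fixtures (20 lesions, DS% 30–80, lengths 5–25 mm)
impose a fixed Q = 1.0 mL/s. This keeps the severest lesions inside the
model's physical regime (at the full default hyperemic flow, lesions beyond
roughly 73% DS exceed Pa and both engines correctly refuse); a dedicated
test asserts that refusal.

## Polar lumen segmentation

An IVUS-style frame resampled to polar coordinates (catheter at origin) shows
a dark lumen inside a brighter wall. The boundary is the minimum-cost closed
path over the (angle, radius) grid: node cost is the negated outward radial
intensity gradient (rescaled to [0, 1]), transitions between adjacent angle
bins are limited to |Δr| ≤ 2 bins with a small per-bin curvature penalty
(0.05), and closure is enforced by solving the shortest path for each
candidate start radius (every 2nd bin) and keeping the cheapest closed tour,
ties broken toward the smaller radius. Because angle increases monotonically
along the path the graph is a DAG and dynamic programming gives the exact
Dijkstra solution; on small grids the tour cost is verified against
exhaustive enumeration. A frame whose intensity has no radial gradient
structure raises an unsegmentable-frame error instead of returning an
arbitrary contour.

Contour area uses the polar-sector sum A = ½·Σ r_i²·Δθ (exact for constant
radius). Pullback frames are gated to one frame per heartbeat (nearest frame
to R-wave time minus an end-diastole offset, default 0) and mapped to arc
length assuming uniform motorized pullback, s = k·speed/rate re-zeroed at
the first gated frame.

## Diagnostic statistics

Ground-truth positivity is invasive FFR ≤ 0.80; an index calls a vessel
positive when its value is ≤ the cutoff (lower = more ischemic, so ROC
scores are negated internally). From a confusion matrix the layer computes
accuracy, sensitivity, specificity, PPV/NPV, likelihood ratios, Youden index
(sens/100 + spec/100 − 1), false discovery/omission rates and the
misclassified fraction. Confidence-interval families follow the conventions
under which such tables are reported:

* exact Clopper–Pearson (beta-quantile) intervals for accuracy, sensitivity
  and specificity;
* Mercaldo standard-logit intervals for PPV/NPV, with
  var(logit PPV) = (1−se)/(se·n₁) + sp/((1−sp)·n₀) and the analogous NPV
  form (n₁/n₀ = diseased/non-diseased counts); degenerate counts fall back
  to the exact binomial on the predictive-value column;
* Simel log-method intervals for likelihood ratios,
  se(ln LR+) = √(1/TP − 1/n₁ + 1/FP − 1/n₀).

Zero-denominator indices are flagged undefined rather than fabricated.
Report formatting rounds half-up to 1 decimal for percentages, 2 for ratios
and 3 for AUC; full precision is kept internally.

AUC is the Mann–Whitney concordance probability with ties counted ½, which
equals the trapezoid area under the empirical ROC from a threshold sweep (a
property test checks this equality on random cohorts). The Youden-optimal
cutoff is searched over the observed index values plus a 0.01-step grid on
[0.50, 0.95]; ties are broken toward the cutoff nearest 0.80, then toward
the larger cutoff. Bland–Altman limits of agreement are mean(d) ± 1.96·SD(d)
of the signed differences with the n−1 SD. No multiple-testing correction
is applied.

## Synthetic data

All generators are pure functions of (spec, seed).

* **Vessels**: diameter = taper line × Π(1 − (DS/100)·bump), with unit-peak
  raised-cosine or truncated-Gaussian bumps; ground-truth MLA/DS%/lesion
  bounds are analytic. Defaults: 60 mm segment, 3.0 mm proximal diameter,
  −0.005 mm/mm taper, EEM 20% above the reference lumen diameter.
* **Polar stacks**: per-frame circular lumen of the local radius, sigmoid
  dark-to-bright edge (width 0.05 mm) plus i.i.d. Gaussian noise; 64 angle ×
  96 radius bins by default; ground-truth contours returned alongside.
* **ECG**: R waves at 60/HR spacing plus Gaussian jitter truncated at 3σ
  (RR-interval SD ≈ √2·jitter SD, slightly attenuated by truncation).
* **Cohorts**: trivariate Gaussian (IVUS index, CT index, FFR) via Cholesky
  factorisation, with default means 0.72/0.74/0.73, SDs 0.10/0.09/0.09 and
  pairwise correlations 0.7913 (IVUS–FFR), 0.6296 (CT–FFR), 0.7323
  (IVUS–CT) — the cohort moments this package's evaluation layer is
  exercised against. Draws outside (0.2, 1.0] are rejected and redrawn
  rather than clipped, preserving the correlation structure; at these
  parameters the truncation shifts means by < 0.002 and correlations by
  < 0.01. Optional 2-decimal rounding mimics clinical FFR reporting
  (off by default).

What the generators do *not* emulate: eccentric/non-circular lumina, speckle
texture and catheter artefacts in the images, cardiac-phase lumen pulsation,
non-uniform catheter motion, side branches, and per-vessel variation in Pa
or blood properties. Passing tests therefore demonstrate correctness of the
algorithms under their stated assumptions, not clinical accuracy on real
pullbacks.

## Numerical choices and problem sizes

* Fixed conversion 1 mmHg = 133.322 Pa; SI internally.
* Profiles resampled to 0.1 mm before hemodynamics; the finite-volume solver
  defaults to 400 cells (600 in cross-checks).
* Lesion-metric ties (equal minimum areas) resolve to the proximal sample;
  tracer ties resolve toward smaller radius.
* Statistical property checks use 200 random cohorts (AUC equality), 10⁴
  binomial replicates at n = 36 (interval coverage), 2×10⁵ Gaussian pairs
  (limits-of-agreement capture), and 10⁵ draws (cohort moment recovery) —
  sizes chosen so Monte-Carlo error is well below the asserted tolerances
  while the whole suite runs in well under a minute per module.
* End-to-end pullback checks use a 40 mm vessel at 1 mm/s and 10 frames/s
  (~400 frames, ~50 gated beats), enough axial sampling to resolve a 10 mm
  lesion.

## Known limitations

* The velocity ∝ d² law is an empirical scaling with no universal constant;
  absolute FFR values depend on k, Pa and k_e, so cross-engine and
  ground-truth-recovery checks — not absolute clinical agreement — are the
  verifiable claims here.
* Steady flow only; no pulsatility, no microvascular resistance model, no
  pressure-drift simulation.
* The segmentation stand-in is a classical minimal-path tracer; it is not a
  substitute for learned segmentation on real speckle imagery and is
  validated only on the synthetic stacks above.
* Per-vessel clustering (multiple lesions per patient) is ignored in the
  statistics layer, as is any AUC-difference test between methods.
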