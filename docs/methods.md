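# Methods

This note records the models, defaults and numerical choices behind
`chemodrop`, and what the synthetic-data generators do and do not emulate.

## Occupancy statistics

**Model.** Founder cells per droplet are Poisson(λ) with
λ = density × volume (CFU/mL × nL × 10⁻⁶). After incubation only
presence/absence of growth is observed, so λ is estimated from the occupied
fraction by the maximum-likelihood occupancy estimator λ̂ = −ln(1 − f_occ),
not from mean counts — per-droplet colony numbers are never observed.

**Confidence intervals.** The assay typically tallies ~100 droplets per
run, so intervals must be valid at small n. We use the exact
Clopper–Pearson interval on the occupied fraction (beta-quantile closed
form) and map it through −ln(1−·); the transform is monotone, so exact
coverage is inherited. Coverage is verified by simulation at
λ ∈ {0.05, 0.5, 2} (2000 replicates each, n = 100): empirical coverage
stays within 2 points of nominal.

**Saturation.** An all-positive droplet array leaves λ unbounded; the
estimator raises `SaturatedOccupancyError` rather than returning infinity.
The assay's own protocol avoids this state by dilution.

**Dual-label deconvolution.** With a fluorescent reference strain and a
non-labelled target co-encapsulated independently, occupancies add:
λ_ref comes from the fluorescent-droplet fraction, λ_total from the union
fraction (fluorescent + growth-only-nonfluorescent), and
λ_target = λ_total − λ_ref. A fluorescent droplet may also contain the
target; independence is what makes the subtraction exact. With the union
tally the difference is non-negative by construction; the clip-to-zero
branch (with a warning) guards externally supplied tallies. The target's
interval is the conservative difference of the two exact intervals.

**Reporting.** λ values are reported to 2 significant figures, matching the
assay's presentation. Note one reporting subtlety: −ln(1 − 0.080) = 0.0834
rounds to 0.083 while the assay community often quotes 0.084 from unrounded
measured fractions; ratios computed from unrounded internal values (e.g.
the enrichment factor 36.4 from 17.43/0.48) likewise differ by ~1% from
ratios of rounded intermediates. Downstream arithmetic here always uses
unrounded values.

**Mixture tallies.** The post-exposure tally is interpreted with 27.1% as
the *total* growth fraction (fluorescent + non-fluorescent): forward
computation then gives λ_target = −ln(1−0.271) − (−ln(1−0.017)) = 0.299,
consistent with the reported 0.298. Reading 27.1% as the target-only
fraction would instead give λ_total = −ln(1 − 0.288) = 0.340 and
λ_target = 0.323; both tallies can be expressed through `OccupancyCount`,
and `deconvolve_dual_label` makes the union construction explicit
(n_fluor + n_growth_nonfluor) so the choice is visible, not silent.

## Gradient model

**Equations.** Depth-averaged 2D (x, y) steady transport
u(y)·∂c/∂x = D·∂²c/∂y², valid when axial diffusion is negligible
(Pe = v̄·w/D ≈ 180 at the default operating point: v̄ = 42 µm/s,
w = 2.1 mm, D = 4.9 × 10⁻⁶ cm²/s, the fluorescein value used as the model
chemoeffector). A warning is emitted below Pe = 10. The transverse gradient
is the quantity of interest and the experimental readout is cross-sectional
profiles, so no 3D/Taylor-dispersion modelling is attempted.

**Discretisation.** x plays the role of time; each x-step solves a
tridiagonal system for the transverse diffusion (θ-scheme, θ = 0.5 with
4 fully implicit start-up steps to damp the discontinuous inlet profile —
the Rannacher device). No-flux walls are mirrored ghost cells, which makes
the discrete mass flux ∫c·u dy conserved to round-off. Defaults
dy = 5 µm, dx = 10 µm give max |error| ≈ 5 × 10⁻⁴ against the erfc
similarity solution of a diffusing two-stream step and < 10⁻⁵ change under
dy-halving. The solver refuses a dy that cannot resolve the narrowest
merged stream.

**Inlet streams.** Merged stream widths are assigned by flow-rate fractions
(0.25 : 0.025 : 0.25 of q_total by default), not physical inlet widths —
co-flowing streams reposition to carry their flow share. Concentrations are
normalised to the inlet maximum; physical units belong to the caller.

**Velocity profile.** Plug flow is the default depth-averaged
approximation; a transverse parabolic ("laminar") profile is selectable for
sensitivity checks. The erfc validation applies to the plug case, which is
also what the similarity solution assumes.

## Synthetic device

**Chemotactic sorting.** The device demonstrates *that* chemotactic cells
sort; it prescribes no kinematic model. The simulator therefore uses an
explicitly invented run-and-tumble model: constant swim speed (20 µm/s),
Poisson tumbling at 1 s⁻¹ with uniform re-orientation, rotational heading
noise (0.1 rad²/s), advection by u(y), reflecting walls. Temporal sensing
biases the walk: the tumble rate is scaled by
max(0, 1 − sensitivity · clip((dc/dt)/s₀, 0, 1)) with s₀ = 0.02 s⁻¹ on the
normalised concentration — chosen so that a cell swimming up the developed
gradient (|∂c/∂y| ≈ 1/500 µm⁻¹ at 20 µm/s) saturates the suppression.
Sensitivity 0 models a cheZ-deletion non-chemotactic mutant; 1 models a
strongly responsive wild type. Cells exit at x = L and are routed to
collection when y exceeds the splitting streamline set by the waste flow
fraction. Fractions carry binomial sampling noise by construction.

**What sorting does not emulate:** shear-induced rheotaxis, cell–wall
hydrodynamic interactions, tumble-angle distributions, receptor adaptation
dynamics, growth-phase heterogeneity. Passing sorting tests therefore shows
the pipeline's statistics are correct under idealised motility, not that
real strains will reproduce specific collection fractions.

**Encapsulation.** Independent Poisson founders per species; growth = any
founder surviving a Bernoulli(growth_probability) thinning (default 1.0;
lower values model viability loss, making growth occupancy Poisson with
mean λp); fluorescence = surviving founder of a labelled species.

**Detector trace.** Per droplet: an oil-baseline gap, a leading meniscus
peak, a plateau at the empty or growth level, a trailing meniscus peak.
Growth plateaus are darker than empty ones (optical absorbance of the grown
culture). Meniscus peaks are symmetric positive excursions above the oil
baseline, applied by pointwise maximum so each apex sits exactly on its
boundary sample; real menisci can be biphasic — kept simple deliberately.
Durations are Gamma-jittered (CV 10%) to avoid metronomic artifacts; noise
is additive Gaussian. The default sample rate is 200 Hz — finer than a
typical assay video rate — so the narrow boundary peaks are resolved; the
trace contract is the signal decomposition, not a camera model. The default
"separable" preset (plateaus 0.80/0.45, noise SD 0.02) keeps classes
cleanly separated, mirroring the significant intensity gap reported between
empty and grown droplets.

## Trace analysis

Peaks are detected by prominence (default 0.4 intensity units) on a lightly
smoothed copy (20 ms box, forced to an odd sample count so apex positions
do not shift); plateau medians are taken on the raw trace with a 100 ms
guard margin. An inter-peak interval is a droplet only if its level differs
from the oil baseline by more than 8 standard errors of its median —
intervals at baseline are oil gaps, and the rule stays valid across noise
levels because it scales with interval length. The growth/empty cut
maximises between-class variance exactly over all sample splits (Otsu's
criterion computed on the samples, not a binned histogram: with a few
hundred tight amplitudes, 256-bin histogram Otsu can land on a cluster edge
and split a class). Near-threshold droplets within 5% of the inter-class
gap are surfaced as `ambiguous` and excluded from tallies; poorly separated
or unimodal amplitude sets flag the result low-confidence rather than
inventing a split. Fluorescence gating thresholds at six robust noise SDs
above the channel's dark baseline by default.

Scale-up plating is represented only as a per-droplet label manifest
(`write_plate_manifest_csv`); colony-image analysis is out of scope.

## Pipeline and scenarios

One root seed is split per stage via `SeedSequence`, so runs are
bit-reproducible and stages re-runnable. The hydraulic bookkeeping maps the
cell-inlet density to the droplet generator:
d_gen = d_in · q_middle · f_collected / (q_collect + q_media).

Bundled scenarios use the stringent-sorting flow split (waste outlet
0.30 µL/min), which puts the splitting streamline above the released cell
stream so that collection requires active up-gradient migration; inlet
densities are set to land control-condition λ values in the assay's working
range (λ_ref ≈ 0.08, λ_target ≈ 0.04 for the mixture; λ ≈ 0.05 for the
pure-culture pair) with 800 droplets per condition. These sizes keep a
scenario run in a few seconds while making the qualitative directions
(enrichment factor > 1 under a gradient, ≈ 1 without; chemotactic species'
λ rising above the mutant's) stable across seeds. Device-measured values
such as the 0.043 → 0.77 λ jump or the 1.5% → 90.0% fraction jump are
experimental outcomes of real strains and are mirrored only directionally.

The enrichment-factor interval reported by scenarios is the conservative
ratio-of-bounds construction from the four λ intervals; it over-covers
(often grossly, when any λ is near zero) and is meant for null-consistency
checks, not efficient inference.

## Known limitations

- The λ estimator ignores growth failure: a founder that fails to grow is
  invisible, so λ̂ estimates *culturable* occupancy (the generator's
  `growth_probability` exposes exactly this gap).
- Deconvolution assumes independent co-encapsulation; cell aggregation or
  interspecies interaction in droplets would bias λ_target.
- The sorting model is a stylised kinematic invention (see above); its
  collection fractions are not device predictions.
- Trace segmentation assumes non-overlapping droplets with visible
  menisci; merged droplets or satellite droplets are not modelled.
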