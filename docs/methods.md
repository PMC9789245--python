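# Methods

## Scope and model

`vestfem` predicts extracellular voltage waveforms and nerve-fiber
recruitment during current-controlled electrical stimulation of vestibular
nerves. The electromagnetic model is the quasi-stationary complex-admittivity
approximation: at each stimulus frequency component `f_i` the potential
solves the source-free Laplace equation

    -div( gamma(x, f_i) grad phi(x, f_i) ) = 0,
    gamma = sigma(f_i) + j 2*pi*f_i eps0 eps_r(f_i),

i.e. conduction and displacement currents are kept but wave propagation and
induction are neglected — valid at the sub-MHz frequencies and centimeter
scales involved. Setting `eps_r = 0` with frequency-independent `sigma`
recovers the classical quasi-static (QS) model, in which every probe
waveform is a scaled copy of the stimulus current; the package keeps that
mode as a reference. The validity ratio `omega*eps0*eps_r/sigma` is exposed
per tissue and frequency (`dielectrics.qs_ratio`).

The field problem is linear in the drive current. Everything downstream
(power limiting, threshold search) exploits this: scaling the stimulus
amplitude scales every potential in the model by the same factor.

## Stimuli and spectra

Stimuli are cathodic-phase-first, charge-balanced biphasic pulses. Defaults
follow the two waveforms studied in vestibular implant work: 200 µs phases
with a 40 µs gap ("long") and 50 µs phases with a 2 µs gap ("short"), both
at 1 mA, placed at 280 µs in a 1 ms window sampled at 1 MHz. The one-sided
DFT uses 1 kHz resolution up to 500 kHz (501 bins including DC); the window
equals `1/df` so the transform is exact and the inverse reconstruction is a
bit-accurate round trip. One source gives the gap as 50 µs in prose; the
40 µs figure from the parameter listing is the default and the gap is
configurable.

Bins whose drive magnitude falls below a configurable floor (default 1e-6 of
the peak bin) are skipped and contribute zero at synthesis; the DC bin of a
charge-balanced stimulus is empty and always skipped. Synthesis takes the
real part of the one-sided sum, which enforces conjugate symmetry, so all
reported time series are exactly real.

## Phantom geometry

The subject-specific anatomy that motivates the method is replaced by the
minimum structure on which recruitment selectivity is meaningful:

* a spherical fluid cavity (radius 3.5 mm, CSF properties) containing the
  electrodes;
* one target and two non-target nerve bundles — cylinders of radius 0.6 mm
  and length 9 mm starting 2.9 mm from the cavity center at 0°, 50° and
  100°, each carrying a uniform fiber-axis field;
* a bone sphere of radius 25 mm and a saline shell to 35 mm, whose outer
  surface is the grounded reference;
* spherical electrodes of radius 150 µm placed along the transversal axis
  of the target bundle: one source at 750 µm from the epithelium center
  (monopolar) or a source/sink pair at 250 µm and 1250 µm (bipolar).

Meshes are Delaunay tetrahedralizations of graded point clouds: electrode
surfaces are sampled at ~55 µm, nerve bundles at ~0.3 mm, and spacing grows
to ~3 mm at the outer boundary. Tetrahedra are labeled by centroid;
electrode interiors are excluded from the conductive domain and their
boundary triangles form conforming contact patches. The default resolution
yields roughly 1e5 elements; a resolution multiplier coarsens all spacings
for fast runs. Jittered Delaunay meshes contain slivers; a minimum-dihedral
floor (~0.1°) and a volume cutoff guard against degenerate elements, and the
direct solver is insensitive to the remaining poor shapes at these sizes.
An optional scar shell (300–500 µm) can be meshed around each contact; the
shell represents encapsulation tissue and may displace (relabel) adjacent
nerve volume, as encapsulation does.

The phantom reproduces the topology of the stimulation problem, not the
anatomy: real ampullae are not spheres, real nerve branches curve and vary
in caliber, and the surrounding temporal bone is not homogeneous. Passing
tests on the phantom therefore validates the machinery and the directional
physics (selectivity orderings, permittivity effects), not absolute
amplitudes on any real anatomy.

## Tissue dielectric data

Embedded four-term Cole-Cole parameter sets (cortical bone, CSF, spinal
cord) follow the published dielectric database. Curves are tabulated on a
log-spaced knot grid (10 per decade, 100 Hz – 500 kHz) and interpolated with
cubic splines on `(log10 f, log10 value)` pairs — the properties span
decades, and log-space splines cannot overshoot into negative values.
Queries outside the knot range are rejected rather than extrapolated.

Nerve anisotropy: the spinal-cord conductivity curve is rescaled so its
100 Hz value matches a longitudinal and a transversal target (defaults
0.33 S/m and 0.033 S/m, order-of-magnitude ratio typical of peripheral
nerve; both are configuration values chosen by the implementers, as is the
0.0295 S/m isotropic reference sometimes quoted for the unscaled curve —
the embedded parameterization evaluates to ≈0.028 S/m at 100 Hz).
Permittivity is not rescaled with conductivity: no directional permittivity
measurements exist to anchor such a scaling, so both directions keep the
isotropic curve.

Uncertainty bounds per tissue: nerve uses ±50 % at every knot; bone and CSF
use symmetric log-space bounds `default·10^(±d)`, with the distance `d`
computed as the median absolute log10 offset from supplied literature
tables when available. The literature knot tables behind the published
bounds are not reprinted anywhere accessible, so the default widths
(bone 0.20 dex, CSF 0.05 dex) are explicit configuration, sized to the
qualitative statements that bone is the most uncertain tissue and CSF the
best measured.

## Field solver

First-order (P1) Galerkin tetrahedra. Assembly is split once per mesh into
per-region geometric stiffness parts — isotropic regions one matrix, nerve
regions a longitudinal (`a a^T`) and transversal (`I − a a^T`) pair — so
each frequency forms a complex linear combination instead of re-assembling.
Row sums of the unconstrained stiffness vanish (partition of unity), which
the tests assert.

Driven electrodes are equipotential floating conductors: all vertices of a
contact patch share one auxiliary terminal unknown and the bin's complex
current is injected at that terminal. This matches a metal contact and makes
the terminal voltage well defined; the alternative (uniform current density
over the patch) has no single terminal voltage to feed the interface
circuit. The outer boundary is eliminated as a homogeneous Dirichlet
(reference) condition. Bipolar pairs must carry opposite currents.

Systems are solved by direct sparse LU with a relative-residual check
(1e-8). A depth-one factorization cache keyed on the admittivity values
makes sweeps over frequency-independent properties refactorize exactly
once while keeping memory flat for frequency-dependent sweeps. Currents
through patches are evaluated by the Galerkin-consistent flux (summing the
stiffness residual over patch vertices), which reproduces the injected
current to machine precision; a raw geometric `gamma grad phi · n` surface
integral is available as a diagnostic but carries discretization error.

The contact impedance `Z_ET = R_scar + 1/(j omega C_dl)` enters only the
reported terminal voltage `V_E = V_M + Z_ET I`; under current control the
tissue solution is independent of it (asserted as an invariant). The
capacitor is open at DC; since charge-balanced stimuli carry no DC, the DC
bin is skipped rather than special-cased.

## Electrode interface and power limitation

`C_dl` is an areal density (default 15 µF/cm², the mean of the 10–20 µF/cm²
range for metal in aqueous solution) times the spherical contact surface.
Scar tissue defaults to the lumped form: the series resistance of a
spherical shell of conductivity 0.1 S/m between the contact radius and
radius + thickness, `R = (1/4πσ)(1/r1 − 1/r2)`; a meshed shell is available
and increases the electrode voltage monotonically with thickness.

The power limitation caps instantaneous power `P(t) = I(t)·V_E(t)` at
`P_max` (default 5 mW). Because the model is linear, limiting the worst
time step with a single global factor `sqrt(P_max / max P)` is equivalent
to the per-step prescription `I_new = sqrt(P_max/Z_tot)` at the binding
step, and it preserves the stimulus shape and charge balance; the
equivalence at the binding step is asserted numerically. After limiting,
the peak power equals the cap exactly. A 5–7 V compliance cap is noted in
the implant literature; it is available as an optional secondary limit and
disabled by default. When the limit binds during recruitment analysis, the
delivered amplitude saturates at the capped value, so fibers with
thresholds above the cap simply never activate.

## Neural model

Each fiber is a SENN chain: excitable nodes of Ranvier coupled by the
axoplasmic conductance of myelinated internodes, driven by the
extracellular potential sampled at the nodes (barycentric interpolation in
the containing tetrahedron, inverse DFT for Fourier fields). A spatially
uniform extracellular potential produces zero drive — the activating
function null space — which the tests assert at machine precision.

Node membrane: voltage-gated Na⁺ (m²h) and K⁺ (n²) conductances with
FH-type rate functions, a leak, and 2 µF/cm² capacitance. Per-node values
derive from the fiber outer diameter D: axon diameter 0.7·D, nodal gap
2.5 µm, internode 100·D, axoplasmic resistivity 1.1 Ω·m. Specific
conductances (Na 1445, K 40, leak 30.3 mS/cm²) and reversal offsets
(+115 mV, −33 mV relative to a −70 mV rest) are documented configuration in
the style of the SENN literature; the leak reversal is solved so the
resting state is an exact fixed point of the discretized dynamics. Rates
are Q10-corrected (1.8 / 2.8 / 3.2 for m / h / n) from their 20 °C
reference to 37 °C.

Integration uses exact-exponential (Rush-Larsen) gating updates and a
backward-Euler cable update with the ionic term linearized at the fresh
gating state (chord conductance), solved by a Thomas pass vectorized across
the fiber batch. The default dt is 1 µs; thresholds change by <0.5 % under
dt halving (asserted), and dt above 2 µs is rejected as outside the
validated range.

Activation: any node's m exceeding 0.7. Thresholds: bisection on the
amplitude scale of the extracellular field, brackets auto-expanded by
doubling, terminating when `(upper − lower)/upper < 1e-3` — the 0.1 %
stopping rule is interpreted relative to the upper bound, and the upper
(activating) bound is reported. Fibers that fail to activate at the search
cap are flagged unconverged and excluded from recruitment denominators
(counts logged).

Three afferent types are sampled per branch (defaults: calyx 15 % at 4 µm,
dimorphic 70 % at 3 µm, bouton 15 % at 2 µm outer diameter, 21 nodes per
fiber); the proportions and calibers are package defaults standing in for
the type statistics tabulated in the neural-modeling literature. Fibers run
parallel to the bundle axis with random radial offset and axial stagger,
deterministic per seed.

## Selectivity

Recruitment is the empirical CDF of converged thresholds on a logarithmic
amplitude grid spanning the observed range ±20 % (100 points by default).
ROC points pair the target fraction (TPR) with the maximum non-target
fraction (FPR) per amplitude; the worst-case branch is the non-target with
the highest final recruitment. Because recruitment-derived ROC curves need
not touch (0,0) or (1,1), the integration convention anchors the curve at
(0,0), keeps any TPR already reached at zero FPR as a vertical segment, and
extends the final TPR horizontally to FPR = 1 before trapezoidal
integration over the full FPR range; the result is clamped to [0, 1]. AUC
is grid-converged to <1e-3 once the grid resolves the threshold steps.

The waveform comparison metric is the RMSE over a fixed window from 40 µs
before stimulus onset to 40 µs after the stimulus ends.

## Problem sizes in the shipped tests

The test suite runs at desk scale by choice: the analytic-sphere benchmark
uses the default ~8.5e4-element mesh; phantom-based tests use a coarsened
(~1.9e4-element) phantom, 500-bin sweeps, and 12–24 fibers per branch.
These sizes keep every directional result (QS/Fourier equivalence,
permittivity-induced slope reduction and threshold shifts, bipolar >
monopolar selectivity) stable across seeds while the full suite completes
in minutes. Absolute AUC values and thresholds on the phantom are
geometry-specific and are not comparable to values computed on
multi-million-element anatomical meshes.

## Known limitations

* The phantom is topological, not anatomical; amplitudes and AUCs are not
  transferable to patient geometry.
* The interface model is linear: no Faradaic electrochemistry, no
  nonlinear polarization, no time-varying scar growth.
* The instrumental electrode model is reduced to its contact impedance;
  cable capacitances and leakage paths are out of scope.
* P1 elements on graded Delaunay meshes lose accuracy within one or two
  element layers of the tiny contact; terminal voltages carry a few percent
  of discretization error at default resolution (probe potentials away from
  the contact are much tighter, as the sphere benchmark shows).
* Band-limited synthesis shows Gibbs ripple within a few microseconds of
  pulse edges; comparisons exclude a ±5 µs band there.
* Stochastic channel behavior, synaptic transduction, and spike-rate coding
  are outside the neural model; it predicts activation thresholds only.
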