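# Methods

This note documents the models, numerical choices and known limitations of
`ribbonca`, in the order data flows through the package.

## Reaction–diffusion model

**Domain.** A rectangular box of (1.28 × 1.28 × 1.1) µm³ voxelized at 20 nm
(default), representing the synaptic-terminal volume available to one
ribbon.  The bottom face is the plasma membrane.  The ribbon is a full
ellipsoid (semi-axes 70 nm laterally, 190 nm along its long horizontal
axis and 190 nm vertically, total height 380 nm) resting on a ridge
(arciform density) of 30 × 60 × 30 nm; both are reflecting obstacles that
carry no concentration state.  The ridge's long edge runs along the
ribbon's long horizontal axis — the orientation in which the arciform
density underlies the ribbon — which also keeps the proximal probe
position (20 nm lateral, 10 nm high, ≈45 nm from the nearest channel
cluster) in free solution.  The ribbon base centre is snapped to the
voxel centre nearest the box centre so the default layout is
mirror-symmetric on the grid.

**Sources.** Four channel clusters sit at the corners of an 80 nm square
centred under the ribbon; each admits a quarter of the total current
(default 1 pA for 10 ms).  A current I pA of divalent ions corresponds to
I·10⁻¹⁵/(2e) ≈ 3121·I ions/ms, injected as a boundary flux into the
single bottom-face voxel nearest each cluster.  A face source rather than
a volume source keeps the ~45 nm probe geometry meaningful.

**Buffers.** Single-site buffers with mass-action kinetics; k_off is
always derived as k_on·K_D.  Defaults: immobile endogenous buffer K_D
2 µM, 1.44 mM (capacity 720 at rest), k_on 0.1 µM⁻¹ms⁻¹; EGTA K_D
0.18 µM, k_on 0.0027 µM⁻¹ms⁻¹; BAPTA K_D 0.22 µM, k_on 0.4 µM⁻¹ms⁻¹;
mobile chelators diffuse at 0.2 µm²/ms (bound and free forms alike).
The endogenous on-rate and the chelator values are standard literature
figures; all are overridable per config.  Ca²⁺ diffusivity is 0.22
µm²/ms and the resting level 0.1 µM.

**Clearance.** Each outer surface extrudes Ca²⁺ by two saturable terms (a
high-capacity/low-affinity exchanger, A_NCX = 0.1 µM·µm/ms, K_NCX = 10 µM,
and a low-capacity/high-affinity pump, A_P = 0.01 µM·µm/ms, K_P = 0.2 µM)
with Hill coefficient 1 on the membrane face and 2 elsewhere, minus a
constant leak fixed so the net flux vanishes at rest.  The magnitudes are
deliberately small: clearance is negligible over a 10 ms pulse and only
shapes the field on the 100 ms scale, consistent with the insensitivity
of short-pulse microdomains to extrusion assumptions.  The resting state
is therefore an exact fixed point of the discrete scheme (verified to
<10⁻³ µM over 20 ms).

**Numerics.** Strang splitting per time step (default 10 µs):
a half-step of the reaction network, solved implicitly per voxel — for
fixed new Ca²⁺ each bound-buffer update is closed-form linear, so
per-voxel conservation reduces the whole network to one monotone scalar
equation solved by safeguarded Newton iteration; then implicit
locally-one-dimensional diffusion (three tridiagonal sweeps with
per-line conductances that vanish across obstacle and boundary faces,
factorizations cached); then the second reaction half-step.  Source
influx and extrusion are applied explicitly — both are slow relative to
the step.  The scheme is unconditionally stable; numba-compiled kernels
accelerate the Thomas sweeps and the Newton loop, with identical
pure-numpy fallbacks.  Divergence (non-finite or >10⁷ µM) aborts with a
diagnostic.

Validation: sealed-box mass conservation tracks the injected charge to
<1 %; the buffer-free field around a single centred source matches the
half-space point-source closed form C₀ + σ/(2πDr) within 15 % for
r = 50–200 nm, sampled at 1 ms — inside the quasi-steady window of the
closed box (late enough for the near field to equilibrate, early enough
that reflected accumulation stays small); halving the grid from 20 to
10 nm moves the proximal peak by ~3 %.

**Probes.** Config-specified points relative to the ribbon base centre,
sampled by trilinear interpolation with obstacle corners dropped and
weights renormalized; a probe inside an obstacle is rejected.  The five
defaults run from the proximal microdomain (20, 0, 10) nm up along the
ribbon flank to the cytosol; the non-proximal positions are this
package's choice — only the proximal location is pinned by the ≈45 nm
cluster distance.

## Synthetic imaging

The generator's conditions are the study conditions: full-size box, 1 pA /
10 ms, the buffer mixes of the chelator-loading experiments, 256-pixel
lines at 1.51 ms/line/channel (3.02 ms between same-channel lines), PSF
FWHM 268/273/561 nm, and high-/low-affinity indicators (K_D 0.32 / 90 µM)
in free or ribbon-anchored form.  Scenario simulations run at 30 nm / 20
µs — the coarsest resolution that still resolves every geometry feature —
so a fixture generates in tens of seconds; the headline numbers always
come from 20 nm runs.

Dye kinetics are post-processed from the free-Ca²⁺ field movie (frames
every 0.5 ms): per voxel the scalar binding ODE is advanced by its exact
exponential relaxation between frames, so no sub-stepping is needed; free
dye additionally diffuses (0.1 µm²/ms), anchored dye does not.  The dye
does not feed back on the Ca²⁺ field — with tens of µM of indicator
against a 1.44 mM endogenous buffer the added buffering is a few percent
of the total capacity.  Dye on-rates (0.45 / 0.1 µM⁻¹ms⁻¹) and the
intracellular dye concentration (50 µM) are package defaults, as the
dialysed concentrations are not printed; the dynamic range R_f defaults
to 100 (typical for this dye family) and is flagged to users wherever a
single-wavelength conversion depends on it.

The scan line crosses the membrane perpendicular through the ribbon
centroid, starting 0.4 µm outside the cell, giving ~5.9 nm pixels over
256 samples.  Because that line lies in the microscope's imaging plane,
the lateral FWHMs are applied along the line and across it, and the
axial FWHM along the optical axis perpendicular to the plane.  Beyond
the box the terminal continues, so the blur extends boundary values
outward ("nearest"), except below the membrane where dark extracellular
space is padded in explicitly.  The marker channel renders the labelled
ribbon itself (ribbon voxels at 2× the cytoplasmic background — a
moderate labelling contrast at which membrane and centroid round-trip
within one pixel) and the ground truth records the membrane crossing,
the blurred-bump centroid, the unblurred probe peaks, and the region
amplitudes a noise-free measurement of the same raster would report.
Photon noise is pure Poisson at a stated baseline budget (default 50
counts/pixel ≈ 20 dB at the rendered amplitudes); there is no read
noise, bleaching, galvo distortion or channel bleed-through.

What passing round-trip tests show — and what they do not: recovery is
demonstrated against data generated by this same forward model, so it
validates the fitting chain's correctness and noise robustness, not the
realism of confocal imaging beyond the modelled effects.

## Line-scan fitting

**Spatial model.** f(x) = s(x) + a·exp(−(x−x₀)²/w²) with the saturating
sigmoid s(x) = b − c/(1 + exp((x_½ − x)/d)).  A sigmoid that transitions
between an intracellular plateau b and an extracellular level b − c with
midpoint x_½ is the only bounded reading of the edge model — an
exponential-shoulder form diverges on the intracellular side and cannot
represent profiles with an interior plateau.  Both signs of d are
explored (either scan orientation fits) and two membrane seeds are tried
(background mid-crossing and steepest gradient); among converged
candidates the best residual wins, subject to one physical constraint:
the emitter must lie on the intracellular side of the membrane, which
rejects a degenerate mode in which the Gaussian impersonates the cell
edge.  With the PSF given, w is constrained to 0.8–2.5× the PSF-limited
width, leaving x_½ and x₀ as the effectively free parameters.  Fits are
flagged (never silently returned) when the bump or the edge is within
the noise floor.

**Windows.** Five pixels (0-based, cytoplasm at increasing index):
proximal centred at the midpoint of (x_½, x₀) rounding toward the
membrane — shrinking to the available gap with a floor of 3 pixels when
the membrane-centroid separation is narrow — distal immediately past x₀,
cytoplasmic one window further; windows are clipped to the scan with a
warning.  ΔF/F_rest uses the spatiotemporal mean of the same window over
the 20 lines (default) before stimulus onset.

**Kinetics.** The rise is fit by a logistic whose plateau is the peak
amplitude; the peak index is found on a 5-point smoothed copy and the
fitted segment extends across the whole plateau (all samples within the
noise band of the maximum), so a single noise excursion can neither
truncate nor bias the fit.  The decay is the constrained bi-exponential
(weights summing to 100 %, τ_fast ≤ τ_slow by construction, τ ∈ [1, 1000]
ms) minimized by differential evolution restarted from seeded initial
populations — 400 restarts by default, best-of-restarts polished —
making identical seeds bit-reproducible.  Fits with τ_slow/τ_fast < 3
are flagged "poorly-identified": bi-exponential decomposition is
ill-conditioned and such pairs should not be interpreted.

**Calibration.** Ratiometric: [Ca²⁺] = K_eff (R − R_min)/(R_max − R),
rejecting R outside [R_min, R_max).  Single-wavelength: F ∝ 1 +
(R_f − 1)·C/(C+K) anchored at the resting concentration, inverted
exactly; implied occupancy ≥ 1 raises a saturation error naming the
largest resolvable ΔF/F_rest.  Defaults K_eff 0.795 µM, dye K_D 0.32 /
90 µM.

## Morphometry

Centre-to-centre distances between traced ribbon centroids; cross-layer
pairs use √(in-plane² + (Δlayer · 50 nm)²).  Nearest-k tables are
per-ribbon directed listings (deduplicated unique-pair counts are also
emitted, since a directed listing of k = 5 neighbours over three cells
is what yields hundreds of comparisons); close-pair fractions are
reported to one decimal percent.  SEM is the sample SD over √n.

## Reproducibility

Every CLI run writes a JSON manifest (command, config echo, seeds,
versions).  A single root seed fans out to per-stage seeds through
`SeedSequence` with stable stage tags, so re-running one stage reproduces
its stream; all seeds stay below 2³¹.  The solver itself is
deterministic — the config's `seed` field is provenance only.

## Known limitations

- No stochastic channel gating, vesicle fusion, ER/mitochondrial fluxes,
  or vesicles as diffusion obstacles.
- Dye does not feed back on the Ca²⁺ field (see above).
- Exchanger/pump densities are order-of-magnitude placeholders; results
  for pulses ≳100 ms depend on them and should not be trusted without
  calibrating the extrusion parameters.
- The imaging model omits read noise, bleaching and spectral
  bleed-through; scan lines are sampled instantaneously per line (no
  intra-line pixel dwell).
- Bi-exponential decay parameters are descriptive, not identifiable, at
  realistic noise; the fitter's flags are the contract.
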