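# ribbonca

Quantitative "nanophysiology" of Ca²⁺ microdomains at retinal bipolar-cell
ribbon synapses: a buffered 3D reaction–diffusion simulator of the [Ca²⁺]
field around a single synaptic ribbon, a synthetic confocal line-scan
generator with known ground truth, the dual-channel x-t scan fitting
pipeline used to localize the ribbon and extract proximal/distal Ca²⁺
kinetics, ratiometric calibration, and serial-section ribbon-distance
morphometry.

## Who this is for

Synaptic physiologists and modellers who measure local Ca²⁺ transients at
ribbon active zones with line-scan confocal imaging and want to (a) predict
the free-[Ca²⁺] field that a given channel arrangement, buffer load and
current produce, (b) understand what their microscope's point-spread
function does to that field, and (c) run the standard fitting chain
(Sigmoid-Gaussian localization → region ΔF/F traces → rise/decay kinetics
→ [Ca²⁺] calibration) on real or synthetic rasters.

## The model

Free Ca²⁺ `C` and each single-site buffer (bound form `CaBᵢ`) obey

    ∂C/∂t    = D_C ∇²C − Σᵢ [k_on,i C Bᵢ − k_off,i CaBᵢ]
    ∂CaBᵢ/∂t = Dᵢ ∇²CaBᵢ + k_on,i C Bᵢ − k_off,i CaBᵢ

in a (1.28 × 1.28 × 1.1) µm³ box — the terminal volume per ribbon for a
5 µm bouton with 36 ribbons.  An ellipsoidal ribbon (semi-axes 70/190/190
nm) on a 60 × 30 × 30 nm ridge is a reflecting obstacle; Ca²⁺ enters
through four channel clusters on an 80 nm square under the ribbon base
(each carrying a quarter of the 1 pA total current for 10 ms) and leaves
through saturable surface extrusion

    Φ_Ca(C) = A_NCX·C/(K_NCX+C) + A_P·C^m/(K_P^m+C^m) − Φ_Leak ,

with Hill coefficient m = 1 on the membrane face (PMCA-like) and m = 2
elsewhere (SERCA-like); the constant leak Φ_Leak zeroes the flux at the
0.1 µM resting level.  The default buffer is 1.44 mM immobile endogenous
buffer (K_D 2 µM, buffering capacity 720), with EGTA/BAPTA mixes for the
chelator-loading conditions.

The imaging model converts the simulated field to indicator occupancy
(per-voxel binding kinetics, K_D 0.32 µM or 90 µM, free or ribbon-anchored
dye), renders fluorescence F ∝ 1 + (R_f − 1)·occupancy, blurs with the
Gaussian PSF (FWHM 268/273 nm lateral, 561 nm axial), samples interleaved
two-channel lines at 1.51 ms/line/channel across the membrane, and adds
Poisson photon noise.

The fitting side mirrors the experimental analysis: spatial profiles are
fit with f(x) = s(x) + g(x), a cell-edge sigmoid (midpoint x_½ = membrane)
plus a Gaussian (centroid x₀ = ribbon, width w ≈ PSF); five-pixel windows
between x_½ and x₀ (proximal), past x₀ (distal) and beyond (cytoplasmic)
give ΔF/F_rest traces; rises are fit by a logistic, decays by a
bi-exponential with a_fast + a_slow = 100 % found by seeded
differential-evolution restarts (400 by default); the Grynkiewicz relation
[Ca²⁺] = K_eff (R − R_min)/(R_max − R) converts ratios to concentration.

Morphometry: ribbons traced in 50 nm serial sections are compared with the
Pythagorean combination of in-plane distance and layer offset; the package
reports per-ribbon nearest-k distance tables, close-pair fractions and
per-cell nearest-neighbour summaries.

## Worked example

Generate a synthetic scan of the reference condition (1.44 mM endogenous
buffer + 0.2 mM EGTA, ribbon-bound low-affinity dye), fit it, and score
the round trip:

```bash
ribbonca recover --scenario egta-0.2 --seed 7 --out report.json
# egta-0.2: PASS []
```

The report (abridged):

```json
{
  "fitted_x_half": 0.3883,   "true_membrane": 0.4,
  "fitted_x0":     0.6438,   "true_centroid": 0.6174,
  "fitted_peaks": {
    "proximal":    3.556,
    "distal":      0.951,
    "cytoplasmic": 0.576
  },
  "proximal_error": 0.037,
  "passed": true
}
```

Reading it: the membrane was localized at 0.388 µm along the scan line
(truth 0.400 — within two 5.9 nm pixels) and the ribbon centroid at 0.644
µm (truth 0.617).  The fitted proximal peak ΔF/F_rest of 3.56 recovers
the generator's noiseless value within 3.7 %, and the proximal/distal
ordering (3.56 vs 0.95) reproduces the steep Ca²⁺ gradient along the
ribbon axis.  The same simulation's unblurred probe values are far apart
(≈83 µM proximal vs ≈1 µM at the ribbon top): the PSF compresses the
true gradient, which is why imaged ratios are always smaller than
simulated ones.

Other entry points: `ribbonca simulate --config sim.yaml --out run.h5`
(probe traces + snapshots), `ribbonca synth --scenario bapta-2 --seed 3
--out fixtures/`, `ribbonca fit --raster scan.tif --out results/`,
`ribbonca morph --sites sites.csv --out morph/ --threshold 0.27`.

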