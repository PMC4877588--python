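# Methods

## Equivalent-circuit model

The microfluidic device is modeled as a single series loop across its
five parallel compartments plus the two electrode channels:

    R_e — Z_pdms — R_media — R_gel — R_media — Z_pdms — R_e

Every compartment conducts across its width w with the shared
cross-section A = channel height × region length, so ohmic elements are
R = ρ·w/A. Each PDMS wall is a resistor–capacitor pair in parallel,

    Z_pdms = R_pdms / (1 + i·2πf·R_pdms·C_pdms),

with R_pdms from the bulk resistivity and C_pdms = ε₀·εr·A/w_wall as a
parallel-plate capacitor. The transfer ratio is the series voltage
divider T(f) = Z_gel / Σ_k Z_k, the gel field is E = |V_in·T| / w_gel,
and the design inverse V_in = E_target·w_gel / |T| is analytic because
the network is linear.

Default parameters (all configurable): ρ_electrode = 1.67×10⁻⁵ Ω·m
(silver-PDMS composite), ρ_media = 0.67 Ω·m, ρ_gel = 800 Ω·m (collagen),
ρ_pdms = 1.2×10¹² Ω·m; gel width 1.3 mm, media channels 500 μm, PDMS
walls 150 μm, electrode channels 500 μm, channel height 120 μm. εr for
PDMS defaults to 2.75, a typical literature value for the cured
elastomer. The region length (default 10 mm) cancels exactly in T(f)
because every impedance scales as 1/A; this invariance is tested.

Numerical behaviour of the defaults: R_gel ≈ 8.7×10⁵ Ω dominates the
resistive chain (electrodes ≈ 7 mΩ, media ≈ 279 Ω each), so the
high-frequency limit of |T| is R_gel/(2R_e + 2R_media + R_gel) ≈ 0.999.
The wall capacitance is ≈ 1.9×10⁻¹³ F, placing the RC corner of the
divider near 1 GHz: at the 150/200 kHz operating points the walls are
still strongly capacitive and |T| ≈ 0.08–0.11, giving required input
amplitudes of ≈ 1.8 V (150 kHz) and ≈ 1.36 V (200 kHz) for 1.1 V/cm.
Reaching the resistive limit at 100 kHz would require an effective wall
capacitance two orders of magnitude above the parallel-plate value
(εr ≈ 370) — possible only if the wall is not a solid dielectric slab
(e.g. posts with conductive gaps), which this model deliberately does
not assume. At DC the walls block the loop entirely (|T| ≈ 3×10⁻⁹).

Voltage convention: V_in and field targets are sinusoidal amplitudes;
an `rms` flag converts generator specifications quoted as RMS by √2.
Both PDMS walls and both electrodes are modeled individually in a
symmetric 7-element chain; media and gel are separate resistors so that
V_gel is the drop across the gel element alone.

## Nuclei-table statistics

For N nuclei at positions pᵢ the aggregate center is the per-axis mean
p̄ and the dispersion is the population RMS 3D distance

    Δ = √( (1/N) Σᵢ ‖pᵢ − p̄‖² ),

with Δ/Δ₀ normalized to the 0 h value. The 1/(N−1) per-axis-variance
convention is available via `ddof=1`; the two differ by √(N/(N−1)),
which cancels in Δ/Δ₀ for comparable N, so the normalized readout is
convention-robust. Δ is rigid-motion invariant and homogeneous of
degree 1 under isotropic scaling (property-tested). Aggregates with
fewer than 3 nuclei at any timepoint are excluded from dispersion
summaries and logged.

Proliferation rate is 100·(N_t − N₀)/N₀ counting all labeled nuclei of
the tracked aggregate (dead nuclei are retained in the tables, as a
cell-impermeant dead-nucleus dye stains them in place, and are counted
in densities and positivity denominators). Cell density is count/volume
over axis-aligned ROI boxes (half-open on the max side so tiling ROIs
never double-count). Positivity is the percentage of flagged nuclei.

Group comparisons use the two-tailed unpaired t-test: pooled variance
(df = n₁+n₂−2) by default, Welch–Satterthwaite for endpoints with
unequal variances (ELISA-like cytokine concentrations). The statistics
are computed by scipy; independently hand-coded formulas serve as test
oracles. Raw p-values are reported without multiplicity correction,
matching the field's reporting convention for these assays; a Holm
step-down helper is provided but off by default. The unit of
replication is the device (ROI values are averaged per device first);
per-ROI pooling is available as a switch since either choice is
defensible.

## Synthetic-data generator

The generator emulates the study's three preparations as seeded point
processes:

* **Aggregates**: n₀ = 80 nuclei uniform in a sphere of radius
  r₀ = 30 μm (within the 40–100 μm diameter range of sieved spheroids).
  Each hour every live nucleus takes an isotropic Gaussian step
  (step_sigma, μm/√h) plus an outward radial drift (μm/h), divides with
  probability p_div (daughter placed 5 μm away in a random direction,
  no volume exclusion) and dies with probability p_die (flagged dead,
  frozen in place). Snapshots at 0/24/48/72 h.
* **Dispersed culture**: Poisson seeding at 300 cells/mm³ (3×10⁵
  cells/ml) in a 1.3 × 3 × 0.12 mm gel slab, same birth–death walk,
  reflecting boundaries (clipping would pile cells exactly on the faces
  where half-open ROIs no longer count them). Density is read per
  random 350 × 350 × 120 μm ROI, 3 ROIs × 3 devices.
* **Endothelial monolayer**: a 10 μm planar band of 400 nuclei at the
  gel–channel interface; only marker fractions are scored.

Markers (Ki-67, caspase-3/7) are Bernoulli flags drawn independently
per nucleus at each output timepoint; dead nuclei never stain for
activity markers.

### Calibration

Division rates are solved from (1+p_div)^t − 1 = target at t = 72 h:
50.77% (stimulated) and 142.10% (control) for aggregates, and from the
72 h density contrast ~1000 vs ~2000 cells/mm³ for the dispersed
culture. A single exponential rate cannot match the 48 h and 72 h
targets simultaneously; calibrating at 72 h implies 48 h expectations
of ≈ 31% and ≈ 80%. Marker probabilities are the published positivity
fractions /100 (lung-carcinoma aggregates: Ki-67 2.38%/37.54%,
co-culture endothelium 6.40%/7.65%; breast-carcinoma dispersed culture:
Ki-67 27.37%/25.94%, caspase 49.20%/23.88%; endothelium caspase
13.04%/11.47%). Dispersion kinetics — step 0.8 μm/√h in both arms,
drift 0.35 (control) vs 0.12 μm/h (stimulated) — were chosen once to
produce a progressive increase in Δ/Δ₀ with the control arm clearly
exceeding the stimulated arm at 72 h (≈ 2.15 vs ≈ 1.47); the cytotoxic
positive-control arm (p_die = 0.05/h, no drift) neither grows nor
disperses. The random-walk-plus-drift motility model is an invented
stand-in — the real study measures dispersion rather than modeling
it — and is labelled as such in every `truth` record.

### What the generator does and does not emulate

It reproduces the count statistics, marker fractions and
condition-dependent dispersion that the quantification pipeline
consumes, so passing tests demonstrate that the pipeline recovers known
ground truth without bias. It does not emulate real confocal imaging
artifacts (touching nuclei, anisotropic PSF, bleaching), cell–cell
mechanics, chemotaxis, or mechanistic TTF action on microtubules, so
the tests say nothing about segmentation robustness on real stacks
beyond the rendered-blob regime. One consequence worth noting: because
daughters stay near their founders, dispersed-culture cells arrive in
lineage clusters and per-ROI counts are strongly overdispersed relative
to Poisson (per-replicate density SD ≈ 20%); estimates are therefore
averaged over replicates.

## Imaging front-end

Global threshold → 26-connected components → components ≥ min_voxels
become nuclei with intensity-weighted centroids at voxel centers
(physical μm, origin at the stack corner). Marker classification
averages the marker channel in a ball around each centroid. No
watershed splitting or adaptive thresholding: adequate for the
synthetic fixtures' non-touching nuclei; touching-nuclei resolution is
a known limitation. The render → segment round trip recovers counts
within 2% and Δ within 5% for non-touching nuclei and is fully
deterministic given the stack.

## Pipeline and reproducibility

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawns (per device × condition), so reruns
are byte-identical and device tables are statistically independent.
The report bundle (circuit solution, tidy summaries, pairwise
comparisons, optional figures) carries a manifest with per-file SHA-256
hashes. Simulated problem sizes (3 devices × 3 ROIs, 80-nucleus
aggregates, 100–300 Monte-Carlo replicates in the acceptance script,
1000 null experiments for the type-I calibration) were chosen so that
Monte-Carlo standard errors are ~1% of each estimate while a full test
run stays inexpensive on a single CPU.

## Known limitations

* The circuit model is zero-dimensional: no spatial field maps, no
  electrode electrochemistry, no thermal effects.
* The wall capacitance assumes a solid parallel-plate dielectric; real
  devices with segmented walls (posts) couple more strongly.
* Touching nuclei are merged by the segmenter.
* The motility model is phenomenological; parameter values for it are
  plausible-scale choices, not fits to trajectory data.
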