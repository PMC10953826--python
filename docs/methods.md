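# Methods

## The assay being modeled

Mouse pancreatic acinar organoids are seeded in Matrigel in 384-well plates
at a density targeting ~50 organoids per well. In *inhibition* mode the
organoids are treated immediately, before acinar-to-ductal metaplasia (ADM)
occurs; by 72 h untreated wells consist mostly of duct-like organoids
(ring-shaped, with a lumen) with ~10% compact acinar clusters remaining. In
*reversal* mode treatment starts after ADM has completed, and vehicle wells
hold ~5% clusters. Wells are imaged in a brightfield-like morphology channel
and a green calcein-AM channel (live cells only); the screen readout is the
percentage of live cluster-like organoids among all live objects. An
effective compound raises that percentage.

## Synthetic-data generator

The generator is first-class, tested code: its defaults define the study
conditions everything downstream is validated against.

**Compound library.** A deterministic 144-entry fixture mirrors the
composition of a commercial epigenetic modulator library: 34 Zn²⁺-dependent
and 9 NAD⁺-dependent HDAC inhibitors plus BET/DMT/HDM/HMT/HAT/PARP/other
classes. Ground-truth effects are parameterized directly on the readout
scale (percentage points added to expected % live clusters per mode) rather
than mechanistically, so every downstream estimate has a closed-form target.
Six compounds are active in inhibition mode (chaetocin, apicidin, IBET151,
OTX015, 3-deazaneplanocin A, B32B3), of which four are strongly cytotoxic
(`cytotox_frac = 0.6`); three are active in reversal mode (chaetocin,
apicidin, tubastatin A), with tubastatin A cytotoxic. All other compounds
have zero effect and cytotoxicity ≤ 0.2. A TSA-like positive control
(not part of the 144) drives ~90% of organoids to the cluster state.

**Effect sizes.** Designed shifts are sized so every true effect carries
Cohen's d ≥ 4 on the per-well readout. For fully viable compounds the
readout SD is ~5 points (3-point well jitter plus binomial counting noise at
~50 objects) and shifts of +50 to +60 give d ≈ 10; for the cytotoxic decoys
only ~20 objects are live, the counting SD grows to ~11 points, and their
shifts are +50 so that d ≈ 4.4. At n = 4 replicate wells this makes
detection of true effects essentially certain (observed power > 0.99),
which is what lets the screen tests assert the designed structure exactly.

**Cytotoxicity level.** The cytotoxic decoys use `cytotox_frac = 0.6`
rather than a value just past the 0.5 boundary: with ~50 objects per well
the within-well live fraction has SD ≈ 0.07, and a true dead fraction of
0.55 would cross the 50% viability floor in ~8% of 4-well averages, making
the designed exclusion count unstable. 0.6 keeps the gate deterministic in
practice while still modeling ">50% cytotoxicity".

**Well noise model.** Expected % clusters = mode baseline + compound shift.
A per-well Gaussian jitter (default SD 3 percentage points) models
replicate-to-replicate variability; near the 0/100 boundaries the jitter SD
is shrunk to (distance to boundary)/3 so that saturated expectations are
recovered without clipping bias (plain clipping of N(100, 3) would bias the
mean ~1.2 points low). Object count is Poisson(50); each object's class and
viability are independent Bernoulli draws. Death is independent of class,
so cytotoxicity alone never shifts the class mix — the reason a cytotoxic
inert compound cannot fake criterion i.

**Rendering.** Object tables can be rendered to (2, H, W) uint16 frames
(default 768×768; the 15 microscope fields of a real well are collapsed
into one pre-stitched frame). Clusters are berry-like unions of disks
(radius ~10 px), ducts are annuli with lumen radius = outer radius/2
(radius ~16 px, scaled by each compound's duct-size factor); live objects
carry green-channel signal. Objects are placed on a jittered grid so
footprints never overlap; a Gaussian PSF (σ 1.2 px) and Gaussian noise
finish the image. Pixels are 0-based, row-major, origin top-left.

**qPCR and DE tables.** CT values invert the 2^−ΔΔCT model:
CT = baseline(gene) − log2 effect + per-sample offset + N(0, 0.15 cycles),
with the offset shared across a sample's genes (it cancels in ΔCT) and 18S
as the reference. DE tables draw acinar genes at +strength, ductal/PDAC
genes at −strength and background genes at 0 (log2 scale, SD 0.3), with
FDR values derived from the effect sizes via a z-statistic and
Benjamini–Hochberg adjustment so larger effects always carry smaller FDR.

**What the generator does not emulate.** Real optics and Matrigel texture,
touching/overlapping organoids, plate-edge effects, the cyst-like
morphology of Kras-mutant cultures, amplification-efficiency differences
between qPCR assays, and count-level RNA-seq. Passing round-trip tests
therefore demonstrates that the analysis chain is correct and calibrated
against its own contracts — not that the segmentation or classifier would
reach the same accuracy on real microscopy.

## Imaging stage

Segmentation is Gaussian smoothing (σ 1 px), a global Otsu threshold, and
connected components; objects under 60 px² are dropped and holes under
16 px² are filled (real lumens are far larger). There is **no declumping**:
touching organoids count as one object, a documented limitation matching
the non-overlapping generator. An Otsu threshold that fails to clear the
background distribution (median + 3 robust SD) is treated as an empty well
rather than thresholding noise. Shape features use the Crofton perimeter
estimate, which keeps a digital circle's form factor at ~1.0 regardless of
radius (the polygonal estimate drifts to ~0.92 by r = 50).

Classification is a fixed, inspectable rule — duct iff lumen_ratio ≥ 0.08,
or (area ≥ 1200 px² and solidity ≤ 0.80) as a fallback for ducts whose
lumen closed during imaging — with thresholds set once against the
generator's geometry. A small decision tree trained on labeled synthetic
objects is available for parity with learned-classifier workflows.
Viability is per-object and binary: live iff ≥ 50% of the object's pixels
exceed the green background (median + 5 robust SD of the whole channel, a
cut that stays meaningful in wells where every object is dead).

## Screen statistics

Per well, duct/cluster percentages are computed over live objects only
(they sum to 100), the total-cluster percentage over all objects, and
viability as the live fraction. Wells with no live objects are flagged and
excluded from group means with a warning, never imputed.

Compounds are compared to their own plate's four vehicle wells with the
two-tailed Welch (unequal-variance) t-test. Significance is
direction-gated: p ≤ 0.05 counts only when the treated mean exceeds the
vehicle mean. No multiple-testing correction is applied across the 144
compounds — a deliberate fidelity choice to the assay's published analysis.
Consequence: each inert compound has a ≈2% chance of passing both
morphology criteria in a given realization, so a full screen typically
contains two to three false-positive hits alongside the designed ones. The
package reports this honestly rather than suppressing it; the error-control
tests bound the per-compound false pass rate at the theoretical ≤5%, and
the designed structure (6 significant / 4 excluded / 2 prioritized in
inhibition; 2 hits in reversal) is asserted over the designed compounds.

Criterion iii is within-well: mean live fraction ≥ 0.5. The
vehicle-relative viability ratio is carried as a diagnostic column only.
Plate quality is the Z'-factor, 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|,
computed from vehicle and TSA-like positive-control wells; > 0.5 is the
screen-ready bar and simulated plates land at ~0.6. Because the sample SD
of four wells is itself noisy (CV ≈ 40%), a single-plate Z' estimate has
SD ≈ 0.11; assay-quality claims therefore average the plate Z' over many
simulated plates rather than trusting one draw.

## Dose–response

The 4PL model is fit by unweighted least squares. Since the model is linear
in (top, bottom) once (hill, IC50) are fixed, those two are profiled out
analytically and the nonlinear search runs over (|hill| ∈ [0.1, 10],
log10 IC50 ∈ dose range ± 2 decades) from a coarse grid followed by bounded
least squares — variable projection. This makes noiseless recovery exact to
machine precision and removes the local-minimum failures a naive
four-parameter multi-start suffers on plateau-heavy designs. After fitting,
parameters are canonicalized to bottom ≤ top with the hill sign carrying
orientation (hill < 0: response rises with dose). Fits at the IC50 search
boundary or on flat data are flagged `converged=False`, never silent.

The low-nM recovery benchmark (true IC50 16 nM, SD 3 points, quadruplicate
wells) uses an 8-point 3.16-fold series from 10 µM down to ~3.2 nM. The
conventional 6-point 32 nM–10 µM series leaves a 16 nM IC50 below the
lowest tested dose, where no free-hill least-squares fit pins it down
(median relative error > 60%); bracketing the IC50 — as any potency
determination would — brings the median error to ~6%. The default 6-point
series itself keeps the 3.162 step so that both conventional endpoints
(10 µM top, ~32 nM bottom) are honored exactly.

## Molecular index

ΔΔCT aggregation averages ΔCT on the cycle scale and then exponentiates
(the standard presentation); a per-replicate mode (exponentiate first, then
average) is available behind a flag. The ADMRI is the ratio of arithmetic
means of linear fold changes, acinar (Amy2a, Cela1, Cpa2) over ductal
(Krt19, Krt7, Sox9); all six genes must be present — the index refuses to
silently subset. It is homogeneous of degree 1 in the acinar set and −1 in
the ductal set, so a large value can reflect a one-sided change; rankings
are dense per dose group with ties sharing a rank and listed in compound-id
order. The packaged volcano panel keeps the published sizes (27 acinar,
23 ductal/PDAC) and the six qPCR genes, filled out with canonical mouse
acinar- and ductal-identity symbols; the supplementary identities are not
public, so the panel is user-replaceable by file and only its sizes and the
six anchors are contractual.

## Reproducibility

Every stochastic routine takes a seed; per-well streams are derived from
the run seed via counter-based `SeedSequence` keys (mode, compound slot,
replicate), so adding wells or reordering loops never perturbs existing
draws, and a run re-executed from its emitted config is bit-identical at
the object-table level. Tables are written with 6-significant-digit floats
to make identical runs byte-identical. Problem sizes in the test suite
(e.g., 6–20 rendered wells, 100-seed error-control loops, 200-fit IC50
benchmarks) were chosen as the smallest scales at which the asserted
statistics are stable.
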