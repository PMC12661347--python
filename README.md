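# catrack

Longitudinal two-photon calcium imaging analysis: cross-day 3-D field
alignment, cell detection and component screening, ΔF/F computation,
assignment-based cell matching across sessions, trial-aligned activity
maps, and glial immunostain quantification — together with a
ground-truthed synthetic-data generator so that every stage is
verifiable at desk scale, without any animal data.

## Who this is for

Labs that image the same cortical population across days or weeks (e.g.
GCaMP-expressing neurons in mouse parietal or prefrontal cortex through a
cranial window) and need to (1) return the microscope to the same imaging
volume on each session, (2) extract per-cell activity, (3) decide which
cell on day N is which cell on day N+k, and (4) relate activity to
behavioral events — plus the histology counterpart of quantifying glial
markers (Iba1, GFAP) around an injection site.

## The methods at the core

**Axial/lateral realignment.** A structural (nuclear) channel is imaged
as a stack over objective offsets z ∈ {+30, +25, …, −30} μm. The top
plane at each Z is cross-correlated with the reference top plane; the
best (dx, dy) comes from the Z with the highest correlation. The shifted
stack's correlation c(z) is then fit with a linear-offset Gaussian

&nbsp;&nbsp;&nbsp;&nbsp;c(z) = a·exp(−(z − μ)² / 2σ²) + b,

and μ is the axial shift. The objective is adjusted and the procedure
repeats until |dx|, |dy|, |dz| are each < 5 μm.

**Cell detection and screening.** Mean projections are brightness
corrected (divided by their 25×25 px median filter), masks extracted by
adaptive thresholding with morphological cleanup, and traces seeded from
the masks with a rank-1 global background. Each trace is deconvolved
under the AR(1) transient model c(t) = γ·c(t−1) + s(t) with nonnegative
sparse spikes s. Components are screened by an SNR scored against a
gamma (not Gaussian) noise null, and by the spatial-consistency r-value;
SNR > 1.2 or r > 0.85 accepts, SNR < 0.5 or r < 0.1 rejects regardless
of the other metric.

**ΔF/F.** Two variants: (i) detrend the denoised trace by its moving
8th percentile (500-frame windows), set F0 = detrending residual + the
background component's moving 8th percentile under the mask, and divide
(unitless); (ii) the simple variant ΔF/F0 = (F − F0)/F0 × 100 with a
blood-vessel background subtraction and F0 from a ~2 s inactive stretch.

**Cross-session matching.** A piecewise-rigid map transfers masks into
the other session's frame; cells are paired by linear sum assignment
with cost = 1 − IoU (cost forced to 1 beyond a 10 px centroid gate),
keeping pairs with cost < 0.8.

**Trial maps.** ΔF/F is averaged into time bins before each trial's
choice moment, min-max normalized to [0, 1] per cell, and cells sorted
by peak bin — with matched cells shown in both sessions under the first
session's ordering.

**Histology.** Line-profile intensities, Otsu (or manual) threshold →
watershed → size-filtered particle counts (minima 5 px² Iba1 / 10 px²
GFAP), expression index = count/area × 10,000, four-section animal
averages, and per-cell multichannel Pearson correlations on z-scored
intensities.

## Worked example

The `analysis/` scripts run the whole pipeline on one simulated
"animal" (two sessions ~4 weeks apart with (9, −6, 8) μm drift and 20%
cell turnover). For instance:

```bash
cd analysis
python 01_simulate.py
python 02_align.py
python 05_match.py
```

prints

```
True drift (9.0, -6.0, 8.0) um; recovered (9.0, -6.0, 6.17) um in 2 iteration(s); converged=True.
Residual error (x, y, z): (0.00, 0.00, 1.83) um — the loop stops once each per-iteration shift is below 5 um.
...
Sessions share 16 of 20/20 cells (ground truth).
Matching kept 16 pairs (cost < 0.8); 16 agree with ground-truth identity (100% precision).
Session-unique: 4 in A, 4 in B.
```

i.e. the closed alignment loop recovers the drift to within its 5 μm
stopping rule in two passes (XY exactly, Z to 1.8 μm — half the 5 μm
stack step is the attainable resolution), and the IoU-cost assignment
recovers every persistent cell with no false pairs. `04_dff.py` reports
peak ΔF/F recovered with ~3% median relative error against the
generator's true amplitude/baseline ratios, and `07_histology.py`
recovers all four sections' true cell counts with the GFAP size
minimum. Tables land in `results/`.

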