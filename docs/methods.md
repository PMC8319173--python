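# Methods

## The measurement being modelled

One well of a 384-well screening plate holds macrophages expressing a
fluorescently tagged ASC adaptor. After LPS priming and nigericin
activation, 35–50% of cells condense the reporter into one bright
speck of roughly 1 µm. Each well is imaged at 10x in two channels
(nuclear stain, reporter) over two fields, and the readout is the
percentage of cells with at least one speck. Plates carry a vehicle +
stimulus *maximum-speck* negative control, MCC950 at 50 nM
(half-maximal inhibition) and 5 µM (full inhibition) as positive
controls, cells-alone and vehicle-only wells, and 280 library
positions dosed at a single concentration.

## Synthetic data generator

`synthgen` emulates that assay at three levels, all seeded through
`numpy.random.default_rng`; equal spec + seed is bit-identical.

**Fields.** Nuclei are hard disks (radius 5 µm) placed by rejection
sampling with a minimum centre separation of one nucleus diameter plus
two pixels; placement failure raises an error naming the constraint.
The default geometry is 2048 × 2048 px at 0.65 µm/px — a typical 10x
sCMOS field — holding 1700 cells, the density implied by 10,000
cells/well imaged in two fields. Each cell has a diffuse cytoplasm
disk (radius 11 µm) in the reporter channel. A deterministic
`round(n_cells · fraction)` count of cells (selected by seeded
permutation; a binomial mode is available behind `binomial_counts`)
receives one speck disk — diameter 1 µm, floored at 2 px so it
survives discretization — placed uniformly within half the cell radius
of the nucleus centre, i.e. perinuclear, as in real images. A disjoint
5% of cells are rendered *over-bright*: their whole footprint takes a
saturating reporter level and they never carry a speck — the artifact
the pipeline's bright-cell filter exists to remove. Intensity levels
(background 100, nucleus 1000, cytoplasm 300, speck 3000, bright cell
4000, additive Gaussian noise σ = 20, arbitrary units) are chosen so
that class separations are comfortable at the default noise and
degrade smoothly as `noise_sd` grows. The generator does not model
optics (no PSF, no vignetting), cell morphology, or focus drift; the
recovery results below therefore demonstrate the pipeline's logic, not
its performance on real micrographs.

**Plates.** Well values are drawn directly at the readout level
(percent speck-positive), not rendered as images: negative controls at
mean 40 (the centre of the stimulated range) with 5% CV, MCC950 50 nM
at half that level, MCC950 5 µM at ~2 with small absolute spread,
cells-alone and vehicle-only near zero. These noise levels make the
simulated plates reproduce the QC metrics the assay reports in routine
operation (rZ′ ≈ 0.8 for the 5 µM control, ≈ 0.55 for the 50 nM
control, SSMD ≈ 16–19, CV ≈ 5%, plate pass rate ≥ 98%). Library wells
carry planted effects: a configurable fraction of inhibitors
(uniform 40–100% inhibition) and activators (negative effects),
recorded in a ground-truth table keyed by well.

**Concentration–response.** Six half-log points descending from
`start_conc`, means from the 4PL, replicates multiplied by
`max(0, 1 + cv·z)` — multiplicative Gaussian truncated at zero, which
matches percent-scale readouts and is simpler than a lognormal while
having the same CV to first order. Presets encode the validated
reference compounds; each preset brackets its IC50 with points from
+1.5 to −1.0 decades around it.

## Imaging pipeline

Nuclei: Gaussian smoothing (σ = 2 px), global Otsu threshold (a fixed
threshold is available), hole filling, removal of objects under
20 px, then a distance-transform watershed seeded at smoothed distance
maxima (minimum peak separation 6 px ≈ one nucleus radius) so that
abutting nuclei split. Fragments under the area floor left by the
watershed are dropped.

Bright-cell rejection measures, per nucleus, the mean reporter
intensity over the nucleus footprint *minus the speck mask* and
removes nuclei above a fixed threshold (default 1500, midway between
the cytoplasm and bright-cell levels on the generator scale; the
`suggest_bright_threshold` helper derives one from control wells by
Otsu on per-nucleus means). Segmenting specks once on the raw reporter
channel *before* rejection resolves the circularity between the spot
mask and the filter: the mask protects legitimate specks overlapping a
nucleus from inflating its intensity. A nucleus fully covered by the
speck mask has no measurable pixels; it is retained and logged rather
than guessed at.

Pseudo-cells: each surviving nucleus is expanded isotropically by
`round(7 µm / pixel size)` pixels. Expansion is collision-aware —
every pixel within range of at least one nucleus joins the nucleus
whose footprint is nearest, with exact ties going to the lower label
id. This is implemented per-label over padded bounding boxes with
exact Euclidean distance transforms, so it agrees pixel-for-pixel with
a brute-force nearest-label scan (tested against one). 7 µm beyond a
5 µm nucleus gives a ~12 µm pseudo-cell, a reasonable macrophage
footprint at this scale.

Specks: white top-hat with a disk structuring element of radius one
expected speck diameter (≥ 2 px), threshold at 500 intensity units
above local background, area gate 2–80 px — roughly a 4× margin
either side of the rendered speck area to tolerate blooming and
merging. Raising the threshold can only shrink or remove
above-threshold components of isolated puncta, so counts are
non-increasing in the threshold in the regime the assay operates in.

Linking assigns each speck to the cell region containing its centroid
(rounded to the nearest pixel); a cell with ≥ 1 assigned speck is
speck-positive; orphan specks are counted separately. The well
statistic divides pooled speck-positive cells by pooled nuclei across
fields — never averaging per-field percentages — and errors on
zero-nucleus wells.

**Denominator.** The final percentage uses the *total* nucleus count
by default, including bright-rejected cells, with
`denominator="selected"` as a switch. The two readings differ by the
bright-cell fraction; the default matches the ground-truth definition
(all cells in the denominator) and keeps the statistic insensitive to
the rejection threshold.

Recovery under defaults: over 20 seeded default fields the pipeline's
percentage tracks truth with a mean absolute error well under 5
percentage points (the residual error comes from specks whose
centroid falls nearer a neighbouring nucleus, and from occasional
speck merging); the error grows monotonically with `noise_sd`.

## Plate QC and normalization

Robust Z′ uses medians and MADs scaled by the conventional rounded
1.4826 Gaussian-consistency factor; the plain mean/SD Z′ is provided
for comparison. SSMD is the method-of-moments form with sample SDs —
at control group sizes of 16–36 wells the UMVUE correction would
change it by a few percent at most. %CV is computed on raw negative-
control values (the spec ties CV to the maximum-speck level, before
any normalization). Replicate correlation is sample Pearson over
paired library wells only, pairwise-complete. Normalization is
single-point: `% formation = 100 · value / median(neg controls)` and
`% inhibition = 100 − % formation` (they sum to 100 exactly by
construction); a two-point min–max mode subtracting the 5 µM control
median is behind a flag. A plate passes QC iff all four metric checks
pass; every failing metric is named.

The uniformity assessment is deliberately simplified relative to the
full NIH template: per-plate mean/SD/CV at max, mid and min signal
levels, between-plate and between-day shifts of the max level, and a
row/column mean summary of max wells flagging the most deviant row
and column.

## Hit calling

Inhibitor hit ⇔ `pct_inhibition ≥ 30` on a QC-passing plate, boundary
inclusive. Compounds on failed plates are never called and are held
out of the screened denominator (the summary reports both the total
and the screened counts), mirroring the practice of repeating failed
plates. Activators are flagged symmetrically at formation ≥ 130%; the
threshold is configurable since no canonical value exists. Rates are
reported to one decimal. In the duplicate phase, a compound is a
screen hit if it scores in either replicate (union rule), with the
concordance table and the hit-in-one-replicate list exposed so an
intersection policy can be applied downstream if preferred.

## Constrained 4PL fitting

The model is the descending logistic with top pinned at 100% of
control; free parameters (bottom, log10 IC50, Hill) are fitted by
bounded least squares on pooled replicate points, equally weighted.
Fitting IC50 on the log scale keeps the problem well conditioned
across the nanomolar–micromolar range; the scale-equivariance test
(scaling concentrations by c scales IC50 by c exactly) confirms this.
Bounds: bottom ∈ [0, 100], log10 IC50 within the sampled range ± 2
decades, Hill ∈ (0, 10] — the sign convention encodes decline with
concentration, and a fit pinned at the slope's lower bound (data that
never decline) is reported unconverged. Initialization: Hill 1, bottom
at the smallest observed response, IC50 at the concentration whose
mean response is nearest the model midpoint `(100 + bottom)/2`; two
further log-spaced IC50 starts are tried only if the first fails.
Curves whose per-concentration means span < 5 percentage points are
declared flat and returned unconverged with no IC50 (5 rather than 10
so that genuine curves bottoming near 90 remain fittable). The IC50
standard error comes from the delta method on the Jacobian.

Mode comparison: `potency_ratio = IC50_activation / IC50_priming`,
priming-biased at ratio ≥ 2 (inclusive), activation-biased at ≤ 1/2,
else equipotent. The two-fold margin is an artifact convention — about
the smallest difference reproducible by eye on semi-log axes.

Curve categories: A = maximal inhibition ≥ 80% with |Hill| < 3 and a
converged fit; B = the same efficacy with a steeper slope;
C = 30–80% maximal inhibition (or an unconverged fit whose best
observed inhibition reaches 30%); none otherwise. The 80% completeness
floor and Hill-3 steepness cutoffs are declared conventions, exposed
as arguments, since the categories are defined qualitatively in
screening practice.

## Problem sizes and seeds

Reference recoveries use 100 seeded datasets per preset (six
concentrations × 3 replicates, 10% CV), enough that the median IC50
is stable to a few percent between master seeds. The imaging recovery
property uses 20 default-geometry fields. All test and script seeds
are fixed integers; the acceptance script derives every stream from
its `--seed` via `SeedSequence.spawn`.

## Known limitations

* Blob-world images: no PSF, no morphology, no illumination gradients;
  thresholds transfer to real data only after recalibration.
* Pseudo-cell regions are geometric, so a speck lying nearer a
  neighbouring nucleus than its own is mis-assigned; at screening
  density this costs well under a percentage point.
* SSMD and robust Z′ estimator variants differ across screening
  platforms; the conventions used here are stated above and in the
  docstrings.
* No spatial (B-score/median-polish) correction: planted plate biases
  are detected by the uniformity assessment but not corrected.
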