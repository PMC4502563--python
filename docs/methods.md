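# Methods

## Scope and model of the data

The pipeline reproduces a two-armed quantification of secretory-pathway
trafficking for clusterin constructs expressed in cultured cells. The
imaging arm scores individual cells in multi-channel fluorescence fields;
the secretion arm turns ELISA (and western-blot) measurements of
conditioned medium (CM) and cell lysate (CL) into per-genotype secreted
fractions; a statistics layer compares every mutant construct against wild
type. Raw experimental data are not available, so a synthetic-data module
generates both input families with known ground truth, and all quantitative
guarantees in the test suite are statements about recovery of that truth.

## Synthetic scenes

Cell geometry is schematic by design: cells are Fourier-perturbed ellipses
placed without overlap (rejection sampling; failure raises an error naming
the cell), nuclei are contained ellipses, the Golgi is a perinuclear
crescent of 2–4 concentric cisterna-like ribbons facing the cell centre,
the ER is the upper tail of a band-pass-filtered noise field restricted to
the cytoplasm (a reticular web covering ≈45% of it), and vesicles are
Poisson-placed puncta. ER and Golgi truth masks are disjoint, and every
organelle pixel lies inside its owning cell mask (asserted in tests).

The reporter expectation per pixel is
`background_level + er_retention·er_unit` on the ER web,
`golgi_enrichment·er_retention·er_unit` on the Golgi, plus a vesicle
amplitude on puncta; an optional diffuse-cytoplasm term defaults to 0 so
that a phenotype with unit enrichment renders ER∪Golgi at one constant
level. Counter-stains trace their truth masks at a common marker
amplitude. Noise is scaled-Poisson shot noise (`Poisson(E/s)·s`, default
`s = 1`) plus additive Gaussian read noise (default sd 5 on a background of
100), clipped at zero; a Gaussian blur flag (off by default) stands in for
the PSF. Intensities live on an arbitrary 16-bit scale (default ER unit
400, marker 3000, vesicle 1500) and are written as 16-bit multi-page TIFF
(channel order reporter, golgi, er, nucleus, actin) with a JSON sidecar and
a label-mask TIFF.

Default phenotype axes were chosen once to give the qualitative contrast
seen in the micrographs — wild type `golgi_enrichment = 8`,
`er_retention = 1.5`, 8 vesicles/cell; ER-retained mutants
`golgi_enrichment = 1`, `er_retention = 6`, no vesicles — and the packaged
secreted fractions are the measured values (Flp-In: wt 0.91, p.R338W 0.68,
p.I360N 0.15; HEK293T: wt 0.766, p.R338W 0.528, p.I360N 0.123). The
truncation mutant p.I303NfsX13 has no measurable secreted fraction (the
antibody epitope is lost); its table entry carries a nominal 0.05 used only
to complete the simulation table.

What the generator does **not** emulate: optical realism (PSF shape,
spectral bleed-through, depth effects), cell crowding and touching cells,
segmentation error in the cell outlines (truth masks stand in for the
manual delineations), and any systematic genotype-correlated technical
artefact. Passing tests therefore demonstrate that the estimators recover
truth under this noise model, not that they are robust to every property of
real acquisitions.

## ELISA and western simulation

Per experiment a total clusterin amount is drawn log-normally around
`total_clu_mean` (default 100 ng/ml) with between-experiment CV 0.2, split
as `CM = f·T`, `CL = (1−f)·T` for true secreted fraction `f`. An observed
well multiplies the true level by the experiment's relative TGF-β1
normalizer (log-normal, CV 0.1) and `1 +` Gaussian replicate noise (CV
0.05), then adds a log-normal matrix-background draw (mean 2 ng/ml, CV
0.3); nontransfected wells carry the background only. The background is
additive and genotype-independent, matching its downstream treatment. The
design is 3 experiments × duplicate wells. Western tables are analogous but
with one band per (experiment, genotype, compartment) and an α-tubulin lane
drawn around a common mean. Defaults were fixed once as plausible assay
noise for estimator testing; they are not fitted to any instrument.

## Imaging quantification

Background is the mean (and sd) of the reporter channel over pixels outside
every cell region (≥100 pixels required). The Golgi is segmented per cell by
Otsu's threshold computed on the Golgi-*marker* intensities inside the cell
region, followed by removal of connected components smaller than
`min_object_px` (default 20 px at the default 0.106 µm/px; 8-connectivity).
Thresholding the marker rather than the reporter keeps the ratio defined
for ER-retained mutants, which have no reporter signal in the Golgi. The
enrichment ratio is `(mean_in − bg)/(mean_out − bg)`; an empty Golgi mask
or a non-positive corrected denominator yields NaN for that cell without
aborting the batch. The exclusion cutoff on the corrected mean signal
outside the Golgi defaults to `bg_mean + 2·bg_sd` and is configurable; the
published value of the original fixed cutoff is unknown. Colocalization is
the plain sample Pearson correlation of reporter vs ER-marker over all
cell pixels — no Costes-style auto-thresholding, matching the default
behaviour of the common colocalization plugin.

## Secretion quantification

The matrix background is the pooled mean of all nontransfected wells
across experiments, subtracted from every sample well; negative corrected
concentrations are physically meaningless and are clamped to zero with a
logged warning. TGF-β1 normalization divides each concentration by
`normalizer / grand-mean normalizer` (unit-preserving); it is applied to
all records of both compartments, since nothing restricts it to CM — a
config-visible choice. Replicates are averaged per (genotype, experiment,
compartment); the CM fraction is computed per experiment and pooled as a
ratio of summed amounts (one bar per genotype). `cm + cl` fractions sum to
1 exactly by construction.

## Statistics

Outlier removal is a single pass per metric on the pooled measurements
(all genotypes together): mean and sd are computed once and values beyond
3 sd removed; a second pass with the original moments removes nothing.
Group means are compared by one-way ANOVA with Tukey HSD contrasts against
wild type (Tukey–Kramer for unbalanced groups; for two groups the Tukey p
reduces to the pooled t-test p, which the tests verify). Significance for
both the Tukey contrasts and the CMH p-values uses the Bonferroni
threshold α/m with m = 11 constructs (0.05/11 ≈ 0.0045).

The CMH test needs counts, but CM/CL amounts are continuous; each
genotype's per-experiment amounts are rescaled so the genotype row sums to
`pseudo_n` (default 1000) with largest-remainder rounding, strata being
experiments. `pseudo_n` is a config knob: it scales the chi-square
statistic and narrows the CI roughly as `1/√pseudo_n`, so reported CIs
should be read as conditional on that choice; the point estimate of the
odds ratio is insensitive to it beyond rounding. The common odds ratio is
reported in the test-vs-reference orientation (an ER-retained mutant gives
OR < 1 against wild type), with the Robins–Breslow–Greenland 95% CI and
the classic (uncorrected) CMH chi-square; a continuity-correction toggle
exists. Degenerate strata with zero margins in every stratum raise an
undefined-OR error.

## Pipeline and numerical choices

`run_pipeline` derives one RNG stream per stage by hashing (master seed,
stage label), so toggling a stage never shifts another stage's draws;
every output file embeds the master seed and a SHA-256 config hash, and
re-running a config is byte-identical. Per-cell failures become NaN
records; stage-level failures abort with the stage name and remove partial
outputs. Coordinates are 0-based row-major; masks are boolean pixel sets.

Default problem sizes (2 fields × 12 cells for the demo pipeline; 200
simulated studies for recovery runs; 1000 replicates for the error-rate and
CI-coverage calibrations) were chosen as the smallest designs at which the
Monte-Carlo standard errors are comfortably below the tolerances being
asserted (e.g. the recovery SE per study is ≈0.5 points, so 200 seeds give
a ≈0.04-point SE on the mean, well inside the 1-point check).

## Known limitations

Cell-level clustering within images is ignored by the ANOVA (cells are
treated as independent, as in the original analysis); no mixed-effects or
FDR alternatives are provided. The pseudo-count bridge injects an arbitrary
effective sample size into the CMH inference (see above). The segmentation
quality guarantee (Dice ≥ 0.8 against truth) holds under the default noise
model and marker amplitude; heavy blur or low marker contrast will degrade
it. ELISA standard-curve fitting is out of scope — inputs are already
concentrations.
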