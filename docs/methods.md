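# Methods

## Screen model and normalisation

The screen is modelled as a two-arm arrayed experiment: each 384-well plate
carries one siRNA reagent per well plus a set of non-targeting control
(siControl) wells, whole plates receive either vehicle or a fixed drug
dose, and the readout is a nuclei count per well. Treatment arm is a
per-plate property; a per-well treatment column is still read and checked
for within-plate consistency. The default design is four replicate plates
split 2 + 2 between arms (the split is configurable via
`ScreenDesign.replicates_per_arm`; how the four plates were divided is not
derivable from the protocol, so 2 + 2 is the package's assumption).

Normalisation proceeds in three steps:

1. **Within plate** — every count is divided by that plate's control
   reference, the *median* siControl count. The median keeps a single dead
   or contaminated control well from shifting a whole plate.
2. **Within reagent/arm** — per-plate ratios are aggregated per reagent
   first within a plate (relevant only for controls, which occupy many
   wells) and then across replicate plates, by median (default) or mean.
   With two replicates per arm the two coincide. Normalise-then-aggregate
   is this package's choice; the alternative order is not exposed.
3. **Across arms** — drug-arm values are multiplied by the drug-effect
   factor `r_control_drug`, the ratio of drug-arm to vehicle-arm control
   references (ratio of medians when an arm has ≤ 2 plates, median of all
   pairwise ratios otherwise; no plate pairing is assumed). After this
   every relative cell number shares the siControl + vehicle reference:
   vehicle-arm siControl is exactly 1 by construction, drug-arm siControl
   is exactly `r_control_drug`.

The cross-arm frame is what makes the CDI formula's three terms mutually
consistent — in a within-plate-only frame the `r(siControl + drug)` term
would be identically 1 and the statistic would collapse.

### Plate-scale identifiability

Dividing by the plate's own control reference removes any per-plate
multiplicative artefact from all within-arm quantities and from CDI
*exactly* (property-tested). It cannot remove it from Δ in general: a
uniform multiplier on the drug-arm plates transforms the data identically
to a stronger drug effect, so the two are confounded for any estimator.
The precise footprint is closed-form — `r_sirna_drug` and `r_control_drug`
scale by the ratio of arm control medians, nothing else moves — and the
tests assert exactly that, plus full invariance of every score and hit
call under multiplier patterns that preserve the cross-arm control-median
ratio (including global rescales). Stating a blanket "plate scale never
changes Δ" would be claiming the unidentifiable.

Spatial plate-effect corrections (B-score, LOESS, edge detrending) are
deliberately absent: the scoring scheme this package reimplements applies
none.

## Interaction metrics and hit calling

Per reagent, `Δ = r(siRNA+vehicle) − r(siRNA+drug)` (positive when the
drug removes more cells from that knockdown) and
`CDI = r(siRNA+drug) / (r(siRNA+vehicle) · r(siControl+drug))`, the
Bliss-independence ratio. A zero denominator yields an undefined flag
(NaN + `cdi_defined=False`), reported and excluded from hit calling, never
imputed — zero-count wells themselves are retained as value 0, since
lethality is signal.

Thresholds are applied inclusively exactly as printed: primary pools pass
at Δ ≥ 0.25 and CDI ≤ 0.9; individual duplexes at Δ ≥ 0.15 and CDI ≤ 0.8;
a gene is validated at ≥ 2 passing duplexes. The secondary screen's
"Bliss independence ≤ 0.8" bound is read as the same CDI statistic under a
tighter threshold; no second formula exists. Concordance is an absolute
count: a gene with only two recovered duplexes still needs two passes.
Hit sets are nested under threshold relaxation and concordance is monotone
in added passing duplexes (property-tested). All outputs are
byte-deterministic; output headers embed the package version and resolved
parameters (no timestamps, so reruns are byte-identical).

## Checkerboard Bliss-excess surfaces

Effect scale is fraction affected, `E = 1 − response/response(0,0)`,
clamped to [0, 1] before Bliss arithmetic (unclamped values are retained
in the output for audit; clamping shifts a cell's excess by at most the
clamp amount). Single-agent vectors are taken from the grid's own first
row and column — no dose–response refitting, so the excess is identically
zero along the axes by construction and `E_exp = E_a + E_b − E_a·E_b` only
ever acts on measured quantities. The summary score is the mean excess
over cells where both doses are positive; the sign convention (positive =
synergy) is printed on every output header. Replicates contribute a
per-cell SD from per-replicate excess surfaces (each replicate anchored to
its own (0,0) cell) and, at n ≥ 3, a per-cell one-sample t test of
excess ≠ 0. With one replicate the surface is still computed and the
uncertainty omitted with a warning. Model-fitted surface smoothing, Loewe
additivity and HSA are out of scope.

## Dose–response and GI doses

The 4PL `r(d) = lower + (upper − lower)/(1 + (d/EC50)^h)` is fit by
least squares (scipy's Levenberg–Marquardt) from a fixed multi-start grid:
Hill ∈ {±0.5, ±1, ±2} crossed with five log-spaced EC50 starts over the
positive dose range, lowest SSE wins. EC50 is parameterised on the log
scale. The seed only jitters the EC50 grid by ±1% as a tie-break against
symmetric local minima; fits are deterministic given the seed. Flat data
return a degenerate fit (EC50 NaN) rather than an error; fits whose SSE
exceeds 20% of the data's total variation carry a warning. No outlier
rejection.

GI doses use the vehicle-fraction convention: GI_L is the dose where the
fitted response equals `(1 − L)·upper`, i.e. GI50 = 50% of vehicle growth
(equal to EC50 when the curve bottoms at zero). A level whose target falls
outside the open fitted span — e.g. GI80 on a curve that plateaus at 40%
of vehicle — raises a no-solution error rather than extrapolating. With a
supplied day-0 baseline, TGI is the dose where the fitted endpoint equals
that baseline (net growth zero, NCI convention). Endpoint-vs-growth-rate
conventions differ across labs; both entry points are exposed and neither
is asserted as canonical. Inversion is analytic, so
`r(gi_dose(L)) = target` to well below 1e−9.

## Synthetic data: what it emulates, and what it does not

Expected count = `N0 · plate_scale · g(gene) · b[drug arm] · s(gene)[combined
condition only]`, with `N0 = 2000` (a plausible end-of-assay nuclei count
for ~1400 seeded cells after two days), 16 control wells per 384-well
plate, and genes overflowing onto additional plate chunks past 368
reagents. Defaults mirror the characterised study conditions: `b = 0.6`
(a GI25–GI50-range drug dose), planted `g = 0.8`, `s = 0.5`, null-gene
effects uniform on (0.5, 1.0), and noise CV 10% unless a study condition
says otherwise. Applying `s` as a single multiplier in the combined
condition is the module's central design lever: it makes CDI equal `s`
exactly in the noiseless limit, so recovery tests have machine-precision
oracles. Duplexes realise a penetrance fraction `p` of both the knockdown
and the interaction (`1 − p·(1−g)`, `1 − p·(1−s)`); the default ladder
{1.0, 0.9, 0.5, 0.2} puts, for `s = 0.5`, three duplexes past the
secondary criteria and leaves the weakest (CDI = 0.9 > 0.8) out — a 3/4
validation, exercising the ≥ 2-of-4 rule away from its trivial corners.

Well noise is multiplicative log-normal with unit mean. Noisy counts are
rounded to integers as real imagers report them; the noiseless path
returns exact expectations unrounded, because it serves as the
machine-precision oracle (rounding at `g·b·s`-scale products would inject
~1e−4 artefacts into identities the tests check at 1e−12).

Not emulated: spatial edge effects, transfection-efficiency gradients,
cell-cycle-structured growth, or count overdispersion beyond log-normal.
Passing recovery tests therefore show the *pipeline arithmetic* is
correct and calibrated under multiplicative noise — not that real screens
are free of the spatial and biological artefacts the generator omits.

## Measured operating characteristics

All numbers below are recomputed at run time by `scripts/acceptance.py`
and the acceptance test suite; problem sizes (200 screens of 100 genes per
noise level for null calibration; 200 screens of 30 genes with 10 planted
synergies for power; 200 noisy 4PL fits) are the package's characterisation
scale. The null false-positive rate of primary calling is reported per
noise CV ∈ {0.2, 0.1, 0.05, 0} and must be monotone in noise and zero in
the noiseless limit; recall of planted `s = 0.5` synergy at 5% CV must
reach 0.95; noiseless checkerboards must recover zero excess and a planted
+0.12 interior excess to 1e−12, and the noisy recovery must sit within two
standard errors; median |log₂ EC50 error| at 5% CV must stay below 0.2.
Common random numbers (one `SeedSequence` per study) couple the noise
levels so the monotonicity comparisons are low-variance.

## Known limitations

* Δ's cross-arm frame inherits the drug-effect estimate; with only two
  control-reference values per arm that estimate is a ratio of
  two-plate medians and carries their sampling noise into every Δ.
* The per-cell t test on checkerboard excess makes no multiplicity
  adjustment across dose pairs; the summary score is the intended
  single-number readout.
* Undefined CDI (complete kill of the vehicle-arm knockdown, or zero drug
  reference) excludes a gene from calling; a screen with many such genes
  needs a lower drug dose, not a different statistic.
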