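# blisscreen

Analysis pipeline for **arrayed siRNA × drug combination screens** scored
under the Bliss independence model, with SMARTpool deconvolution hit
validation, **drug–drug checkerboard synergy surfaces**, and 4PL
dose–response fitting for GI-dose anchoring.

The intended user runs (or re-analyses) a two-arm high-content screen: a
genome-wide siRNA library arrayed one reagent per well of 384-well plates,
with replicate plates receiving either vehicle or a fixed drug dose, read
out as DAPI-stained nuclei counts. The question per gene is whether
knockdown *cooperates* with the drug beyond what independent action
predicts.

## The statistics

Counts are normalised within each plate to the median of its non-targeting
control (siControl) wells, and drug-arm values are rescaled by the measured
drug-effect factor so every relative cell number `r` shares the
siControl + vehicle reference. Per reagent:

```
Δ   = r(siRNA + vehicle) − r(siRNA + drug)
CDI = r(siRNA + drug) / ( r(siRNA + vehicle) × r(siControl + drug) )
```

CDI (coefficient of drug interaction) is observed combined survival over
the Bliss-independence product of single-perturbation survivals: CDI < 1
synergy, = 1 independence, > 1 antagonism. Hit calling is two-stage:

* **primary** (pools): Δ ≥ 0.25 and CDI ≤ 0.9 (bounds inclusive);
* **deconvolution** (the pool's four individual duplexes, tighter bar):
  Δ ≥ 0.15 and CDI ≤ 0.8, with a gene **validated** when ≥ 2 of 4
  duplexes pass — concordance across independent sequences argues against
  off-target artefacts.

For two-drug checkerboards, raw dose-matrix responses become fraction
affected `E(i,j) = 1 − response(i,j)/response(0,0)`, the expected surface is
`E_a + E_b − E_a·E_b` from the grid's own single-agent row/column, and the
**Bliss excess** `E_obs − E_exp` (positive = synergy) is reported per dose
pair with replicate SD and a one-sample t test. Dose anchors (GI25/GI50/TGI)
come from a multi-start 4PL fit `r(d) = lower + (upper−lower)/(1+(d/EC50)^h)`
inverted analytically.

A synthetic-screen generator with known ground truth (multiplicative gene,
drug, plate and interaction effects; log-normal well noise; a duplex
penetrance ladder) backs every stage: in the noiseless limit the pipeline
recovers CDI equal to the planted interaction multiplier exactly.

## Worked example

```
$ blisscreen simulate-screen --n-genes 8 --n-synergy 2 --noise-cv 0.05 \
      --seed 11 --out screen.tsv --truth-out truth.tsv
wrote 96 wells to screen.tsv
$ blisscreen score screen.tsv --out scores.tsv
scored 8 reagents -> scores.tsv
$ blisscreen call scores.tsv --out hits.tsv
2/8 genes pass -> hits.tsv
```

`scores.tsv` (abridged):

```
reagent_id   gene    r_sirna_vehicle  r_sirna_drug  r_control_drug  delta   cdi
pool_G0001   G0001   0.829            0.245         0.614           0.584   0.481
pool_G0002   G0002   0.807            0.246         0.614           0.561   0.497
pool_G0003   G0003   0.826            0.517         0.614           0.309   1.019
```

G0001 and G0002 carry the planted interaction (s = 0.5): their CDI sits
near 0.5 — knockdown + drug kills twice as much as independence predicts —
and both clear Δ ≥ 0.25 and CDI ≤ 0.9, so `hits.tsv` flags exactly those
two genes. G0003 has a comparable knockdown effect but CDI ≈ 1.0: the drug
and the knockdown act independently, and the gene is (correctly) not
called. The same screen in `--layout duplex` feeds
`blisscreen deconvolve`, which reports per-gene validation as e.g. `3/4`.
`blisscreen synergy rep1.tsv rep2.tsv rep3.tsv --out surface.tsv` writes
the checkerboard excess surface, and `blisscreen doseresponse` the 4PL fit
plus a GI-dose table.

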