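# mcsquant

Quantification pipelines for fluorescence-microscopy studies of IP₃
receptor (IP₃R) clusters, their KRAP/ITPRID2 partners and ER–mitochondrial
membrane contact sites (ERMCSs), plus dual-indicator Ca²⁺ trace analysis —
with a synthetic-data generator that provides known ground truth for every
stage.

## Who this is for

Cell biologists quantifying confocal or widefield images of
diffraction-limited protein puncta want answers to questions like: *what
fraction of IP₃R puncta colocalize with KRAP, is that more than chance,
does the answer differ on versus off mitochondria, how many proximity
ligation assay (PLA) spots appear per cell, and how large are stimulus-
evoked Ca²⁺ responses relative to the saturated indicator signal?*  The
original measurements behind such studies are made with interactive tools
(ImageJ plugins, MetaMorph); `mcsquant` re-implements the quantitative
core as a tested, scriptable library so the same procedures can be run
reproducibly and validated on simulated data.

## What it computes

**Object-based colocalization.**  Puncta are detected (Gaussian smoothing
at the PSF scale, mean + k·σ threshold, watershed splitting), and for each
reference punctum the centre-to-centre nearest-neighbour distance (NND) to
the partner channel is computed in nanometres.  Puncta are *colocalized*
when NND < 233 nm (≈ the confocal lateral resolution; 3 px at 77.7 nm/px).
Significance comes from a permutation null: partner puncta are shuffled
uniformly within the cell mask (100 iterations), the colocalized fraction
is recomputed per iteration, and the observed fraction is significant when
it falls outside the empirical 95% CI of the null.  The analytic
complete-spatial-randomness expectation, 1 − (1 − πr²/A)ⁿ, cross-checks
the empirical null, and a chance-corrected estimate
f̂ = (f_obs − f_null)/(1 − f_null) recovers the truly paired fraction.
Mask-restricted analysis partitions puncta into mitochondria-associated
and non-associated subsets before the same statistics.

**Pixel-based colocalization.**  Thresholded Manders split coefficients
M1/M2 (fraction of one channel's supra-threshold intensity in pixels where
the other channel is also above threshold) and a Costes randomization
P-value (percentage of block-scrambles whose Pearson r falls below the
observed r).

**PLA quantification.**  Max z-projection, background subtraction,
binarization, connected-component counting with an area filter, DAPI
nucleus counting, and spots-per-cell per field, compared across conditions
by ANOVA.

**Ca²⁺ traces.**  ROI traces normalized to the pharmacologically saturated
indicator signal (F/F_max), peak response ΔF/F_max = max(response window)
− mean(baseline window), with a linearity flag when responses leave the
~linear regime (peak > 50% of F_max).

**Synthetic data.**  Scenes with a wobbly-disc cell mask, a tubular
mitochondrial mask (smoothed random walks), puncta placed with exact
colocalized/mitochondrial fractions and sub-resolution Gaussian pairing
offsets, Poisson + Gaussian camera noise; PLA fields with Poisson
spots-per-cell; two-channel trace pairs with a stimulus transient and an
F_max plateau.  Every generator records its ground truth.

## Worked example

```bash
mcsquant all --seed 1 --out results/
```

runs the three tracks on simulated defaults and prints/writes reports.
With seed 1 the colocalization report reads:

```json
{"direction": "ref_to_partner", "threshold_nm": 233.0, "n_cells": 3,
 "mean_fraction_coloc_mito": 0.466, "mean_null_mito": 0.138,
 "n_significant_mito": 3}
```

meaning: of the detected mitochondria-associated reference puncta, 46.6%
lay within 233 nm of a partner punctum, versus 13.8% expected by chance
for shuffled partners in these (dense, 200-puncta) cells, and all 3
simulated cells were individually significant under the 95%-CI shuffle
rule.  The PLA report for the same seed gives group means of 19.7 vs 10.2
spots per cell for the two simulated conditions (generated at 20 and 10;
omnibus p ≈ 4.5 × 10⁻⁷), and the calcium report shows mean mitochondrial
ΔF/F_max of 0.298 (control, generated 0.30) vs 0.029 (knockdown, generated
0.02).

The same pipelines are importable:

```python
from mcsquant.config import default_config
from mcsquant.pipelines import run_coloc_pipeline

cfg = default_config()
cfg["seed"] = 1
report = run_coloc_pipeline(cfg, "results/coloc")
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs all three analysis tracks end-to-end from freshly simulated inputs
(colocalization scenes with detection, shuffle nulls and chance
correction; PLA fields with counting and condition comparison; calcium
trace pairs with F/F_max quantification) and writes the result summary.
Quantitative validation — oracle equivalence of the NND search, null-model
calibration against the analytic CSR value, recovery of generated
colocalized/mitochondrial fractions and ΔF/F_max, exact PLA counting, and
byte-level determinism — lives in `tests/test_acceptance.py`.
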