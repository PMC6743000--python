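# isofodder

Seasonal and lifetime reconstruction of C4 (millet) dietary intake in
ancient livestock from stable isotopes, with mitochondrial taxon
assignment of sheep/goat remains.

## The problem

Mobile pastoralists of Bronze Age Inner Asia foddered their livestock with
cultivated broomcorn millet through the harsh winters. Millet is a C4
plant, offset from the local C3 steppe flora by ≈14 permil in delta13C, so
foddering leaves an isotopic trace: sequentially sampled tooth-enamel
bioapatite records the *seasonal* timing of C4 intake band by band, while
bone collagen integrates dietary protein over the animal's lifetime. Two
inferential steps stand between measurements and dietary history:

1. **When was each enamel band deposited?** Intra-tooth delta18O follows
   the annual cosine of meteoric water. Fitting
   `d18O(x) = M + A·cos(2π(x−x0)/X)` to band position `x` and anchoring
   the fitted maximum to mid-summer maps every band to a day-of-year
   ("Julian days", day 0 = January 15th), normalising individual
   differences in tooth growth. delta13C values are then averaged in
   calendar two-month bins per tooth.
2. **How much millet?** After subtracting diet–tissue spacing, each
   group's dietary delta13C values feed a Bayesian two-source mixing
   model: `x ~ N(p·μ_C4 + (1−p)·μ_C3, p²σ²_C4 + (1−p)²σ²_C3 + σ²_res)`
   with uniform priors on the C4 fraction `p` and residual sd. Posteriors
   are computed either by deterministic 2-D quadrature or by an adaptive
   random-walk MCMC with convergence diagnostics; the two agree to ≤0.01.

Around this core sit collagen quality screening (atomic C:N in
[2.9, 3.6], %C/%N ranges), the comparative statistics used in
palaeodietary work (Pearson delta13C–delta15N correlations, Mann–Whitney
livestock-vs-wild delta15N contrasts for manuring signals), Hamming-based
assignment of 110-bp MT-CYB amplicons against a labelled haplotype panel
(sheep/goat vs wild argali/urial/ibex/markhor), and forward simulators
that generate every input with known ground truth.

Everything is exposed both as scikit-learn-style estimators
(`SeasonalCosineRegressor`, `TwoSourceMixingModel`, `CollagenQC`,
`HaplotypeClassifier`) and as plain functions, plus an `isofodder` CLI.

## Worked example

Simulate six teeth from animals winter-foddered at a 50% millet share
(pulse mid-November to mid-March), then run the seasonal fit, day
assignment, bimonthly binning and mixing model:

```python
from isofodder import process_tooth_table
from isofodder.mixing import run_mixing_by_group, results_table
from isofodder.synthetic import (DEFAULT_C3, DEFAULT_C4, FodderSchedule,
                                 simulate_tooth_cohort)

series, truth = simulate_tooth_cohort(6, FodderSchedule(pulse_fraction=0.5), seed=1)
bands, bins, fits = process_tooth_table(series)
f = fits["T001"]
print(f"T001: period {f.period:.2f} mm/yr, amplitude {f.amplitude:.2f} permil")

bins = bins.dropna(subset=["mean_d13C_apa"]).assign(
    dietary_d13C=lambda d: d.mean_d13C_apa - 14.1)   # enamel spacing
res = results_table(run_mixing_by_group(bins, (DEFAULT_C3, DEFAULT_C4),
                                        engine="grid"))
print(res[["bimonth", "n", "p_mean", "p_lo90", "p_hi90"]].round(3))
```

Output:

```
T001: period 23.77 mm/yr, amplitude 2.70 permil
bimonth  n  p_mean  p_lo90  p_hi90
Jan-Feb  6   0.453   0.407   0.497
Jul-Aug  6   0.039   0.003   0.094
Mar-Apr  6   0.167   0.098   0.230
May-Jun  6   0.039   0.003   0.094
Nov-Dec  6   0.343   0.288   0.394
Sep-Oct  6   0.059   0.008   0.121
```

The fitted period (23.8 mm) is one year of crown growth; the posterior C4
fraction peaks in the Jan–Feb bin (~45%) and collapses to a few percent in
summer — the winter-foddering signature. Bin means sit slightly below the
nominal 50% pulse because enamel maturation averages the dietary input
over ~3 months, attenuating the pulse edges; the simulator records the
maturation-smoothed truth per band (`truth["true_c4_smoothed"]`), and the
credible intervals are calibrated against that (see `docs/methods.md`).

The same pipeline runs end-to-end from a YAML config:

```sh
isofodder simulate tooth --seed 1 --out data/
isofodder run --config run.yaml          # fit-seasons → end-members →
                                         # mixing → collagen stats → mtDNA
```

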