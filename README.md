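# midquant

Targeted quantification of **mass isotopomer distributions (MIDs)** from
stable-isotope labeling mass-spectrometry experiments.

Stable-isotope tracing (¹³C, ¹⁵N, ²H, ¹⁸O, ³⁴S) is the workhorse of
metabolic flux analysis, but general-purpose metabolomics software is
optimized to quantify *abundance*, not isotope *enrichment*. Enrichments
are exquisitely sensitive to how chromatographic peaks are bounded and
integrated: a weak M+4 isotopologue integrated with its own sloppy bounds
can be biased by a factor of two while the total peak area looks fine.
midquant automates the whole path from raw vendor-agnostic files to
corrected MIDs for users running targeted labeling experiments — single or
dual tracers, low- or high-resolution instruments, MS1 or MS/MS.

## What it does

For each target ion (known formula, charge, expected retention time,
tracer and isotopologues to track) in each raw file:

1. **Parse** mzML 1.1, mzXML 3.x or ANDI-MS netCDF into a uniform scan
   model (profile data is centroided on the fly).
2. **Extract** one EIC per isotopologue at
   mᵢ/z = m₀/z + i·Δm_tracer/|z| within a ppm or Th tolerance.
3. **Locate** the peak on the Savitzky–Golay-smoothed *composite* trace
   (the pointwise sum of all isotopologue EICs), scoring candidate apexes
   by a Gaussian retention-time kernel times relative height, anchored by
   characteristic ions which also drive piecewise-linear RT warping.
4. **Bound** the peak by walking from the composite apex until the signal
   falls below *baseline + k·noise*, with a local-minimum shoulder guard
   and an asymmetry cap; the **same bounds** integrate every isotopologue
   of the cluster, which is what keeps low-abundance channel ratios exact.
5. **Integrate** raw (unsmoothed) intensities, normalize to the raw MID
   `Mᵢ = areaᵢ / Σⱼ areaⱼ`, and compute the average percent enrichment
   APE = 100 · Σᵢ i·Mᵢ / n.
6. **Correct for natural isotopic abundance**: the observed MID is
   `M·x` where `x` is the tracer-derived label distribution and column
   *j* of `M` is the natural isotopologue distribution of the ion
   carrying *j* labels (full formula at unit resolution; tracer element
   only at high resolution; product-ion formula for MS/MS; Kronecker
   combination for dual tracers). midquant solves
   `min ‖M·x − M_raw‖₂, x ≥ 0` and renormalizes.
7. **Report** a .xlsx workbook plus CSV mirror: MIDs, APEs, abundances,
   per-group mean ± SD, Welch t-tests with Benjamini–Hochberg adjustment,
   and RMSE of unlabeled controls against theory.

A synthetic-data generator (`midquant.synthetic`) writes valid mzML runs
with fully known ground truth — Gaussian/EMG peaks, baseline drift,
multiplicative + additive noise — sharing the exact forward model the
corrector inverts, so every pipeline stage is testable without downloads.

## Worked example

Correct a measured glutamine MID (`examples/01_natural_abundance_correction.py`):

```text
observed (raw) MID:   [0.6633 0.0359 0.0008 0.     0.     0.3   ]
corrected MID:        [0.7 0.  0.  0.  0.  0.3]
fit residual norm:    2.43e-19
```

A 70% unlabeled / 30% U-¹³C₅ mixture appears at the instrument as 66.3%
M+0 with 3.6% leaked into M+1 by natural ¹³C; inversion recovers the
clean 70/30 label distribution.

Full pipeline on a simulated noisy run (`examples/02_simulate_and_quantify.py`):

```text
flags:          ['ok']
raw MID:        [4.677e-01 2.080e-02 2.000e-04 1.500e-03 2.900e-03 5.069e-01]
corrected MID:  [0.491  0.     0.     0.0015 0.0029 0.5046]
APE (13C):      50.78 %
```

The simulated truth was a 50/50 unlabeled/U-¹³C₅ mixture with 2%
multiplicative noise; the corrected MID lands within ~1% and the average
percent enrichment reads ~50%: half of all carbon positions are labeled.

The other examples demonstrate dual-label and tandem matrices
(`examples/03_dual_label_and_tandem.py`) and batch processing with group
statistics (`examples/04_batch_group_statistics.py`).

## Command line

```sh
midquant simulate --spec sim.json --out data/ --seed 1
midquant process --method method.json --data 'data/*.mzML' \
                 --meta meta.csv --compare low:high --out results/
midquant validate-method method.json
```

Method files are declarative JSON (schema in `midquant/method.py`
docstring); exit codes are 0 (ok), 1 (config error), 2 (no file
processed).

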