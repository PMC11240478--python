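# thzcontrast

Paired nonparametric analysis of broadband terahertz (THz) spectra for
evaluating nanoparticle contrast agents in cancer-cell discrimination.

## The problem

Broadband THz spectroscopy (0.06–4 THz) can in principle distinguish tumor
from normal cells, and gadolinium-oxide contrast nanoparticles may enhance
that distinction — but the effects are small, band-localized, and measured
under two different geometries (attenuated total reflection, ATR, and
transmission). This package implements the statistical pipeline that turns a
set of condition spectra into defensible answers: *do nanoparticles change
the spectra, do they widen the tumor–normal gap, in which frequency bands,
and does one measurement geometry beat the other?*

It is written for spectroscopists and biostatisticians who have per-condition
spectra on a shared frequency grid (six sample types — support medium, normal
cells, tumor cells, each with/without nanoparticles — times two modalities)
and want the full inference, not a black box.

## The statistics

The workhorse is a from-scratch **Wilcoxon signed-rank test** applied to
frequency-point-paired spectra. For paired series $x_i, y_i$ over $n$
frequency points, form $d_i = x_i - y_i$, drop zeros, rank $|d_i|$ (midranks
on ties), and sum ranks of positive and negative differences separately into
$W^+$ and $W^-$. The statistic is $W = \min(W^+, W^-)$ and the two-sided
p-value is $2\,P_0(W^- \le W)$ capped at 1, where $P_0$ is the null
distribution over all $2^n$ equiprobable sign assignments — computed exactly
(dynamic program) for tie-free $n \le 25$, and by a tie-corrected normal
approximation with continuity correction otherwise:

$$ z = \frac{|W^+ - \tfrac{n(n+1)}{4}| - \tfrac12}
           {\sqrt{\tfrac{n(n+1)(2n+1)}{24} - \sum_t \tfrac{t^3-t}{48}}} .$$

On top of the test, the pipeline provides:

- **Pairwise contrast tables** — five condition contrasts per modality over
  the entire domain, and four cell contrasts within 1-THz bands
  (0.06–1, 1–2, 2–3, 3–4 THz);
- **Difference of differences (DoD)** — within a modality, signed-rank of
  (tumor+NP − normal+NP) against (tumor − normal): did nanoparticles change
  the discriminative gap?  Across modalities, the named difference series
  d1…d8 (e.g. d7 = ATR tumor+NP − ATR normal+NP, d8 its transmission
  counterpart) are compared pairwise: which geometry sees the effect better?
- **Band ranking** — per-band p-value plus mean absolute enhancement,
  sorted to find the most useful frequency window;
- **A synthetic-data generator** — smooth per-modality baselines, per-type
  offsets, band-confined flat or Gaussian effects, i.i.d. (optionally AR(1))
  Gaussian noise — plus calibration and power studies of the whole pipeline.

## Worked example

Inject a +0.3 nanoparticle effect on ATR tumor cells confined to 3–4 THz
(noise sd 0.1) and ask the pipeline to find it:

```python
from thzcontrast import (SimConfig, EffectSpec, Band, Modality, SampleType,
                         generate_dataset, run_pairwise, rank_bands,
                         dod_cross_modality, default_band_edges)

config = SimConfig(
    seed=7, noise_sd=0.1,
    effects=(EffectSpec(target=(Modality.ATR, SampleType.TUMOR_NP),
                        band=Band(3.0, 4.0), magnitude=0.3),),
)
dataset = generate_dataset(config)
print(run_pairwise(dataset, Modality.ATR, bands=default_band_edges()).render())
```

```
Sample Type                                                         0.06–1 THz  1–2 THz  2–3 THz  3–4 THz
Normal cells vs. normal cells with nanoparticles                    0.1959      0.3872   0.4161   0.1083
Tumor cells vs. tumor cells with nanoparticles                      0.3655      0.1685   0.4713   0.0000 *
Normal cells vs. tumor cells                                        0.5923      0.0951   0.4122   0.4379
Normal cells with nanoparticles vs. tumor cells with nanoparticles  0.4440      0.3506   0.8568   0.0000 *
Difference in differences                                           0.7831      0.0964   0.4260   0.0000 *
```

Only the loaded band lights up, and it lights up in the three rows it
should: the nanoparticle effect on tumor cells, the with-NP tumor–normal
contrast, and the DoD (nanoparticles widened the gap). Band ranking puts the
loaded band first,

```python
ranking = rank_bands(dataset.get(Modality.ATR, SampleType.TUMOR),
                     dataset.get(Modality.ATR, SampleType.TUMOR_NP),
                     default_band_edges())
print(ranking.to_frame().head(1).to_string(index=False))
#    band  lo_thz  hi_thz      p_value  mean_abs_enhancement  rank
# 3–4 THz     3.0     4.0 3.647176e-18              0.294639     1
```

and the cross-modality DoD confirms that ATR (where the effect lives) beats
transmission for NP-assisted discrimination:

```python
res = dod_cross_modality(dataset, "d7–d8")
# statistic=25634.0 p=2.98e-09 (normal_approx, n=395)
```

## Command line

```sh
thz-contrast simulate config.yaml out/sim          # 12 spectrum CSVs + manifest
thz-contrast analyze out/sim/manifest.yaml out/an  # 5 p-value tables, d-series, curves
thz-contrast power config.yaml out/pw --reps 500   # calibration or power study
```

`analyze` accepts `--bands`, `--alpha`, `--correction holm` and
`--decimate` (keep every k-th frequency point, a guard against
pseudo-replication from spectral autocorrelation).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at the given seed — simulates the
default synthetic world, runs every analysis stage into `results/run/`, and
writes the results JSON to `--out`.
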