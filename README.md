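# preictal

Supervised spectral filters and a KNN pipeline for forecasting epileptic
seizures from intracranial EEG (iEEG).

## The problem

Seizure forecasting from chronic iEEG is usually framed as a two-class
problem: classify a ten-minute multichannel clip as **preictal** (recorded
in the hour before a seizure) or **interictal** (baseline, far from any
seizure).  The classical feature set is the spectral power in six canonical
bands — δ (0.1–4 Hz), θ (4–8), α (8–12), β (12–30), low-γ (30–70) and
high-γ (70–180) — obtained as a *uniform* average of FFT magnitude bins
within each band (the power band filter, **PBF**).  Uniform averaging is
unsupervised: if the class difference lives in a narrow sub-band, it is
diluted across thousands of bins.

This package replaces the uniform average with *supervised* band filters: a
unit weight vector **u** per (channel, band), fitted on labeled training
windows so the weighted average emphasises the frequencies that actually
separate the classes.

## The filters

Let **Z** be the vector of log-compressed FFT magnitudes of one analysis
window from an interictal clip and **Y** the same for a preictal clip,
restricted to one band's bins.  Each filter maximises a quadratic objective
in the projection π<sub>u</sub>(x) = **u**·**x** over unit vectors **u**:

| method | objective | optimum |
|---|---|---|
| DM  | E[π(**Z**) − π(**Y**)] | closed form: E[**Z**−**Y**] / ‖E[**Z**−**Y**]‖ |
| VAR | Var π(**Z**) − Var π(**Y**) | top eigenvector of E[**ZZ**ᵀ]−E[**YY**ᵀ]−E[**Z**]E[**Z**]ᵀ+E[**Y**]E[**Y**]ᵀ |
| TVM | (E[π(**Z**)−π(**Y**)])² + Var π(**Z**) − Var π(**Y**) | top eigenvector of E[**ZZ**ᵀ]−E[**YY**ᵀ]+(E[**Y**]−E[**Z**])E[**Y**]ᵀ+E[**Y**](E[**Y**]−E[**Z**])ᵀ |
| DS  | E[π(**Z**)² − π(**Y**)²] | top eigenvector of E[**ZZ**ᵀ]−E[**YY**ᵀ] |
| SqD | E[(π(**Z**) − π(**Y**))²] | top eigenvector of E[(**Z**−**Y**)(**Z**−**Y**)ᵀ] |

A 60-second window at 5000 Hz has 262,144 retained bins per channel, so
these matrices are never formed: every objective is expressed as a
matrix-free matvec over the stored class sample matrices and the dominant
eigenpair is found by **power iteration** (with a spectral shift when the
dominant eigenvalue is negative, so the algebraically largest eigenpair is
always reported).

## The pipeline

1. Slice each clip into 60 s Hamming windows with 30 s step (19 windows per
   ten-minute clip); zero-pad to the next power of two, FFT, keep the
   positive-frequency magnitude bins (DC excluded), compress with log1p.
2. Reduce each window to `channels × 6` features with a filter bank
   (PBF or one of the supervised methods).
3. Score each window with a distance-weighted KNN posterior
   (K = 40 by default):
   Pr(G=1|x) = Σ<sub>y∈K₁</sub> e^(−‖y−x‖²/2) / Σ<sub>y∈K</sub> e^(−‖y−x‖²/2).
4. Aggregate the n window posteriors into one clip probability:
   Pr(preictal) = 1 − (∏ₜ (1 − pₜ))^(1/n).
5. Evaluate with ROC/AUC; compare two scorers with DeLong's paired test.

Real contest recordings are read from their MAT v5 clip files; a synthetic
generator (`preictal.synthetic`) produces clips with *planted* narrow-band
class effects so every stage is testable without the multi-gigabyte gated
dataset.

## Worked example

Train-and-evaluate on synthetic subjects carrying a faint quarter-Hertz
40 Hz preictal oscillation on half the channels (held-out sequences, five
simulated subjects):

```python
from preictal.synthetic import narrowband_benchmark_config, benchmark, summarize_benchmark

table = benchmark(narrowband_benchmark_config(), methods=["PBF", "DS"], seeds=range(5))
print(summarize_benchmark(table).to_string(index=False))
```

```
method  mean_auc   sd_auc  n_seeds
    DS  0.903472 0.037212        5
   PBF  0.651852 0.054154        5
```

The uniform band average (PBF) dilutes the planted line across ~3300
low-γ bins and barely separates the classes (AUC 0.65); the supervised DS
filter concentrates its weights near 40 Hz and reaches AUC 0.90 on the same
clips.

The same workflow from the shell:

```
preictal --seed 7 synth --out data --synth-config synth.yaml
preictal --seed 7 train-filters --data data --method ds --out ds.json
preictal --seed 7 predict --data data --train data --filters ds.json --k 12 --out preds.csv
preictal evaluate --preds preds.csv --truth data/manifest.csv
```

```
subject           n      auc
Demo_1           36    1.000
pool             36    1.000
```

(here the AUC is in-sample — the demo predicts the clips it trained on; use
`preictal cv --scheme loso` for leave-one-seizure-out estimates.)

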