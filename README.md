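# strokeeg

Quantitative-EEG biomarkers of ischemic stroke and transcranial
direct-current stimulation (tDCS), for researchers analyzing multi-group
electrophysiology experiments: per-band **relative power (RP)**,
**Lempel-Ziv complexity (LZC)** and **sample entropy (SampEn)**, compared
across experimental groups with one-way ANOVA and η² effect sizes.  A
seeded synthetic-cohort simulator emulates the classic four-group rodent
design — Control, MCAO (middle cerebral artery occlusion), MCAO+tDCS and
MCAO+Sham — so the entire pipeline can be exercised, tested and
demonstrated without access to recordings.

## The metrics

Signals are analyzed in the four bands δ (1–4 Hz), θ (4–8 Hz),
α (8–13 Hz) and β (13–20 Hz), which tile the 1–20 Hz reference range.

**Relative power.** From a Welch spectral estimate P(f),

    RP_band = ∫_band P(f) df / ∫_1^20 P(f) df  ∈ [0, 1]

so the four band RPs sum to one. After ischemic stroke, power
redistributes toward δ; effective tDCS pulls it back.

**Lempel-Ziv complexity.** Each band-filtered epoch is binarized at its
median and parsed into the c(n) phrases of the exhaustive LZ76
production history, normalized by the random-sequence asymptote:

    LZC = c(n) · log_α(n) / n        (α = alphabet size, default 2)

i.i.d. random sequences score ≈ 1, periodic sequences ≈ 0.

**Sample entropy.** With embedding dimension m = 2, tolerance
r = 0.2 × epoch SD and Chebyshev distance, excluding self-matches:

    SampEn(m, r, N) = −ln( A / B )

where B counts template pairs of length m within r and A the same at
length m + 1.  Lower values mean a more regular, predictable signal;
injured cortex is expected to lose complexity on both measures.

**Group comparison.** Per metric × band, a one-way fixed-effects ANOVA
with η² = SS_between / SS_total, mean ± SEM group summaries and
significance stars (\*p < 0.05, \*\*p < 0.01, \*\*\*p < 0.001).
Normality (Shapiro–Wilk) and variance-homogeneity (Levene) checks are
reported as advisories; Holm adjustment and Welch's ANOVA are available
behind flags.

## Worked example

Simulate the default cohort (4 groups × 10 subjects, 60 s single-channel
records at 250 Hz) and run the full analysis:

```sh
strokeeg run --seed 42 --out demo
```

`demo/comparison.tsv` then contains (group means abridged):

```
metric  band  Control  MCAO   MCAO_tDCS  MCAO_Sham      F        p  eta_squared stars
    RP delta    0.307  0.875      0.583      0.875 3960.9 2.14e-45        0.997   ***
    RP alpha    0.289  0.036      0.155      0.036 2482.9 9.25e-42        0.995   ***
   LZC alpha    0.308  0.167      0.290      0.171  856.1 1.65e-33        0.986   ***
SampEn alpha    0.583  0.384      0.585      0.379 2570.2 4.98e-42        0.995   ***
```

Reading the rows: the lesioned (MCAO) group concentrates 87.5% of its
1–20 Hz power in the δ band versus 30.7% for Control, and its α-band
complexity drops on both measures (LZC 0.167 vs 0.308; SampEn 0.384 vs
0.583); simulated tDCS restores both toward Control while Sham tracks
MCAO.  The omnibus ANOVA is decisive in every band (synthetic effect
sizes are intentionally strong; only the directions are calibrated).
`demo/rp.tsv`, `demo/lzc.tsv` and `demo/sampen.tsv` hold the per-subject
tables and `demo/report.json` the provenance (config hash, seed,
version, warnings).

The same stages are available as a library:

```python
from strokeeg import SimConfig, generate_cohort, rp_table, compare_groups

cohort = generate_cohort(SimConfig(master_seed=42))
table = rp_table(cohort)
for c in compare_groups(table, ["Control", "MCAO", "MCAO_tDCS", "MCAO_Sham"]):
    print(c.band, f"F={c.F:.1f}", f"eta2={c.eta_squared:.3f}", c.stars)
```

Real recordings enter the same way: a directory of per-subject CSVs with
a `manifest.tsv` (subject_id, group, fs, file), or EDF files referenced
from the manifest (`strokeeg analyze --in <dir> --metric rp ...`).

## Layout

- `strokeeg.simulate` — group profiles and the seeded cohort generator
- `strokeeg.spectral` — zero-phase band-pass, Welch PSD, relative power
- `strokeeg.complexity` — symbolization, LZ76, normalized LZC, SampEn
- `strokeeg.group_stats` — ANOVA, η², stars, assumption checks
- `strokeeg.pipeline` / `strokeeg.cli` — orchestration, I/O, `strokeeg` CLI
- `docs/methods.md` — models, defaults and design decisions
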