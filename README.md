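# meaphen

Spike-train phenotyping for multi-electrode-array (MEA) recordings of
cultured cortical networks, and dose–response analysis of GIRK-channel
inhibition measured by two-electrode voltage clamp (TEVC) in *Xenopus*
oocytes.

The package is built for the analysis setting of a *GNB1*-encephalopathy
model: cortical cultures from *Gnb1* K78R/+ mice show aberrant network
bursting on 48-well MEA plates (16 electrodes per well), the anti-absence
drug ethosuximide (ETX) rescues the phenotype in a concentration-dependent
way, and ETX inhibits Gβγ-activated GIRK channels in oocytes with apparent
affinities that place therapeutic concentrations in the effective range.
`meaphen` re-implements that full analysis as a tested, reusable library
plus a synthetic-data generator, so every stage runs end to end without
any recordings.

## What's inside

| module | contents |
|---|---|
| `meaphen.types` / `io` / `validate` | domain containers (spike lists, plate maps, feature tables, TEVC traces) and their CSV formats |
| `meaphen.burst` | Maximum-Interval burst detection (begin ISI ≤ 0.1 s, end ISI ≤ 0.25 s, merge < 0.8 s, ≥ 5 spikes, ≥ 0.05 s) |
| `meaphen.netsync` | network spikes (10 ms bins, ≥ 5 electrodes), spike-time tiling coefficient, mutual information |
| `meaphen.features` | activity QC (≥ 5 spikes/min electrodes; well removal by inactive-day majority) and the per-well feature table |
| `meaphen.stats` | per-plate WT normalisation, label-permutation Mann–Whitney tests, Fisher combination, drug-ratio comparisons with Bonferroni |
| `meaphen.dose` | TEVC protocol segmentation, % inhibition vs the Ba²⁺-blocked baseline, one-site / Hill / two-site fits, fixed-n⁴ activation fit |
| `meaphen.synth` | generators: bursty spike trains with genotype presets and a dose-dependent drug effect; TEVC traces under the ND96 → HK24 → ETX steps → Ba²⁺ protocol |
| `meaphen.pipeline` / `cli` | end-to-end orchestration and the `meaphen` command-line tool |

The statistical core: per feature and plate, every well value is divided
by the plate × DIV WT mean; a two-sided Mann–Whitney U test on per-well
values gets an empirical permutation p-value from 1,000 label shuffles,
`p_perm = (1 + #{p_π ≤ p_obs}) / (n_perm + 1)`; per-plate p-values combine
by Fisher's method, −2 Σ ln pᵢ ~ χ²(2k).  The dose–response core: %
inhibition = 100 (1 − GIRK(x)/GIRK(HK24)) with GIRK = I − I(Ba²⁺), fitted
by 100 x/(x + K_d,app), its Hill generalisation, and the two-site
isotherm.  See `docs/methods.md` for definitions, defaults and
limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data and write tables under `results/`:

```sh
python analysis/01_simulate_mea.py        # demo plate: 8+8 wells, 3 DIVs
python analysis/02_extract_features.py
python analysis/03_genotype_stats.py
python analysis/04_drug_rescue.py
python analysis/05_tevc_dose_response.py
```

`02` prints the per-genotype feature means of the demo plate:

```
            mfr  bursts_per_min  mean_burst_duration  mean_ibi
genotype
K78R      5.321           2.961                2.790    17.990
WT        5.355          12.030                0.406     4.573
```

— the mutant phenotype in numbers: with overall firing (`mfr`, Hz) almost
unchanged, K78R wells burst a quarter as often, four times longer
(seconds), and wait four times longer between bursts.  `03` then confirms
the directions statistically (1,000-permutation MWU, 8 vs 8 wells):
`bursts_per_min` down in K78R at `p_perm ≈ 0.001`, `mean_burst_duration`,
`mean_ibi` and `mean_spikes_per_burst` up at `p_perm ≤ 0.002`.  `04` shows
the concentration dependence of the simulated chronic-ETX rescue — 0.25 mM
barely moves the K78R rows, 0.75 mM restores near-WT bursting
(9.2 bursts/min, 1.2 s bursts), and 2 mM overshoots, dropping firing to
0.67 Hz, far below the WT 5 Hz.  `05` fits the oocyte dose–response:

```
GIRK1_2: pooled 48 points from 6 oocytes; best model one_site
         (Kd_app 1.001 mM, truth 1); predicted inhibition at 0.7 mM: 41.2%
GIRK2:   pooled 48 points from 6 oocytes; best model one_site
         (Kd_app 0.055 mM, truth 0.055); predicted inhibition at 0.7 mM: 92.7%
```

The same chain is available as a CLI (`meaphen simulate-mea`,
`detect-bursts`, `extract-features`, `compare-groups`, `simulate-tevc`,
`dose-fit`, `run-all`, `write-config`), e.g.

```sh
meaphen run-all --seed 1 --out results/run1
```

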