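# Methods

`meaphen` implements two linked analysis chains: a multi-electrode-array
(MEA) spike-train phenotyping pipeline for cultured cortical networks from
wild-type (WT) and *Gnb1* K78R/+ mice, and a two-electrode voltage-clamp
(TEVC) pharmacology pipeline for ethosuximide (ETX) inhibition of GIRK
channels expressed in *Xenopus* oocytes.  A synthetic-data generator with
known ground truth feeds every stage, so each step is testable end to end
without any recordings.

## MEA pipeline

### Burst detection

Bursts are detected per electrode with the Maximum-Interval algorithm.
A burst is initiated at spike *i* when the inter-spike interval (ISI) to
the next spike is ≤ `max_begin_isi` (default **0.1 s**) and extended while
subsequent ISIs are ≤ `max_end_isi` (**0.25 s**).  Raw bursts separated by
**< 0.8 s** are merged transitively; bursts shorter than **0.05 s** or with
fewer than **5 spikes** are then discarded.

Numerical and boundary choices:

* thresholds stated as maxima compare with `≤`; the merge gap compares with
  strict `<`;
* merging runs *before* the size/duration filters, so two sub-threshold
  bursts can merge into one valid burst; the reverse order is available via
  `BurstParams(merge_before_filter=False)` since the convention differs
  between published implementations;
* burst duration is last spike time − first spike time; the inter-burst
  interval (IBI) is next burst start − previous burst end;
* simultaneous timestamps (ISI = 0) are legal and count as within-burst
  intervals.

The implementation is vectorised (runs of end-qualifying ISIs, with the
burst anchored at the first begin-qualifying ISI of the run); the test
suite proves it equivalent to a direct sequential transcription of the
rules on a thousand random trains.

### Network events and synchrony

A *network spike* is a run of consecutive 10 ms bins (fixed grid anchored
at t = 0) in which at least **5 electrodes** (> 25 % of the 16-electrode
well) fire.  Three well-level synchrony measures are reported:

* **% spikes in network spikes** — percentage of the well's spikes inside
  any network-spike span;
* **mean STTC** — the spike-time tiling coefficient with a ± 50 ms window,
  averaged over all pairs of spiking electrodes.  The standard published
  definition is used (the source analysis package names the statistic
  without printing a formula);
* **mean MI** — plug-in mutual information (bits) of binary 100 ms bin
  occupancies, averaged over rook-adjacent electrode pairs ("nearby" is not
  defined in the source; grid adjacency is this package's reading).

Network *bursts* (coincident electrode-level bursts on ≥ 5 electrodes) are
provided by `detect_network_bursts` but flagged as a reconstruction and
kept out of the headline feature table, because the platform's exact
definition is not public.

### QC and features

An electrode is **active** at ≥ 5 spikes/min (inclusive).  A well is
removed when more than half (strict >) of its recorded days have fewer
than 4 active electrodes.  Features are computed on active electrodes
only.  Mean firing rate and bursts/min are normalised per active
electrode, which makes wells with different electrode yields comparable;
whether the original platform normalises per well or per electrode is not
documented, so this is a package choice.  "Periodicity of bursting" is
implemented as the coefficient of variation of IBIs and labelled a proxy.
Missing values are NaN throughout and are never silently zero.

### Statistics

Per plate and per DIV, every feature is divided by the mean over WT wells
(WT mean ≡ 1 after normalisation; a zero or missing WT mean propagates
missingness with a warning).  Wells are the independent unit: values are
averaged per well across the selected DIVs before testing (a pooled mode
keeping each well × DIV observation exists behind
`StatsParams(div_combine="pool")`).

Group comparison is a two-sided Mann–Whitney U test with an empirical
permutation p-value: well labels are shuffled `n_perm` = 1,000 times and
`p_perm = (1 + #{p_π ≤ p_obs}) / (n_perm + 1)` (add-one, never exactly 0).
When the number of distinct label assignments is ≤ `n_perm` the assignment
set is enumerated exhaustively instead.  The MWU p-value itself uses the
tie-corrected normal approximation with continuity correction, vectorised
across permutations; the exact tail (rank-subset enumeration) replaces it
when both groups have ≤ 8 observations and no ties.  Per-plate permutation
p-values are combined across plates with Fisher's method
(−2 Σ ln pᵢ ~ χ²(2k)).  Drug comparisons test per-well drug/baseline
ratios and Bonferroni-multiply by the number of features tested in the
call.

The type-I error of the permutation test is verified by simulation: on 500
null datasets (24 + 24 wells whose labels differ but whose generator is
the identical WT preset) the fraction of `p_perm < 0.05` must stay within
[0.03, 0.07].  The calibration datasets use 60 s recordings — type-I
calibration is a property of the test statistic, not of the recording
length, and the shorter recordings keep the simulation economical.

## Synthetic MEA data

`generate_well` builds one well as: well-level burst onsets → per-burst
electrode recruitment (probability `participation_prob`, default 1.0) →
per-electrode onset jitter (Gaussian, sd 10 ms) → within-burst Poisson
spiking at `intraburst_rate` for a gamma-distributed duration (shape 4) →
plus an independent tonic Poisson background per electrode.  Everything is
deterministic given the seed; per-well seeds derive from the master seed by
the counter scheme `default_rng([master, well_index, div_index])`.

**Burst onsets are a renewal process, not a plain Poisson process.**
Successive onsets are separated by the burst's own duration, a dead time
`min_burst_gap` (default 1.0 s), and an exponential waiting time whose mean
is set so the marginal onset rate equals `burst_rate` exactly.  The dead
time exceeds the detector's 0.8 s merge window, so distinct generated
bursts remain distinct after detection.  A homogeneous Poisson process at
the WT rate (12 bursts/min) would place roughly a fifth of consecutive
bursts inside the merge window, biasing recovered bursts/min down and
burst durations up by ~20–30 % — which would defeat the generator's
purpose of carrying recoverable ground truth.  The recovery contract
(bursts/min and mean burst duration within 15 % of the generator
parameters over 100 WT wells) is enforced in the test suite.

Genotype presets (documented configuration, not claims about biology):

| parameter            | WT   | K78R | direction in the mutant |
|----------------------|------|------|-------------------------|
| tonic rate (Hz)      | 0.5  | 0.5  | —                       |
| bursts/min           | 12   | 3    | fewer bursts            |
| burst duration (s)   | 0.4  | 3.0  | longer bursts           |
| intraburst rate (Hz) | 60   | 35   | sparser bursts          |

The implied phenotype follows the mutant direction on every axis: longer
IBIs (≈ 17 s vs ≈ 4.6 s) and more spikes per burst (105 vs 24) emerge from
the table above.  `participation_prob` and onset jitter are equal across
genotypes ("equal-synchrony generation"): no quantitative synchrony
difference is modelled, since the original comparison found none.

**Limitation — equal recruitment is not equal synchrony statistics.**  The
three synchrony measures are functionals of burst rate, duration and
within-burst density, all of which differ between presets by design.  With
dozens of wells per group the permutation test therefore detects
systematic differences in % spikes in network spikes, MI and STTC even
under equal-recruitment generation; a simulated study should not be
expected to reproduce the original null synchrony result, and the
acceptance check for that clause fails for this structural reason.  More
generally the generator makes no attempt at biophysical realism: no
refractory periods, no waveforms, no maturation dynamics (a per-DIV rate
scale hook exists but defaults to off), and tonic spikes are uniform in
time.  Passing tests demonstrate correctness of the *analysis* under the
generator's statistical structure, not fidelity of the generator to real
cultures.

### Drug-effect model

`apply_drug` interpolates every float generator parameter from the source
(mutant) toward a target (WT) preset with a Hill weight
`w(dose) = dose^n / (dose^n + EC50_eff^n)`; at or above `overshoot_dose`
all rates are additionally multiplied by a suppression factor.  Defaults
(`EC50_eff` 0.5 mM, `n_eff` 2, overshoot at 2 mM with factor 0.3) were
chosen once to reproduce the qualitative chronic-ETX pattern — little
effect at 0.25 mM (w ≈ 0.2), near-rescue at 0.75 mM (w ≈ 0.69), and a
high-dose overshoot in which firing falls below the WT level.  The model
is continuous and monotone in dose below the overshoot threshold.

## TEVC pipeline

A recording follows the standard solution protocol: ND96 (5 s), HK24
(30 s, basal GIRK current), eight ETX steps at 0.01–30 mM (30 s each,
strictly increasing), then HK24 + Ba²⁺ (30 s) to block all GIRK current
and reveal the non-GIRK leak.  Currents are in µA at −80 mV; inward GIRK
currents are negative.

Per segment the steady-state current is the mean over the final `window`
seconds (default 5 s), never reaching into the first 1 s after a solution
switch: the averaging window is clipped at `segment start + guard`.  With
the defaults this matters only for the 5 s ND96 segment, where the
effective window is 4 s; a window longer than the shortest segment is an
error.  GIRK current at any step is the step current minus the Ba²⁺-block
current, and

    % inhibition(x) = 100 × (1 − GIRK(x) / GIRK(HK24)).

Values outside [0, 100] are legal (noise) and not clamped; a zero HK24
GIRK reference is an error.

### Dose–response models and fitting

Three standard models are fitted (x in mM):

* one-component isotherm: `%inh = 100 x / (x + Kd_app)`
* Hill: `%inh = 100 xⁿ / (xⁿ + Kd_appⁿ)`
* two-component isotherm:
  `%inh = 100 c x / (x + Kd1_app) + 100 (1 − c) x / (x + Kd2_app)`

Fitting is bounded least squares (`Kd > 0`, `n > 0`, `0 ≤ c ≤ 1`) with
multi-start initialisation: Kd over a 5-point geometric grid spanning the
tested concentrations, n ∈ {0.5, 1, 2}, c ∈ {0.2, 0.5, 0.8}; the best
start by residual sum of squares wins, with objective tolerances of 1e−12.
Reports include asymptotic standard errors, RSS and small-sample AICc; the
package ranks models by AICc but declares no automatic winner, since
near-nested models (e.g. a Hill fit with n ≈ 1 on one-site data) can fit
equally well.  For the two-site model the high-affinity site is
canonically site 1 (`Kd1 < Kd2`); with degenerate data (`c → 0` or `1`)
the second site is unidentifiable and its standard error diverges —
expected, not an error.  Points from several oocytes are pooled for
fitting by default.

A separate fixed-exponent activation fit, `I = Imax G⁴ / (G⁴ + Kd⁴)`,
relates GIRK2 current to measured Gβγ surface density (arbitrary
fluorescence units); only `Imax` and `Kd` are free, the Hill coefficient
is fixed at 4 by the tetrameric stoichiometry of channel activation.

### Synthetic TEVC traces

`generate_tevc` renders the protocol with a chosen inhibition model:
target current is `leak` in ND96/Ba²⁺ and `leak + girk_max (1 − inh(x)/100)`
otherwise, with first-order settling (τ default 0.25 s, 0 = instant) at
each switch and additive Gaussian noise.  Noiseless traces reproduce model
values exactly (e.g. 1 mM ETX against a 1 mM one-site Kd gives exactly
half the GIRK current), which anchors the segmentation and inhibition
arithmetic in closed form.

## Problem sizes

Default study conditions: one 48-well plate, 24 wells per genotype, 15 min
recordings on five days in vitro (DIV 15–27).  The analysis demo scripts
default to a smaller plate (8 + 8 wells, three days, 5 min) chosen so the
whole chain reruns in seconds; `--full` restores the study size.  The
permutation-calibration simulation uses 500 datasets of 48 wells at 60 s
per recording, as discussed above.

## Known limitations

* The spike-list CSV dialect (`time_s,electrode,well`) is this package's
  own; platform exports need renaming to these columns.
* The MI estimator and the network-burst definition are reconstructions of
  statistics whose reference implementations are not published in text
  form; both are parameterised and the network-burst variant is excluded
  from headline features.
* Whether rates should use the active period rather than total duration,
  and whether the original per-well MFR is electrode-normalised, is
  undocumented upstream; this package uses total duration and per-active-
  electrode normalisation.
* Dose–response standard errors are asymptotic (from the Jacobian at the
  optimum), not profile or bootstrap intervals.
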