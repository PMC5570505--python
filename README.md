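# forkcomb

Replication kinetics and fork-stall inference from dual-pulse DNA combing
data, with a ground-truthed fiber simulator.

## The problem

In a combing experiment, S-phase cells are pulse-labeled with CldU (red)
for 5 minutes and chased with IdU (green) for 10 minutes; single DNA
molecules are stretched and each fiber is measured as an ordered list of
red, green and unlabeled tracks (kb). Forks read as RG/GR events, origins
as GRG (first pulse) or isolated G (second pulse), terminations as RGR.
But a fork that **stalls** — stops and never resumes — before the chase
leaves only red, and an isolated red track is ambiguous: termination,
stalled fork, or origin with both forks stalled.

forkcomb resolves this from the context of neighboring forks. A
red–unlabeled–green junction (RUG/GUR) is unambiguous evidence of exactly
one stalled fork; green–unlabeled–green (GUG) of none. The **apparent
stall rate**

    s = (RUG + GUR) / (RUG + GUR + GUG)

is then used as the per-fork stall probability to weight every reading of
the remaining ambiguous patterns (RUR, UR, URU, GRUR, RURUR, ...): an
interpretation requiring *k* extra stalls gets weight *s^k*, so at
s = 0.10 an RUR event has a 1% chance of being two converging stalled
forks. From the weighted expected counts the package computes
stall-corrected replication statistics per fiber and dataset:

* origin firing rate *I* (origins per kb unlabeled DNA per min; ~2.3/Mb/min
  in unperturbed fission yeast),
* fork density per pulse (forks per kb unlabeled),
* fork rate *v* from a Gaussian fit to the green-track rate histogram
  (~0.91 kb/min),
* stalls per kb and the fork stall rate (stalls over pulse-1 forks,
  stalled forks in the denominator — one origin with one stalled fork is a
  50% stall rate),
* treated/untreated ratios with Welch t-tests,
* Poisson lesion densities from gel intact-fragment fractions.

A stochastic simulator (`forkcomb.simulate`) generates labeled fibers with
full ground truth — origins, per-fork speeds, lesion pause/stall
interactions, permanent stalls, fragmentation, optical-resolution merging,
measurement noise — and is what every estimator is validated against. See
`docs/methods.md` for the model and its limits.

## Worked example

```
$ forkcomb simulate --seed 1 --out fibers.tsv --truth truth.json
untreated: 63 fibers (46 analyzable), 25.0 Mb -> fibers.tsv
$ forkcomb analyze fibers.tsv --out summary.json
```

Key fields of `summary.json` for this run:

```
"s_apparent": 0.29771
"fork_rate":  {"fit_mean_kb_min": 0.887, "sample_mean_kb_min": 0.966, "n_samples": 471}
"origin_rate_total": {"mean": 0.0022226, "sd": 0.0011079, "n": 46}
"stall_rate":        {"mean": 0.1529,    "sd": 0.0682,    "n": 46}
```

Reading the numbers: 46 fibers ≥120 kb (~24 Mb) were analyzed. The
Gaussian-fit fork rate 0.887 kb/min recovers the simulated 0.91 kb/min
within 3% — note the plain sample mean (0.966) is dragged up by tracks
fused across sub-resolution gaps, which is why the histogram is fitted.
The origin rate 0.00222 origins/kb/min = 2.2 origins/Mb/min recovers the
simulated 2.3. The mean per-fiber stall rate 0.153 tracks the simulation's
true detectable stall fraction (0.14 at these settings); the apparent rate
s = 0.30 is junction-census-based and deliberately not a per-fork
probability estimate (see the methods note). And

```
$ forkcomb lesions --intact-fraction 0.37 --fragment-kb 20
intact=0.3700 over 20 kb -> 0.049713 lesions/kb (one per 20.1 kb); ...
```

is the Poisson inversion λ = −ln(0.37)/20.

The numbered scripts under `analysis/` run the full study design on
synthetic data — `01_simulate_datasets.py` (untreated plus three damage
regimes: frequent mild lesions 1/kb, rare severe 1/25 kb, strand breaks
1/50 kb), `02_analyze_datasets.py`, `03_compare_treatments.py`
(treated/untreated ratio tables) and `04_lesion_density.py` — writing
tables under `results/`.

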