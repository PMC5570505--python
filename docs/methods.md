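# Methods

## The measurement problem

Single-molecule DNA combing stretches genomic DNA on glass so that
replication tracks can be measured by immunofluorescence. Cells are pulsed
with CldU (detected red) for 5 minutes and chased with IdU (green) for 10
minutes; each combed fiber then carries an ordered sequence of red, green
and unlabeled tracks with lengths in kb. Unlabeled DNA on a mid-S-phase
fiber is ambiguous by construction: it is either DNA replicated *before*
the first pulse or DNA still unreplicated at harvest, and nothing local
distinguishes the two. That ambiguity is exactly what makes fork stalls —
forks that stop and never resume within the experiment — hard to score: an
isolated red track may be a termination, a stalled elongating fork, or an
origin whose two forks both stalled.

forkcomb implements the context-based resolution of this ambiguity: the
colors flanking each unlabeled gap constrain its state, definite stalls are
pinned where the geometry allows only one reading, and the rest is handled
probabilistically.

## Gap-state model

Every interior unlabeled gap is assigned a binary latent state:
pre-pulse-replicated (**P**) or unreplicated (**N**).

* A **green edge** facing a gap is always an active fork head moving into
  it, so the gap must be N.
* A **red edge** facing a P gap is a fork tail (the fork came from there);
  facing an N gap it is the head of a fork that stalled before the second
  pulse.

Consequences, which reproduce the classical pattern taxonomy and the stall
signatures:

| junction | state | reading |
|---|---|---|
| green–U–green (GUG) | N forced | two unstalled converging forks |
| red–U–green (RUG/GUR) | N forced | exactly one stalled fork (red side) |
| red–U–red (RUR) | free | both tails (P) or both stalled heads (N) — coupled |
| any flank at a fiber end | unknown | uninformative |

Within a labeled segment (a maximal run of red/green tracks) the parse is
forced: every interior red track is a first-pulse origin (two forks
diverging inside it), every interior green track a second-pulse termination
(two forks converging), and a red edge facing an N gap splits a stalled
head plus an origin off the edge track. Fork chains are read off between
these split points; a chain counts toward the first pulse if it covers any
red, the second if any green. A single red track with both gaps P is a
first-pulse termination (two forks); with one N, a stalled elongating fork;
with both N, an origin with both forks stalled. Readings that would require
an *invisible* stall (a fork stalled before labeling, leaving no track at a
gap boundary) are excluded, which is why a shared red–red gap admits
exactly two readings rather than four.

Labeled tracks cut by the physical fiber end are parsed as continuations
(no stall inference at breaks) and flagged; the `exclude_ends` option drops
such events entirely, mirroring the end-artifact re-analysis customary for
combing data.

## Probabilistic resolution of ambiguous events

The dataset's **apparent stall rate** is estimated once, from unambiguous
junctions pooled over all analyzable fibers:

    s = (RUG + GUR) / (RUG + GUR + GUG)

Ambiguous events are then enumerated. Segments linked through shared
red–red gaps form one event group; each shared gap is one free binary
state, and each red edge facing an uninformative (fiber-end) gap is an
independent free state. All 2^E assignments are evaluated, assignments with
identical event counts collapse into one interpretation, and an
interpretation requiring k stalls beyond the group's forced minimum gets
unnormalized weight s^k; the minimal-stall interpretation absorbs the
remainder (weights are renormalized proportionally if s is so large the
remainder would be negative). Two consequences fix the conventions: an
isolated red with uninformative context gets weights 1−s−s² / s / s² for
its termination / stalled-fork / doubly-stalled-origin readings, and an
RUR event at s = 0.10 carries a 1% probability of being two stalled forks.
Expected origin, termination, fork and stall counts per fiber are the
weight-averaged sums; `mode="naive"` instead applies the single-reading
taxonomy (isolated red = termination, no stalls), which is what the plain
fork-density formulas assume.

## Estimators

All per-fiber normalizations use the fiber's **unlabeled DNA length**,
knowingly conflating pre-pulse-replicated with unreplicated DNA — over the
labeling window the two conventions nearly cancel, since the unlabeled
fraction at harvest approximates the average unreplicated fraction during
the pulses.

* **Origin firing rate**: expected origins (GRG-type for pulse 1, isolated
  green for pulse 2; stall-corrected in probabilistic mode) per kb unlabeled
  per minute of pulse (15 min combined; 5 and 10 min for the per-pulse
  rates).
* **Fork density**: expected forks ongoing in each pulse per kb unlabeled;
  stalled forks count in pulse 1 only. In naive mode this reduces exactly
  to "origins and terminations twice, unidirectional forks once".
* **Fork rate**: each green track continuing from a red track (RG, GR, and
  both outer greens of GRG) divided by the 10-min chase. The dataset value
  is the mean of an unweighted least-squares Gaussian fit to the 0.1
  kb/min-binned histogram, initialized at the sample moments; this is
  deliberately robust to the low-side pedestal from forks that stalled or
  broke during the chase and to the high-side tail from tracks fused across
  sub-resolution gaps, both of which drag the plain sample mean (reported
  alongside). Below 30 samples, or on non-convergence, the sample moments
  are returned flagged.
* **Stalls per kb**: expected stalls (definite plus weighted ambiguous) per
  kb unlabeled — the contribution of stalling to replication slowing.
* **Stall rate**: expected stalls over expected pulse-1 forks, stalled
  forks kept in the denominator; an origin with one stalled fork is a 50%
  stall rate. Dataset means are unweighted across fibers with SD across
  fibers; zero-denominator fibers are skipped with a log entry.
* **Comparisons**: treated/untreated ratio of dataset means with a Welch
  (unequal-variance) t-test on per-fiber values (per-sample for fork rate);
  ratio error bars by first-order delta-method propagation.

**Lesion densities** use the Poisson inversion λ = −ln(intact fraction)/L
for gel-quantified restriction fragments (default L = 20 kb for bands
pooled at the gel exclusion volume), plus the arithmetic for nick spacing
from a nick:DSB excess range and for expected lesion encounters per fork
(speed × duration × density).

## The synthetic-fiber generator

A 1-D nucleation-and-growth model on a 25 Mb linear molecule: origins fire
as a Poisson process at 2.3 origins per unreplicated Mb per minute (no
fixed origin map — the estimator measures exactly this homogeneous rate);
each origin launches two forks with speeds drawn once per fork from a
truncated normal (mean 0.91 kb/min, CV 0.1); forks terminate on meeting.
Replication starts 10 minutes before labeling so pre-pulse-replicated DNA
exists (the source of RUR ambiguity); harvest ends the 5+10 min label
window, and DNA is painted by replication time. Lesions are Poisson-placed;
at each lesion a fork stalls permanently with probability
`p_stall_per_lesion`, else pauses `pause_min_per_lesion` (the local-slowing
mechanism: net speed v/(1+λτv)). Spontaneous permanent stalls occur at
0.0225 per kb traversed, the hazard that puts the untreated operating point
at a detectable stall fraction of ~0.14; stalled forks never restart. The
molecule is fragmented by Poisson cutting (mean 450 kb), tracks below the
2 kb optical resolution are absorbed into neighbors (a sub-resolution gap
between like colors fuses them), multiplicative 2% length noise is applied,
and fibers under 120 kb are flagged excluded. Integration is time-stepped
(0.05 min) with alternating fork priority at shrinking gaps; discretization
error is far below resolution and noise. Runs are bit-reproducible per
seed.

Ground truth records every origin, lesion and stall. A stall is flagged
**detectable** when it begins before the second pulse: such stalls leave
either a red track with no green or an unlabeled gap that neighboring-fork
context can expose, and the paper's detection window is defined the same
way. A `covered` flag additionally records stalled heads later overrun by a
converging fork (their signature vanishes from the fiber); the
ground-truth pulse-1 fork count includes detectable stalled forks, matching
the estimator's denominator convention.

Damage presets set the three studied regimes: frequent mild lesions
(1/kb, 0.5% stall per lesion, 0.35 min pause — reproducing the ~76%
fork-rate ratio), rare severe lesions (1/25 kb, 5% stall per lesion), and
rare strand breaks (1/50 kb, every break stops the incoming fork). The
rare-lesion presets scale the origin firing rate by 0.47 and 0.58
respectively, emulating the checkpoint's origin inhibition, which is not
mechanistically modeled.

## What the simulator does and does not emulate

It emulates the labeling design, fragmentation, optical resolution and
measurement noise, fork-speed heterogeneity, pause-based slowing and
permanent stalling. It does not model checkpoint signaling dynamics,
fork restart or repair, dNTP-pool coupling between origin number and fork
speed (the mechanism behind the experimentally observed fork-rate *increase*
under rare bulky lesions), replication timing structure, or cell-to-cell
asynchrony. Passing recovery tests therefore show the estimators are
faithful to the assay geometry and the stated stochastic model — not that
real chromatin obeys homogeneous origin firing.

## Known limitations and accuracy

* The apparent stall rate s systematically exceeds the per-fork stall
  probability late in S phase: GUG evidence is destroyed when converging
  forks terminate, while stalled gaps persist. At the untreated operating
  point s ≈ 0.30 against a true per-window fraction of 0.14. The
  junction-census formula is retained as specified; the end-to-end stall
  *rate* still recovers the true detectable fraction within ±0.05 across
  true fractions 0–0.42 (tested at 25 Mb), because the inflated ambiguous
  mass and the detection losses (sub-resolution red stubs, covered heads)
  act in opposite directions.
* Stalls-per-kb ratios saturate near ~2× under heavy stalling: killing
  forks also inflates the unreplicated-DNA denominator. The >3× increase
  reported experimentally for the frequent-lesion regime is not reachable
  jointly with a 0.5%-per-lesion stall probability in this generative
  model.
* Track fusion across sub-resolution gaps inflates a minority of fork-rate
  samples (visible as a high sample mean at high replication fraction);
  the Gaussian fit is the guard against it.
* Interpretation groups are capped at 2^20 assignments; longer coupled
  red chains than this do not occur in realistic fibers and raise an error
  rather than being truncated.
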