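# Methods

## Model

`tandemhmm` models a sequence as alternating background and tandemly
repetitive stretches. The hidden state space contains one context-blind
non-repetitive state (NR), one repetitive state R(p) per period p ∈ 1..k,
and, per period, indel-offset machinery: runs of up to i insertion states
(emitting at background, look-back 0), runs of up to d silent deletion
states, and — for every run length — a chain of exactly p J-states whose
emissions use the shifted look-back (p + a after a insertions, p − j after
j deletions) before control returns to R(p). Deletion runs in a period-p
repeat are capped at p − 1 so the shifted look-back stays positive;
overshooting D states and their chains are still enumerated (the explicit
state count is 1 + Σ_p (1 + i + d + (i+d)·p)) but receive no incoming
transitions.

Emissions in repetitive/J states: the letter p (or shifted q) positions
back repeats with probability m; the remaining 1 − m is distributed over
mismatching letters proportionally to their background frequency, so the
distribution sums to one for every context letter. The ambiguity letter N
is ratio-neutral in context-blind states and a guaranteed mismatch in
context-sensitive ones (its background mass is treated as zero in the
mismatch renormalization), which stops N-runs from scoring as repeats.
Positions whose look-back reaches before the start of the decode window are
scored as a mismatch against an unknown context.

Decoding maximizes transitions × relative emission likelihood (E/E₀) in
natural-log space. Because our emission model defines repeat emissions
relative to the same background used for E₀, decoding with raw emissions
differs from relative-likelihood decoding only by a per-position constant,
a property the test suite checks.

## Transition parameterization and defaults

All outgoing probability mass sums to one per state:

| parameter | meaning | default |
|---|---|---|
| k | maximum period | 100 |
| λ | period-prior decay, γ_p = λ^p/Σλ^i | 0.85 |
| ν_in | NR → repeat entry | 0.02 |
| ν_out | repeat → NR exit | 0.05 |
| m | match probability Pr[S_t = S_{t−p}] | 0.7 |
| AT | background A+T fraction | 0.6 |
| indel_open | total I/D opening mass (split evenly) | 0.001 |
| indel_extend | consecutive-indel continuation ρ | 0.2 |
| i, d | max consecutive insertions/deletions | 10, 10 |
| min_unit | minimum full units reported | 2 |

An insertion run of length a costs log(open/2) + (a−1)log ρ + log(1−ρ)
(the last factor is dropped at the bound a = i, where the run must exit
into its J-chain); deletion runs are analogous with the per-period cap.
When a period supports no deletions (p = 1) the deletion-opening mass folds
into the self-transition.

Defaults were chosen, once, to satisfy two competing demands we measured
during design: annotations of mutated repeats must stay coherent at 20–30%
substitution rates (m = 0.7 is decisive here; larger values fragment the
Viterbi path into period-hopping pieces), and random sequence must still
yield a usable density of null annotations (~70 regions/Mb at k = 50) for
score calibration (ν_in = 0.02, ν_out = 0.05). All are overridable by flag,
config file, or `tune`.

## Windowed decoding

Viterbi memory is window × states. Long sequences are tiled with windows of
`memory_budget / (state_count × 8 B)` positions (256 MiB budget per thread
by default), clamped below by max(10 k, 2 × overlap), with overlap
max(1000, 4 k). Windows decode independently (parallelizable by threads;
results are identical regardless of thread count) and each contributes the
labels of its core region, cut at overlap midpoints; a sequence fitting in
one window is decoded identically to the unwindowed path. The stitched
path's running score is rebuilt from its labels; at a stitch point whose
label pair is topologically impossible (rare — the overlap is at least
four periods) the position is scored as a fresh entry, and repeats spanning
a boundary merge into a single annotation, which the tests verify against
an unwindowed decode. The dynamic program never materializes J-states:
once entered, a J-chain is a forced walk, so every indel excursion
collapses to one transition evaluated in O(1) from prefix sums of the
shifted emission scores. Equivalence with the fully explicit state space is
enforced by a brute-force oracle in the test suite (scores to 1e−9, labels
exactly); prefix-sum association makes bitwise score equality unattainable,
observed differences are ~1e−13.

## Annotation and scoring

Maximal non-NR runs of the path become regions; a run shorter than
min_unit × p is dropped; the start is adjusted to max(0, t_start − p). The
region score is the sum of log-transition + log-relative-emission terms
over the raw span, identically the difference of the cumulative path score
at its ends; both are computed and must agree within 1e−6. Ties during
decoding prefer NR, then smaller periods, then non-indel states.

## Repeat splitting

Letters of a region get cyclic profile indices 1..p (insertions '\*', not
advancing the cycle; deletions advance it without consuming a letter). Two
adjacent windows of w = max(12 p, 60) letters slide along the region; at
each boundary both windows are summarized as p × |Σ| frequency profiles
(pseudocount 0.5 per cell, rows normalized) and compared with half the
symmetrized Kullback–Leibler sum. Strict local maxima above `--split_val`
(default 2.5), at least w apart, are candidate splits. Each candidate is
then refined: the consensus units of the two sides are tiled across the
neighbourhood (phases anchored on the adjacent sequence) and the boundary
is placed at the maximum-likelihood changepoint between the two templates.
Adjacent subrepeats with the same canonical unit (the lexicographically
minimal rotation) are re-merged, which removes splits faked by undetected
indels.

Choices made here, and why: the window width gives ≥ 12 observations per
profile row — narrower windows (we tried 4 p) leave the null divergence
distribution overlapping the true-boundary peaks for small periods. The
threshold 2.5 was calibrated on single-pattern repeats (periods 1–10,
substitution rates 0–0.2, mutated but never switching units): 0/300 false
pattern changes at those rates, ~2% at rate 0.3. The changepoint refinement
exists because both the divergence peak and Viterbi fragment boundaries
jitter by tens of nt under mutation while the benchmark asks for ±10 nt
localization.

`pattern_changes` chains subrepeats across region fragments: neighbouring
segments whose units are rotation- or harmonic-equivalent (identity > 50%
after tiling to the least common multiple of the unit lengths) are merged —
a decayed repeat is often annotated in pieces at harmonic periods — and the
refined junctions between genuinely different units are reported as
pattern changes. The two-subrepeat benchmark counts exactly these.

## P-values

Annotating random sequence at the model's background composition gives ω
(fraction of letters annotated) and a set of null region scores whose upper
tail is exponential. The fit anchors the location μ at the 5% score
quantile and takes σ as the mean excess above it — exact for a true
location-scale exponential by memorylessness, and robust to the soft lower
edge the reporting threshold imposes (the sample minimum is an outlier that
inflates a min-anchored scale by ~70% and breaks the survival agreement).
`P(s) = min(1, ω e^{(μ−s)/σ})`, clamped because the raw formula exceeds 1
below μ. The packaged defaults (`--ploc 2.582`, `--pscale 0.990`,
`--pfreq 0.00195`) come from a 10 Mb calibration of the default model with
seed 20240601 (recorded in `tandemhmm/data/default_pvalue.json`); they are
artifacts of this implementation and should be recalibrated (`tandemhmm
calibrate`) after changing model parameters or for unusual compositions.

## Tuning

`tune` evaluates a candidate grid (built-in: AT ∈ {0.3..0.7} × m ∈
{0.6, 0.7, 0.9}, 15 candidates; arbitrary grids via `--tune_file`) on the
input and on a locally shuffled copy (independent permutations inside
fixed windows, preserving regional composition as observed in isochores).
FDR is estimated as shuffled coverage over original coverage; the winner
maximizes coverage subject to FDR ≤ 10%. Candidate runs disable indel
states for speed unless `--tune_indel`; the final annotation re-enables
them. Coverage is the fraction of positions under the union of
annotations.

## Synthetic data

The generators are pure functions of their seed. `random_sequence` draws
i.i.d. letters at a given AT richness; `mutate` substitutes each position
independently, replacing uniformly among the three other letters;
`make_split_case` rejection-samples two period-p units with rotation
similarity ≤ 50%, concatenates 500 nt perfect repeats of each, and mutates
the 1000 nt result. These emulate the point-substitution decay of real
repeats but not indel mutation, multi-pattern mosaics, higher-order repeat
structure, or the compositional heterogeneity of real genomes — passing
benchmarks on them demonstrates the algorithmic contract, not field
performance on a genome.

## Problem sizes used by the shipped experiments

Score-distribution and calibration checks run on 6 Mb (fit) + 3 Mb (fresh
null) of 60% AT random sequence at k = 50; the shipped P-value defaults use
10 Mb at k = 100; the splitting benchmark runs 200 cases per (period 1–10 ×
substitution rate {0, 0.2}) condition; tuning runs the 15-candidate grid on
a ~48 kb half-repetitive synthetic genome. These are the package's chosen
desk-scale study sizes; all are parameters of the respective functions.

## Known limitations

- DNA/RNA only; no protein alphabet.
- Indel modeling covers consecutive runs only (up to i insertions or d
  deletions per excursion); complex interleaved indel patterns are
  approximated by consecutive ones.
- Window-stitch points can, in principle, bisect a repeat longer than the
  window overlap; such repeats merge at the region level but their scores
  are then sums over stitched labels rather than a single-window Viterbi
  score.
- P-value calibration assumes the null composition matches the model
  background; strongly biased genomes need retuning and recalibration.
- No hierarchical characterization of higher-order repeats: subrepeats are
  a flat segmentation.
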