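# tandemhmm

Tandem repeats — adjacent copies of a short unit, from microsatellites to
megabase satellite arrays — are among the most common patterns in genomic
DNA and among the most troublesome: they break homology search statistics,
inflate false positives, and decay under mutation until they are hard to
recognize. `tandemhmm` identifies and labels locally repetitive DNA/RNA,
producing scored, P-value-annotated repeat regions with canonical unit
names and subrepeat structure, suitable for masking workflows or for
downstream repeat analysis.

## The model

The annotator is a context-sensitive hidden Markov model decoded with a
windowed Viterbi algorithm:

- one **non-repetitive state** emits letters at background frequency
  (`--at` controls AT richness);
- a **repetitive state R(p)** for every period p = 1..k emits the letter
  seen p positions back with probability m (`-m`), spreading the remaining
  1 − m over mismatches proportionally to background. Entry into period p
  is weighted by a decaying prior γ_p = λ^p / Σ_i λ^i;
- **indel-offset states**: up to i consecutive insertions (I, context-blind)
  or d consecutive deletions (D, silent) inside a period-p repeat feed a
  chain of p **J-states** that carries the shifted look-back (p + a after a
  insertions, p − j after j deletions) back to R(p), so a single indel does
  not cost p spurious mismatches.

Decoding maximizes the product of transitions with *relative* emission
likelihoods E/E₀ (emission over background), which keeps scores honest in
biased compositions. A region annotated over positions t_start..t_end with
period p is reported from t_start − p (the first unit of a repeat precedes
the first position a backward-looking state can recognize) with score

    score = Σ log T + log(E/E₀) = log P′(t_end) − log P′(t_start)   [nats]

Post-processing finds **repeat splits** — changes of pattern inside a
region — by sliding two adjacent windows along the repeat, comparing their
per-profile-index letter frequencies with a symmetrized Kullback–Leibler
divergence, and refining each candidate boundary with a maximum-likelihood
changepoint against the two unit templates. Units are named by their
lexicographically smallest rotation (`GTTG` → `GGTT`).

Scores convert to P-values via a null model calibrated on random sequence:
with ω the repetitive fraction of the null and (μ, σ) an exponential fit to
null region scores, `P(s) = min(1, ω·exp((μ − s)/σ))`. A `tune` subcommand
grid-searches parameters against a window-shuffled null, keeping the
candidate with the greatest coverage whose estimated false discovery rate
(shuffled coverage / original coverage) stays below 10%.

## Worked example

Generate a synthetic two-pattern repeat (500 nt of one unit, 500 nt of
another, 10% substitutions) and annotate it:

```sh
tandemhmm simulate --kind split-case -p 4 --rate 0.1 --seed 11 --out example.fa
tandemhmm annotate example.fa -p 10 --pval
```

```
seq	start	end	period	score	pvalue	unit	n_subrepeats
split_case_p4_r0.1_seed11	1	1000	4	637.2875	5.56e-282	AGGG	2
```

One period-4 region covers the whole sequence with score 637.3 nats — far
beyond anything random sequence produces, hence the vanishing P-value. The
JSON output shows the two subrepeats and the detected pattern change at
position 500, each unit named canonically:

```
"subrepeats": [
 {"start": 4,   "end": 500,  "pattern": "AATC", "canonical_unit": "AATC"},
 {"start": 500, "end": 1000, "pattern": "GGGA", "canonical_unit": "AGGG"}
]
```

Useful flags: `--mem` prints the expected decode memory and exits;
`--winsize`/`--overlap` control windowed decoding; `--min_unit 0` reports
repeats shorter than two full units; `--split_val` adjusts the splitting
threshold; `--ploc/--pscale/--pfreq` override the packaged P-value
calibration; `--mask-out masked.fa` writes a soft-masked FASTA.

Library use mirrors the CLI:

```python
from tandemhmm import ModelParams, annotate_sequence
regions = annotate_sequence(sequence, ModelParams(k=50))
```

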