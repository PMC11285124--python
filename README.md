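# ssvfilter

A software implementation of the single-segment ungapped Viterbi (SSV)
nucleotide homology filter: FASTA targets are searched against HMMER3-format
profile HMMs using threshold-scaled signed 8-bit emission scores, a
reset-on-overflow/underflow dynamic-programming engine with per-cell hit
reporting, all-to-all search over concatenated coordinate spaces, and a
host-side validity check that removes padding and record-boundary artifacts.

For each model a threshold score `t` (bits) is derived from Gumbel tail
statistics at a requested P-value (default 0.02), and emissions are rescaled
by `tau = 256/t` so an accumulated ungapped segment passes the threshold
exactly when the 8-bit accumulator reaches 256. Models without precomputed
statistics can be calibrated by simulation.

## Layout

| module | contents |
|---|---|
| `ssvfilter.phmm_io` | HMMER3 ASCII `.hmm` read/write, concatenated model DB |
| `ssvfilter.sequence_io` | FASTA input, 2-bit encoding with seeded ambiguity replacement, concatenated/padded target DB |
| `ssvfilter.projection` | Gumbel thresholds, `tau` scaling, int8 quantization, simulation calibration |
| `ssvfilter.ssv_core` | max-score recurrence, row-major reference hit engine, vectorized segmented engine, 8-bit adder cell semantics |
| `ssvfilter.hits` | global→local hit resolution, single-diagonal boundary validation, TSV/BED output |
| `ssvfilter.synthetic` | random models/targets, planted segments with exact ground-truth scores |
| `ssvfilter.cli` | `run_search` pipeline and the `ssvfilter` command |

## CLI

```sh
ssvfilter targets.fa models.hmm \
    --pvalue 0.02 --seed 1 --out hits.tsv \
    --bed-out hits.bed --summary-out run.json --verbose
```

Models lacking `STATS` lines need `--calibrate N:LEN` (e.g. `--calibrate
4000:1000`) to fit Gumbel parameters from simulated random sequences. Other
flags: `--adjust-bits` (additive threshold offset in bits), `--segment-width`
(evaluation-order segment size, default 12288), `--strand forward|both`,
`--report-rejected` (keep boundary-rejected hits, flagged).

The hit table reports the threshold-crossing cell of each validated hit in
1-based per-record coordinates.

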