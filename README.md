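# oligobench

Standardized, reproducible benchmarking of error-correction codecs for
DNA data storage.

Storing digital data in synthetic oligonucleotide pools requires a codec
that maps a binary payload onto many short DNA sequences and recovers it
from noisy, unevenly sampled sequencing reads. Every stage of the
workflow — array synthesis, PCR amplification, dilution, sequencing —
introduces substitutions, deletions, insertions, coverage bias and
outright sequence loss. Comparing codecs fairly therefore requires a
fixed channel, fixed evaluation protocol and harmonized code rates.
`oligobench` packages that whole pipeline: channel simulators, read
clustering and consensus calling, reference codecs, an adaptive
sensitivity-analysis harness, and storage-density accounting. It is
aimed at developers of DNA-storage codecs and clustering tools who want
desk-scale, seed-reproducible comparisons.

## What it measures

A *trial* runs encode → channel → cluster/consensus → decode and
succeeds only if the decoded file is byte-identical to the input. The
standard performance metric is the channel-parameter value x* at which
decoding succeeds with 95% probability, estimated by logistic
regression of success on log x:

    P(success | x) = logistic(β₀ + β₁ log x),   x* : P(success | x*) = 0.95

Outcomes come from a three-stage adaptive scan (10 log-spaced points
over the full range, then twice 10 more over [t/2, 2t] around the
running estimate — 30 trials in total). Two-parameter trade-offs
(e.g. physical redundancy R vs sequencing depth s) are mapped by fixing
one parameter at 10 log-spaced values while scanning the other and
keeping the Pareto-efficient threshold pairs.

Storage density converts code rate ρ (bit/nt) and physical redundancy R
(oligo copies per sequence) into payload bytes per gram of DNA:

    D = ρ·N_A / (R·M·8·10¹⁸)  [EB/g],  M = 662 g·mol⁻¹·bp⁻¹ for dsDNA

which gives ≈ 227 EB/g at the biophysical limit (ρ = 2, R = 1).

## Components

| Module | Contents |
| --- | --- |
| `oligobench.core` / `seqio` | domain types, seeded payloads, FASTA/FASTQ I/O |
| `oligobench.channel` | iid error channel (53/45/2 sub/del/ins mix, dropout) and a multi-stage workflow channel (synthesis → PCR → dilution → PCR → sequencing) with high-/low-fidelity presets (~0.1% / ~1.5% nt⁻¹) |
| `oligobench.codecs` | no-ECC baseline, Reed–Solomon inner/outer codec, fountain (LT) codec with detection-only inner parity, subprocess adapter for external codecs; rate presets 0.50/1.00/1.50 bit/nt |
| `oligobench.cluster` | naïve (unique-read) clustering, MinHash/LSH greedy clustering, star-alignment consensus, sensitivity/accuracy/specificity metrics |
| `oligobench.bench` | resource-limited trials, adaptive 95%-threshold scans, Pareto fronts, serial-dilution / serial-amplification / down-sampling protocols |
| `oligobench.density` | storage density, mass↔redundancy conversion, read-set error and coverage profiling |

## Worked example

Encode a 904-byte payload with the Reed–Solomon inner/outer codec at
0.50 bit/nt, push it through the iid channel at 2% errors with 30 reads
per sequence, cluster, and decode:

```bash
oligobench fixtures payload --size 904 --seed 1 --out p.bin
oligobench encode --codec rs --rate-preset 0.50 --in p.bin --out pool.fasta
# -> 96 sequences, code rate 0.496 bit/nt
oligobench channel basic --refs pool.fasta --out reads.fastq --rate 0.02 --seed 3
# -> 2880 reads from 96 references
oligobench cluster --reads reads.fastq --out cons.fasta --length 152
# -> 96 consensus sequences
oligobench cluster-eval --consensus cons.fasta --refs pool.fasta
# -> {"sensitivity": 1.0, "accuracy": 1.0, "specificity": 1.0}
oligobench decode --codec rs --rate-preset 0.50 --in cons.fasta --out out.bin \
    --payload-size 904
# -> decoded 904 bytes  (byte-identical to p.bin)
oligobench density --rate 1.85 --redundancy 32
# -> 6.57 EB/g
```

The 96 reference sequences were recovered perfectly (every consensus
equals its reference, one per reference), so the outer code saw no
erasures and decoding returned the exact payload. The same pipeline is
available as library calls (`get_codec`, `run_basic_scenario`,
`cluster_and_consensus`, `run_trial`, `adaptive_scan`).

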