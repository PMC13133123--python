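# Methods

This note documents the models, parameter choices and numerical
conventions behind `oligobench`, and what the simulations do and do not
capture about real DNA data-storage experiments.

## Channel models

### Basic iid error scenario

`run_basic_scenario` draws, independently at every template position,
an error with probability r; the error type is drawn from a fixed
composition, by default 53% substitutions, 45% deletions and 2%
insertions — the mix observed in array-synthesized, Illumina-sequenced
pools. Substitutions replace the base with one of the other three
uniformly; insertions place one uniform base before the position;
deletions skip it. Each surviving reference yields exactly `copies`
reads (default 30). Sequence dropout removes a fixed fraction of
references (count rounded half-up) *before* read generation, by uniform
sampling without replacement. Supported sweep ranges are r ∈ [0.001,
0.40] and dropout ∈ [0.005, 0.99]; reads carry their true origin index,
which simulation makes exact.

### Workflow channel

`run_workflow` is a stage-structured approximation of a storage
experiment:

1. **Synthesis.** Each reference receives a relative abundance weight
   drawn from Gamma(1/cv², cv²) (mean 1, coefficient of variation
   `abundance_cv`), plus per-oligo errors from the synthesis error
   spec. A gamma rather than lognormal weight model was chosen because
   its left tail is what controls sequence dropout at finite sequencing
   depth: lognormal weights matching the observed coverage CV produce
   essentially no dropout, while gamma weights reproduce both the CV
   range observed for material-deposition vs electrochemical synthesis
   (~0.4 vs ~1.1) and the dropout levels of those workflows (<1% vs
   >2%) simultaneously.
2. **PCR 1** (default 15 cycles): every molecule duplicates with
   probability η per cycle (η = 0.95). Growth is simulated exactly on
   aggregate per-reference counts (the per-cycle Galton–Watson step
   `n ← n + Binomial(n, η)`), which is the exact population law.
   Polymerase substitutions accumulate at e_pol per nt per replication;
   a random surviving lineage undergoes ≈ cycles·η/(1+η) replications,
   and that expected rate is applied to each post-dilution template.
3. **Dilution** to a mean physical redundancy R: a multinomial sample
   of R·N total oligo copies over current abundances. References drawn
   zero times are physically lost — dropout *emerges* from sampling.
4. **PCR 2** (default 25 cycles), as PCR 1.
5. **Sequencing** at mean depth s: s·N reads sampled multinomially from
   final abundances. Each read descends from one specific post-dilution
   oligo, so reads from the same oligo share that oligo's synthesis and
   first-round-PCR error pattern (correlated errors, which matter for
   consensus calling); second-round-PCR substitutions are applied
   per read as an iid rate, a deliberate simplification that ignores
   the lineage structure within an oligo's post-dilution family.

Oligo templates are materialized lazily (only oligos that are actually
sequenced), from a per-oligo RNG stream derived from (seed, reference,
oligo id), keeping the simulation deterministic and fast at desk scale.

**Presets.** `high_fidelity` models material-deposition synthesis with
a proofreading polymerase: synthesis error 1×10⁻³ nt⁻¹ (sub/del/ins
5/4/1×10⁻⁴), e_pol 10⁻⁶, cv 0.38. `low_fidelity` models
electrochemical synthesis with Taq: synthesis sub 9×10⁻³, del
4.4×10⁻³, ins 1.0×10⁻³ nt⁻¹, e_pol 3×10⁻⁵, cv 1.12. The deletion and
insertion rates of the low-fidelity preset follow published
electrochemical synthesis characterizations; its substitution rate is a
calibration choice. End-to-end these give mean read error rates of
≈0.1% and ≈1.5% nt⁻¹ and dropout ≈0% and ≈4% at R = 1000, s = 50,
verified by simulation in the test suite. What the channel does *not*
model: positional error profiles along the synthesis direction, paired
reads and their merging, quality scores, PCR stochasticity at high copy
number (negligible), aging or nanopore error profiles.

## Codecs

All codecs map bytes to DNA at 2 bit/nt (A/C/G/T = 00/01/10/11) with no
GC or homopolymer constraints, and prepend an 8-byte header (payload
length + CRC32). The header lets every decoder verify byte-exact
recovery internally, so a decoder can never report success with a wrong
payload (probability ~2⁻³²; the trial harness additionally compares
against the original).

* **Baseline** — a 2-byte big-endian index plus a raw payload chunk per
  sequence. Decoding requires every index exactly once (duplicates are
  resolved by abundance); it has no correction capability and tolerates
  no dropout.
* **Reed–Solomon inner/outer** — the code-separation strategy. Each
  sequence is an inner RS(n, k) codeword over GF(256) (primitive
  polynomial 0x11D) holding index + chunk + parity; the inner decoder
  corrects up to ⌊(n−k)/2⌋ symbol errors, otherwise the sequence
  becomes an erasure. An outer RS(N, K) code runs column-wise across
  the K data sequences of each block; outer decoding is
  errors-and-erasures (2e + f ≤ N−K), so it recovers up to N−K dropped
  sequences per block and additionally corrects residual
  inner-miscorrection errors. Pools larger than one block are split
  into B blocks interleaved round-robin by global index (sequence g at
  position g÷B of block g mod B), bounding per-block erasures under
  clustered loss.
* **Fountain (LT)** — each sequence is a droplet: a 4-byte seed, the
  XOR of a robust-soliton-distributed subset of the K source segments
  (c = 0.03, δ = 0.05), and a 4-byte inner RS parity used only to
  *detect* corrupted droplets, which are discarded. Decoding peels
  degree-one droplets (belief propagation); when peeling stalls the
  remaining equations are solved by GF(2) Gaussian elimination. The
  elimination fallback is required for the high-rate presets: at the
  small K of desk-scale payloads, pure peeling needs droplet overheads
  well above the ~5% that a 1.50 bit/nt rate allows, whereas the
  combined decoder succeeds whenever the droplet matrix has full rank.
* **External adapter** — wraps subprocess encode/decode commands in the
  same contract; nonzero exit, missing output or a wall-clock timeout
  is a decode failure.

Rate presets (0.50/1.00/1.50 bit/nt at L = 152 nt, i.e. 38 bytes) are
recorded in `src/oligobench/data/presets.yaml`, including the
inner/outer redundancy split for the RS codec — a free design choice at
each rate: inner (38,26)+outer (48,19) at 0.50; (38,30)+(28,19) at
1.00; (38,34)+(64,57) at 1.50. Per-block dropout tolerance (N−K)/N is
thus 60.4%, 32.1% and 10.9%. Achieved code rates are within 5% of the
nominal targets for the standardized 19456-byte ("19 kB") payload;
small payloads pay a larger padding overhead.

## Clustering and consensus

*Naïve clustering* collapses reads to unique sequences ordered by
descending abundance (ties lexicographic — the output is permutation
invariant), padded or trimmed to the design length; no alignment is
performed. *LSH clustering* processes unique reads in that same order;
each read's MinHash signature (64 independent affine hash functions
modulo 2⁶¹−1 over its k-mer set) is compared against the signatures of
existing cluster founders, and the read joins the earliest cluster
whose estimated Jaccard similarity reaches τ, else founds a new one.

The defaults k = 8, τ = 0.15 were set from the k-mer collision
structure of noisy reads: an error destroys ~k k-mers *and* creates ~k
novel ones, so two reads of the same reference at a 2% error rate share
a true Jaccard of only ≈0.35 (k = 12) to ≈0.55 (k = 8), while two
*different* 150-nt references share ≈0.01 at k = 8. τ = 0.15 sits far
above the cross-reference similarity and below the within-reference
similarity up to error rates of ~10%; with ground-truth origins the
clusterer shows zero origin-mixing up to r = 0.14 and exactly N
clusters at r ≤ 0.02.

*Consensus calling* star-aligns every member to the cluster's
highest-abundance member using exact bit-parallel global edit-distance
alignment (edlib) — an unbounded exact alignment rather than a banded
approximation. Votes are tallied per representative column (gap votes
included) and per insertion slot; plurality wins, with ties broken by
the fixed base order A<C<G<T and non-gap over gap; gap-majority columns
are deleted; the result is padded (with "A") or trimmed to the design
length L.

*Evaluation* assigns each consensus to the reference minimizing
Levenshtein distance (ties to the lowest reference index). Sensitivity
is the fraction of references with ≥1 assigned consensus; specificity
divides the same numerator by the total consensus count; accuracy is
the mean, over all references, of the Levenshtein similarity
(1 − d/max(|a|,|b|)) of each reference's closest consensus. Averaging
over *all* references (unmatched ones contribute their best similarity)
is a recorded convention; an alternative would average matched
references only.

## Threshold estimation and scans

Decoding success at parameter x is modelled as
logistic(β₀ + β₁ log x); the performance threshold is the x solving
p = 0.95. The fit is a statsmodels ML logistic regression on the
30 binary outcomes of the three-stage adaptive scan. Conventions:

* Directions: error rate and dropout are harder-is-larger; physical
  redundancy and sequencing depth are harder-is-smaller. The fitted
  slope must carry the corresponding sign, else the fit is discarded.
* All-success (all-fail) outcome sets are censored at the hard (easy)
  range extreme, flagged, and the refinement window defaults to the
  corresponding decade of the range.
* On complete separation the ML fit diverges; the threshold falls back
  to the p\*-quantile interpolation in log space between the extreme
  success and failure points (the plain midpoint would estimate the
  50%-success point and systematically overshoot a 95% threshold).
* Stage-2/3 windows [t/2, 2t] are clipped to the global range; the
  log-space fit makes estimates equivariant under axis rescaling.

Resource limits convert violations into trial failures. Wall time is
checked cooperatively after each pipeline stage (and enforced as a real
timeout for subprocess codecs); the memory limit is advisory for
in-process codecs. Desk-scale defaults are 60 s / 1 GiB; the
paper-scale configuration (3600 s / 8 GiB / 1 core) is available via
`ResourceLimits.paper_scale()`.

Pareto fronts run 10 fixed-value scans per axis and keep the
non-dominated (x, y) threshold pairs under explicit direction flags;
the filter is verified against brute-force pairwise dominance. The
literature protocols (serial dilution ×10 per iteration, serial
re-amplification, read down-sampling) run each iteration ten times with
distinct seeds and report the highest iteration with 10/10 successes,
stopping at the first failure.

## Density accounting

Storage density D = ρ·N_A/(R·M·8·10¹⁸) EB/g uses decimal exabytes —
the convention under which the dsDNA limit at ρ = 2 bit/nt, R = 1,
M = 662 g·mol⁻¹·bp⁻¹ evaluates to ≈227 EB/g; binary units do not
reproduce that figure. The `with_adapters` basis scales by
payload-length/total-length, both explicit inputs. Mass-to-redundancy
conversion is R = m·N_A/(n·L·M) with the molecular weight exposed as a
parameter, since published per-mass redundancy figures are sensitive to
the M convention used.

Error profiling aligns each read to its origin reference (edlib global
alignment) and counts substitutions, deletions and insertions from the
alignment path, normalized by aligned reference length; alignment
tie-breaking follows edlib's deterministic path choice, so counts are
reproducible. At low error rates the alignment-estimation bias is far
below the binomial 4σ bands used in the tests; at rates ≳10% minimal
alignments systematically re-explain error combinations and per-type
rates become biased — parameter-recovery checks are therefore run at
r ≤ 5%.

## Reproducibility and problem sizes

Every randomized operation derives its RNG stream from (root seed,
stage tag, …) via hashed SeedSequence keys, so identical configurations
give bit-identical outputs and stages can be re-run in isolation. The
shipped evaluations use desk-scale problem sizes chosen to keep full
runs in minutes on one core: a 904-byte payload (≈100 sequences of
152 nt at 0.50 bit/nt) for end-to-end scans, a 19456-byte payload for
code-rate accounting, 300-sequence pools for channel calibration, and
30-trial adaptive scans throughout. Scaling the payload up changes
none of the interfaces; runtimes grow roughly linearly in total reads.

## Known limitations

* The workflow channel is calibrated to end-to-end means (error rate,
  dropout, coverage CV), not to stage-resolved measurements; its PCR
  error model collapses lineage structure beyond the dilution
  bottleneck.
* Passing tests on the iid channel say little about structured error
  modes (homopolymer slippage, position-dependent synthesis errors,
  strand-specific damage) that real pools exhibit.
* The LSH clusterer compares reads only against cluster founders;
  pathological read orders could split clusters that a
  multi-representative comparison would keep together.
* The fountain codec's Gaussian-elimination fallback is O(K³) in the
  worst case; for payloads far beyond desk scale a sparse inactivation
  decoder would be preferable.
* Reported thresholds inherit the ±1 grid-step resolution of the
  three-stage scan (a factor ≤1.17 at stage 3) plus Bernoulli noise;
  the estimator-recovery test quantifies this (median error ≲5%,
  well within the 15% acceptance band).
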