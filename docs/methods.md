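# Methods

## Scope and model

`pmffrc` optimizes the joint compression of a collection of FASTQ files by a
"cascaded" backend reads compressor. The only stream compressed and restored
is the reads stream: sequence lines, uppercased, with any character outside
{A, C, G, T, N} normalized to N. Headers and quality strings participate in
pre-compression memory probes (probe samples are complete 4-line records) but
are never archived or restored; restored output is one-read-per-line
`<name>.reads` text. Paired-end files are treated as two independent
single-end files. Input FASTQ must be strict 4-line records (plain or gzip);
multi-line-sequence dialects are rejected with an error naming the offending
line rather than silently truncated.

## Peak-memory model

Backends differ wildly in memory behaviour, so the model is measured, not
assumed. Two probe FASTQs are built by sampling x1 and x2 records per file
(defaults x1 = 100, x2 = 100,100; sampling is without replacement unless a
file is smaller than the sample, in which case it is with replacement — small
files must still contribute x records so the probe workload scales as
v·x). The backend's compress command runs as a child process whose
resident-set size, summed over the whole process tree, is polled every 50 ms;
the maximum observed value is its peak. From the two peaks:

- `Y_res = Y_peak1` — the intercept is identified with size-independent
  resident memory (dictionaries, hash tables);
- `slope = |Y_peak2 − Y_peak1| / (v·(x2 − x1))` bytes per read;
- `Y_reads = slope · M`, `Y_cpm = Y_res + Y_reads` for the M-read collection.

The files-level cluster count is `K1 = ceil(β · Y_reads / (U_ram − Y_res))`,
floored at 1 (the unfloored value is 0 whenever `Y_reads = 0`, and a cluster
count of zero is meaningless). `U_ram ≤ Y_res` is reported as an infeasible
budget: no clustering can help if the backend's fixed footprint alone exceeds
the budget. β (default 1.0 for the built-in backends, configurable per
backend) absorbs mildly nonlinear memory growth of real compressors; no
nonlinear model is fitted. Nondeterminism in measured peaks (polling phase,
allocator behaviour) perturbs K1 by design; everything downstream of K1 is
deterministic.

## Features and similarity

Each read r maps to the integer key
`k(r) = Π_{e∈{A,C,G,T}} (count_e(r) + 1)`; the real-valued feature is
`k(r)/n` with n the collection-wide mean read length (total bases / total
records, computed after normalization). The division by a collection-wide
constant can neither reorder keys nor change equality structure, so pairwise
comparison operates on the exact integer keys — this removes floating-point
equality hazards from the multiset intersection. N contributes to no count;
an empty read has key 1.

File pairs are scored with a size-corrected dice coefficient on key
multisets: `sim(a,b) = α · 2|A∩B| / (|A|+|B|)` with min-multiplicity
(multiset) intersection — repeated redundant reads are precisely the
phenomenon of interest — and `α = (|A|+|B|) / (2·min(|A|,|B|))`. α corrects
for unbalanced file sizes and exceeds 1 for unequal pairs; scores are left
unclamped because only their order is consumed downstream. A pair involving
an empty file has a degenerate α (division by zero); it scores 0 with a
logged warning so one empty file cannot abort a large run. All v(v−1)/2
pairs are sorted descending with ties broken by (a, b) ascending.

The cyclic parallel contract (file i → worker i mod Pr, pair s → worker
s mod Pr) is implemented as a recorded logical assignment with sequential
evaluation and index-ordered merge. The observable contract — bitwise
identical output for every Pr — is what the tests assert; an actual process
pool would add scheduling nondeterminism risk with no behavioural upside at
the scales this package targets.

## Clustering

With per-cluster budget `ave = floor(M/K1)`:

1. Seed a cluster with the highest-scoring pair of unassigned files. The
   seed pair is never split even when its combined total exceeds `ave`
   (logged as a budget warning): the design keeps the most redundant pair
   together, and budget pressure is handled by closing early.
2. Grow by single linkage: while the total is below `ave`, the unassigned
   file with the highest similarity to any member is tried (ties to the
   lower index). Acceptance requires the tentative total not to exceed
   `ave`; the first rejection closes the cluster with no backtracking to the
   next-best candidate.
3. Entries of assigned files are dead; leftover files become singletons in
   ascending index order. Files individually larger than `ave` therefore end
   up as singletons — a file is never split across clusters.

The result is a partition (asserted), conserving M; the realized cluster
count K may exceed K1. When K1 = 1, `ave = M` admits every file, so K = 1.

## Archive container

`.pmffrc` layout: magic `PMFC`, u32 format version, u64 manifest length,
canonical JSON manifest (sorted keys), concatenated backend payloads.
The manifest stores per-file name/index/record-count/SHA-256 reads
fingerprint, the cluster table, and per-payload offsets and sizes; offsets
are validated against the physical file size before any payload is touched,
so truncation is detected early. Clusters are compressed and decompressed
strictly sequentially — the memory model budgets one backend instance at a
time. Decompression splits each merged stream at the recorded per-member
record counts and verifies every fingerprint; a mismatch names the file. The
SHA-256 of the newline-joined reads stream is the lossless criterion.

## Backends

A backend is a pair of shell-free command templates (`{input}`, `{output}`,
optional `{threads}`) plus β and a thread default; extra backends load from
an INI file. The built-in `generic` backend is a deterministic LZMA stream
compressor (`python -m pmffrc._xz_backend`, preset 6) run as a real child
process, so probing, failure handling and joint compression exercise the
same code path external reads compressors would. A `zstd` template is also
registered for hosts that have it. Specialized compressors that insist on
FASTQ input rather than raw reads text would need a wrapping adapter; none
is shipped.

## Synthetic data

The generator emulates the one property the optimizer exploits: cross-file
read duplication. Files are partitioned into redundancy groups; each group
samples one shared pool of uniform-random ACGT reads (pool size = the
group's largest file), and each member draws `shared_fraction` of its
records from the pool — without replacement while the pool suffices, so a
fully-shared equal-size pair is an identical multiset with dice score
exactly 1 — and the rest as fresh random reads. Quality is a constant
character. It does not emulate sequencing error, quality distributions,
positional base bias, reverse-complement redundancy, or realistic k-mer
structure; passing tests demonstrate the clustering and round-trip machinery
on planted composition-level redundancy, not compression performance on real
sequencers' output.

The packaged five-file worked example fixes per-file counts
(200, 310, 260, 140, 150; only the pair sums 340/650/460 and M = 1060 are
constrained, the split is a packaged constant) and a similarity list whose
two printed maxima (0.92 for pair (3,0), 0.90 for (4,1)) are embedded among
free entries chosen pairwise distinct and strictly below 0.90, arranged so
the first cluster's growth candidate is file 1. Tests assert only the
constrained quantities.

## Numerical and design choices

- Record sampling for probes is scattered (uniform random indices), not
  contiguous; deterministic per seed.
- The feature formula's division by n is applied once to the whole product;
  since n is a collection-wide constant the choice cannot affect similarity
  or clustering, which consume integer keys only.
- n is computed after non-ACGTN normalization.
- `cr` in the gain metric is original bytes / compressed bytes (larger is
  better), so `crg` equals `cs_without/cs_with − 1`; a bits-per-base helper
  is provided for display parity with the lower-is-better convention.
- Probe peaks of very fast child processes can be undersampled by the 50 ms
  poll; peaks only enter K1, whose downstream effect is bounded (K1 is
  floored and the budget test tolerates slope noise at desk scale).

## Problem sizes in the test suite

Module and acceptance tests run at desk scale, chosen as the package's
default verification envelope: randomized round trips use ≤ 12 files and a
few hundred records per file; the directional-gain check uses 6 files of
~900 100-bp reads (70% within-group sharing) and compares the whole archive
size (manifest included, i.e. conservatively) against the summed per-file
compressed sizes with the identical backend; planted-group recovery runs 20
seeds at 6 × 40 reads. The full suite completes in well under a minute on
one CPU.

## Known limitations

- Memory extrapolation is affine; strongly nonlinear backends are handled
  only through β, and no rule for choosing β per dataset is provided.
- Cluster growth is greedy with no backtracking; it is not a bin-packing
  optimum, by design (speed and faithfulness to the stated procedure).
- No random access into archives; restoration is whole-archive.
- Headers and qualities are not restored; the tool targets reads-stream
  archival, not full FASTQ round-tripping.
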