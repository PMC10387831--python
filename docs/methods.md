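# Methods

## Model

The object being matched is the positional nucleotide profile: for reads of
one length L and k-mer size k, an (L − k + 1) × 4^k matrix whose row p is the
frequency distribution of the k-mer starting at position p. Positional
frequencies are only well defined among reads of equal length, so profiles
are maintained **per read length** and every operation (scoring, adjustment,
distance) acts on each length's matrix independently. Reads containing any
base outside A/C/G/T are discarded before profiling; discarded counts are
reported, never silently dropped.

Simulation pairs each retained input read 1:1 with one output read of the
same length. This construction makes the count and length-distribution
guarantees exact by definition and gives quality-string copying an
unambiguous meaning (read i's quality goes to simulated read i). Candidate
subsequences are drawn uniformly over all valid start positions — genome-wide
via cumulative chromosome offsets, or within user-supplied BED intervals;
genome-wide sampling is implemented as region sampling over full-chromosome
intervals so both paths share one code path and candidates can never span a
boundary. Strand is a fair coin; minus-strand candidates are
reverse-complemented and the emitted BED interval records forward-strand
coordinates plus the strand. Candidates containing non-ACGT bases are redrawn
(mirroring the input-read filter); more than 10,000 consecutive rejections
abort with a diagnostic, which in practice only happens on N-rich references
or regions.

A candidate x of length L is scored against the working profile W as

    score(x) = Σ_p log(W[p, kmer(x, p)] + ε),   ε = 10⁻⁶

i.e. a positional log-likelihood with a pseudocount so k-mers never observed
in the input stay scoreable. One candidate is then chosen by a weighted draw
with weight exp(score − max score); if every weight underflows to zero the
choice is uniform. A deterministic argmax would collapse the diversity of the
output toward a handful of high-scoring sequences and overshoot the profile;
the weighted draw keeps the output stochastic, and in the case of candidates
differing at a single position it selects exactly proportionally to the
positional frequency — which is what makes the output profile converge to the
input profile at all.

## Convergence schedule

The working profile starts equal to the input (target) profile. After each
⌊n/10⌋ simulated reads (10 checkpoints by default, none after the final
read), the working profile is replaced by

    W ← W − f · (NP_sim − NP_target),   f = 0.5

where NP_sim is the cumulative profile of *all* reads simulated so far.
Entries driven negative are clamped to zero and each positional row is
renormalised (the raw rows always sum to 1 before clamping, so renormalising
is safe). Subtracting half the simulated-minus-target difference
over-corrects the working profile in the direction the selection process
undershoots — e.g. a target T frequency of 0.9 that selection alone only
reaches at ~0.85 pushes the working frequency above 0.9 — and because the
correction uses the cumulative simulated profile at fixed fractions of the
run, the result is insensitive to input read order. The fraction f is
exposed (`adjustment_fraction`, default 0.5) along with the checkpoint count
(`n_checkpoints`, default 10).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `candidate_count` ("sens") | 50 | candidates scored per read; fewer is faster, more gives closer profile fidelity |
| `k` | 1 | profile k-mer length (1 = single nucleotides) |
| `adjustment_fraction` | 0.5 | fraction of the simulated−target difference subtracted per checkpoint |
| `n_checkpoints` | 10 | adjustment after every 1/n of the reads |
| `PSEUDOCOUNT` | 1e-6 | added to frequencies before log |
| `quality_mode` | copy | copy input qualities verbatim, or a constant character |

## Profile comparison

Two k = 1 profiles are compared with a two-sample Hotelling's T². Each
observation is the (A, C, G) frequency vector of one position of the most
populous shared read length; T is dropped because the four frequencies sum
to one and would make the covariance singular. With n₁ and n₂ positions and
d = 3, the p-value uses the standard F approximation
T²·(n₁+n₂−d−1)/(d·(n₁+n₂−2)) ~ F(d, n₁+n₂−d−1). The choice of observation
unit (positions of the dominant length, one base dropped) is this package's
own construction; at least 5 positions per profile are required, and a
singular pooled covariance (e.g. constant frequencies) raises an error
rather than returning a misleading p-value.

## Synthetic data generator

`make_fixtures` / `generate_biased_reads` emulate protocol-driven positional
base enrichment on an unbiased background: the genome is i.i.d. uniform over
ACGT and reads are uniform forward-strand genome subsequences whose bases at
specified positions are replaced by draws from a stated distribution
(e.g. T with probability 0.9 at the two 3′-most positions, mimicking the
thymine enrichment of XR-seq reads; bases missing from a position's
specification share the remaining mass equally). The default study
conditions used throughout the tests are a 1 Mb genome and 50,000 reads of
length 20 with T = 0.9 at positions 18–19.

What the generator does **not** emulate — and therefore what passing tests do
not show about real data: real genomes are not i.i.d. uniform (GC
heterogeneity, repeats, N gaps), real bias profiles are smooth across many
positions rather than concentrated at two, real read sets mix lengths with
protocol-dependent proportions, and real reads carry sequencing errors.
The convergence machinery does not depend on any of these, but absolute
distance values measured on synthetic data should not be read as predictions
for real libraries.

## Numerical and design choices

- Scores are summed in log space; selection weights are normalised by the
  maximum score before exponentiation, so candidate sets whose absolute
  scores are all tiny remain well conditioned.
- Weighted selection uses an explicit cumulative-sum inverse-CDF draw, and a
  single seeded PCG64 generator drives every draw (candidate positions,
  strands, redraws, selection) in a fixed order: identical inputs and seed
  give byte-identical output files.
- Ties and degenerate inputs: a profile row built from reads that all share
  a base is a point mass (no pseudocount is stored in the profile itself;
  the pseudocount applies only at scoring time); lengths with very few reads
  still get their own profile with no pooling or smoothing across lengths —
  their positional frequencies are correspondingly noisy, a known
  limitation for sparsely populated lengths.
- Reference bases outside A/C/G/T (including IUPAC ambiguity codes) are
  treated as N and hence rejected in candidates; soft-masked (lowercase)
  bases are uppercased and treated as normal.
- BED coordinates are 0-based half-open throughout, matching the BED
  standard; a strand column in a region-restriction BED is ignored (both
  strands are sampled within a region).
- Heavier invariant checks (order-robustness of convergence, monotone
  fidelity in candidate count) run on scaled-down conditions — 3–5 k reads,
  100 kb genome, 3–5 seeds — chosen so their statistical oracles remain
  valid while the whole suite stays quick; the full-scale conditions are
  exercised by the end-to-end fidelity tests and `scripts/acceptance.py`.

## Known limitations

- Single-end reads only; no error, variant or quality-score simulation (by
  design — compose with other simulators if those are needed).
- Input-sequencing mode produces no genomic coordinates, so BED export is
  refused there.
- The Hotelling comparison uses only the dominant shared read length;
  information in minor lengths is ignored.
- For k > 1 the profile matrices grow as 4^k and per-length read counts
  dilute across 4^k columns; k beyond 3 needs deep input sets to be
  meaningful.
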