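# Methods

## Generative model

The simulator produces reads per sample in a fixed order of mechanisms, one
seeded `numpy` generator driving everything (identical seed → byte-identical
outputs):

1. **Reference.** Uniform random ACGT sequence of configurable length
   (default 1 kb; the low-frequency benchmark uses 5 kb). No external genome
   is used; alignment is simulated, so every read carries its true 0-based
   coordinates and insert bases are stored in reference orientation (R2 in
   FASTQ output is the reverse complement). Bases at spike-in variant
   positions are forced to the declared reference allele.
2. **Molecules.** Each library fragment is one molecule with a uniform start,
   a random strand, and length equal to the read length (single-coordinate,
   single-end-style model; paired-end two-coordinate keys are out of scope).
3. **Variant alleles.** Each molecule covering a spike-in position carries
   the alternate allele with probability equal to the variant's allele
   fraction. All PCR copies of a carrier molecule show the allele — this is
   what distinguishes true variants from per-copy artifacts downstream.
4. **oxoG damage.** With probability `oxo_damage_rate` per molecule (default
   in the benchmark: 0.02, an FFPE-like level of oxidative damage), one
   uniformly chosen G/C position within the fragment is marked damaged —
   damage sits on whichever strand presents the G, so artifacts surface as
   G>T or C>A in reference orientation. Each PCR copy *independently*
   misreads the damaged base with probability `oxo_misread_prob` (benchmark:
   0.5). True misincorporation kinetics are not modeled; the misread
   probability is a free parameter.
5. **Adapter arms.** The i7-bearing and i5-bearing arms of each fragment are
   drawn independently from the sample's adapter pool. A contamination event
   (target well, source well, rate c, optional arm) either applies to both
   arms independently (duplex stage — both strands of the contaminating
   adapter are in the pool, giving the c² / 2c(1−c) split) or to the one
   designated arm only (oligo stage — only that strand's oligo leaked,
   giving a skewed cross-talk pattern). This independent-arm draw is the
   model assumption behind the squared-contamination result; the benchmark
   experiments verify it Monte-Carlo against the closed form.
6. **UMI and amplification.** Each molecule gets a UMI uniform over 4^k
   (default k = 6) and emits a family of reads sharing its UMI, coordinates
   and adapter indices. Family-size distributions: `degenerate(k)`,
   `poisson_plus_one(λ)` (default λ = 2), `geometric_plus_one(p)` (support
   {1, 2, ...}, mean 1/p).
7. **Index hopping.** Per read and per index independently, with probability
   `hop_rate` the observed index is replaced by the corresponding index of a
   uniformly chosen *other* pool member (free-adapter re-annealing picture).
   Whether a physical hop affects one or both indices per event is not
   settled; the independent per-index model is the documented choice, and
   the estimator below is calibrated to it. A single-plex pool cannot hop.
8. **Index sequencing error.** Substitution-only: each base of i7, i5 and
   UMI flips to a uniform different base with probability
   `index_error_rate` (indels would shift fixed-cycle index reads and are
   out of scope). Insert base qualities are fixed at Q30 — insert-level
   sequencing error is not the phenomenon under study and is not simulated.

Every read carries truth fields (sample, molecule, event tags) that the
demultiplexer and consensus caller never see; a read-by-read audit property
in the tests checks that the event tags exactly account for every
observed-vs-true index discrepancy.

### What the generator does not emulate

Capture-bait efficiency and coverage non-uniformity, adapter dimers,
insert-level error profiles, quality-score variation, basecalling and
pass-filter behaviour, and platform-specific (patterned vs non-patterned
flow cell) hopping mechanisms — platform differences are represented only by
different `hop_rate`/contamination choices. Passing tests therefore
demonstrate the behaviour of the decision logic (demultiplexing, estimation,
consensus, thresholds) under the stated generative assumptions, not
end-to-end performance on real instrument data.

## Demultiplexing

Index matching is Hamming-based with 0 or 1 allowed mismatches per index; N
calls count as mismatches. With one mismatch allowed, the candidate sets
must be pairwise > 2 mismatches apart (checked at policy load) so nearest
candidates are unique; ambiguous hits resolve to *unassigned* — false
assignment is the failure mode under study, so the matcher never guesses.
UMI bases are split off the I1 read before matching. The cross-talk matrix
counts reads for every (i7, i5) candidate combination including unused
indices; its total is the number of reads with both indices matched, which
is also the denominator of every reported rate.

## Estimators and diagnostics

* **Misassignment report.** A matrix cell is misassigned when it resolves to
  an unused plate well or to no well at all (mismatched pair under the
  unique-dual scheme). Per-unused-well counts plus the no-well count sum
  exactly to the misassigned total.
* **Row/column decomposition** (combinatorial only): each unused well
  receiving reads is classified by whether it shares a row only, column
  only, both, or neither with *any* used well, since several wells are
  typically in use at once.
* **Hop-rate estimate.** Corrected rate = pool mismatched-pair rate minus
  the single-plex baseline (adapter contamination), floored at zero because
  rates are physical. Under the per-index hop model the excess estimates
  1−(1−h)², so the per-index rate is reported as 1−sqrt(1−corrected); the
  both-indices-hop-to-the-same-well collision term (h²/(plex−1)) is below
  the Monte-Carlo resolution at the benchmark sizes.
* **Symmetry diagnostic.** Score = Σ|off(i,j)−off(j,i)| / Σ(off(i,j)+off(j,i))
  over off-diagonal cells. Verdict thresholds: skewed > 0.5, symmetric
  < 0.2, with at least 50 off-diagonal reads required (else indeterminate);
  the two simulated stages separate by far more than 3σ at these settings.
  The diagnostic presumes contamination is not exactly mutual between well
  pairs — a perfectly reciprocal oligo-stage leak would mimic symmetry.

## UMI consensus

Grouping buckets mapq-passing reads by (start, strand) and clusters distinct
UMIs with the directed-adjacency rule: edge A→B when the UMIs are within
`umi_edits` (default 1) mismatches and count(A) ≥ 2·count(B) − 1; families
grow greedily from the highest-count unassigned UMI (ties broken
lexicographically for determinism). The tests pin this against an
independent graph-reachability implementation.

Consensus calling is deliberately simple and fully specified — it is *not*
bit-identical to any external consensus tool. Per position the
strict-majority base (> half of non-N member bases) wins; ties or zero depth
give N. Member base qualities are capped at `error_rate_post_umi`
(Phred 30) *before* summation, and the consensus quality is the sum of
agreeing minus disagreeing capped qualities, floored at 2. Applying the cap
per member rather than to the finished consensus is what makes the filter
set coherent: three agreeing Q30 reads give a Q90 consensus base, which
survives the min-base-quality-40 mask, whereas a post-hoc Q30 cap would mask
every base and reject every read.

Filtering (defaults: min 3 reads, mean per-base error ≤ 0.05, base quality
≥ 40, per-base error ≤ 0.1, no-call fraction ≤ 0.1, mapq ≥ 10) rejects on
family size and read error first, then masks failing bases to N/Q2 and
re-evaluates the no-call fraction. The mapq gate is vacuous on simulated
reads (fixed Q60) but implemented for completeness. The no-UMI comparator is
coordinate-only deduplication: one read per (start, strand), highest mean
quality, ties by read id.

## Variant calling and evaluation

The pileup caller emits a candidate for every non-reference base with ≥ 1
supporting read at ≥ `min_depth` (default 100, a deep-panel setting) and
calls it at allele fraction ≥ 0.2%, except C>A/G>T substitutions, which
need ≥ 0.3% (the oxoG mutation-specific threshold, applied to the reported
ref→alt pair — strand is already folded into the pileup). Raising a
threshold can only shrink the call set (exact set inclusion, tested).
Evaluation matches calls to truth exactly on (position, ref, alt) — no
indels are simulated — stratifies by expected allele fraction (0.5%, 1%,
>1%), and reports PPV as NA rather than 0 when there are no positive calls.
Multi-allelic sites are evaluated per alternate allele.

## Benchmark problem sizes

The contamination benchmarks use 10⁶ fragments (single-index) and 10⁷
fragments (dual-matched, where the measured rate is c² = 10⁻⁴); both run in
seconds because reads are held column-wise in numpy arrays. The
low-frequency variant benchmark uses 25 000 molecules at mean family size 4
over a 5 kb reference — about 2000× raw and 400× consensus depth, echoing a
deep targeted panel — with 6 spike-ins at 1% and 10 at 0.5% allele fraction
(two of them C>A/G>T, to confirm the mutation-specific threshold spares real
variants at 0.5% ≥ 0.3%). Hop-rate recovery uses 10⁶ reads per pool at
plex 4/8/16 with injected per-index rates 0.001/0.002/0.004 and a 0.0005
duplex contamination background, paired so hopping grows with plex size.

## Known limitations

* Coordinates are taken from the simulator, not an aligner; mapping error
  and realignment of consensus reads are out of scope.
* Single-strand consensus only; duplex (double-strand) consensus is not
  implemented.
* The caller is a threshold-on-pileup model with no statistical test, error
  model or strand-bias filter; it isolates the effect of consensus calling
  and thresholds rather than reproducing a production caller.
* Real-instrument cross-talk rates depend on library-specific contamination
  levels that are not knowable a priori; the package reports formats and
  recovers *injected* parameters, it does not predict a given flow cell.
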