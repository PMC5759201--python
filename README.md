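# crosstalkqc

Sample-index cross-talk is the silent failure mode of multiplexed Illumina
sequencing: a read produced from one library is demultiplexed to another
sample. For genotyping it is a rounding error; for low-allele-fraction work —
ctDNA variant detection, microbial reads in human samples, ancient DNA — a
0.1% cross-talk rate is larger than the signal being chased, and it sets the
assay's limit of detection.

`crosstalkqc` is a toolkit for studying this failure mode quantitatively. It

* **simulates** multiplexed libraries with the processes that cause
  cross-talk — adapter cross-contamination (at the single-stranded-oligo or
  duplexed-adapter stage), index hopping in multiplexed capture pools, index
  sequencing error — plus UMI-tagged PCR duplication, low-AF spike-in
  variants and strand-asymmetric 8-oxoguanine damage, all with a hidden
  per-read truth table;
* **demultiplexes** under the two adapter designs in common use:
  *combinatorial* plates (12 i7 × 8 i5 oligos make 96 wells, so single
  indices are shared along rows and columns) and *unique dual-matched*
  plates (each well's i5 and i7 are identical and shared with no other
  well), with perfect or one-mismatch Hamming matching;
* **quantifies** misassignment over the full candidate index grid (used and
  unused indices), decomposes it by plate geometry, estimates index-hopping
  rates with a single-plex contamination baseline, and diagnoses the
  contamination stage from the (a)symmetry of the cross-talk matrix;
* **collapses** UMI families (directed adjacency grouping, edit distance 1)
  into consensus reads, filters them, and calls low-AF variants from a
  pileup with a 0.2% threshold plus a mutation-specific 0.3% threshold for
  C>A/G>T oxoG artifacts, evaluating sensitivity and PPV against the
  simulation truth.

## The model in one paragraph

Each fragment's i7-bearing and i5-bearing adapter arms are drawn
*independently* from the sample's adapter pool. If the pool is contaminated
at fraction *c* by another well's duplexed adapter, a single-index design
misassigns a fraction *c* of reads, while a dual-matched design misassigns
only *c*² (both arms must come from the contaminant) and excludes the
2*c*(1−*c*) single-arm events as mismatched index pairs. Index hopping is an
independent per-index swap (probability *h*) to another pool member, so the
mismatched-pair rate of an *n*-plex capture is ≈ 1−(1−*h*)² above the
contamination baseline measured in a single-plex capture. Consensus calling
votes per-copy errors (oxoG misreads at damaged G's) out of UMI families,
which a coordinate-only deduplication cannot do.

## Worked example

```python
import crosstalkqc as cq

res = cq.benchmarks.single_index_misassignment(n_fragments=10**6,
                                               contamination=0.01, seed=1)
print(res["percent_misassigned"])   # -> 1.0124

res = cq.benchmarks.dual_matched_misassignment(n_fragments=10**7,
                                               contamination=0.01, seed=2)
print(res["percent_misassigned"])   # -> 0.00931
print(res["percent_filtered"])      # -> 1.97575
```

With a 1% adapter contamination, single-index demultiplexing misassigns
~1.0% of reads; the unique dual-matched design misassigns ~0.01% (= 1%²) and
flags ~1.98% (= 2·0.01·0.99) as mismatched pairs that are excluded from
analysis — the squared-contamination advantage in action.

The full pipeline runs from the shell:

```bash
crosstalkqc run-all --config config.yaml --out-dir out/ --seed 11
```

writing FASTQ (R1/R2/I1/I2, with the 6-nt UMI appended to i7 in I1), the
truth table, the cross-talk matrix and report, consensus reads, a variant
table and a sensitivity/PPV report. A minimal `config.yaml`:

```yaml
plate: {scheme: unique_dual, n_indices: 8, umi_length: 6}
samples: [S1]
sim:
  n_fragments: 5000
  reference_length: 2000
  variants:
    - {position: 500, ref: A, alt: G, allele_fraction: 0.01}
```

Subcommands `simulate`, `demux`, `crosstalk`, `hop-estimate`, `consensus`,
`call` and `evaluate` expose the stages individually over file artifacts.

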