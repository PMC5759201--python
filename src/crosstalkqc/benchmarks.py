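"""Reference experiments: the contamination -> misassignment model, end to end.

Both experiments realize the same physical story — a sample's adapter pool is
contaminated at fraction c by a neighbouring well's adapter after duplexing —
and measure what demultiplexing then does with it:

* under combinatorial indexing, the contaminant shares the sample's i5 (same
  plate row), so only the i7 discriminates and a fraction c of reads is
  misassigned outright;
* under unique dual-matched indexing, both independently drawn arms must come
  from the contaminant (probability c^2) to misassign, while single-arm
  contamination (2c(1-c)) produces mismatched index pairs that are filtered.
"""

from __future__ import annotations

from .demux import DemuxPolicy, build_crosstalk_matrix, single_index_counts
from .plates import (
    SampleEntry,
    SampleSheet,
    Well,
    default_combinatorial_plate,
    default_unique_dual_plate,
)
from .simulate import ContaminationEvent, FamilySizeSpec, SimConfig, simulate_experiment
from .stats import mismatched_pair_rate


def _one_read_per_fragment(n: int, **kw) -> SimConfig:
    kw.setdefault("duplicate_family_size", FamilySizeSpec("degenerate", 1))
    kw.setdefault("umi_length", 0)
    kw.setdefault("reference_length", 200)
    kw.setdefault("read_length", 100)
    return SimConfig(n_fragments=n, **kw)


def single_index_misassignment(
    n_fragments: int = 10**6, contamination: float = 0.01, seed: int = 0
) -> dict:
    """Combinatorial plate, duplex contamination of A1 by A2, i7-only demux.

    Returns the percent of A1's fragments assigned to A2's i7 under perfect
    matching; A1 and A2 share the i5 index (same plate row).
    """
    plate = default_combinatorial_plate(seed=seed)
    a1, a2 = Well("A", 1), Well("A", 2)
    sheet = SampleSheet([SampleEntry("A1", a1)])
    cfg = _one_read_per_fragment(
        n_fragments, seed=seed,
        contamination=(ContaminationEvent(a1, a2, contamination),),
    )
    reads, _ = simulate_experiment(plate, sheet, cfg)
    counts = single_index_counts(reads, plate.i7_sequences(), which="i7", max_mismatches=0)
    misassigned = int(counts[plate.i7_of(a2)])
    return {
        "percent_misassigned": 100.0 * misassigned / n_fragments,
        "misassigned_reads": misassigned,
        "n_fragments": n_fragments,
    }


def dual_matched_misassignment(
    n_fragments: int = 10**7, contamination: float = 0.01, seed: int = 0,
    n_indices: int = 35,
) -> dict:
    """Unique dual-matched plate, duplex contamination, both-index demux.

    Returns the percent of fragments assigned to the contaminant well (both
    indices must match it) and the percent excluded as mismatched pairs.
    """
    plate = default_unique_dual_plate(n=n_indices, seed=seed, umi_length=0)
    wells = plate.sorted_wells()
    a1, a2 = wells[0], wells[1]
    sheet = SampleSheet([SampleEntry("A1", a1)])
    cfg = _one_read_per_fragment(
        n_fragments, seed=seed,
        contamination=(ContaminationEvent(a1, a2, contamination),),
    )
    reads, _ = simulate_experiment(plate, sheet, cfg)
    policy = DemuxPolicy.for_plate(plate, max_mismatches=0)
    matrix = build_crosstalk_matrix(reads, policy, used_wells=[a1])
    k = policy.i7_candidates.index(plate.i7_of(a2))
    misassigned = int(matrix.counts[k, k])
    mismatched = mismatched_pair_rate(matrix) * matrix.total
    return {
        "percent_misassigned": 100.0 * misassigned / n_fragments,
        "percent_filtered": 100.0 * mismatched / n_fragments,
        "misassigned_reads": misassigned,
        "n_fragments": n_fragments,
    }


def hopping_pool_experiment(
    plex: int,
    hop_rate: float,
    n_reads_total: int = 10**6,
    contamination: float = 0.0005,
    seed: int = 0,
):
    """One multiplexed capture pool: chained one-way duplex contamination + hopping.

    Returns the pool's crosstalk matrix over the full plate candidate set.
    ``plex=1`` is the hopping-free baseline that isolates adapter
    contamination.
    """
    plate = default_unique_dual_plate(n=20, seed=11, umi_length=0)
    wells = plate.sorted_wells()
    sheet = SampleSheet([SampleEntry(f"s{i}", wells[i]) for i in range(plex)])
    events = tuple(
        ContaminationEvent(wells[i], wells[(i + 1) % max(plex, 2)], contamination)
        for i in range(plex)
    )
    cfg = _one_read_per_fragment(
        max(n_reads_total // plex, 1), seed=seed,
        contamination=events, hop_rate=hop_rate,
    )
    reads, _ = simulate_experiment(plate, sheet, cfg)
    policy = DemuxPolicy.for_plate(plate, max_mismatches=1)
    return build_crosstalk_matrix(reads, policy, used_wells=sheet.wells), len(reads)


def contamination_stage_experiment(
    stage: str, seed: int = 0, n_per_sample: int = 50_000, contamination: float = 0.01
):
    """Four-sample pool with chained one-way contamination at the given stage."""
    plate = default_unique_dual_plate(n=6, seed=13, umi_length=0)
    wells = plate.sorted_wells()
    sheet = SampleSheet([SampleEntry(f"s{i}", wells[i]) for i in range(4)])
    arm = "i7" if stage == "oligo" else None
    events = tuple(
        ContaminationEvent(wells[i], wells[(i + 1) % 4], contamination, arm=arm)
        for i in range(4)
    )
    cfg = _one_read_per_fragment(
        n_per_sample, seed=seed, contamination=events, contamination_stage=stage,
    )
    reads, _ = simulate_experiment(plate, sheet, cfg)
    policy = DemuxPolicy.for_plate(plate, max_mismatches=0)
    return build_crosstalk_matrix(reads, policy, used_wells=sheet.wells)
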