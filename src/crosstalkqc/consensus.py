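"""UMI family grouping, molecular consensus calling and consensus filtering.

Grouping uses the directed-adjacency strategy: within each (reference start,
strand) bucket, distinct UMIs are linked A -> B when they are within
``umi_edits`` mismatches and count(A) >= 2*count(B) - 1, and families grow
greedily from the highest-count unassigned UMI.  This merges sequencing-error
satellites of a true UMI without merging two genuinely distinct molecules of
similar abundance.

Consensus calling is a deliberately simple, fully specified scheme (not
bit-identical to any external tool): per position, the strict-majority base
over non-N member bases wins (tie or zero depth -> N); member base qualities
are capped at ``error_rate_post_umi`` (Phred) *before* summation so that the
consensus quality — sum of agreeing minus disagreeing capped qualities,
floored at 2 — can accumulate above the cap when several reads agree.  That
is what lets a min-base-quality filter of 40 coexist with a per-read cap of
30: three agreeing Q30 reads give a Q90 consensus base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._util import hamming, seq_to_codes
from .simulate import ReadRecord

_BASES = "ACGTN"


class FamilyTooSmall(ValueError):
    """A family below the consensus min_reads threshold."""


@dataclass
class UmiFamily:
    """Reads sharing (ref_start, strand) whose UMIs form one adjacency group."""

    ref_start: int
    strand: str
    canonical_umi: str
    members: list[ReadRecord]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def key(self) -> tuple:
        return (self.ref_start, self.strand, self.canonical_umi)


@dataclass
class ConsensusRead:
    ref_start: int
    strand: str
    canonical_umi: str
    bases: str
    quals: np.ndarray  # Phred ints
    depths: np.ndarray  # non-N member depth per position
    family_size: int
    error_fractions: np.ndarray  # disagreeing / depth per position

    @property
    def insert_bases(self) -> str:  # pileup duck-typing with ReadRecord
        return self.bases

    @property
    def no_call_fraction(self) -> float:
        return self.bases.count("N") / len(self.bases) if self.bases else 0.0

    @property
    def mean_error_fraction(self) -> float:
        return float(self.error_fractions.mean()) if len(self.error_fractions) else 0.0


@dataclass
class ConsensusFilterParams:
    """Published filter settings for consensus reads."""

    min_reads: int = 3
    max_read_error_rate: float = 0.05
    min_base_quality: int = 40
    max_base_error_rate: float = 0.1
    max_no_call_fraction: float = 0.1
    min_map_q: int = 10
    umi_edits: int = 1


def _adjacency_groups(umi_counts: dict[str, int], umi_edits: int) -> list[list[str]]:
    """Directed-adjacency clustering of distinct UMIs within one bucket.

    Roots are taken in decreasing count order (ties broken lexicographically
    for determinism); each root greedily absorbs unassigned UMIs reachable
    through edges u -> v with hamming(u, v) <= umi_edits and
    count(u) >= 2*count(v) - 1.
    """
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    assigned: set[str] = set()
    groups = []
    for root in order:
        if root in assigned:
            continue
        group = [root]
        assigned.add(root)
        frontier = [root]
        while frontier:
            nxt = []
            for u in frontier:
                for v in order:
                    if v in assigned:
                        continue
                    if hamming(u, v) <= umi_edits and umi_counts[u] >= 2 * umi_counts[v] - 1:
                        assigned.add(v)
                        group.append(v)
                        nxt.append(v)
            frontier = nxt
        groups.append(group)
    return groups


def group_reads_by_umi(
    reads: Iterable[ReadRecord], umi_edits: int = 1, min_map_q: int = 10
) -> list[UmiFamily]:
    """Partition mapq-passing reads into molecular families.

    Reads are bucketed by (ref_start, strand); within a bucket, UMIs within
    the adjacency network collapse into one family whose canonical UMI is the
    highest-count member.
    """
    buckets: dict[tuple[int, str], list[ReadRecord]] = {}
    umi_len = None
    for r in reads:
        if r.mapq < min_map_q:
            continue
        if umi_len is None:
            umi_len = len(r.umi_obs)
        elif len(r.umi_obs) != umi_len:
            raise ValueError(f"inconsistent UMI length on read {r.read_id}")
        buckets.setdefault((r.ref_start, r.strand), []).append(r)

    families: list[UmiFamily] = []
    for (start, strand), members in sorted(buckets.items()):
        by_umi: dict[str, list[ReadRecord]] = {}
        for r in members:
            by_umi.setdefault(r.umi_obs, []).append(r)
        counts = {u: len(v) for u, v in by_umi.items()}
        for group in _adjacency_groups(counts, umi_edits):
            fam_members = [r for u in group for r in by_umi[u]]
            families.append(UmiFamily(start, strand, group[0], fam_members))
    return families


def call_consensus(
    family: UmiFamily, min_reads: int = 1, error_rate_post_umi: int = 30
) -> ConsensusRead:
    """Collapse one family into a consensus read.

    Per position: strict-majority base over non-N member bases (tie or zero
    depth -> N); quality = sum of agreeing member Phred scores minus sum of
    disagreeing, with each member score first capped at
    ``error_rate_post_umi``, floored at 2; error fraction = disagreeing/depth.
    """
    if family.size < min_reads:
        raise FamilyTooSmall(
            f"family {family.key} has {family.size} reads < min_reads={min_reads}"
        )
    length = len(family.members[0].insert_bases)
    codes = np.empty((family.size, length), np.uint8)
    quals = np.empty((family.size, length), np.int64)
    for k, r in enumerate(family.members):
        if len(r.insert_bases) != length:
            raise ValueError("family members must be length-aligned")
        codes[k] = seq_to_codes(r.insert_bases)
        quals[k] = np.minimum(np.asarray(r.insert_quals, np.int64), error_rate_post_umi)

    counts = np.zeros((5, length), np.int64)
    qsums = np.zeros((5, length), np.int64)
    pos = np.arange(length)
    for k in range(family.size):
        np.add.at(counts, (codes[k], pos), 1)
        np.add.at(qsums, (codes[k], pos), quals[k])

    depth = counts[:4].sum(axis=0)  # non-N depth
    top = counts[:4].argmax(axis=0)
    top_count = counts[:4].max(axis=0)
    strict = top_count * 2 > depth  # strict majority of non-N bases
    called = strict & (depth > 0)

    agree_q = qsums[top, pos]
    total_q = qsums[:4].sum(axis=0)
    qual = np.where(called, np.maximum(agree_q - (total_q - agree_q), 2), 2)
    err = np.zeros(length)
    nz = depth > 0
    err[nz] = np.where(called[nz], (depth[nz] - top_count[nz]) / depth[nz], 0.0)

    bases = np.where(called, top, 4)
    base_str = "".join(_BASES[b] for b in bases)
    return ConsensusRead(
        ref_start=family.ref_start,
        strand=family.strand,
        canonical_umi=family.canonical_umi,
        bases=base_str,
        quals=qual.astype(np.int64),
        depths=depth,
        family_size=family.size,
        error_fractions=err,
    )


@dataclass
class RejectedConsensus:
    consensus: ConsensusRead
    reason: str


def filter_consensus(
    consensus_list: Iterable[ConsensusRead], params: ConsensusFilterParams
) -> tuple[list[ConsensusRead], list[RejectedConsensus]]:
    """Apply the consensus filters; returns (kept, rejected-with-reason).

    Rejection: family_size < min_reads, mean per-base error fraction above
    max_read_error_rate, or — after masking individual bases with quality
    below min_base_quality or error fraction above max_base_error_rate — a
    no-call (N) fraction above max_no_call_fraction.  Kept reads carry the
    masked bases (N, quality 2).
    """
    kept: list[ConsensusRead] = []
    rejected: list[RejectedConsensus] = []
    for cons in consensus_list:
        if cons.family_size < params.min_reads:
            rejected.append(RejectedConsensus(cons, "min_reads"))
            continue
        if cons.mean_error_fraction > params.max_read_error_rate:
            rejected.append(RejectedConsensus(cons, "read_error_rate"))
            continue
        mask = (cons.quals < params.min_base_quality) | (
            cons.error_fractions > params.max_base_error_rate
        )
        if mask.any():
            chars = np.array(list(cons.bases))
            chars[mask] = "N"
            quals = cons.quals.copy()
            quals[mask] = 2
            cons = ConsensusRead(
                cons.ref_start, cons.strand, cons.canonical_umi,
                "".join(chars), quals, cons.depths, cons.family_size,
                cons.error_fractions,
            )
        if cons.no_call_fraction > params.max_no_call_fraction:
            rejected.append(RejectedConsensus(cons, "no_call_fraction"))
            continue
        kept.append(cons)
    return kept, rejected


def raw_duplicate_collapse(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Coordinate-only deduplication — the no-UMI comparator.

    Retains one read per (ref_start, strand): highest mean base quality,
    ties broken by read_id order.
    """
    best: dict[tuple[int, str], ReadRecord] = {}
    for r in reads:
        key = (r.ref_start, r.strand)
        cur = best.get(key)
        # strict > keeps the first-seen read on quality ties (read_id order)
        if cur is None or r.mean_quality > cur.mean_quality:
            best[key] = r
    return [best[k] for k in sorted(best)]


def consensus_pipeline(
    reads: Iterable[ReadRecord],
    params: ConsensusFilterParams | None = None,
    error_rate_post_umi: int = 30,
) -> tuple[list[ConsensusRead], list[RejectedConsensus]]:
    """group -> call (min_reads=1) -> filter, with the published defaults."""
    params = params or ConsensusFilterParams()
    families = group_reads_by_umi(reads, umi_edits=params.umi_edits, min_map_q=params.min_map_q)
    consensus = [call_consensus(f, min_reads=1, error_rate_post_umi=error_rate_post_umi)
                 for f in families]
    return filter_consensus(consensus, params)


def write_consensus_tsv(consensus_list: list[ConsensusRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_start\tstrand\tumi\tfamily_size\tbases\tquals\tdepths\n")
        for c in consensus_list:
            fh.write(
                f"{c.ref_start}\t{c.strand}\t{c.canonical_umi}\t{c.family_size}\t"
                f"{c.bases}\t{','.join(map(str, c.quals))}\t{','.join(map(str, c.depths))}\n"
            )
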