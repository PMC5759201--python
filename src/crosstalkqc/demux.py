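"""Read-to-sample assignment under perfect or one-mismatch index matching.

Matching is Hamming-based over fixed-cycle index reads (indels are not
modeled); N calls count as mismatches.  Ambiguous one-mismatch hits resolve
to unassigned — false assignment is the failure mode under study, so the
matcher never guesses.  UMI bases are split off the I1 read before matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import hamming
from .plates import AdapterPlate, SampleSheet, Well
from .simulate import ReadSet
from .stats import CrosstalkMatrix

UNMATCHED = -1
AMBIGUOUS = -2


class PolicyError(ValueError):
    """Raised when a demultiplexing policy cannot guarantee unique matches."""


@dataclass
class DemuxPolicy:
    """Candidate index sets (used + unused) plus the matching tolerance."""

    i7_candidates: list[str]
    i5_candidates: list[str]
    max_mismatches: int = 0
    scheme: str | None = None

    def __post_init__(self):
        if not self.i7_candidates or not self.i5_candidates:
            raise PolicyError("candidate sets must be non-empty")
        if self.max_mismatches not in (0, 1):
            raise PolicyError("max_mismatches must be 0 or 1")
        for name, cands in (("i7", self.i7_candidates), ("i5", self.i5_candidates)):
            if len({len(c) for c in cands}) != 1:
                raise PolicyError(f"{name} candidates have mixed lengths")
            if len(set(cands)) != len(cands):
                raise PolicyError(f"duplicate {name} candidates")
            if self.max_mismatches >= 1:
                sep = min(
                    (hamming(a, b) for i, a in enumerate(cands) for b in cands[i + 1 :]),
                    default=2 * self.max_mismatches + 1,
                )
                if sep <= 2 * self.max_mismatches:
                    raise PolicyError(
                        f"{name} candidates only {sep} mismatches apart; "
                        f"need > {2 * self.max_mismatches} for unique matching"
                    )

    @classmethod
    def for_plate(cls, plate: AdapterPlate, max_mismatches: int = 0) -> "DemuxPolicy":
        return cls(
            i7_candidates=plate.i7_sequences(),
            i5_candidates=plate.i5_sequences(),
            max_mismatches=max_mismatches,
            scheme=plate.scheme,
        )


def match_index(observed: str, candidates: list[str], max_mismatches: int = 0) -> str | None:
    """The unique candidate within Hamming distance <= max_mismatches, else None.

    Two or more candidates at the same minimal qualifying distance -> None
    (ambiguity is treated as no match).
    """
    cand, _, _ = _match_one(observed, candidates, max_mismatches)
    return cand


@dataclass
class Assignment:
    read_id: str
    i7_match: str | None
    i5_match: str | None
    well: Well | None
    combination: tuple[str, str] | None
    mismatches: tuple[int | None, int | None]
    flags: set[str] = field(default_factory=set)

    @property
    def resolved(self) -> bool:
        return self.combination is not None


def _match_one(observed: str, candidates: list[str], max_mismatches: int):
    best, best_d, tied = None, max_mismatches + 1, False
    for cand in candidates:
        d = hamming(observed, cand)
        if d < best_d:
            best, best_d, tied = cand, d, False
        elif d == best_d:
            tied = True
    if best is None or best_d > max_mismatches:
        return None, None, False
    if tied:
        return None, None, True
    return best, best_d, False


def assign_read(read, policy: DemuxPolicy, plate: AdapterPlate | None = None) -> Assignment:
    """Assign a single read; i7 and i5 are matched independently.

    Combinations not on the plate are retained as combination-assignments
    (flagged ``not_a_well``; additionally ``mismatched_pair`` when the two
    matched labels differ, the unique-dual exclusion signal).
    """
    i7, d7, amb7 = _match_one(read.i7_obs, policy.i7_candidates, policy.max_mismatches)
    i5, d5, amb5 = _match_one(read.i5_obs, policy.i5_candidates, policy.max_mismatches)
    flags = set()
    if amb7:
        flags.add("ambiguous_i7")
    if amb5:
        flags.add("ambiguous_i5")
    if i7 is None or i5 is None:
        return Assignment(read.read_id, i7, i5, None, None, (d7, d5), flags | {"unassigned"})
    well = plate.well_of_pair(i7, i5) if plate is not None else None
    if well is None:
        flags.add("not_a_well")
        if i7 != i5:
            flags.add("mismatched_pair")
    return Assignment(read.read_id, i7, i5, well, (i7, i5), (d7, d5), flags)


@dataclass
class DemuxResult:
    """Vectorized assignment of a ReadSet: candidate indices per read."""

    i7_idx: np.ndarray  # index into policy.i7_candidates, UNMATCHED/AMBIGUOUS
    i5_idx: np.ndarray
    policy: DemuxPolicy

    @property
    def both_matched(self) -> np.ndarray:
        return (self.i7_idx >= 0) & (self.i5_idx >= 0)

    @property
    def n_assigned(self) -> int:
        return int(self.both_matched.sum())

    @property
    def n_unassigned(self) -> int:
        return len(self.i7_idx) - self.n_assigned


def _code_matcher(pool: list[str], candidates: list[str], max_mismatches: int) -> np.ndarray:
    """Map every sequence in the observed pool to its candidate index."""
    exact = {c: k for k, c in enumerate(candidates)}
    out = np.empty(len(pool), np.int32)
    for i, seq in enumerate(pool):
        k = exact.get(seq)
        if k is None and max_mismatches > 0 and len(seq) == len(candidates[0]):
            cand, _, tied = _match_one(seq, candidates, max_mismatches)
            k = AMBIGUOUS if tied else (exact[cand] if cand is not None else UNMATCHED)
        elif k is None:
            k = UNMATCHED
        out[i] = k
    return out


def assign_reads(reads: ReadSet, policy: DemuxPolicy) -> DemuxResult:
    """Vectorized per-read assignment over a ReadSet."""
    m7 = _code_matcher(reads.index_pool, policy.i7_candidates, policy.max_mismatches)
    m5 = _code_matcher(reads.index_pool, policy.i5_candidates, policy.max_mismatches)
    return DemuxResult(m7[reads.i7_code], m5[reads.i5_code], policy)


def build_crosstalk_matrix(
    reads: ReadSet,
    policy: DemuxPolicy,
    used_wells=(),
) -> CrosstalkMatrix:
    """Count reads for every (i7 candidate, i5 candidate) combination.

    The matrix total equals the number of reads with both indices matched.
    """
    res = assign_reads(reads, policy)
    n7, n5 = len(policy.i7_candidates), len(policy.i5_candidates)
    ok = res.both_matched
    flat = res.i7_idx[ok].astype(np.int64) * n5 + res.i5_idx[ok]
    counts = np.bincount(flat, minlength=n7 * n5).reshape(n7, n5)
    used = {w.label if isinstance(w, Well) else str(w) for w in used_wells}
    return CrosstalkMatrix(counts, list(policy.i7_candidates), list(policy.i5_candidates),
                           used, policy.scheme)


def single_index_counts(
    reads: ReadSet,
    candidates: list[str],
    which: str = "i7",
    max_mismatches: int = 0,
) -> pd.Series:
    """Per-candidate read counts when demultiplexing on a single index.

    This is the genotyping-style mode in which only the i7 (or only the i5)
    index discriminates samples.
    """
    codes = reads.i7_code if which == "i7" else reads.i5_code
    matcher = _code_matcher(reads.index_pool, list(candidates), max_mismatches)
    matched = matcher[codes]
    counts = np.bincount(matched[matched >= 0], minlength=len(candidates))
    return pd.Series(counts, index=list(candidates), name=f"{which}_count")


def assignments_dataframe(reads: ReadSet, policy: DemuxPolicy, plate: AdapterPlate) -> pd.DataFrame:
    """Per-read assignment table (read_id, matches, well, flags)."""
    res = assign_reads(reads, policy)
    rows = []
    for i in range(len(reads)):
        k7, k5 = int(res.i7_idx[i]), int(res.i5_idx[i])
        i7 = policy.i7_candidates[k7] if k7 >= 0 else None
        i5 = policy.i5_candidates[k5] if k5 >= 0 else None
        flags = []
        if k7 == AMBIGUOUS:
            flags.append("ambiguous_i7")
        if k5 == AMBIGUOUS:
            flags.append("ambiguous_i5")
        well = None
        if i7 is not None and i5 is not None:
            w = plate.well_of_pair(i7, i5)
            well = w.label if w else None
            if w is None:
                flags.append("not_a_well")
                if i7 != i5:
                    flags.append("mismatched_pair")
        else:
            flags.append("unassigned")
        rows.append((reads.read_id(i), i7 or ".", i5 or ".", well or ".", ",".join(flags) or "."))
    return pd.DataFrame(rows, columns=["read_id", "i7_match", "i5_match", "well", "flags"])


def demux_sheet_counts(
    matrix: CrosstalkMatrix, plate: AdapterPlate, sheet: SampleSheet
) -> pd.Series:
    """Reads per sample: the matrix cell of each sample's (i7, i5) pair."""
    col = {lab: j for j, lab in enumerate(matrix.i5_labels)}
    row = {lab: i for i, lab in enumerate(matrix.i7_labels)}
    out = {}
    for e in sheet.entries:
        i7, i5 = plate.wells[e.well]
        out[e.sample_id] = int(matrix.counts[row[i7], col[i5]])
    return pd.Series(out, name="reads")
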