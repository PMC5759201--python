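"""Cross-talk quantification, plate geometry, hop-rate estimation, diagnostics.

All statistics operate on a :class:`CrosstalkMatrix` — the count of dual-index
matched reads for every (i7 candidate, i5 candidate) combination, including
indices that were never used in library preparation.  Reads landing on an
unused combination are direct evidence of cross-talk.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plates import COMBINATORIAL, AdapterPlate, Well


@dataclass
class CrosstalkMatrix:
    """N x M counts of reads per observed (i7, i5) candidate combination."""

    counts: np.ndarray
    i7_labels: list[str]
    i5_labels: list[str]
    used_wells: set[str] = field(default_factory=set)  # well labels
    scheme: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.i7_labels), len(self.i5_labels)):
            raise ValueError("counts shape does not match label lists")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if len(set(self.i7_labels)) != len(self.i7_labels) or len(set(self.i5_labels)) != len(self.i5_labels):
            raise ValueError("duplicate labels")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.i7_labels, columns=self.i5_labels)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "i7"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, used_wells=(), scheme=None) -> "CrosstalkMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            df.to_numpy(dtype=np.int64),
            [str(x) for x in df.index],
            [str(x) for x in df.columns],
            set(used_wells),
            scheme,
        )


@dataclass
class RowColumnPartition:
    """Misassigned-to-well reads classified by plate geometry vs ANY used well."""

    same_row_only: int = 0
    same_column_only: int = 0
    same_row_and_column: int = 0
    neither: int = 0

    @property
    def total(self) -> int:
        return self.same_row_only + self.same_column_only + self.same_row_and_column + self.neither


@dataclass
class CrosstalkReport:
    total_reads: int
    misassigned_reads: int
    overall_rate: float
    per_unused_index: dict[str, int]
    not_a_well_reads: int = 0
    row_column_partition: RowColumnPartition | None = None

    def to_dict(self) -> dict:
        d = {
            "total_reads": self.total_reads,
            "misassigned_reads": self.misassigned_reads,
            "overall_rate": self.overall_rate,
            "per_unused_index": self.per_unused_index,
            "not_a_well_reads": self.not_a_well_reads,
        }
        if self.row_column_partition is not None:
            p = self.row_column_partition
            d["row_column_partition"] = {
                "same_row_only": p.same_row_only,
                "same_column_only": p.same_column_only,
                "same_row_and_column": p.same_row_and_column,
                "neither": p.neither,
            }
        return d


@dataclass
class HopEstimate:
    plex_size: int
    mismatched_pair_rate: float
    baseline_rate: float | None
    corrected_hop_rate: float
    per_index_hop_rate: float
    corrected: bool = True

    def to_dict(self) -> dict:
        return dict(
            plex_size=self.plex_size,
            mismatched_pair_rate=self.mismatched_pair_rate,
            baseline_rate=self.baseline_rate,
            corrected_hop_rate=self.corrected_hop_rate,
            per_index_hop_rate=self.per_index_hop_rate,
            corrected=self.corrected,
        )


@dataclass
class SymmetryDiagnostic:
    asymmetry_score: float
    verdict: str  # skewed | symmetric | indeterminate
    off_diagonal_reads: int


def _normalize_used(used_wells) -> set[str]:
    out = set()
    for w in used_wells:
        out.add(w.label if isinstance(w, Well) else str(w))
    return out


def misassignment_report(
    matrix: CrosstalkMatrix, used_wells, plate: AdapterPlate
) -> CrosstalkReport:
    """Count reads demultiplexed to combinations not used in library prep.

    A cell is misassigned when its (i7, i5) pair either resolves to an unused
    plate well or resolves to no well at all (mismatched pair under the
    unique-dual scheme).  The rate denominator is the matrix total, i.e.
    reads with both indices matched.
    """
    used = _normalize_used(used_wells)
    for label in used:
        if Well.from_label(label) not in plate.wells:
            raise ValueError(f"used well {label} not on plate")
    total = matrix.total
    misassigned = 0
    not_a_well = 0
    per_unused: dict[str, int] = {}
    for i, i7 in enumerate(matrix.i7_labels):
        row = matrix.counts[i]
        for j, i5 in enumerate(matrix.i5_labels):
            c = int(row[j])
            if c == 0:
                continue
            well = plate.well_of_pair(i7, i5)
            if well is None:
                not_a_well += c
                misassigned += c
            elif well.label not in used:
                per_unused[well.label] = per_unused.get(well.label, 0) + c
                misassigned += c
    rate = misassigned / total if total else 0.0
    report = CrosstalkReport(
        total_reads=total,
        misassigned_reads=misassigned,
        overall_rate=rate,
        per_unused_index=per_unused,
        not_a_well_reads=not_a_well,
    )
    if plate.scheme == COMBINATORIAL:
        report.row_column_partition = row_column_decomposition(report, plate, used)
    return report


def row_column_decomposition(
    report: CrosstalkReport, plate: AdapterPlate, used_wells
) -> RowColumnPartition:
    """Classify misassigned-to-unused-well reads by shared plate row/column.

    Each unused well receiving reads is compared against ANY used well:
    shares a row only, a column only, both, or neither.  Only defined for
    the combinatorial scheme, where single oligos are shared along rows and
    columns.
    """
    if plate.scheme != COMBINATORIAL:
        raise ValueError("row/column decomposition applies to combinatorial plates only")
    used = [Well.from_label(w) for w in _normalize_used(used_wells)]
    part = RowColumnPartition()
    for label, count in report.per_unused_index.items():
        well = Well.from_label(label)
        row_hit = any(u.row == well.row for u in used)
        col_hit = any(u.column == well.column for u in used)
        if row_hit and col_hit:
            part.same_row_and_column += count
        elif row_hit:
            part.same_row_only += count
        elif col_hit:
            part.same_column_only += count
        else:
            part.neither += count
    return part


def mismatched_pair_rate(matrix: CrosstalkMatrix) -> float:
    """Fraction of matrix reads whose i7 and i5 labels differ (unique-dual)."""
    total = matrix.total
    if total == 0:
        return 0.0
    matched = 0
    col_of = {lab: j for j, lab in enumerate(matrix.i5_labels)}
    for i, lab in enumerate(matrix.i7_labels):
        j = col_of.get(lab)
        if j is not None:
            matched += int(matrix.counts[i, j])
    return (total - matched) / total


def hop_rate_estimate(
    pool_matrices: dict[int, CrosstalkMatrix],
    singleplex_matrix: CrosstalkMatrix | None = None,
) -> list[HopEstimate]:
    """Baseline-corrected hop estimates per multiplexed capture pool.

    The single-plex pool cannot hop (nothing to hop to), so its mismatched
    pair rate measures adapter contamination alone; subtracting it (floored
    at zero — rates are physical) isolates hopping.  The corrected excess
    estimates 1-(1-h)^2 for a per-index hop probability h, hence the
    reported ``per_index_hop_rate`` = 1 - sqrt(1 - corrected).
    """
    baseline = mismatched_pair_rate(singleplex_matrix) if singleplex_matrix is not None else None
    out = []
    for plex in sorted(pool_matrices):
        rate = mismatched_pair_rate(pool_matrices[plex])
        if baseline is None:
            corrected, flag = rate, False
        else:
            corrected, flag = max(0.0, rate - baseline), True
        out.append(
            HopEstimate(
                plex_size=plex,
                mismatched_pair_rate=rate,
                baseline_rate=baseline,
                corrected_hop_rate=corrected,
                per_index_hop_rate=1.0 - math.sqrt(max(0.0, 1.0 - corrected)),
                corrected=flag,
            )
        )
    return out


def symmetry_diagnostic(
    matrix: CrosstalkMatrix,
    skew_threshold: float = 0.5,
    symmetric_threshold: float = 0.2,
    min_off_diagonal: int = 50,
) -> SymmetryDiagnostic:
    """Diagnose the contamination stage from off-diagonal (a)symmetry.

    Single-stranded-oligo contamination leaks one arm only, producing a
    skewed off-diagonal pattern; post-duplexing contamination delivers both
    arms, producing a symmetric pattern.  The score is
    sum |off(i,j) - off(j,i)| / sum (off(i,j) + off(j,i)).
    """
    c = matrix.counts
    if c.shape[0] != c.shape[1] or matrix.i7_labels != matrix.i5_labels:
        raise ValueError("symmetry diagnostic needs a square matrix with matching labels")
    off = c.copy()
    np.fill_diagonal(off, 0)
    denom = int(off.sum())
    if denom == 0:
        return SymmetryDiagnostic(0.0, "indeterminate", 0)
    score = float(np.abs(off - off.T).sum() / (off + off.T).sum())
    if score > skew_threshold and denom >= min_off_diagonal:
        verdict = "skewed"
    elif score < symmetric_threshold and denom >= min_off_diagonal:
        verdict = "symmetric"
    else:
        verdict = "indeterminate"
    return SymmetryDiagnostic(score, verdict, denom)


def expected_misassignment(c: float, mode: str) -> tuple[float, float]:
    """Analytic contamination -> misassignment model.

    ``single_index``: a fraction c of reads carries the contaminant's only
    discriminating index, so (misassigned, filtered) = (c, 0).
    ``dual_matched`` with independent per-arm draws: both arms must come from
    the contaminant to misassign (c^2); exactly one contaminated arm makes a
    mismatched pair that is filtered out (2c(1-c)).
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("contamination rate must be in [0,1]")
    if mode == "single_index":
        return c, 0.0
    if mode == "dual_matched":
        return c * c, 2.0 * c * (1.0 - c)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# output formats


def plate_grid(matrix: CrosstalkMatrix, plate: AdapterPlate) -> pd.DataFrame:
    """Per-well read counts arranged as the physical plate (rows x columns)."""
    import string

    rows = list(string.ascii_uppercase[: plate.n_rows])
    grid = pd.DataFrame(0, index=rows, columns=range(1, plate.n_cols + 1))
    i5_col = {lab: j for j, lab in enumerate(matrix.i5_labels)}
    for i, i7 in enumerate(matrix.i7_labels):
        for i5, j in i5_col.items():
            well = plate.well_of_pair(i7, i5)
            if well is not None:
                grid.loc[well.row, well.column] += int(matrix.counts[i, j])
    return grid


def write_report_json(report: CrosstalkReport, path, hop_estimates: list[HopEstimate] | None = None,
                      extra: dict | None = None) -> None:
    payload = report.to_dict()
    if hop_estimates:
        payload["hop_estimates"] = [h.to_dict() for h in hop_estimates]
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
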