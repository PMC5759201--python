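"""Adapter plates, index sets and sample sheets.

Two indexing schemes are modeled:

* ``combinatorial`` — the TruSeq-HT-style 96-well layout in which 12 i7 and
  8 i5 oligos combine so that every well in a column shares its i7 and every
  well in a row shares its i5.  Only 20 oligo sequences exist on the plate,
  so single indices are shared across samples.
* ``unique_dual`` — each well carries its own adapter whose i5 and i7 index
  sequences are identical (dual-matched) and shared with no other well, plus
  a UMI appended 3' of the i7 index.
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._util import hamming, validate_dna

COMBINATORIAL = "combinatorial"
UNIQUE_DUAL = "unique_dual"

DEFAULT_INDEX_LENGTH = 8
DEFAULT_UMI_LENGTH = 6


class DesignError(ValueError):
    """Raised when an index set or plate violates a design invariant."""


class SampleSheetError(ValueError):
    """Raised on malformed or inconsistent sample sheets."""


def gc_fraction(index: str) -> float:
    """Fraction of G/C bases of an index sequence."""
    validate_dna(index, name="index")
    return (index.count("G") + index.count("C")) / len(index)


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@dataclass(frozen=True, order=True)
class Well:
    """One plate position, e.g. row 'A', column 1."""

    row: str
    column: int

    def __post_init__(self):
        if len(self.row) != 1 or self.row not in string.ascii_uppercase:
            raise ValueError(f"well row must be a single letter A-Z, got {self.row!r}")
        if self.column < 1:
            raise ValueError(f"well column must be >= 1, got {self.column}")

    @property
    def label(self) -> str:
        return f"{self.row}{self.column}"

    @classmethod
    def from_label(cls, label: str) -> "Well":
        label = label.strip().upper()
        if len(label) < 2:
            raise ValueError(f"cannot parse well label {label!r}")
        return cls(row=label[0], column=int(label[1:]))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class AdapterPlate:
    """A plate of adapters: map well -> (i7 index, i5 index).

    ``n_rows``/``n_cols`` default to the production 8x12 format but are
    configurable so small plates can be built in tests.
    """

    scheme: str
    wells: dict[Well, tuple[str, str]]
    umi_length: int = 0
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self):
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def index_length(self) -> int:
        i7, _ = next(iter(self.wells.values()))
        return len(i7)

    def i7_of(self, well: Well) -> str:
        return self.wells[well][0]

    def i5_of(self, well: Well) -> str:
        return self.wells[well][1]

    def i7_sequences(self) -> list[str]:
        """Distinct i7 sequences in well order."""
        seen: dict[str, None] = {}
        for i7, _ in self.wells.values():
            seen.setdefault(i7)
        return list(seen)

    def i5_sequences(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, i5 in self.wells.values():
            seen.setdefault(i5)
        return list(seen)

    def all_index_sequences(self) -> list[str]:
        seen: dict[str, None] = {}
        for i7, i5 in self.wells.values():
            seen.setdefault(i7)
            seen.setdefault(i5)
        return list(seen)

    def well_of_pair(self, i7: str, i5: str):
        """The well carrying exactly this (i7, i5) pair, or None."""
        return self._pair_lookup().get((i7, i5))

    def _pair_lookup(self) -> dict[tuple[str, str], Well]:
        if not hasattr(self, "_pairs"):
            self._pairs = {pair: well for well, pair in self.wells.items()}
        return self._pairs

    def sorted_wells(self) -> list[Well]:
        return sorted(self.wells, key=lambda w: (w.row, w.column))

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.scheme not in (COMBINATORIAL, UNIQUE_DUAL):
            raise DesignError(f"unknown scheme {self.scheme!r}")
        if not self.wells:
            raise DesignError("plate has no wells")
        lengths = {len(s) for pair in self.wells.values() for s in pair}
        if len(lengths) != 1:
            raise DesignError(f"mixed index lengths on plate: {sorted(lengths)}")
        rows = string.ascii_uppercase[: self.n_rows]
        for well, (i7, i5) in self.wells.items():
            if well.row not in rows or well.column > self.n_cols:
                raise DesignError(f"well {well.label} outside {self.n_rows}x{self.n_cols} plate")
            validate_dna(i7, name=f"i7 of {well.label}")
            validate_dna(i5, name=f"i5 of {well.label}")
        pairs = list(self.wells.values())
        if len(set(pairs)) != len(pairs):
            raise DesignError("duplicate (i7, i5) pair on plate")
        if self.scheme == COMBINATORIAL:
            self._validate_combinatorial()
            if self.umi_length != 0:
                raise DesignError("combinatorial plates carry no UMI")
        else:
            self._validate_unique_dual()

    def _validate_combinatorial(self) -> None:
        by_col: dict[int, set[str]] = {}
        by_row: dict[str, set[str]] = {}
        for well, (i7, i5) in self.wells.items():
            by_col.setdefault(well.column, set()).add(i7)
            by_row.setdefault(well.row, set()).add(i5)
        for col, i7s in by_col.items():
            if len(i7s) != 1:
                raise DesignError(f"column {col} wells disagree on i7")
        for row, i5s in by_row.items():
            if len(i5s) != 1:
                raise DesignError(f"row {row} wells disagree on i5")

    def _validate_unique_dual(self) -> None:
        seen: dict[str, Well] = {}
        for well, (i7, i5) in self.wells.items():
            if i7 != i5:
                raise DesignError(f"well {well.label}: unique_dual requires i7 == i5")
            if i7 in seen:
                raise DesignError(
                    f"index {i7} shared by wells {seen[i7].label} and {well.label}"
                )
            seen[i7] = well


def make_combinatorial_plate(
    i7_list: list[str],
    i5_list: list[str],
    n_rows: int | None = None,
    n_cols: int | None = None,
) -> AdapterPlate:
    """Build a combinatorial plate: well (row r, column c) gets (i7_list[c], i5_list[r]).

    The production plate uses 12 i7 and 8 i5 oligos for 96 wells; smaller lists
    build correspondingly smaller plates (useful in tests).
    """
    n_cols = len(i7_list) if n_cols is None else n_cols
    n_rows = len(i5_list) if n_rows is None else n_rows
    if len(i7_list) != n_cols or len(i5_list) != n_rows:
        raise DesignError("index list lengths must match plate dimensions")
    if len(set(i7_list)) != len(i7_list) or len(set(i5_list)) != len(i5_list):
        raise DesignError("duplicate sequences within an index list")
    if set(i7_list) & set(i5_list):
        raise DesignError("a sequence appears in both the i7 and i5 lists")
    wells = {}
    for r, i5 in zip(string.ascii_uppercase, i5_list):
        for c, i7 in enumerate(i7_list, start=1):
            wells[Well(r, c)] = (i7, i5)
    return AdapterPlate(COMBINATORIAL, wells, umi_length=0, n_rows=n_rows, n_cols=n_cols)


def make_unique_dual_plate(
    indices: list[str],
    umi_length: int = DEFAULT_UMI_LENGTH,
    n_rows: int = 8,
    n_cols: int = 12,
) -> AdapterPlate:
    """Build a unique dual-matched plate filling wells row-major from A1.

    Each well carries i7 == i5 == one input index; no index repeats.
    """
    if len(indices) > n_rows * n_cols:
        raise DesignError(f"{len(indices)} indices exceed {n_rows}x{n_cols} plate")
    if len(set(indices)) != len(indices):
        raise DesignError("duplicate index sequences")
    wells = {}
    for k, idx in enumerate(indices):
        well = Well(string.ascii_uppercase[k // n_cols], k % n_cols + 1)
        wells[well] = (idx, idx)
    return AdapterPlate(UNIQUE_DUAL, wells, umi_length=umi_length, n_rows=n_rows, n_cols=n_cols)


def min_pairwise_edit_distance(plate: AdapterPlate) -> int:
    """Minimum Levenshtein distance over all pairs of distinct index sequences."""
    seqs = plate.all_index_sequences()
    if len(seqs) < 2:
        raise DesignError("plate carries fewer than 2 distinct index sequences")
    best = min(
        levenshtein(seqs[i], seqs[j])
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    )
    return best


def generate_index_set(
    n: int,
    length: int = DEFAULT_INDEX_LENGTH,
    min_distance: int = 3,
    gc_content: float = 0.5,
    seed: int = 0,
    avoid: list[str] | None = None,
    max_tries: int = 200_000,
) -> list[str]:
    """Generate n index sequences with the published design constraints.

    Every index has exactly ``round(length * gc_content)`` G/C bases, and every
    pair (including pairs with ``avoid``) is at Levenshtein *and* Hamming
    distance >= ``min_distance`` — the Hamming bound additionally guarantees
    unique nearest candidates under one-mismatch demultiplexing.
    """
    rng = np.random.default_rng(seed)
    n_gc = round(length * gc_content)
    accepted: list[str] = list(avoid or [])
    n_skip = len(accepted)
    for _ in range(max_tries):
        if len(accepted) - n_skip >= n:
            break
        gc_slots = set(rng.permutation(length)[:n_gc].tolist())
        picks = rng.integers(0, 2, size=length)
        cand = "".join(
            "GC"[picks[i]] if i in gc_slots else "AT"[picks[i]] for i in range(length)
        )
        if all(
            hamming(cand, s) >= min_distance and levenshtein(cand, s) >= min_distance
            for s in accepted
        ):
            accepted.append(cand)
    if len(accepted) - n_skip < n:
        raise DesignError(f"could not generate {n} indices after {max_tries} tries")
    return accepted[n_skip:]


def default_combinatorial_plate(seed: int = 0, index_length: int = DEFAULT_INDEX_LENGTH) -> AdapterPlate:
    """A full 96-well combinatorial plate from a generated 20-oligo design."""
    seqs = generate_index_set(20, length=index_length, seed=seed)
    return make_combinatorial_plate(seqs[:12], seqs[12:])


def default_unique_dual_plate(
    n: int = 35,
    seed: int = 0,
    umi_length: int = DEFAULT_UMI_LENGTH,
    index_length: int = DEFAULT_INDEX_LENGTH,
) -> AdapterPlate:
    """A unique dual-matched plate with n generated indices (paper-style: 35)."""
    seqs = generate_index_set(n, length=index_length, seed=seed)
    return make_unique_dual_plate(seqs, umi_length=umi_length)


# --- sample sheets ---------------------------------------------------------

@dataclass
class SampleEntry:
    sample_id: str
    well: Well


@dataclass
class SampleSheet:
    entries: list[SampleEntry] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def wells(self) -> list[Well]:
        return [e.well for e in self.entries]

    def well_of(self, sample_id: str) -> Well:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e.well
        raise KeyError(sample_id)

    def validate(self, plate: AdapterPlate | None = None) -> None:
        ids = self.sample_ids
        if len(set(ids)) != len(ids):
            raise SampleSheetError("duplicate sample_id in sheet")
        wells = self.wells
        if len(set(wells)) != len(wells):
            raise SampleSheetError("duplicate well in sheet")
        if plate is not None:
            for e in self.entries:
                if e.well not in plate.wells:
                    raise SampleSheetError(f"sample {e.sample_id}: well {e.well.label} not on plate")


def sheet_for_samples(plate: AdapterPlate, sample_ids: list[str]) -> SampleSheet:
    """Convenience: assign samples to the plate's wells in row-major order."""
    wells = plate.sorted_wells()
    if len(sample_ids) > len(wells):
        raise SampleSheetError("more samples than plate wells")
    sheet = SampleSheet([SampleEntry(s, w) for s, w in zip(sample_ids, wells)])
    sheet.validate(plate)
    return sheet


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "row", "column"])
        for e in sheet.entries:
            w.writerow([e.sample_id, e.well.row, e.well.column])


def read_sample_sheet(path, plate: AdapterPlate | None = None) -> SampleSheet:
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < {"sample_id", "row", "column"}:
            raise SampleSheetError(f"{path}: header must be sample_id,row,column")
        for lineno, row in enumerate(reader, start=2):
            try:
                entries.append(SampleEntry(row["sample_id"], Well(row["row"].strip(), int(row["column"]))))
            except (ValueError, KeyError) as exc:
                raise SampleSheetError(f"{path}:{lineno}: {exc}") from exc
    sheet = SampleSheet(entries)
    try:
        sheet.validate(plate)
    except SampleSheetError as exc:
        raise SampleSheetError(f"{path}: {exc}") from exc
    return sheet


def write_plate_csv(plate: AdapterPlate, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# scheme={plate.scheme} umi_length={plate.umi_length} "
                 f"n_rows={plate.n_rows} n_cols={plate.n_cols}\n")
        w = csv.writer(fh)
        w.writerow(["row", "column", "i7", "i5"])
        for well in plate.sorted_wells():
            i7, i5 = plate.wells[well]
            w.writerow([well.row, well.column, i7, i5])


def read_plate_csv(path) -> AdapterPlate:
    with open(path, newline="") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise DesignError(f"{path}: missing '# scheme=...' header line")
        meta = dict(kv.split("=", 1) for kv in header[1:].split())
        reader = csv.DictReader(fh)
        wells = {}
        for row in reader:
            wells[Well(row["row"].strip(), int(row["column"]))] = (row["i7"], row["i5"])
    return AdapterPlate(
        meta["scheme"],
        wells,
        umi_length=int(meta.get("umi_length", 0)),
        n_rows=int(meta.get("n_rows", 8)),
        n_cols=int(meta.get("n_cols", 12)),
    )
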