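"""Synthetic multiplexed-library read simulator with recorded truth.

The generator emulates the processes that create index cross-talk in pooled
Illumina-style sequencing:

* adapter cross-contamination, either while adapters are single-stranded
  oligos (directional: only the leaked arm can swap) or after duplexing
  (both arms of the contaminating duplex enter the pool, so the i7- and
  i5-bearing arms of a fragment are drawn independently and both can come
  from the contaminant — this independence is what makes dual-matched
  misassignment scale as the square of the contamination level);
* index hopping in multiplexed capture pools (independent per-index swap to
  a uniformly chosen other pool member);
* per-base substitution errors on the index and UMI reads;
* PCR duplication with UMI tagging (each molecule's copies share its UMI,
  coordinates and adapter indices);
* low-allele-fraction spike-in variants;
* strand-asymmetric 8-oxoguanine damage: a damaged molecule carries one
  oxidized G (on either strand, i.e. at a reference G or C), and each PCR
  copy independently misreads it as the transversion allele (G>T / C>A).

Reads are stored column-wise (`ReadSet`) so multi-million-fragment runs are
cheap; per-read `ReadRecord` objects are materialized on demand.  Insert
bases are carried in reference orientation with 0-based coordinates —
alignment is simulated, not performed.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import DNA, decode_kmer, encode_kmer, phred_string, reverse_complement
from .plates import (
    DEFAULT_UMI_LENGTH,
    AdapterPlate,
    SampleSheet,
    Well,
    default_unique_dual_plate,
    sheet_for_samples,
)

OLIGO = "oligo"
DUPLEX = "duplex"

# event-tag bits; serialized names below
CONTAM_I7 = 0x01
CONTAM_I5 = 0x02
HOP_I7 = 0x04
HOP_I5 = 0x08
ERR_I7 = 0x10
ERR_I5 = 0x20
ERR_UMI = 0x40
OXO_MISREAD = 0x80

_TAG_NAMES = [
    (CONTAM_I7, "contaminated_i7_arm"),
    (CONTAM_I5, "contaminated_i5_arm"),
    (HOP_I7, "hopped_i7"),
    (HOP_I5, "hopped_i5"),
    (ERR_I7 | ERR_I5 | ERR_UMI, "index_seq_error"),
    (OXO_MISREAD, "oxo_misread"),
]


def tag_names(bits: int) -> frozenset[str]:
    return frozenset(name for mask, name in _TAG_NAMES if bits & mask)


class ConfigError(ValueError):
    """Raised on invalid simulation / run configuration."""


@dataclass(frozen=True)
class ContaminationEvent:
    """Adapter from ``source`` present in ``target``'s adapter pool at ``rate``.

    ``arm`` designates which strand's oligo leaked ('i7' or 'i5'); it is
    required at the oligo stage and must be absent at the duplex stage.
    """

    target: Well
    source: Well
    rate: float
    arm: str | None = None


@dataclass(frozen=True)
class Variant:
    position: int  # 0-based
    ref: str
    alt: str
    allele_fraction: float

    @property
    def is_oxoG_class(self) -> bool:
        return (self.ref, self.alt) in (("C", "A"), ("G", "T"))


@dataclass(frozen=True)
class FamilySizeSpec:
    """PCR duplicate family-size distribution (k >= 1 reads per molecule)."""

    name: str = "poisson_plus_one"
    param: float = 2.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.name == "degenerate":
            return np.full(n, int(self.param), dtype=np.int64)
        if self.name == "poisson_plus_one":
            return rng.poisson(self.param, n).astype(np.int64) + 1
        if self.name == "geometric_plus_one":
            # failures before first success, plus one => support {1, 2, ...}
            return rng.geometric(self.param, n).astype(np.int64)
        raise ConfigError(f"unknown family size distribution {self.name!r}")

    @property
    def mean(self) -> float:
        if self.name == "degenerate":
            return float(self.param)
        if self.name == "poisson_plus_one":
            return self.param + 1.0
        return 1.0 / self.param


@dataclass
class SimConfig:
    """All knobs of the simulator; every rate is a probability in [0, 1]."""

    n_fragments: int | dict[str, int] = 10_000
    contamination: tuple[ContaminationEvent, ...] = ()
    contamination_stage: str = DUPLEX
    hop_rate: float = 0.0
    index_error_rate: float = 0.0
    umi_length: int | None = None  # None -> take the plate's
    duplicate_family_size: FamilySizeSpec = field(
        default_factory=lambda: FamilySizeSpec("poisson_plus_one", 2.0)
    )
    reference_length: int = 1_000
    read_length: int = 100
    variants: tuple[Variant, ...] = ()
    oxo_damage_rate: float = 0.0
    oxo_misread_prob: float = 0.0
    insert_quality: int = 30
    mapping_quality: int = 60
    seed: int = 0

    def fragments_for(self, sample_id: str) -> int:
        if isinstance(self.n_fragments, dict):
            return int(self.n_fragments[sample_id])
        return int(self.n_fragments)

    def validate(self, plate: AdapterPlate | None = None) -> None:
        for name, rate in [
            ("hop_rate", self.hop_rate),
            ("oxo_damage_rate", self.oxo_damage_rate),
            ("oxo_misread_prob", self.oxo_misread_prob),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {rate}")
        if not 0.0 <= self.index_error_rate <= 0.25:
            raise ConfigError("index_error_rate must be in [0, 0.25]")
        if self.contamination_stage not in (OLIGO, DUPLEX):
            raise ConfigError(f"unknown contamination_stage {self.contamination_stage!r}")
        if self.read_length < 1 or self.read_length > self.reference_length:
            raise ConfigError("read_length must be in [1, reference_length]")
        budgets: dict[tuple, float] = {}
        for ev in self.contamination:
            if not 0.0 <= ev.rate <= 1.0:
                raise ConfigError(f"contamination rate {ev.rate} outside [0,1]")
            if self.contamination_stage == OLIGO:
                if ev.arm not in ("i7", "i5"):
                    raise ConfigError("oligo-stage contamination must designate arm 'i7' or 'i5'")
                keys = [(ev.target, ev.arm)]
            else:
                if ev.arm is not None:
                    raise ConfigError("duplex-stage contamination must not designate an arm")
                keys = [(ev.target, "i7"), (ev.target, "i5")]
            if plate is not None and (ev.source not in plate.wells or ev.target not in plate.wells):
                raise ConfigError(f"contamination wells {ev.source.label}->{ev.target.label} not on plate")
            for key in keys:
                budgets[key] = budgets.get(key, 0.0) + ev.rate
        for (well, arm), total in budgets.items():
            if total > 1.0:
                raise ConfigError(f"contamination rates for {well.label}/{arm} sum to {total} > 1")
        seen = set()
        for v in self.variants:
            if not 0 <= v.position < self.reference_length:
                raise ConfigError(f"variant position {v.position} outside reference")
            if v.ref == v.alt or v.ref not in DNA or v.alt not in DNA:
                raise ConfigError(f"invalid variant {v.ref}>{v.alt}")
            if not 0.0 <= v.allele_fraction <= 1.0:
                raise ConfigError("allele_fraction outside [0,1]")
            if v.position in seen:
                raise ConfigError(f"duplicate variant position {v.position}")
            seen.add(v.position)


@dataclass(frozen=True)
class Molecule:
    """One pre-PCR library molecule (scalar view; simulation is array-based)."""

    molecule_id: int
    true_sample: str
    ref_start: int
    length: int
    strand: str  # '+' or '-'
    umi: str
    i7_well: Well
    i5_well: Well
    variant_alleles: tuple[tuple[int, str], ...] = ()
    oxo_damaged_positions: frozenset[int] = frozenset()


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read; truth fields never feed demultiplexing."""

    read_id: str
    i7_obs: str
    i5_obs: str
    umi_obs: str
    insert_bases: str
    insert_quals: tuple[int, ...]
    ref_start: int
    strand: str
    mapq: int = 60
    true_sample: str | None = None
    molecule_id: int = -1
    event_tags: frozenset[str] = frozenset()

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.insert_quals)) if self.insert_quals else 0.0


class ReadSet:
    """Column-wise container of simulated (or loaded) reads.

    Observed index/UMI sequences live in a shared string pool (``index_pool``)
    addressed by integer codes; insert bases are reference slices plus a
    sparse per-read substitution map.
    """

    def __init__(
        self,
        index_pool: list[str],
        i7_code: np.ndarray,
        i5_code: np.ndarray,
        umi_rank: np.ndarray,
        umi_length: int,
        ref_start: np.ndarray,
        read_length: int,
        strand: np.ndarray,
        reference: str | None,
        subs: dict[int, tuple[tuple[int, str], ...]] | None = None,
        molecule_id: np.ndarray | None = None,
        true_sample: np.ndarray | None = None,
        sample_names: list[str] | None = None,
        event_tags: np.ndarray | None = None,
        true_i7_code: np.ndarray | None = None,
        true_i5_code: np.ndarray | None = None,
        mapq: int = 60,
        insert_quality: int = 30,
        explicit_bases: list[str] | None = None,
    ):
        n = len(i7_code)
        self.index_pool = index_pool
        self.i7_code = i7_code
        self.i5_code = i5_code
        self.umi_rank = umi_rank
        self.umi_length = umi_length
        self.ref_start = ref_start
        self.read_length = read_length
        self.strand = strand
        self.reference = reference
        self.subs = subs if subs is not None else {}
        self.molecule_id = molecule_id if molecule_id is not None else np.arange(n, dtype=np.int64)
        self.true_sample = true_sample if true_sample is not None else np.full(n, -1, np.int32)
        self.sample_names = sample_names or []
        self.event_tags = event_tags if event_tags is not None else np.zeros(n, np.uint16)
        self.true_i7_code = true_i7_code
        self.true_i5_code = true_i5_code
        self.mapq = mapq
        self.insert_quality = insert_quality
        self.explicit_bases = explicit_bases

    def __len__(self) -> int:
        return len(self.i7_code)

    @property
    def n(self) -> int:
        return len(self)

    # -- per-read materialization -------------------------------------------
    def read_id(self, i: int) -> str:
        return f"r{i:09d}"

    def i7_obs(self, i: int) -> str:
        return self.index_pool[self.i7_code[i]]

    def i5_obs(self, i: int) -> str:
        return self.index_pool[self.i5_code[i]]

    def umi_obs(self, i: int) -> str:
        if self.umi_length == 0 or self.umi_rank[i] < 0:
            return ""
        return decode_kmer(int(self.umi_rank[i]), self.umi_length)

    def insert_bases(self, i: int) -> str:
        if self.explicit_bases is not None:
            return self.explicit_bases[i]
        start = int(self.ref_start[i])
        bases = self.reference[start : start + self.read_length]
        if i in self.subs:
            chars = list(bases)
            for pos, alt in self.subs[i]:
                chars[pos - start] = alt
            bases = "".join(chars)
        return bases

    def i7_strings(self) -> np.ndarray:
        return np.asarray(self.index_pool, dtype=object)[self.i7_code]

    def i5_strings(self) -> np.ndarray:
        return np.asarray(self.index_pool, dtype=object)[self.i5_code]

    def record(self, i: int) -> ReadRecord:
        name = None
        if self.true_sample[i] >= 0 and self.sample_names:
            name = self.sample_names[self.true_sample[i]]
        return ReadRecord(
            read_id=self.read_id(i),
            i7_obs=self.i7_obs(i),
            i5_obs=self.i5_obs(i),
            umi_obs=self.umi_obs(i),
            insert_bases=self.insert_bases(i),
            insert_quals=tuple([self.insert_quality] * self.read_length),
            ref_start=int(self.ref_start[i]),
            strand="+" if self.strand[i] == 0 else "-",
            mapq=self.mapq,
            true_sample=name,
            molecule_id=int(self.molecule_id[i]),
            event_tags=tag_names(int(self.event_tags[i])),
        )

    def records(self):
        for i in range(len(self)):
            yield self.record(i)


@dataclass
class TruthTable:
    """Hidden truth of a simulation: per-read rows plus experiment summaries."""

    reads: ReadSet
    variants: tuple[Variant, ...]
    per_sample_fragments: dict[str, int]
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        rs = self.reads
        names = np.asarray(rs.sample_names + ["?"], dtype=object)
        tags = [
            ",".join(sorted(tag_names(int(t)))) if t else "."
            for t in rs.event_tags
        ]
        return pd.DataFrame(
            {
                "read_id": [rs.read_id(i) for i in range(len(rs))],
                "true_sample": names[rs.true_sample],
                "molecule_id": rs.molecule_id,
                "event_tags": tags,
                "ref_start": rs.ref_start,
                "strand": np.where(rs.strand == 0, "+", "-"),
                "umi": [rs.umi_obs(i) for i in range(len(rs))],
            }
        )


# ---------------------------------------------------------------------------
# mechanism primitives


def _categorical_sources(
    n: int, events: list[tuple[int, float]], rng: np.random.Generator
) -> np.ndarray:
    """Draw n arm sources: local index 0 = the sample's own adapter."""
    out = np.zeros(n, dtype=np.int32)
    if events:
        r = rng.random(n)
        cum = 0.0
        for src, rate in events:
            out[(r >= cum) & (r < cum + rate)] = src
            cum += rate
    return out


def _arm_codes(
    n: int,
    sample_well: Well,
    events: tuple[ContaminationEvent, ...],
    stage: str,
    rng: np.random.Generator,
) -> tuple[list[Well], np.ndarray, np.ndarray]:
    """Independent per-arm adapter-source draws for n fragments."""
    relevant = [ev for ev in events if ev.target == sample_well]
    wells: list[Well] = [sample_well]
    i7_events: list[tuple[int, float]] = []
    i5_events: list[tuple[int, float]] = []
    for ev in relevant:
        wells.append(ev.source)
        src = len(wells) - 1
        if stage == DUPLEX:
            i7_events.append((src, ev.rate))
            i5_events.append((src, ev.rate))
        elif ev.arm == "i7":
            i7_events.append((src, ev.rate))
        else:
            i5_events.append((src, ev.rate))
    i7_src = _categorical_sources(n, i7_events, rng)
    i5_src = _categorical_sources(n, i5_events, rng)
    return wells, i7_src, i5_src


def draw_adapter_arms(
    sample_well: Well,
    plate: AdapterPlate,
    contamination: tuple[ContaminationEvent, ...],
    contamination_stage: str,
    rng: np.random.Generator,
) -> tuple[Well, Well]:
    """Draw the source wells of one fragment's i7- and i5-bearing arms."""
    if sample_well not in plate.wells:
        raise ConfigError(f"{sample_well.label} not on plate")
    wells, i7_src, i5_src = _arm_codes(1, sample_well, tuple(contamination), contamination_stage, rng)
    return wells[int(i7_src[0])], wells[int(i5_src[0])]


def apply_index_hopping(
    reads: ReadSet,
    pool_wells: list[Well],
    plate: AdapterPlate,
    hop_rate: float,
    rng: np.random.Generator,
) -> ReadSet:
    """Independently swap each index to a uniformly chosen *other* pool well.

    Mutates ``reads`` in place and returns it.  Hop targets exclude the
    read's own sample well; a single-well pool is a no-op (with a warning).
    """
    if hop_rate == 0.0 or len(reads) == 0:
        return reads
    if len(pool_wells) < 2:
        warnings.warn("index hopping requested in a single-well pool; nothing to hop to")
        return reads
    pool_lookup = {s: i for i, s in enumerate(reads.index_pool)}
    i7_codes = np.array([pool_lookup[plate.i7_of(w)] for w in pool_wells], np.int32)
    i5_codes = np.array([pool_lookup[plate.i5_of(w)] for w in pool_wells], np.int32)
    # position of each read's true sample well within the pool (-1 if outside)
    well_pos = {w: i for i, w in enumerate(pool_wells)}
    sample_wells = getattr(reads, "_sample_wells", None)
    if sample_wells:
        sample_pos = np.array([well_pos.get(w, -1) for w in sample_wells], np.int64)
        own = np.where(reads.true_sample >= 0, sample_pos[np.clip(reads.true_sample, 0, None)], -1)
    else:
        own = np.full(len(reads), -1, np.int64)
    p = len(pool_wells)
    for code_arr, hop_bit in ((reads.i7_code, HOP_I7), (reads.i5_code, HOP_I5)):
        mask = rng.random(len(reads)) < hop_rate
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        j = rng.integers(0, p - 1, idx.size)
        own_i = own[idx]
        # reads whose own well is outside the pool hop uniformly over all wells
        tgt = np.where(own_i >= 0, j + (j >= own_i), rng.integers(0, p, idx.size))
        code_arr[idx] = (i7_codes if hop_bit == HOP_I7 else i5_codes)[tgt]
        reads.event_tags[idx] |= hop_bit
    return reads


def apply_index_sequencing_error(
    reads: ReadSet, error_rate: float, rng: np.random.Generator
) -> ReadSet:
    """Substitution-only sequencing error on i7, i5 and UMI bases (in place)."""
    if error_rate == 0.0 or len(reads) == 0:
        return reads
    if not 0.0 <= error_rate <= 0.25:
        raise ConfigError("index error rate must be in [0, 0.25]")
    pool = reads.index_pool
    pool_lookup = {s: i for i, s in enumerate(pool)}
    idx_len = len(pool[0]) if pool else 0

    for code_arr, err_bit in ((reads.i7_code, ERR_I7), (reads.i5_code, ERR_I5)):
        n_err = rng.binomial(idx_len, error_rate, len(reads))
        for row in np.nonzero(n_err)[0]:
            seq = list(pool[code_arr[row]])
            positions = rng.choice(idx_len, n_err[row], replace=False)
            for pos in positions:
                options = [b for b in DNA if b != seq[pos]]
                seq[pos] = options[rng.integers(0, 3)]
            new = "".join(seq)
            code = pool_lookup.get(new)
            if code is None:
                code = len(pool)
                pool.append(new)
                pool_lookup[new] = code
            code_arr[row] = code
            reads.event_tags[row] |= err_bit

    if reads.umi_length > 0:
        k = reads.umi_length
        n_err = rng.binomial(k, error_rate, len(reads))
        for row in np.nonzero(n_err)[0]:
            rank = int(reads.umi_rank[row])
            positions = rng.choice(k, n_err[row], replace=False)
            for pos in positions:
                shift = 2 * (k - 1 - pos)
                old = (rank >> shift) & 3
                new = (old + 1 + rng.integers(0, 3)) % 4
                rank += (int(new) - old) << shift
            reads.umi_rank[row] = rank
            reads.event_tags[row] |= ERR_UMI
    return reads


# ---------------------------------------------------------------------------
# molecule amplification


def _amplify_arrays(
    k: np.ndarray,
    mol_subs: dict[int, tuple[tuple[int, str], ...]],
    oxo_pos: np.ndarray,  # -1 = undamaged
    oxo_alt: np.ndarray,  # object array of alt bases ('' when undamaged)
    p_mis: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[int, tuple[tuple[int, str], ...]], np.ndarray]:
    """Expand molecules to reads: repeat index, read subs, oxo tags."""
    offsets = np.concatenate(([0], np.cumsum(k)))
    n_reads = int(offsets[-1])
    mol_of_read = np.repeat(np.arange(len(k)), k)
    read_subs: dict[int, tuple[tuple[int, str], ...]] = {}
    tags = np.zeros(n_reads, np.uint16)
    for mol, subs in mol_subs.items():
        for row in range(offsets[mol], offsets[mol + 1]):
            read_subs[row] = subs
    damaged = np.nonzero(oxo_pos >= 0)[0]
    for mol in damaged:
        pos = int(oxo_pos[mol])
        alt = oxo_alt[mol]
        for row in range(offsets[mol], offsets[mol + 1]):
            if rng.random() < p_mis:
                read_subs[row] = read_subs.get(row, ()) + ((pos, alt),)
                tags[row] |= OXO_MISREAD
    return mol_of_read, read_subs, tags


def amplify_with_umi(
    molecules: list[Molecule],
    duplicate_family_size: FamilySizeSpec,
    oxo_misread_prob: float,
    plate: AdapterPlate,
    reference: str,
    rng: np.random.Generator,
    insert_quality: int = 30,
    mapping_quality: int = 60,
) -> ReadSet:
    """Emit k >= 1 reads per molecule; copies share UMI, coordinates, indices."""
    n = len(molecules)
    read_length = molecules[0].length if molecules else 0
    umi_length = len(molecules[0].umi) if molecules else 0
    k = duplicate_family_size.sample(rng, n)
    mol_subs = {i: m.variant_alleles for i, m in enumerate(molecules) if m.variant_alleles}
    oxo_pos = np.full(n, -1, np.int64)
    oxo_alt = np.empty(n, object)
    oxo_alt[:] = ""
    for i, m in enumerate(molecules):
        if m.oxo_damaged_positions:
            pos = min(m.oxo_damaged_positions)
            oxo_pos[i] = pos
            oxo_alt[i] = "T" if reference[pos] == "G" else "A"
    mol_of_read, read_subs, tags = _amplify_arrays(k, mol_subs, oxo_pos, oxo_alt, oxo_misread_prob, rng)

    index_pool = plate.all_index_sequences()
    pool_lookup = {s: i for i, s in enumerate(index_pool)}
    i7 = np.array([pool_lookup[plate.i7_of(m.i7_well)] for m in molecules], np.int32)
    i5 = np.array([pool_lookup[plate.i5_of(m.i5_well)] for m in molecules], np.int32)
    umi = np.array([encode_kmer(m.umi) if m.umi else -1 for m in molecules], np.int64)
    start = np.array([m.ref_start for m in molecules], np.int64)
    strand = np.array([0 if m.strand == "+" else 1 for m in molecules], np.uint8)
    mol_ids = np.array([m.molecule_id for m in molecules], np.int64)
    return ReadSet(
        index_pool=index_pool,
        i7_code=i7[mol_of_read],
        i5_code=i5[mol_of_read],
        umi_rank=umi[mol_of_read],
        umi_length=umi_length,
        ref_start=start[mol_of_read],
        read_length=read_length,
        strand=strand[mol_of_read],
        reference=reference,
        subs=read_subs,
        molecule_id=mol_ids[mol_of_read],
        event_tags=tags,
        true_i7_code=i7[mol_of_read].copy(),
        true_i5_code=i5[mol_of_read].copy(),
        mapq=mapping_quality,
        insert_quality=insert_quality,
    )


# ---------------------------------------------------------------------------
# full experiment


def _make_reference(config: SimConfig, rng: np.random.Generator) -> str:
    codes = rng.integers(0, 4, config.reference_length)
    chars = np.array(list(DNA))[codes]
    for v in config.variants:
        chars[v.position] = v.ref
    return "".join(chars)


def simulate_experiment(
    plate: AdapterPlate, sheet: SampleSheet, config: SimConfig
) -> tuple[ReadSet, TruthTable]:
    """Run the whole generative pipeline; deterministic given ``config.seed``.

    Per-molecule order: reference draw -> variant allele assignment -> oxoG
    damage -> adapter-arm draw -> UMI assignment -> amplification -> index
    hopping -> index sequencing error.
    """
    config.validate(plate)
    sheet.validate(plate)
    rng = np.random.default_rng(config.seed)
    reference = _make_reference(config, rng)
    ref_codes = np.frombuffer(reference.encode(), np.uint8)
    gc_positions = np.nonzero((ref_codes == ord("G")) | (ref_codes == ord("C")))[0]
    umi_length = plate.umi_length if config.umi_length is None else config.umi_length
    L = config.read_length

    index_pool = plate.all_index_sequences()
    pool_lookup = {s: i for i, s in enumerate(index_pool)}
    sample_names = [e.sample_id for e in sheet.entries]

    cols: dict[str, list[np.ndarray]] = {
        k: [] for k in ("i7", "i5", "umi", "start", "strand", "mol", "sample", "tags", "ti7", "ti5")
    }
    all_subs: dict[int, tuple[tuple[int, str], ...]] = {}
    per_sample_fragments: dict[str, int] = {}
    mol_base = 0
    row_base = 0

    for s_idx, entry in enumerate(sheet.entries):
        n = config.fragments_for(entry.sample_id)
        per_sample_fragments[entry.sample_id] = n
        start = rng.integers(0, config.reference_length - L + 1, n)
        strand = rng.integers(0, 2, n).astype(np.uint8)

        mol_subs: dict[int, tuple[tuple[int, str], ...]] = {}
        for v in config.variants:
            covered = (start <= v.position) & (v.position < start + L)
            carrier = covered & (rng.random(n) < v.allele_fraction)
            for i in np.nonzero(carrier)[0]:
                mol_subs[i] = mol_subs.get(i, ()) + ((v.position, v.alt),)

        oxo_pos = np.full(n, -1, np.int64)
        oxo_alt = np.empty(n, object)
        oxo_alt[:] = ""
        if config.oxo_damage_rate > 0:
            damaged = np.nonzero(rng.random(n) < config.oxo_damage_rate)[0]
            for i in damaged:
                lo = np.searchsorted(gc_positions, start[i])
                hi = np.searchsorted(gc_positions, start[i] + L)
                if hi > lo:
                    pos = int(gc_positions[rng.integers(lo, hi)])
                    oxo_pos[i] = pos
                    oxo_alt[i] = "T" if reference[pos] == "G" else "A"

        arm_wells, i7_src, i5_src = _arm_codes(
            n, entry.well, config.contamination, config.contamination_stage, rng
        )
        arm_i7_codes = np.array([pool_lookup[plate.i7_of(w)] for w in arm_wells], np.int32)
        arm_i5_codes = np.array([pool_lookup[plate.i5_of(w)] for w in arm_wells], np.int32)
        mol_i7 = arm_i7_codes[i7_src]
        mol_i5 = arm_i5_codes[i5_src]
        mol_tags = np.zeros(n, np.uint16)
        mol_tags[i7_src != 0] |= CONTAM_I7
        mol_tags[i5_src != 0] |= CONTAM_I5

        umi = (
            rng.integers(0, 4**umi_length, n, dtype=np.int64)
            if umi_length > 0
            else np.full(n, -1, np.int64)
        )

        k = config.duplicate_family_size.sample(rng, n)
        mol_of_read, read_subs, read_tags = _amplify_arrays(
            k, mol_subs, oxo_pos, oxo_alt, config.oxo_misread_prob, rng
        )
        read_tags |= mol_tags[mol_of_read]

        cols["i7"].append(mol_i7[mol_of_read])
        cols["i5"].append(mol_i5[mol_of_read])
        cols["ti7"].append(np.full(len(mol_of_read), pool_lookup[plate.i7_of(entry.well)], np.int32))
        cols["ti5"].append(np.full(len(mol_of_read), pool_lookup[plate.i5_of(entry.well)], np.int32))
        cols["umi"].append(umi[mol_of_read])
        cols["start"].append(start[mol_of_read])
        cols["strand"].append(strand[mol_of_read])
        cols["mol"].append(mol_of_read + mol_base)
        cols["sample"].append(np.full(len(mol_of_read), s_idx, np.int32))
        cols["tags"].append(read_tags)
        for row, subs in read_subs.items():
            all_subs[row + row_base] = subs
        mol_base += n
        row_base += len(mol_of_read)

    reads = ReadSet(
        index_pool=index_pool,
        i7_code=np.concatenate(cols["i7"]).astype(np.int32),
        i5_code=np.concatenate(cols["i5"]).astype(np.int32),
        umi_rank=np.concatenate(cols["umi"]),
        umi_length=umi_length,
        ref_start=np.concatenate(cols["start"]),
        read_length=L,
        strand=np.concatenate(cols["strand"]),
        reference=reference,
        subs=all_subs,
        molecule_id=np.concatenate(cols["mol"]),
        true_sample=np.concatenate(cols["sample"]),
        sample_names=sample_names,
        event_tags=np.concatenate(cols["tags"]),
        true_i7_code=np.concatenate(cols["ti7"]),
        true_i5_code=np.concatenate(cols["ti5"]),
        mapq=config.mapping_quality,
        insert_quality=config.insert_quality,
    )
    reads._sample_wells = [e.well for e in sheet.entries]

    if config.hop_rate > 0 and len(sheet.entries) > 1:
        apply_index_hopping(reads, [e.well for e in sheet.entries], plate, config.hop_rate, rng)
    elif config.hop_rate > 0:
        warnings.warn("hop_rate > 0 in a single-plex pool; no hopping possible")
    apply_index_sequencing_error(reads, config.index_error_rate, rng)

    truth = TruthTable(reads, config.variants, per_sample_fragments, config.seed)
    return reads, truth


# ---------------------------------------------------------------------------
# file I/O


def _open_out(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def write_fastq(reads: ReadSet, out_prefix: str, compress: bool = False) -> list[str]:
    """Write the four-file FASTQ set (R1/R2 insert, I1 = i7[+UMI], I2 = i5)."""
    ext = ".fastq.gz" if compress else ".fastq"
    paths = [f"{out_prefix}_{tag}{ext}" for tag in ("R1", "R2", "I1", "I2")]
    qual_insert = phred_string(reads.insert_quality, reads.read_length)
    idx_len = len(reads.index_pool[0]) if reads.index_pool else 0
    qual_i1 = phred_string(reads.insert_quality, idx_len + reads.umi_length)
    qual_i2 = phred_string(reads.insert_quality, idx_len)
    with _open_out(paths[0]) as r1, _open_out(paths[1]) as r2, \
         _open_out(paths[2]) as i1, _open_out(paths[3]) as i2:
        for i in range(len(reads)):
            rid = reads.read_id(i)
            bases = reads.insert_bases(i)
            i1_seq = reads.i7_obs(i) + reads.umi_obs(i)
            r1.write(f"@{rid}\n{bases}\n+\n{qual_insert}\n")
            r2.write(f"@{rid}\n{reverse_complement(bases)}\n+\n{qual_insert}\n")
            i1.write(f"@{rid}\n{i1_seq}\n+\n{qual_i1}\n")
            i2.write(f"@{rid}\n{reads.i5_obs(i)}\n+\n{qual_i2}\n")
    return paths


def read_fastq_set(paths_or_prefix, index_length: int, umi_length: int = 0) -> ReadSet:
    """Load a four-file FASTQ set into a ReadSet (observed fields only).

    ``paths_or_prefix`` is either the simulator's output prefix or an
    explicit (R1, R2, I1, I2) path tuple.  The trailing ``umi_length`` bases
    of I1 are split off as the UMI.
    """
    import os

    import pysam

    if isinstance(paths_or_prefix, (list, tuple)):
        p_r1, _, p_i1, p_i2 = paths_or_prefix
    else:
        pref = str(paths_or_prefix)
        ext = ".fastq" if os.path.exists(pref + "_R1.fastq") else ".fastq.gz"
        p_r1, p_i1, p_i2 = (pref + s + ext for s in ("_R1", "_I1", "_I2"))

    bases: list[str] = []
    ids: list[str] = []
    i7s: list[str] = []
    i5s: list[str] = []
    umis: list[int] = []
    with pysam.FastxFile(str(p_r1)) as r1, pysam.FastxFile(str(p_i1)) as i1, \
         pysam.FastxFile(str(p_i2)) as i2:
        for rec1, rec_i1, rec_i2 in zip(r1, i1, i2):
            if not (rec1.name == rec_i1.name == rec_i2.name):
                raise ValueError(f"read id mismatch across FASTQ files at {rec1.name}")
            ids.append(rec1.name)
            bases.append(rec1.sequence)
            i7s.append(rec_i1.sequence[:index_length])
            umi = rec_i1.sequence[index_length : index_length + umi_length]
            umis.append(encode_kmer(umi) if umi and "N" not in umi else -1)
            i5s.append(rec_i2.sequence)
    pool: list[str] = []
    lookup: dict[str, int] = {}

    def code_of(s: str) -> int:
        c = lookup.get(s)
        if c is None:
            c = len(pool)
            pool.append(s)
            lookup[s] = c
        return c

    n = len(ids)
    read_length = len(bases[0]) if bases else 0
    rs = ReadSet(
        index_pool=pool,
        i7_code=np.array([code_of(s) for s in i7s], np.int32),
        i5_code=np.array([code_of(s) for s in i5s], np.int32),
        umi_rank=np.array(umis, np.int64),
        umi_length=umi_length,
        ref_start=np.zeros(n, np.int64),
        read_length=read_length,
        strand=np.zeros(n, np.uint8),
        reference=None,
        explicit_bases=bases,
    )
    rs._read_ids = ids
    return rs


def write_truth_tsv(truth: TruthTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={truth.seed}\n")
        truth.to_dataframe().to_csv(fh, sep="\t", index=False)


def write_reads_tsv(reads: ReadSet, path) -> None:
    """The simulator's 'aligned read' table consumed by the consensus stage."""
    with open(path, "w") as fh:
        fh.write("read_id\ti7_obs\ti5_obs\tumi_obs\tref_start\tstrand\tmapq\tbases\n")
        for i in range(len(reads)):
            fh.write(
                f"{reads.read_id(i)}\t{reads.i7_obs(i)}\t{reads.i5_obs(i)}\t"
                f"{reads.umi_obs(i)}\t{reads.ref_start[i]}\t"
                f"{'+' if reads.strand[i] == 0 else '-'}\t{reads.mapq}\t{reads.insert_bases(i)}\n"
            )


def read_reads_tsv(path, insert_quality: int = 30) -> list[ReadRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"umi_obs": str}, keep_default_na=False)
    return [
        ReadRecord(
            read_id=row.read_id,
            i7_obs=row.i7_obs,
            i5_obs=row.i5_obs,
            umi_obs=row.umi_obs,
            insert_bases=row.bases,
            insert_quals=tuple([insert_quality] * len(row.bases)),
            ref_start=int(row.ref_start),
            strand=row.strand,
            mapq=int(row.mapq),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# study presets


def lowfreq_benchmark(
    seed: int = 0,
    n_molecules: int = 25_000,
    reference_length: int = 5_000,
    read_length: int = 100,
) -> tuple[AdapterPlate, SampleSheet, SimConfig]:
    """Preset for the low-frequency variant / oxoG consensus experiment.

    One unique dual-matched sample, UMI-tagged, mean family size 4
    (Poisson(3)+1), spike-in variants at 1% and 0.5% allele fraction, and
    oxoG damage (2% of molecules, misread probability 0.5 per copy).  At the
    default molecule count the raw-read depth is ~2000x over a 5 kb
    reference, echoing a deep targeted panel.
    """
    plate = default_unique_dual_plate(n=4, seed=7)
    sheet = sheet_for_samples(plate, ["S1"])
    one_pct = [("A", "G"), ("T", "C"), ("C", "T"), ("G", "A"), ("C", "G"), ("A", "T")]
    half_pct = [
        ("T", "A"), ("G", "C"), ("A", "C"), ("T", "G"), ("C", "T"), ("G", "A"),
        ("A", "G"), ("T", "C"), ("C", "A"), ("G", "T"),  # last two are oxoG-class truths
    ]
    variants = tuple(
        [Variant(int((0.05 + 0.13 * i) * reference_length), r, a, 0.01)
         for i, (r, a) in enumerate(one_pct)]
        + [Variant(int((0.086 + 0.09 * i) * reference_length), r, a, 0.005)
           for i, (r, a) in enumerate(half_pct)]
    )
    config = SimConfig(
        n_fragments=n_molecules,
        umi_length=DEFAULT_UMI_LENGTH,
        duplicate_family_size=FamilySizeSpec("poisson_plus_one", 3.0),
        reference_length=reference_length,
        read_length=read_length,
        variants=variants,
        oxo_damage_rate=0.02,
        oxo_misread_prob=0.5,
        seed=seed,
    )
    return plate, sheet, config
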