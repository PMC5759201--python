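"""Pileup-based low-allele-fraction variant calling and truth evaluation.

The caller applies a global allele-fraction threshold (default 0.2%) and a
stricter mutation-specific threshold (default 0.3%) for C>A / G>T
substitutions, the signature of 8-oxoguanine damage.  It is a deliberately
simple pileup caller: coordinates are 0-based internally and converted to
1-based only at the output boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import seq_to_codes
from .simulate import Variant

_BASES = "ACGT"
OXO_PAIRS = {("C", "A"), ("G", "T")}


@dataclass
class Pileup:
    """Per-position A/C/G/T/N counts over a reference."""

    counts: np.ndarray  # (5, L)
    reference: str

    @property
    def depth(self) -> np.ndarray:
        """Non-N depth per position."""
        return self.counts[:4].sum(axis=0)

    def base_count(self, position: int, base: str) -> int:
        return int(self.counts[_BASES.index(base), position])


def build_pileup(records, reference: str) -> Pileup:
    """Stack read (or consensus) bases into per-position counts.

    ``records`` need only carry ``ref_start`` and ``insert_bases``; N bases
    are tallied but excluded from depth.
    """
    L = len(reference)
    counts = np.zeros((5, L), np.int64)
    for rec in records:
        start = rec.ref_start
        bases = rec.insert_bases
        end = start + len(bases)
        if start < 0 or end > L:
            raise ValueError(f"record at {start}..{end} exceeds reference bounds (0..{L})")
        codes = seq_to_codes(bases)
        np.add.at(counts, (codes, np.arange(start, end)), 1)
    return Pileup(counts, reference)


@dataclass
class VariantCall:
    position: int  # 0-based
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int
    allele_fraction: float
    is_oxoG_class: bool
    called: bool
    filter: str  # PASS | below_threshold | oxoG_threshold


def call_variants(
    pileup: Pileup,
    reference: str | None = None,
    threshold: float = 0.002,
    oxoG_threshold: float = 0.003,
    min_depth: int = 100,
) -> list[VariantCall]:
    """Emit a VariantCall for every non-reference base seen at adequate depth.

    A call passes when its allele fraction reaches ``threshold``, except that
    C>A and G>T substitutions must reach ``oxoG_threshold``.
    """
    if not 0.0 < threshold < 1.0 or not 0.0 < oxoG_threshold < 1.0:
        raise ValueError("thresholds must be in (0, 1)")
    if oxoG_threshold < threshold:
        raise ValueError("oxoG_threshold must be >= threshold")
    reference = reference if reference is not None else pileup.reference
    depth = pileup.depth
    calls: list[VariantCall] = []
    candidates = np.nonzero(depth >= min_depth)[0]
    ref_codes = seq_to_codes(reference)
    for pos in candidates:
        ref_base = reference[pos]
        for alt_code, alt_base in enumerate(_BASES):
            if alt_code == ref_codes[pos]:
                continue
            alt_count = int(pileup.counts[alt_code, pos])
            if alt_count < 1:
                continue
            af = alt_count / depth[pos]
            oxo = (ref_base, alt_base) in OXO_PAIRS
            cutoff = oxoG_threshold if oxo else threshold
            called = af >= cutoff
            if called:
                filt = "PASS"
            elif oxo and af >= threshold:
                filt = "oxoG_threshold"
            else:
                filt = "below_threshold"
            calls.append(
                VariantCall(int(pos), ref_base, alt_base, alt_count, int(depth[pos]),
                            af, oxo, called, filt)
            )
    return calls


@dataclass
class StratumResult:
    label: str
    tp: int
    fn: int
    fp: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def ppv(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None


@dataclass
class EvalReport:
    strata: list[StratumResult]
    overall: StratumResult

    def to_dict(self) -> dict:
        def one(s: StratumResult) -> dict:
            return dict(tp=s.tp, fn=s.fn, fp=s.fp,
                        sensitivity=s.sensitivity,
                        ppv=s.ppv if s.ppv is not None else None)

        return {"overall": one(self.overall),
                "strata": {s.label: one(s) for s in self.strata}}


DEFAULT_STRATA: tuple[tuple[str, float, float], ...] = (
    ("0.5%", 0.0, 0.0075),
    ("1%", 0.0075, 0.02),
    (">1%", 0.02, 1.01),
)


def evaluate_calls(
    calls: list[VariantCall],
    truth_variants: list[Variant],
    strata: tuple[tuple[str, float, float], ...] = DEFAULT_STRATA,
) -> EvalReport:
    """Sensitivity / PPV against simulation truth, stratified by allele fraction.

    Matching is exact on (position, ref, alt).  True/false positives are
    stratified by the truth's expected AF when matched and by the observed AF
    otherwise; PPV with zero positive calls is reported as None (NA).
    """
    truth_lookup = {(v.position, v.ref, v.alt): v for v in truth_variants}
    called = [c for c in calls if c.called]
    called_keys = {(c.position, c.ref_base, c.alt_base) for c in called}

    def stratum_of(af: float) -> str | None:
        for label, lo, hi in strata:
            if lo <= af < hi:
                return label
        return None

    results = {label: StratumResult(label, 0, 0, 0) for label, _, _ in strata}
    overall = StratumResult("overall", 0, 0, 0)
    for c in called:
        key = (c.position, c.ref_base, c.alt_base)
        if key in truth_lookup:
            overall.tp += 1
            lab = stratum_of(truth_lookup[key].allele_fraction)
            if lab:
                results[lab].tp += 1
        else:
            overall.fp += 1
            lab = stratum_of(c.allele_fraction)
            if lab:
                results[lab].fp += 1
    for key, v in truth_lookup.items():
        if key not in called_keys:
            overall.fn += 1
            lab = stratum_of(v.allele_fraction)
            if lab:
                results[lab].fn += 1
    return EvalReport([results[label] for label, _, _ in strata], overall)


def write_variants_tsv(calls: list[VariantCall], path, chrom: str = "ref") -> None:
    """Tab-separated variant table; POS is 1-based in the output only."""
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\tDP\tAD\tAF\tFILTER\n")
        for c in calls:
            fh.write(
                f"{chrom}\t{c.position + 1}\t{c.ref_base}\t{c.alt_base}\t"
                f"{c.depth}\t{c.alt_count}\t{c.allele_fraction:.6g}\t{c.filter}\n"
            )


def read_variants_tsv(path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        oxo = (row.REF, row.ALT) in OXO_PAIRS
        out.append(VariantCall(int(row.POS) - 1, row.REF, row.ALT, int(row.AD),
                               int(row.DP), float(row.AF), oxo, row.FILTER == "PASS",
                               row.FILTER))
    return out


def write_eval_json(report: EvalReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
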