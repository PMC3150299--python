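"""Microsatellite (SSR) discovery and inter-source repeat polymorphism.

The scanner reports maximal perfect tandem repeats of primitive 2-10 bp
motifs at configurable unit thresholds (defaults: dinucleotides at 7
units, tri- through octanucleotides at 5, nona- and decanucleotides at
4).  Homopolymer runs are suppressed by default.  Two repeats separated
by at most ``max_interruption`` bp are additionally recorded as one
compound SSR.

Polymorphic SSRs between the two DNA sources are found by scanning each
source's consensus, pairing loci by exact flanking-sequence anchors, and
comparing repeat unit counts (or detecting an indel within the repeat
span).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from estpoly.alnio import BASES, Pileup, revcomp

#: IUPAC codes for the modal-base ties a consensus can produce.
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}

#: unit thresholds per motif length: di=7, tri..octa=5, nona/deca=4
DEFAULT_MIN_UNITS = {2: 7, 3: 5, 4: 5, 5: 5, 6: 5, 7: 5, 8: 5, 9: 4, 10: 4}


@dataclass(frozen=True)
class SsrThresholds:
    min_units: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_UNITS))
    max_interruption: int = 100
    report_homopolymers: bool = False

    def __post_init__(self):
        for k, u in self.min_units.items():
            if not 1 <= k <= 10:
                raise ValueError("motif lengths must be 1-10")
            if u < 2:
                raise ValueError("min_units must be >= 2")


@dataclass(frozen=True)
class SsrLocus:
    """A perfect tandem repeat: ``span`` is 0-based half-open and covers
    exactly ``units`` complete copies of ``motif``."""

    contig: str
    span: tuple[int, int]
    motif: str
    canonical_class: str
    units: int
    compound: bool = False


@dataclass(frozen=True)
class CompoundSsr:
    """Two or more SSRs within ``max_interruption`` bp of each other."""

    contig: str
    span: tuple[int, int]
    components: tuple[SsrLocus, ...]


@dataclass(frozen=True)
class PolymorphicSsr:
    contig: str
    span: tuple[int, int]          # span in the source-A consensus
    motif: str
    units_a: int
    units_b: int
    difference_type: str           # "unit-count" | "internal-indel"


@dataclass(frozen=True)
class UnresolvedSsr:
    """An SSR whose flank anchor could not be placed in the other source."""

    contig: str
    span: tuple[int, int]
    motif: str
    found_in: str


def is_primitive(motif: str) -> bool:
    """True unless the motif is itself a repetition of a shorter motif."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical class label of a motif: the lexicographically smallest
    cyclic rotation of the motif or of its reverse complement, rendered
    as ``X/revcomp(X)`` (e.g. GT -> AC/GT, GGT -> ACC/GGT)."""
    if set(motif) - set(BASES):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    rc = revcomp(motif)
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    rep = min(rotations)
    return f"{rep}/{revcomp(rep)}"


def find_ssrs(sequence: str, contig: str = "seq",
              thresholds: SsrThresholds = SsrThresholds()) -> list[SsrLocus]:
    """All maximal perfect SSRs in one sequence.

    For each motif length k the sequence is scanned for maximal runs in
    which every base equals the base k positions earlier; a run of r
    matching positions carries floor(r/k + 1) complete units anchored at
    the run's left end.  Non-primitive motifs are skipped (their runs
    are reported at the shorter period), as are homopolymers unless
    enabled.  Compound labelling is applied afterwards.
    """
    loci: list[SsrLocus] = []
    n = len(sequence)
    ks = sorted(k for k in thresholds.min_units if k >= 2)
    if thresholds.report_homopolymers:
        ks = [1] + ks
    min_units = dict(thresholds.min_units)
    min_units.setdefault(1, 10)   # MISA-like mononucleotide threshold
    for k in ks:
        if n < 2 * k:
            continue
        j = k
        while j < n:
            if sequence[j] != sequence[j - k] or sequence[j] == "N":
                j += 1
                continue
            run_start = j
            while j < n and sequence[j] == sequence[j - k] and sequence[j] != "N":
                j += 1
            start = run_start - k
            units = (j - start) // k
            if units < min_units[k]:
                continue
            motif = sequence[start:start + k]
            if not is_primitive(motif):
                continue
            if len(set(motif)) == 1 and not thresholds.report_homopolymers:
                continue
            loci.append(SsrLocus(
                contig=contig, span=(start, start + units * k), motif=motif,
                canonical_class=canonical_motif(motif), units=units))
    loci.sort(key=lambda s: (s.span, len(s.motif)))
    compounds = find_compound_ssrs(loci, thresholds.max_interruption)
    in_compound = {s.span for comp in compounds for s in comp.components}
    return [SsrLocus(s.contig, s.span, s.motif, s.canonical_class, s.units,
                     compound=s.span in in_compound) for s in loci]


def find_compound_ssrs(loci: Sequence[SsrLocus],
                       max_interruption: int = 100) -> list[CompoundSsr]:
    """Chain SSRs on the same contig whose gaps are <= max_interruption bp."""
    compounds: list[CompoundSsr] = []
    by_contig: dict[str, list[SsrLocus]] = {}
    for s in sorted(loci, key=lambda s: (s.contig, s.span)):
        by_contig.setdefault(s.contig, []).append(s)
    for contig, group in by_contig.items():
        chain = [group[0]]
        for s in group[1:]:
            if s.span[0] - chain[-1].span[1] <= max_interruption:
                chain.append(s)
            else:
                if len(chain) > 1:
                    compounds.append(CompoundSsr(
                        contig, (chain[0].span[0], chain[-1].span[1]), tuple(chain)))
                chain = [s]
        if len(chain) > 1:
            compounds.append(CompoundSsr(
                contig, (chain[0].span[0], chain[-1].span[1]), tuple(chain)))
    return compounds


# ---------------------------------------------------------------------------
# Per-source consensus
# ---------------------------------------------------------------------------

def source_consensus(pileup: Pileup, source: str, contig: str) -> str:
    """Modal-base consensus of one source's reads over a contig: ties
    yield the IUPAC ambiguity code for the tied bases, uncovered
    positions yield N."""
    c = pileup.counts(contig, source)[:, :4]
    depth = c.sum(axis=1)
    out = []
    for pos in range(len(depth)):
        if depth[pos] == 0:
            out.append("N")
            continue
        row = c[pos]
        m = row.max()
        tied = frozenset(BASES[i] for i in range(4) if row[i] == m)
        out.append(_IUPAC[tied])
    return "".join(out)


# ---------------------------------------------------------------------------
# Inter-source comparison
# ---------------------------------------------------------------------------

def _count_units_at(seq: str, pos: int, motif: str) -> tuple[int, int]:
    """Complete copies of ``motif`` in ``seq`` around ``pos``: extends
    left and right from the anchored start.  Returns (start, units)."""
    k = len(motif)
    start = pos
    while start - k >= 0 and seq[start - k:start] == motif:
        start -= k
    units = 0
    while seq[start + units * k: start + (units + 1) * k] == motif:
        units += 1
    return start, units


def compare_ssrs_between_sources(consensus_a: str, consensus_b: str,
                                 contig: str = "seq",
                                 thresholds: SsrThresholds = SsrThresholds(),
                                 flank: int = 20
                                 ) -> tuple[list[PolymorphicSsr], list[UnresolvedSsr]]:
    """Pair SSRs between the two source consensuses of one contig and
    report inter-source repeat differences.

    An SSR found in either consensus is anchored in the other via its
    left flank (``flank`` bp of exact sequence immediately 5' of the
    repeat, required to occur exactly once); the unit count of the same
    motif at the anchored location is then compared.  Differing counts
    give a unit-count polymorphism; equal counts with a length change
    between the flanking anchors give an internal indel.  SSRs whose
    anchor cannot be placed are returned as unresolved, never as
    polymorphic.
    """
    found = {"A": find_ssrs(consensus_a, contig, thresholds),
             "B": find_ssrs(consensus_b, contig, thresholds)}
    seqs = {"A": consensus_a, "B": consensus_b}
    polymorphic: list[PolymorphicSsr] = []
    unresolved: list[UnresolvedSsr] = []
    claimed: set[tuple[str, int]] = set()   # (motif canonical, start-in-A)

    for src, other in (("A", "B"), ("B", "A")):
        for ssr in found[src]:
            start, end = ssr.span
            if start < flank:
                unresolved.append(UnresolvedSsr(contig, ssr.span, ssr.motif, src))
                continue
            left = seqs[src][start - flank:start]
            hit = seqs[other].find(left)
            if hit < 0 or seqs[other].find(left, hit + 1) >= 0:
                unresolved.append(UnresolvedSsr(contig, ssr.span, ssr.motif, src))
                continue
            anchor = hit + flank
            o_start, o_units = _count_units_at(seqs[other], anchor, ssr.motif)
            units = {src: ssr.units, other: o_units}
            span_a = ssr.span if src == "A" else (o_start, o_start + units["A"] * len(ssr.motif))
            key = (ssr.canonical_class, span_a[0])
            if key in claimed:
                continue
            claimed.add(key)
            if units["A"] != units["B"]:
                polymorphic.append(PolymorphicSsr(
                    contig, span_a, ssr.motif, units["A"], units["B"],
                    "unit-count"))
                continue
            # equal unit counts: look for an indel between the flank
            # anchors by comparing right-flank positions
            right = seqs[src][end:end + flank]
            if len(right) == flank:
                o_end_expected = o_start + o_units * len(ssr.motif)
                rhit = seqs[other].find(right, o_start)
                if rhit >= 0 and rhit != o_end_expected:
                    polymorphic.append(PolymorphicSsr(
                        contig, span_a, ssr.motif, units["A"], units["B"],
                        "internal-indel"))
    return polymorphic, unresolved


# ---------------------------------------------------------------------------
# Frequency matrix
# ---------------------------------------------------------------------------

_LENGTH_LABELS = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
_UNIT_COLUMNS = ("5", "6", "7", "8", "9", ">=10")


def _length_label(k: int) -> str:
    return _LENGTH_LABELS.get(k, ">=hepta")


def _unit_column(units: int) -> str:
    return str(units) if units < 10 else ">=10"


def summarize_ssrs(loci_per_source: Mapping[str, Sequence[SsrLocus]]
                   ) -> pd.DataFrame:
    """Frequency matrix of repeat type by repeat number, per source.

    Rows are motif lengths (di ... >=hepta), columns unit counts
    (5, 6, 7, 8, 9, >=10) with per-source totals; a second level of
    per-source percentage rows accompanies the totals.
    """
    rows = ["di", "tri", "tetra", "penta", "hexa", ">=hepta"]
    data: dict[tuple[str, str], dict[str, int]] = {}
    for source, loci in loci_per_source.items():
        counts = Counter((_length_label(len(s.motif)), _unit_column(s.units))
                         for s in loci)
        for col in _UNIT_COLUMNS:
            data[(source, col)] = {row: counts.get((row, col), 0) for row in rows}
    df = pd.DataFrame(data)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["source", "units"])
    df = df.reindex(rows)
    for source in loci_per_source:
        df[(source, "total")] = df[source].sum(axis=1)
    return df.sort_index(axis=1)


def summarize_motif_classes(loci: Sequence[SsrLocus]) -> dict[str, int]:
    """Counts per canonical motif class (AC/GT style labels)."""
    return dict(Counter(s.canonical_class for s in loci).most_common())
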