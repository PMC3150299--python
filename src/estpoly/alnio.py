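"""Alignment-layer I/O.

FASTA reading/writing, read-placement tables, per-source pileup
construction, the ungapped single-mismatch short-read mapper, and
VCF 4.x / GFF3 export.

Coordinate convention: everything in memory is 0-based half-open;
everything written to VCF/GFF3 is 1-based (inclusive for GFF3 spans),
per those formats' norms.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

BASES = "ACGT"
#: index 4 is N / anything unrecognised; N never participates in allele calls.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N (case-insensitive) to uint8 codes 0-4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class FastaParseError(ValueError):
    """Raised on a structurally malformed FASTA file; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class PlacementError(ValueError):
    """A read placement that falls outside its contig."""


@dataclass(frozen=True)
class Read:
    """A (possibly source-labelled) sequencing read."""

    read_id: str
    seq: str
    source: str | None = None


@dataclass(frozen=True)
class Placement:
    """True or inferred location of a read on a contig (0-based offset)."""

    read_id: str
    contig: str
    offset: int
    strand: str = "+"


@dataclass(frozen=True)
class UngappedHit:
    """Best ungapped placement of a read, at most ``max_mismatch`` mismatches."""

    read_id: str
    contig: str
    offset: int
    strand: str
    mismatches: int


@dataclass
class SourcedPileupColumn:
    """Per-position base counts split by DNA source."""

    contig: str
    position: int
    counts: dict[str, dict[str, int]]

    def source_depth(self, source: str) -> int:
        """Called-base (A/C/G/T) depth for one source; N is excluded."""
        c = self.counts.get(source, {})
        return sum(c.get(b, 0) for b in BASES)

    def depth(self) -> int:
        """Total called-base depth over all sources."""
        return sum(self.source_depth(s) for s in self.counts)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, normalising bases to uppercase.

    Lowercase input is accepted (soft-masked sequence) but flagged in the
    log.  A file whose first non-blank content is not a header line is
    rejected with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    seen_header = False
    for i, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            seen_header = True
        elif not seen_header:
            raise FastaParseError("sequence data before any '>' header", i)
    records = list(SeqIO.parse(path, "fasta"))
    for rec in records:
        s = str(rec.seq)
        if not s.isupper() and s:
            log.warning("record %s contains lowercase bases; normalised", rec.id)
            rec.seq = Seq(s.upper())
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write SeqRecords as wrapped FASTA."""
    SeqIO.write(records, str(path), "fasta")


def write_reads_fasta(reads: Iterable[Read], path: str | Path) -> None:
    """Write labelled reads; the source label travels in the description."""
    recs = []
    for r in reads:
        desc = f"source={r.source}" if r.source is not None else ""
        recs.append(SeqRecord(Seq(r.seq), id=r.read_id, description=desc))
    write_fasta(recs, path)


def read_reads_fasta(path: str | Path) -> list[Read]:
    """Read labelled reads back; inverse of :func:`write_reads_fasta`."""
    reads = []
    for rec in read_fasta(path):
        source = None
        for token in rec.description.split():
            if token.startswith("source="):
                source = token.split("=", 1)[1]
        reads.append(Read(rec.id, str(rec.seq), source))
    return reads


# ---------------------------------------------------------------------------
# Placements
# ---------------------------------------------------------------------------

_PLACEMENT_COLS = ["read_id", "contig", "offset", "strand"]


def write_placements(placements: Iterable[Placement], path: str | Path) -> None:
    df = pd.DataFrame([(p.read_id, p.contig, p.offset, p.strand) for p in placements],
                      columns=_PLACEMENT_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_placements(path: str | Path) -> list[Placement]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "contig": str})
    return [Placement(r.read_id, r.contig, int(r.offset), r.strand)
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

class Pileup:
    """Dense per-contig, per-source base-count arrays with a column view.

    Internally one ``(n_sources, L, 5)`` uint32 array per contig
    (A, C, G, T, N).  Vectorised consumers read the arrays directly;
    :meth:`columns` yields :class:`SourcedPileupColumn` for covered
    positions only.
    """

    def __init__(self, contig_lengths: Mapping[str, int], sources: Sequence[str]):
        self.contig_lengths = dict(contig_lengths)
        self.sources = list(sources)
        self._source_index = {s: i for i, s in enumerate(self.sources)}
        self._arr = {c: np.zeros((len(self.sources), length, 5), dtype=np.uint32)
                     for c, length in self.contig_lengths.items()}

    def counts(self, contig: str, source: str) -> np.ndarray:
        """The ``(L, 5)`` count array for one contig and source."""
        return self._arr[contig][self._source_index[source]]

    def add_read(self, contig: str, source: str, offset: int, seq: str) -> None:
        arr = self._arr[contig]
        length = self.contig_lengths[contig]
        if offset < 0 or offset + len(seq) > length:
            raise PlacementError(
                f"placement [{offset}, {offset + len(seq)}) exceeds contig "
                f"{contig} of length {length}")
        codes = encode_seq(seq)
        np.add.at(arr[self._source_index[source]],
                  (np.arange(offset, offset + len(seq)), codes), 1)

    def column(self, contig: str, position: int) -> SourcedPileupColumn:
        arr = self._arr[contig]
        counts = {}
        for s, si in self._source_index.items():
            row = arr[si, position]
            counts[s] = {b: int(row[i]) for i, b in enumerate("ACGTN") if row[i]}
        return SourcedPileupColumn(contig, position, counts)

    def columns(self, contig: str | None = None) -> Iterator[SourcedPileupColumn]:
        """Yield columns for every position covered by at least one read."""
        contigs = [contig] if contig is not None else sorted(self._arr)
        for c in contigs:
            covered = np.flatnonzero(self._arr[c].sum(axis=(0, 2)))
            for pos in covered:
                yield self.column(c, int(pos))


def build_pileup(contigs: Mapping[str, str] | Mapping[str, int],
                 placements: Iterable[Placement],
                 reads: Mapping[str, Read],
                 default_source: str = "sample") -> Pileup:
    """Stack placed reads into a :class:`Pileup`.

    ``contigs`` maps contig id to sequence or to length.  Reads lacking a
    source label are pooled under ``default_source``.  A placement that
    exceeds its contig's bounds is rejected, naming the read.
    """
    lengths = {c: (v if isinstance(v, int) else len(v)) for c, v in contigs.items()}
    placements = list(placements)
    sources = sorted({(reads[p.read_id].source or default_source) for p in placements}) or [default_source]
    pile = Pileup(lengths, sources)
    for p in placements:
        if p.contig not in lengths:
            raise PlacementError(f"read {p.read_id}: unknown contig {p.contig}")
        read = reads[p.read_id]
        seq = read.seq if p.strand == "+" else revcomp(read.seq)
        try:
            pile.add_read(p.contig, read.source or default_source, p.offset, seq)
        except PlacementError as exc:
            raise PlacementError(f"read {p.read_id}: {exc}") from None
    return pile


# ---------------------------------------------------------------------------
# Ungapped mapper
# ---------------------------------------------------------------------------

@dataclass
class MappingResult:
    hits: list[UngappedHit]
    unmapped: list[str]
    ambiguous: list[str]

    def placements(self) -> list[Placement]:
        return [Placement(h.read_id, h.contig, h.offset, h.strand) for h in self.hits]


def _candidate_offsets(seq: str, index: dict[str, list[tuple[str, int]]],
                       k: int) -> set[tuple[str, int]]:
    cands: set[tuple[str, int]] = set()
    for read_off in (0, k):
        seed = seq[read_off:read_off + k]
        for contig, pos in index.get(seed, ()):
            cands.add((contig, pos - read_off))
    return cands


def map_reads_ungapped(reads: Iterable[Read],
                       contigs: Mapping[str, str],
                       max_mismatch: int = 1) -> MappingResult:
    """Place reads on contigs with no gaps and at most ``max_mismatch``
    substitutions (default one, both strands searched).

    Each read is reported at its unique best placement; reads whose best
    mismatch count is achieved at more than one locus are discarded as
    ambiguous, and reads with no qualifying placement are unmapped.
    Seeding uses the pigeonhole principle: with at most one mismatch, at
    least one of two adjacent k-mers at the start of the read is exact.
    """
    reads = list(reads)
    if not reads:
        return MappingResult([], [], [])
    if max_mismatch > 1:
        raise ValueError("seeding scheme supports max_mismatch <= 1")
    enc_contigs = {c: encode_seq(s) for c, s in contigs.items()}
    min_len = min(len(r.seq) for r in reads)
    k = min(32, min_len // 2)
    brute = k < 4

    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    if not brute:
        for cid, seq in contigs.items():
            for pos in range(len(seq) - k + 1):
                index[seq[pos:pos + k]].append((cid, pos))

    hits, unmapped, ambiguous = [], [], []
    for read in reads:
        best_mm = max_mismatch + 1
        best: list[tuple[str, int, str]] = []
        for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
            enc = encode_seq(seq)
            if brute:
                cands = {(c, o) for c, e in enc_contigs.items()
                         for o in range(len(e) - len(enc) + 1)}
            else:
                cands = _candidate_offsets(seq, index, k)
            for contig, off in cands:
                ref = enc_contigs[contig]
                if off < 0 or off + len(enc) > len(ref):
                    continue
                mm = int(np.count_nonzero(ref[off:off + len(enc)] != enc))
                if mm < best_mm:
                    best_mm, best = mm, [(contig, off, strand)]
                elif mm == best_mm:
                    loc = (contig, off, strand)
                    if loc not in best:
                        best.append(loc)
        if best_mm > max_mismatch:
            unmapped.append(read.read_id)
        elif len(best) > 1:
            ambiguous.append(read.read_id)
        else:
            contig, off, strand = best[0]
            hits.append(UngappedHit(read.read_id, contig, off, strand, best_mm))
    return MappingResult(hits, unmapped, ambiguous)


# ---------------------------------------------------------------------------
# VCF / GFF3 export
# ---------------------------------------------------------------------------

def write_vcf(snps: Sequence, contigs: Mapping[str, str], path: str | Path) -> None:
    """Write discriminating SNP calls as VCF 4.2.

    By convention REF is the source-A allele and ALT the source-B allele;
    per-source depths, the minor-allele fraction, the mutation class and
    the genic region travel in INFO.  Positions are converted to VCF's
    1-based convention on output.
    """
    header = pysam.VariantHeader()
    header.add_line('##source=estpoly')
    for cid, seq in sorted(contigs.items()):
        header.contigs.add(cid, length=len(seq))
    header.add_line('##INFO=<ID=DPA,Number=1,Type=Integer,Description="Source A depth">')
    header.add_line('##INFO=<ID=DPB,Number=1,Type=Integer,Description="Source B depth">')
    header.add_line('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele fraction">')
    header.add_line('##INFO=<ID=MUT,Number=1,Type=String,Description="transition or transversion">')
    header.add_line('##INFO=<ID=REGION,Number=1,Type=String,Description="CDS, UTR or unannotated">')
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for s in snps:
            if s.contig not in contigs:
                raise ValueError(f"SNP references unknown contig {s.contig}")
            if not 0 <= s.position < len(contigs[s.contig]):
                raise ValueError(
                    f"SNP position {s.position} outside contig {s.contig}")
            rec = vf.new_record(contig=s.contig, start=s.position,
                                stop=s.position + 1,
                                alleles=(s.allele_a, s.allele_b))
            rec.info["DPA"] = s.depth_a
            rec.info["DPB"] = s.depth_b
            rec.info["MAF"] = float(s.minor_fraction)
            rec.info["MUT"] = s.mutation_type
            rec.info["REGION"] = s.region
            vf.write(rec)


def read_vcf(path: str | Path) -> list:
    """Read a VCF written by :func:`write_vcf` back into SnpCall objects."""
    from estpoly.snps import SnpCall  # local import avoids a module cycle

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            calls.append(SnpCall(
                contig=rec.contig, position=rec.start,
                allele_a=rec.ref, allele_b=rec.alts[0],
                depth_a=int(rec.info["DPA"]), depth_b=int(rec.info["DPB"]),
                minor_fraction=round(float(rec.info["MAF"]), 6),
                mutation_type=str(rec.info["MUT"]),
                region=str(rec.info["REGION"])))
    return calls


def write_gff3(ssrs: Sequence, path: str | Path) -> None:
    """Write SSR loci as GFF3 (1-based inclusive spans)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ssr in enumerate(ssrs):
            start, end = ssr.span
            attrs = (f"ID=ssr{i:05d};motif={ssr.motif};"
                     f"class={ssr.canonical_class};units={ssr.units};"
                     f"compound={'true' if ssr.compound else 'false'}")
            fh.write("\t".join([ssr.contig, "estpoly", "microsatellite",
                                str(start + 1), str(end), ".", "+", ".",
                                attrs]) + "\n")
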