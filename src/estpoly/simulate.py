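"""Synthetic EST data with machine-readable truth.

Emulates the study design the pipeline targets: two diverged diploid
subspecies (each simulated as two haplotypes), EST read sets labelled by
DNA source, planted microsatellites whose repeat counts may differ
between the sources, open reading frames carrying a controlled mix of
synonymous and non-synonymous differences, and short unlabelled reads of
a tetraploid drawn as a mixture of the two diploid haplotype sets.

Fixed inter-source differences are planted homozygously (on both
haplotypes of source B), heterozygous sites on a single haplotype of one
source, mirroring the distinction between subspecies-discriminating SNPs
and intra-accession heterogeneity.  All randomness flows through one
seeded generator, so a fixed config reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from estpoly.alnio import Placement, Read, revcomp, write_fasta, write_reads_fasta, write_placements

SOURCE_A = "A"
SOURCE_B = "B"

_CODON_TABLE = unambiguous_dna_by_id[1]
_STOPS = set(_CODON_TABLE.stop_codons)
_SENSE_CODONS = sorted(set(_CODON_TABLE.forward_table))

#: bp of untouched sequence kept on each side of a planted SSR so that
#: exact flank anchoring in the comparison stage is never broken by a
#: planted substitution.
SSR_GUARD = 30


class SsrPlacementError(ValueError):
    """A planted SSR cannot fit in its contig."""


class ConfigError(ValueError):
    """An invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic transcriptome.

    Rates are per bp; ``contig_length`` and ``read_length`` are
    (mean, sd) pairs in bp.  ``fixed_divergence`` plants homozygous
    differences between the two source consensuses (the study's
    between-subspecies SNP density was roughly 1 per 1.1 kb);
    ``het_rate`` plants within-source heterozygous sites (observed
    within-accession variant density was roughly 1 per 200-250 bp).
    ``ka_ks_target`` steers the non-synonymous:synonymous mix of planted
    ORF differences.  ``ssr_plant_spec`` lists
    (motif, units_source_A, units_source_B, n_contigs) tuples; each
    planted SSR occupies its own contig, near the 3' end.
    ``tetraploid_mixture`` is the proportion of tetraploid reads drawn
    from source-A-derived haplotypes.
    """

    n_contigs: int = 50
    contig_length: tuple[float, float] = (1000.0, 100.0)
    gc_fraction: float = 0.5
    fixed_divergence: float = 1e-3
    het_rate: float = 4e-3
    orf_fraction: float = 0.6
    ka_ks_target: float = 0.3
    ssr_plant_spec: list[tuple[str, int, int, int]] = field(default_factory=list)
    read_depth: float = 20.0
    read_length: tuple[float, float] = (400.0, 60.0)
    error_rate: float = 1e-3
    tetraploid_mixture: float = 0.5
    tetraploid_read_length: int = 80
    tetraploid_depth: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("gc_fraction", "orf_fraction", "tetraploid_mixture"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("fixed_divergence", "het_rate", "error_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.read_depth <= 0 or self.tetraploid_depth <= 0:
            raise ConfigError("read depths must be > 0")
        if self.n_contigs < 1:
            raise ConfigError("n_contigs must be >= 1")
        for motif, ua, ub, count in self.ssr_plant_spec:
            if not motif or set(motif) - set("ACGT"):
                raise ConfigError(f"SSR motif {motif!r} must be non-empty A/C/G/T")
            if min(ua, ub) < 1 or count < 1:
                raise ConfigError("SSR unit counts and contig counts must be >= 1")


@dataclass(frozen=True)
class Orf:
    """An open reading frame annotation (0-based half-open span)."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    frame: int = 0


@dataclass(frozen=True)
class PlantedSnp:
    contig: str
    position: int
    base_a: str
    base_b: str


@dataclass(frozen=True)
class PlantedHet:
    contig: str
    position: int
    source: str
    bases: tuple[str, str]


@dataclass(frozen=True)
class PlantedSsr:
    contig: str
    start: int
    motif: str
    units: dict[str, int] = field(hash=False)


@dataclass
class TruthTable:
    """Machine-readable record of everything the generator planted."""

    planted_snps: list[PlantedSnp] = field(default_factory=list)
    planted_het_sites: list[PlantedHet] = field(default_factory=list)
    planted_ssrs: list[PlantedSsr] = field(default_factory=list)
    orf_truth: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self, contig_lengths: dict[str, int]) -> None:
        seen = set()
        for s in self.planted_snps:
            if not 0 <= s.position < contig_lengths[s.contig]:
                raise ValueError(f"truth position outside contig: {s}")
            if s.base_a == s.base_b:
                raise ValueError(f"planted SNP bases identical: {s}")
            key = (s.contig, s.position)
            if key in seen:
                raise ValueError(f"duplicate truth position: {key}")
            seen.add(key)
        for h in self.planted_het_sites:
            if not 0 <= h.position < contig_lengths[h.contig]:
                raise ValueError(f"het position outside contig: {h}")


@dataclass
class ReferenceSet:
    """Everything :func:`generate_reference_set` produces for one config."""

    config: SimulationConfig
    contigs: dict[str, str]                       # reference = source-A consensus
    consensus: dict[str, dict[str, str]]          # source -> contig -> sequence
    haplotypes: dict[str, dict[str, tuple[str, str]]]  # contig -> source -> 2 haplotypes
    orfs: list[Orf]
    truth: TruthTable


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Random base array (as a character list) at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _codon_change_options(codon: str) -> tuple[list, list]:
    """All single-base changes of a sense codon, split synonymous /
    non-synonymous; changes creating a stop codon are excluded (they
    would break the planted reading frame)."""
    aa = _CODON_TABLE.forward_table[codon]
    syn, non = [], []
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if mut in _STOPS:
                continue
            (syn if _CODON_TABLE.forward_table[mut] == aa else non).append((i, b))
    return syn, non


def generate_reference_set(config: SimulationConfig) -> ReferenceSet:
    """Build the two diploid haplotype sets, ORF annotations and truth.

    Planted fixed differences are homozygous-distinct between sources;
    heterozygous sites sit on one haplotype of one source only.  SSRs are
    planted one per contig near the 3' end with an untouched guard zone
    around them, so every position left of the SSR shares coordinates
    across sources even when the repeat lengths differ.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    ssr_plants: list[tuple[str, int, int]] = []
    for motif, ua, ub, count in config.ssr_plant_spec:
        ssr_plants.extend([(motif, ua, ub)] * count)
    if len(ssr_plants) > config.n_contigs:
        raise SsrPlacementError(
            f"{len(ssr_plants)} SSR plants requested but only "
            f"{config.n_contigs} contigs available (one SSR per contig)")

    contigs: dict[str, str] = {}
    consensus: dict[str, dict[str, str]] = {SOURCE_A: {}, SOURCE_B: {}}
    haplotypes: dict[str, dict[str, tuple[str, str]]] = {}
    orfs: list[Orf] = []
    truth = TruthTable()
    mean_len, sd_len = config.contig_length

    for ci in range(config.n_contigs):
        cid = f"contig_{ci:04d}"
        L = max(200, int(round(rng.normal(mean_len, sd_len)))) if sd_len > 0 \
            else max(200, int(round(mean_len)))
        core = _random_sequence(rng, L, config.gc_fraction)

        ssr = ssr_plants[ci] if ci < len(ssr_plants) else None
        if ssr is not None:
            motif, ua, ub = ssr
            if len(motif) * max(ua, ub) + 2 * SSR_GUARD >= L:
                raise SsrPlacementError(
                    f"SSR {motif}x{max(ua, ub)} does not fit in contig {cid} "
                    f"of length {L}")
        # insertion point for the SSR; sequence at [insert, L) forms the
        # right flank.  Everything mutable must lie left of the guard zone.
        insert = L - SSR_GUARD if ssr is not None else None
        mutable_end = (insert - SSR_GUARD) if insert is not None else L
        if ssr is not None:
            # repair the shared flanks once, before the per-source copies,
            # so the planted run can extend into neither flank and both
            # sources keep identical anchor sequence
            motif = ssr[0]
            if core[insert - 1] == motif[-1]:
                core[insert - 1] = rng.choice(
                    [b for b in "ACGT" if b != motif[-1]])
            if core[insert] == motif[0]:
                core[insert] = rng.choice(
                    [b for b in "ACGT" if b != motif[0]])

        # --- ORF ------------------------------------------------------
        orf = None
        if config.orf_fraction > 0:
            max_codons = mutable_end // 3
            n_codons = min(int(round(L * config.orf_fraction / 3)), max_codons)
            if n_codons >= 2:
                orf_start = max(0, (mutable_end - n_codons * 3) // 2)
                orf_end = orf_start + n_codons * 3
                codons = rng.choice(_SENSE_CODONS, size=n_codons)
                core[orf_start:orf_end] = list("".join(codons))
                orf = Orf(cid, orf_start, orf_end)
                orfs.append(orf)

        seq_a = core.copy()
        seq_b = core.copy()

        # --- fixed inter-source differences ---------------------------
        n_fix = rng.binomial(mutable_end, config.fixed_divergence)
        taken: set[int] = set()
        syn_count = non_count = 0
        for _ in range(n_fix):
            for _attempt in range(100):
                pos = int(rng.integers(0, mutable_end))
                if orf is not None and orf.start <= pos < orf.end:
                    codon_i = (pos - orf.start) // 3
                    cstart = orf.start + codon_i * 3
                    if taken & set(range(cstart, cstart + 3)):
                        continue
                    codon = "".join(seq_a[cstart:cstart + 3])
                    syn_opts, non_opts = _codon_change_options(codon)
                    if not syn_opts and not non_opts:
                        continue
                    s_c, n_c = len(syn_opts) / 3.0, len(non_opts) / 3.0
                    r = config.ka_ks_target
                    q = (r * n_c) / (s_c + r * n_c) if (s_c + r * n_c) > 0 else 1.0
                    if non_opts and (not syn_opts or rng.random() < q):
                        i, b = non_opts[int(rng.integers(len(non_opts)))]
                        non_count += 1
                    else:
                        i, b = syn_opts[int(rng.integers(len(syn_opts)))]
                        syn_count += 1
                    pos = cstart + i
                    if pos in taken:
                        continue
                    seq_b[pos] = b
                else:
                    if pos in taken:
                        continue
                    choices = [b for b in "ACGT" if b != seq_a[pos]]
                    seq_b[pos] = choices[int(rng.integers(3))]
                taken.add(pos)
                truth.planted_snps.append(
                    PlantedSnp(cid, pos, str(seq_a[pos]), str(seq_b[pos])))
                break
        if orf is not None:
            truth.orf_truth[cid] = {"syn": syn_count, "nonsyn": non_count}

        # --- within-source heterozygous sites -------------------------
        het_alt: dict[str, dict[int, str]] = {SOURCE_A: {}, SOURCE_B: {}}
        for source, base_seq in ((SOURCE_A, seq_a), (SOURCE_B, seq_b)):
            n_het = rng.binomial(mutable_end, config.het_rate)
            for _ in range(n_het):
                for _attempt in range(100):
                    pos = int(rng.integers(0, mutable_end))
                    if pos in taken:
                        continue
                    ref = str(base_seq[pos])
                    alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
                    het_alt[source][pos] = alt
                    taken.add(pos)
                    truth.planted_het_sites.append(
                        PlantedHet(cid, pos, source, (ref, alt)))
                    break

        # --- SSR insertion --------------------------------------------
        def _assemble(base: np.ndarray, units: int | None) -> str:
            s = "".join(base)
            if ssr is None or units is None:
                return s
            return s[:insert] + ssr[0] * units + s[insert:]

        cons_a = _assemble(seq_a, ssr[1] if ssr else None)
        cons_b = _assemble(seq_b, ssr[2] if ssr else None)
        if ssr is not None:
            truth.planted_ssrs.append(
                PlantedSsr(cid, len(cons_a[:insert]), ssr[0],
                           {SOURCE_A: ssr[1], SOURCE_B: ssr[2]}))

        def _with_het(cons: str, alts: dict[int, str]) -> str:
            arr = list(cons)
            for pos, alt in alts.items():
                arr[pos] = alt
            return "".join(arr)

        contigs[cid] = cons_a
        consensus[SOURCE_A][cid] = cons_a
        consensus[SOURCE_B][cid] = cons_b
        haplotypes[cid] = {
            SOURCE_A: (cons_a, _with_het(cons_a, het_alt[SOURCE_A])),
            SOURCE_B: (cons_b, _with_het(cons_b, het_alt[SOURCE_B])),
        }

    truth.validate({c: len(s) for c, s in contigs.items()})
    return ReferenceSet(config, contigs, consensus, haplotypes, orfs, truth)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _draw_read(rng: np.random.Generator, hap: str, read_len: int,
               error_rate: float) -> tuple[int, str] | None:
    """One read of up to ``read_len`` bp from a haplotype; reads may run
    off either contig end and are truncated, which keeps the realised
    depth uniform along the contig.  Returns (offset, sequence) or None
    when the truncated read is shorter than 20 bp."""
    L = len(hap)
    o = int(rng.integers(-(read_len - 1), L))
    start, end = max(0, o), min(L, o + read_len)
    if end - start < 20:
        return None
    seq = list(hap[start:end])
    n_err = rng.binomial(len(seq), error_rate) if error_rate > 0 else 0
    for pos in rng.choice(len(seq), size=n_err, replace=False) if n_err else ():
        seq[pos] = [b for b in "ACGT" if b != seq[pos]][int(rng.integers(3))]
    return start, "".join(seq)


def simulate_est_reads(refset: ReferenceSet,
                       config: SimulationConfig | None = None
                       ) -> tuple[list[Read], list[Placement]]:
    """Labelled EST-like reads from both haplotypes of each source, with
    their true placements recorded so pileup construction needs no
    aligner.  Reverse-strand reads are emitted reverse-complemented; the
    placement strand says so."""
    config = config or refset.config
    rng = np.random.default_rng((config.seed + 1) % 2**31)
    mean_rl, sd_rl = config.read_length
    reads: list[Read] = []
    placements: list[Placement] = []
    n = 0
    for cid in sorted(refset.haplotypes):
        for source in (SOURCE_A, SOURCE_B):
            haps = refset.haplotypes[cid][source]
            L = len(haps[0])
            # a read of mean length rl drawn anywhere in [-(rl-1), L) covers
            # rl*L/(L+rl-1) bases on average, so this count gives a mean
            # per-position depth of ~read_depth
            n_reads = max(1, int(round(
                config.read_depth * (L + mean_rl - 1) / mean_rl)))
            for _ in range(n_reads):
                hap = haps[int(rng.integers(2))]
                rl = max(40, int(round(rng.normal(mean_rl, sd_rl)))) if sd_rl > 0 \
                    else int(mean_rl)
                drawn = _draw_read(rng, hap, rl, config.error_rate)
                if drawn is None:
                    continue
                offset, seq = drawn
                strand = "+" if rng.random() < 0.5 else "-"
                rid = f"read_{n:07d}"
                n += 1
                reads.append(Read(rid, seq if strand == "+" else revcomp(seq), source))
                placements.append(Placement(rid, cid, offset, strand))
    return reads, placements


@dataclass(frozen=True)
class PolyploidReadTruth:
    read_id: str
    contig: str
    offset: int
    source: str
    haplotype: int
    strand: str


def simulate_polyploid_reads(refset: ReferenceSet,
                             config: SimulationConfig | None = None
                             ) -> tuple[list[Read], list[PolyploidReadTruth]]:
    """Short unlabelled reads of a tetraploid drawn from the union of the
    four haplotypes, a ``tetraploid_mixture`` proportion of them from the
    source-A pair.  True origins are recorded per read."""
    config = config or refset.config
    rng = np.random.default_rng((config.seed + 2) % 2**31)
    rl = config.tetraploid_read_length
    reads: list[Read] = []
    origins: list[PolyploidReadTruth] = []
    n = 0
    for cid in sorted(refset.haplotypes):
        L = len(refset.haplotypes[cid][SOURCE_A][0])
        n_reads = max(1, int(round(config.tetraploid_depth * (L + rl - 1) / rl)))
        for _ in range(n_reads):
            source = SOURCE_A if rng.random() < config.tetraploid_mixture else SOURCE_B
            hap_i = int(rng.integers(2))
            hap = refset.haplotypes[cid][source][hap_i]
            drawn = _draw_read(rng, hap, rl, config.error_rate)
            if drawn is None:
                continue
            offset, seq = drawn
            strand = "+" if rng.random() < 0.5 else "-"
            rid = f"wyo_{n:07d}"
            n += 1
            reads.append(Read(rid, seq if strand == "+" else revcomp(seq), None))
            origins.append(PolyploidReadTruth(rid, cid, offset, source, hap_i, strand))
    return reads, origins


# ---------------------------------------------------------------------------
# On-disk truth / reference output
# ---------------------------------------------------------------------------

def write_reference_set(refset: ReferenceSet, outdir: str | Path) -> dict[str, Path]:
    """Write contigs, per-source consensuses, ORFs and truth tables as
    FASTA / TSV; returns the file map.  Coordinates on disk are 0-based
    half-open."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["contigs"] = outdir / "contigs.fasta"
    write_fasta([SeqRecord(Seq(s), id=c, description="")
                 for c, s in sorted(refset.contigs.items())], files["contigs"])
    for source in (SOURCE_A, SOURCE_B):
        key = f"consensus_{source}"
        files[key] = outdir / f"consensus_{source}.fasta"
        write_fasta([SeqRecord(Seq(s), id=c, description="")
                     for c, s in sorted(refset.consensus[source].items())],
                    files[key])

    files["orfs"] = outdir / "orfs.tsv"
    pd.DataFrame([(o.contig, o.start, o.end, o.strand, o.frame)
                  for o in refset.orfs],
                 columns=["contig", "start", "end", "strand", "frame"]
                 ).to_csv(files["orfs"], sep="\t", index=False)

    t = refset.truth
    files["truth_snps"] = outdir / "truth_snps.tsv"
    pd.DataFrame([(s.contig, s.position, s.base_a, s.base_b)
                  for s in t.planted_snps],
                 columns=["contig", "position", "base_a", "base_b"]
                 ).to_csv(files["truth_snps"], sep="\t", index=False)
    files["truth_hets"] = outdir / "truth_hets.tsv"
    pd.DataFrame([(h.contig, h.position, h.source, h.bases[0], h.bases[1])
                  for h in t.planted_het_sites],
                 columns=["contig", "position", "source", "ref", "alt"]
                 ).to_csv(files["truth_hets"], sep="\t", index=False)
    files["truth_ssrs"] = outdir / "truth_ssrs.tsv"
    pd.DataFrame([(s.contig, s.start, s.motif, s.units[SOURCE_A], s.units[SOURCE_B])
                  for s in t.planted_ssrs],
                 columns=["contig", "start", "motif", "units_a", "units_b"]
                 ).to_csv(files["truth_ssrs"], sep="\t", index=False)
    files["truth_orfs"] = outdir / "truth_orf_divergence.tsv"
    pd.DataFrame([(c, v["syn"], v["nonsyn"]) for c, v in sorted(t.orf_truth.items())],
                 columns=["contig", "syn", "nonsyn"]
                 ).to_csv(files["truth_orfs"], sep="\t", index=False)
    return files


def write_simulated_reads(reads: Sequence[Read], placements: Sequence[Placement],
                          outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {"reads": outdir / "reads.fasta", "placements": outdir / "placements.tsv"}
    write_reads_fasta(reads, files["reads"])
    write_placements(placements, files["placements"])
    return files
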