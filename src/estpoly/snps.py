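"""Discriminating-SNP calling between two DNA sources, within-source
variant detection, and the summary tabulations.

A position is called as a discriminating SNP when (1) total called-base
depth meets ``min_total_depth``; (2) each source contributes at least
``min_source_depth`` reads; (3) within each source the modal base
accounts for at least ``homogeneity`` of that source's reads (no modal
tie); (4) the two modal bases differ; and (5) the rarer of the two modal
alleles, counted over all reads, reaches ``min_minor_fraction`` of the
total depth.  Defaults are depth >= 8, minor fraction >= 20% and
homogeneity >= 90%; a 99% homogeneity setting supports stringency
re-analysis.  N bases never participate.

Homogeneity is applied per source: at a 100x position where source A
contributes 80 reads and source B 20, a G<->A difference is called when
at least 72 of the A reads carry G and at least 18 of the B reads carry
A.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from estpoly.alnio import BASES, Pileup, SourcedPileupColumn
from estpoly.simulate import Orf

TRANSITION_PAIRS = ({"A", "G"}, {"C", "T"})
#: Table-style labels for the six unordered base pairs.
MUTATION_CLASSES = ("C/T", "A/G", "A/T", "C/G", "A/C", "G/T")


class SourceConfigError(ValueError):
    """Pileup does not carry exactly the expected source labels."""


@dataclass(frozen=True)
class SnpCallingParams:
    """Thresholds of the discriminating-SNP rule.

    ``min_source_depth`` guards the homogeneity test: a single read
    cannot evidence within-source homogeneity.
    """

    min_total_depth: int = 8
    min_minor_fraction: float = 0.20
    homogeneity: float = 0.90
    min_source_depth: int = 2

    def __post_init__(self):
        if not 0 < self.min_minor_fraction <= 0.5:
            raise ValueError("min_minor_fraction must be in (0, 0.5]")
        if not 0.5 < self.homogeneity <= 1.0:
            raise ValueError("homogeneity must be in (0.5, 1]")


@dataclass(frozen=True)
class SnpCall:
    """One discriminating SNP between the two DNA sources."""

    contig: str
    position: int
    allele_a: str
    allele_b: str
    depth_a: int
    depth_b: int
    minor_fraction: float
    mutation_type: str
    region: str = "unannotated"


@dataclass
class CallDiagnostics:
    """Positions skipped or noteworthy during calling."""

    zero_depth_source: int = 0
    modal_tie: int = 0
    third_base_positions: list[tuple[str, int]] = field(default_factory=list)


def classify_mutation_type(allele_a: str, allele_b: str) -> str:
    """Transition for purine<->purine / pyrimidine<->pyrimidine pairs
    ({A,G} and {C,T}); every other pair is a transversion."""
    if allele_a == allele_b:
        raise ValueError("identical bases have no mutation type")
    pair = {allele_a, allele_b}
    return "transition" if pair in TRANSITION_PAIRS else "transversion"


def mutation_class(allele_a: str, allele_b: str) -> str:
    """The Table-style unordered pair label, e.g. 'C/T'."""
    return "/".join(sorted((allele_a, allele_b)))


def locate_region(contig: str, position: int, orfs: Sequence[Orf]) -> str:
    """CDS if inside an ORF span on this contig, UTR if the contig has an
    ORF but the position is outside it, unannotated otherwise."""
    has_orf = False
    for orf in orfs:
        if orf.contig != contig:
            continue
        has_orf = True
        if orf.start <= position < orf.end:
            return "CDS"
    return "UTR" if has_orf else "unannotated"


def call_discriminating_snps(pileup: Pileup,
                             params: SnpCallingParams = SnpCallingParams(),
                             orfs: Sequence[Orf] = (),
                             diagnostics: CallDiagnostics | None = None
                             ) -> list[SnpCall]:
    """Apply the five-condition discriminating rule to a two-source pileup.

    Positions where either source has zero depth are skipped and tallied
    in ``diagnostics``; modal-base ties within a source are never called.
    """
    if len(pileup.sources) != 2:
        raise SourceConfigError(
            f"expected exactly 2 source labels, got {pileup.sources}")
    src_a, src_b = pileup.sources
    diag = diagnostics if diagnostics is not None else CallDiagnostics()
    calls: list[SnpCall] = []
    for cid in sorted(pileup.contig_lengths):
        a = pileup.counts(cid, src_a)[:, :4].astype(np.int64)
        b = pileup.counts(cid, src_b)[:, :4].astype(np.int64)
        da, db = a.sum(axis=1), b.sum(axis=1)
        total = da + db
        covered = total > 0
        diag.zero_depth_source += int(np.count_nonzero(
            covered & ((da == 0) | (db == 0))))

        ok = (total >= params.min_total_depth) \
            & (da >= params.min_source_depth) \
            & (db >= params.min_source_depth)
        if not ok.any():
            continue
        max_a, max_b = a.max(axis=1), b.max(axis=1)
        tie_a = (a == max_a[:, None]).sum(axis=1) > 1
        tie_b = (b == max_b[:, None]).sum(axis=1) > 1
        diag.modal_tie += int(np.count_nonzero(ok & (tie_a | tie_b)))
        ok &= ~tie_a & ~tie_b
        modal_a, modal_b = a.argmax(axis=1), b.argmax(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ok &= np.where(da > 0, max_a / np.maximum(da, 1), 0.0) >= params.homogeneity
            ok &= np.where(db > 0, max_b / np.maximum(db, 1), 0.0) >= params.homogeneity
        ok &= modal_a != modal_b
        if not ok.any():
            continue
        idx = np.arange(len(total))
        count_allele_a = a[idx, modal_a] + b[idx, modal_a]
        count_allele_b = a[idx, modal_b] + b[idx, modal_b]
        minor = np.minimum(count_allele_a, count_allele_b)
        minor_frac = np.where(total > 0, minor / np.maximum(total, 1), 0.0)
        ok &= minor_frac >= params.min_minor_fraction

        for pos in np.flatnonzero(ok):
            aa, ab = BASES[modal_a[pos]], BASES[modal_b[pos]]
            if int(total[pos]) > int(count_allele_a[pos] + count_allele_b[pos]):
                diag.third_base_positions.append((cid, int(pos)))
            calls.append(SnpCall(
                contig=cid, position=int(pos), allele_a=aa, allele_b=ab,
                depth_a=int(da[pos]), depth_b=int(db[pos]),
                minor_fraction=round(float(minor_frac[pos]), 6),
                mutation_type=classify_mutation_type(aa, ab),
                region=locate_region(cid, int(pos), orfs)))
    return calls


def call_within_source_variants(pileup: Pileup, source: str,
                                params: SnpCallingParams = SnpCallingParams()
                                ) -> list[tuple[str, int, str, str, float]]:
    """Variant positions within a single source: depth >=
    ``min_total_depth`` and second-most-common base at >=
    ``min_minor_fraction`` of that source's reads.  Returns
    (contig, position, major base, minor base, minor fraction) tuples;
    quantifies intra-accession heterogeneity."""
    out = []
    for cid in sorted(pileup.contig_lengths):
        c = pileup.counts(cid, source)[:, :4].astype(np.int64)
        depth = c.sum(axis=1)
        order = np.argsort(c, axis=1)
        first, second = order[:, -1], order[:, -2]
        idx = np.arange(len(depth))
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, c[idx, second] / np.maximum(depth, 1), 0.0)
        ok = (depth >= params.min_total_depth) & (frac >= params.min_minor_fraction)
        for pos in np.flatnonzero(ok):
            out.append((cid, int(pos), BASES[first[pos]], BASES[second[pos]],
                        round(float(frac[pos]), 6)))
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

#: left-closed minor-allele-fraction bins: [20,30), [30,40), [40,50]
MAF_BIN_LABELS = ("20-30%", "30-40%", "40-50%")
#: contigs carrying more SNPs than this are flagged as assembly-suspect
ABUNDANT_SNP_THRESHOLD = 13


@dataclass
class SnpSummary:
    n_snps: int
    snps_per_contig: dict[str, int]
    histogram: dict[int, int]
    flagged_contigs: list[str]
    density_bp_per_snp: float
    maf_bins: dict[str, int]
    ts_tv_table: dict[str, int]
    n_transitions: int
    n_transversions: int
    region_counts: dict[str, int]

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["histogram"] = {str(k): v for k, v in self.histogram.items()}
        return d


def summarize_snps(calls: Sequence[SnpCall],
                   contig_lengths: Mapping[str, int]) -> SnpSummary:
    """Tabulate calls: per-contig histogram, >13-SNP flags, density in bp
    per SNP over the total assembled length, MAF bins and the
    transition/transversion table."""
    per_contig = Counter(c.contig for c in calls)
    histogram = Counter(per_contig.values())
    flagged = sorted(c for c, n in per_contig.items()
                     if n > ABUNDANT_SNP_THRESHOLD)
    total_bp = sum(contig_lengths.values())
    density = total_bp / len(calls) if calls else float("inf")
    maf_bins = dict.fromkeys(MAF_BIN_LABELS, 0)
    for c in calls:
        if c.minor_fraction < 0.30:
            maf_bins["20-30%"] += 1
        elif c.minor_fraction < 0.40:
            maf_bins["30-40%"] += 1
        else:
            maf_bins["40-50%"] += 1
    ts_tv = dict.fromkeys(MUTATION_CLASSES, 0)
    for c in calls:
        ts_tv[mutation_class(c.allele_a, c.allele_b)] += 1
    n_ts = sum(1 for c in calls if c.mutation_type == "transition")
    region_counts = Counter(c.region for c in calls)
    return SnpSummary(
        n_snps=len(calls),
        snps_per_contig=dict(sorted(per_contig.items())),
        histogram=dict(sorted(histogram.items())),
        flagged_contigs=flagged,
        density_bp_per_snp=density,
        maf_bins=maf_bins,
        ts_tv_table=ts_tv,
        n_transitions=n_ts,
        n_transversions=len(calls) - n_ts,
        region_counts=dict(region_counts),
    )
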