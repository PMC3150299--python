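"""Allele-origin classification of a polyploid read set at
parent-discriminating SNPs.

At each discriminating SNP, reads of the polyploid sample overlapping
the position are tallied.  A SNP is evaluable only at depth >=
``min_depth`` (default 20); an allele is considered present when it is
carried by at least ``min_variant_fraction`` (default 10%) of all reads
overlapping the position.  A SNP with both parental alleles present is
evidence of mixed (allopolyploid-like) ancestry; one parental allele
gives A_only / B_only; anything else — including a non-parental base
reaching the variant fraction — is classified other.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from estpoly.alnio import BASES, Pileup
from estpoly.snps import SnpCall

VERDICTS = ("both", "A_only", "B_only", "other", "insufficient_depth")


@dataclass(frozen=True)
class PolyploidParams:
    min_depth: int = 20
    min_variant_fraction: float = 0.10

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.min_variant_fraction <= 0.5:
            raise ValueError("min_variant_fraction must be in (0, 0.5]")


@dataclass(frozen=True)
class PolyploidVerdict:
    contig: str
    position: int
    depth: int
    fraction_a: float
    fraction_b: float
    verdict: str


def classify_counts(counts: Mapping[str, int], allele_a: str, allele_b: str,
                    params: PolyploidParams = PolyploidParams()) -> tuple[str, int, float, float]:
    """Verdict for one SNP from base counts of the polyploid reads.

    Fractions are computed over all called (A/C/G/T) reads overlapping
    the position, including non-parental bases.  Returns
    (verdict, depth, fraction_a, fraction_b).
    """
    depth = sum(counts.get(b, 0) for b in BASES)
    if depth < params.min_depth:
        return "insufficient_depth", depth, 0.0, 0.0
    fa = counts.get(allele_a, 0) / depth
    fb = counts.get(allele_b, 0) / depth
    t = params.min_variant_fraction
    third = any(counts.get(b, 0) / depth >= t
                for b in BASES if b not in (allele_a, allele_b))
    if third:
        verdict = "other"
    elif fa >= t and fb >= t:
        verdict = "both"
    elif fa >= t:
        verdict = "A_only"
    elif fb >= t:
        verdict = "B_only"
    else:
        verdict = "other"
    return verdict, depth, fa, fb


def classify_polyploid_snps(pileup: Pileup, snp_calls: Sequence[SnpCall],
                            params: PolyploidParams = PolyploidParams()
                            ) -> list[PolyploidVerdict]:
    """Classify every discriminating SNP against the polyploid pileup.

    The pileup is summed over whatever source labels it carries (the
    polyploid sample is unlabelled).  SNP positions not covered at all
    are reported as insufficient_depth.
    """
    verdicts = []
    for snp in snp_calls:
        counts: Counter[str] = Counter()
        if snp.contig in pileup.contig_lengths and \
                snp.position < pileup.contig_lengths[snp.contig]:
            for source in pileup.sources:
                row = pileup.counts(snp.contig, source)[snp.position]
                for i, b in enumerate(BASES):
                    counts[b] += int(row[i])
        verdict, depth, fa, fb = classify_counts(
            counts, snp.allele_a, snp.allele_b, params)
        verdicts.append(PolyploidVerdict(
            snp.contig, snp.position, depth,
            round(fa, 6), round(fb, 6), verdict))
    return verdicts


@dataclass
class AncestryReport:
    """Summary of mixed-ancestry evidence over all evaluable SNPs."""

    counts: dict[str, int]
    n_evaluable: int
    both_fraction: float
    n_contigs_with_both: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def summarize_ancestry(verdicts: Sequence[PolyploidVerdict]) -> AncestryReport:
    """Counts per verdict class and the fraction of evaluable SNPs (depth
    passed) at which both parental alleles were observed; SNPs below
    depth are excluded from the denominator."""
    counts = dict.fromkeys(VERDICTS, 0)
    for v in verdicts:
        counts[v.verdict] += 1
    evaluable = sum(n for k, n in counts.items() if k != "insufficient_depth")
    both_fraction = counts["both"] / evaluable if evaluable else 0.0
    contigs_with_both = len({v.contig for v in verdicts if v.verdict == "both"})
    return AncestryReport(counts, evaluable, both_fraction, contigs_with_both)
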