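"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by literal enumeration (per-offset
scans, per-condition checks, pathway listings) and stay independent of
the library code paths they validate.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# --- discriminating-SNP rule, condition by condition -----------------------

def brute_snp_check(counts_a: dict[str, int], counts_b: dict[str, int],
                    min_total_depth=8, min_minor_fraction=0.20,
                    homogeneity=0.90, min_source_depth=2):
    """Literal check of the five calling conditions; returns the
    (allele_a, allele_b) pair for a call, else None."""
    da = sum(counts_a.get(b, 0) for b in BASES)
    db = sum(counts_b.get(b, 0) for b in BASES)
    if da + db < min_total_depth:
        return None
    if da < min_source_depth or db < min_source_depth:
        return None

    def modal(c):
        best = max(BASES, key=lambda b: c.get(b, 0))
        if sum(1 for b in BASES if c.get(b, 0) == c.get(best, 0)) > 1:
            return None
        return best

    ma, mb = modal(counts_a), modal(counts_b)
    if ma is None or mb is None:
        return None
    if counts_a.get(ma, 0) / da < homogeneity:
        return None
    if counts_b.get(mb, 0) / db < homogeneity:
        return None
    if ma == mb:
        return None
    n_ma = counts_a.get(ma, 0) + counts_b.get(ma, 0)
    n_mb = counts_a.get(mb, 0) + counts_b.get(mb, 0)
    if min(n_ma, n_mb) / (da + db) < min_minor_fraction:
        return None
    return ma, mb


# --- polyploid verdict ------------------------------------------------------

def brute_polyploid_verdict(counts: dict[str, int], allele_a: str,
                            allele_b: str, min_depth=20,
                            min_variant_fraction=0.10) -> str:
    depth = sum(counts.get(b, 0) for b in BASES)
    if depth < min_depth:
        return "insufficient_depth"
    t = min_variant_fraction
    for b in BASES:
        if b not in (allele_a, allele_b) and counts.get(b, 0) / depth >= t:
            return "other"
    has_a = counts.get(allele_a, 0) / depth >= t
    has_b = counts.get(allele_b, 0) / depth >= t
    if has_a and has_b:
        return "both"
    if has_a:
        return "A_only"
    if has_b:
        return "B_only"
    return "other"


# --- SSR scanning -----------------------------------------------------------

def _primitive(motif: str) -> bool:
    k = len(motif)
    return not any(k % d == 0 and motif == motif[:d] * (k // d)
                   for d in range(1, k))


def brute_ssrs(seq: str, min_units: dict[int, int],
               report_homopolymers=False) -> list[tuple[int, int, str, int]]:
    """Exhaustive start x motif-length enumeration of maximal perfect
    repeats: (start, end, motif, units) tuples, left-anchored at the
    base level."""
    out = []
    ks = sorted(k for k in min_units if k >= 2)
    if report_homopolymers:
        ks = [1] + ks
    thresholds = dict(min_units)
    thresholds.setdefault(1, 10)
    for k in ks:
        for start in range(len(seq) - 2 * k + 1):
            motif = seq[start:start + k]
            if "N" in motif or not _primitive(motif):
                continue
            if len(set(motif)) == 1 and not report_homopolymers:
                continue
            u = 1
            while seq[start + u * k:start + (u + 1) * k] == motif:
                u += 1
            if u < thresholds[k]:
                continue
            if start > 0 and seq[start - 1] == seq[start + k - 1]:
                continue  # extensible left at the base level: not anchored
            out.append((start, start + u * k, motif, u))
    return sorted(out)


# --- ungapped mapping --------------------------------------------------------

def brute_map(read_seq: str, contigs: dict[str, str], max_mismatch=1):
    """All-offsets, both-strand scan; returns (best placement or None,
    status) where status is 'mapped', 'ambiguous' or 'unmapped'."""
    best_mm = max_mismatch + 1
    best = []
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        for cid in sorted(contigs):
            ref = contigs[cid]
            for off in range(len(ref) - len(seq) + 1):
                mm = sum(a != b or a == "N"
                         for a, b in zip(ref[off:off + len(seq)], seq))
                if mm < best_mm:
                    best_mm, best = mm, [(cid, off, strand)]
                elif mm == best_mm and (cid, off, strand) not in best:
                    best.append((cid, off, strand))
    if best_mm > max_mismatch:
        return None, "unmapped"
    if len(best) > 1:
        return None, "ambiguous"
    return (best[0][0], best[0][1], best[0][2], best_mm), "mapped"


# --- codon counting ----------------------------------------------------------

def enumerate_codon_sites(codon: str) -> tuple[float, float]:
    """Fraction of the 9 single-base mutations that are synonymous,
    via Biopython translation (changes to stops count non-synonymous)."""
    aa = str(Seq(codon).translate())
    syn = 0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if str(Seq(mut).translate()) == aa:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def enumerate_pair_substitutions(c1: str, c2: str) -> tuple[float, float]:
    """Equal-weight pathway enumeration between two codons; pathways
    through stops ('*') excluded, with an all-paths fallback."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    all_paths, valid_paths = [], []
    for order in permutations(diff):
        cur, steps, ok = c1, [], True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if str(Seq(nxt).translate()) == "*":
                ok = False
            steps.append((str(Seq(cur).translate()), str(Seq(nxt).translate())))
            cur = nxt
        all_paths.append(steps)
        if ok:
            valid_paths.append(steps)
    use = valid_paths or all_paths
    syn = sum(1 for steps in use for a, b in steps if a == b) / len(use)
    non = sum(1 for steps in use for a, b in steps if a != b) / len(use)
    return syn, non
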