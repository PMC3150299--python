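"""Ka/Ks selection analysis with pseudocounted Jukes-Cantor correction.

Sites and substitutions are counted in the Nei-Gojobori style: each
codon position contributes the fraction of its three possible single-
base changes that are synonymous to the synonymous site total S (the
remainder, including changes to stop codons, to N), and multi-hit codon
pairs are averaged over all minimal mutational pathways with equal
weight, excluding pathways that pass through a stop codon.

One unit is added to both substitution classes before the proportions
are formed — pS = (Sd + 1)/S, pN = (Nd + 1)/N — so the ratio stays
finite and positive when either class has no observed changes.  Each
proportion is then Jukes-Cantor corrected, d = -(3/4)·ln(1 - 4p/3).

Ratios above 2.5 are discarded as probable alignment artifacts; the
remainder are classified as stabilizing (< 0.15), intermediate
([0.15, 0.50)) or diversifying ([0.50, 2.50]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np

from estpoly.alnio import revcomp
from estpoly.simulate import Orf
from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)


class StopCodonError(ValueError):
    """An internal stop codon in a sequence submitted for site counting."""


class SaturationError(ValueError):
    """A corrected proportion outside the Jukes-Cantor domain (p >= 3/4)."""


def _translate(codon: str) -> str:
    return _TABLE.forward_table.get(codon, "*")


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame pair of coding sequences on shared codon coordinates."""

    contig: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_a) % 3:
            raise ValueError("aligned length must be divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]


@dataclass(frozen=True)
class KaKsResult:
    contig: str
    syn_sites: float
    nonsyn_sites: float
    syn_subs: float
    nonsyn_subs: float
    ka: float
    ks: float
    ratio: float
    discarded: bool
    selection_class: str


@dataclass(frozen=True)
class BootstrapInterval:
    n_draws: int
    alpha: float
    lower: float
    upper: float
    seed: int


# ---------------------------------------------------------------------------
# Site and substitution counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    aa = _translate(codon)
    syn = 0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            if _translate(codon[:i] + b + codon[i + 1:]) == aa:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def count_sites(seq: str) -> tuple[float, float]:
    """Fractional synonymous and non-synonymous site counts (S, N) of an
    in-frame coding sequence; S + N equals the sequence length.  An
    internal stop codon is an error naming the codon index."""
    if len(seq) % 3:
        raise ValueError("sequence length must be divisible by 3")
    s = n = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in _STOPS:
            raise StopCodonError(f"stop codon {codon} at codon index {i // 3}")
        cs, cn = _codon_sites(codon)
        s += cs
        n += cn
    return s, n


@lru_cache(maxsize=None)
def _codon_pair_subs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/non-synonymous substitution counts between two codons,
    averaged with equal weight over all minimal mutational pathways;
    pathways through stop codons are excluded (all-stop fallback: every
    pathway counted)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        valid = True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in _STOPS:
                valid = False
            steps.append((cur, nxt))
            cur = nxt
        paths.append((valid, steps))
    use = [steps for valid, steps in paths if valid] or [s for _, s in paths]
    syn = non = 0.0
    for steps in use:
        for a, b in steps:
            if _translate(a) == _translate(b):
                syn += 1
            else:
                non += 1
    return syn / len(use), non / len(use)


def count_substitutions(alignment: CodonAlignment) -> tuple[float, float]:
    """Total (Sd, Nd) over the alignment's codon pairs."""
    sd = nd = 0.0
    for ca, cb in alignment.codons():
        s, n = _codon_pair_subs(ca, cb)
        sd += s
        nd += n
    return sd, nd


# ---------------------------------------------------------------------------
# The pseudocounted Jukes-Cantor estimator
# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """d = -(3/4)·ln(1 - 4p/3); domain p < 3/4."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} is outside the JC domain")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


DISCARD_ABOVE = 2.5
STABILIZING_BELOW = 0.15
DIVERSIFYING_FROM = 0.50


def classify_selection(ratio: float) -> str:
    """Selection class of a Ka/Ks ratio: < 0.15 stabilizing,
    [0.15, 0.50) intermediate, [0.50, 2.50] diversifying, > 2.50
    discarded (treated as alignment artifact)."""
    if ratio > DISCARD_ABOVE:
        return "discarded"
    if ratio < STABILIZING_BELOW:
        return "stabilizing"
    if ratio < DIVERSIFYING_FROM:
        return "intermediate"
    return "diversifying"


def kaks_modified_jc(syn_subs: float, nonsyn_subs: float,
                     syn_sites: float, nonsyn_sites: float,
                     pseudocount: float = 1.0,
                     discard_above: float = DISCARD_ABOVE,
                     contig: str = "pair") -> KaKsResult:
    """Ka, Ks and their ratio from counted sites and substitutions.

    The pseudocount is added to both substitution classes before the
    proportions are formed, which keeps the ratio finite and positive
    for pairs with no observed changes in either class.
    """
    if syn_sites <= 0 or nonsyn_sites <= 0:
        raise ValueError("site counts must be positive")
    ps = (syn_subs + pseudocount) / syn_sites
    pn = (nonsyn_subs + pseudocount) / nonsyn_sites
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    ratio = ka / ks
    return KaKsResult(
        contig=contig, syn_sites=syn_sites, nonsyn_sites=nonsyn_sites,
        syn_subs=syn_subs, nonsyn_subs=nonsyn_subs, ka=ka, ks=ks,
        ratio=ratio, discarded=ratio > discard_above,
        selection_class=classify_selection(ratio))


def analyze_pair(alignment: CodonAlignment, pseudocount: float = 1.0,
                 discard_above: float = DISCARD_ABOVE) -> KaKsResult:
    """Full chain for one contig pair: NG-style site counts (averaged
    over the two sequences), pathway-averaged substitution counts, then
    the pseudocounted JC estimator."""
    sa, na = count_sites(alignment.seq_a)
    sb, nb = count_sites(alignment.seq_b)
    s, n = (sa + sb) / 2.0, (na + nb) / 2.0
    sd, nd = count_substitutions(alignment)
    return kaks_modified_jc(sd, nd, s, n, pseudocount, discard_above,
                            contig=alignment.contig)


# ---------------------------------------------------------------------------
# Alignment construction from per-source consensuses
# ---------------------------------------------------------------------------

def codon_alignment_from_consensus(cons_a: str, cons_b: str, orf: Orf
                                   ) -> CodonAlignment | None:
    """Extract the in-frame codon alignment of one contig's two source
    consensuses using its ORF annotation.

    The two consensuses must agree in length over the ORF (length-
    changing repeat polymorphisms break shared coordinates; such contigs
    are not analysable this way and yield None).  Codons containing a
    non-ACGT base or a stop codon in either source are dropped.
    """
    a, b = cons_a[orf.start:orf.end], cons_b[orf.start:orf.end]
    if len(a) != len(b) or len(cons_a) != len(cons_b):
        return None
    if orf.strand == "-":
        a, b = revcomp(a), revcomp(b)
    keep_a, keep_b = [], []
    for i in range(0, len(a) - len(a) % 3, 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if (set(ca) | set(cb)) - set("ACGT"):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        keep_a.append(ca)
        keep_b.append(cb)
    if not keep_a:
        return None
    return CodonAlignment(orf.contig, "".join(keep_a), "".join(keep_b))


# ---------------------------------------------------------------------------
# Bootstrap and distribution summary
# ---------------------------------------------------------------------------

def bootstrap_interval(ratios: Sequence[float], n_draws: int = 146744,
                       alpha: float = 0.025, seed: int = 0) -> BootstrapInterval:
    """Pooled-resample percentile interval of the ratio distribution:
    ``n_draws`` resamples with replacement are pooled and the alpha and
    (1 - alpha) quantiles of the pool are the interval endpoints."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("ratio list is empty")
    rng = np.random.default_rng(seed)
    draws = rng.choice(ratios, size=n_draws, replace=True)
    lower = float(np.quantile(draws, alpha))
    upper = float(np.quantile(draws, 1.0 - alpha))
    return BootstrapInterval(n_draws, alpha, lower, upper, seed)


@dataclass
class KaKsSummary:
    n_pairs: int
    n_discarded: int
    median: float
    std: float
    class_counts: dict[str, int]
    histogram: tuple[list[float], list[int]]

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["histogram"] = {"bin_edges": self.histogram[0],
                          "counts": self.histogram[1]}
        return d


def summarize_kaks(results: Sequence[KaKsResult], bins: int = 25
                   ) -> KaKsSummary:
    """Distribution report over non-discarded ratios: median, standard
    deviation (ddof=1), a histogram and counts per selection class."""
    kept = [r.ratio for r in results if not r.discarded]
    n_disc = sum(1 for r in results if r.discarded)
    class_counts = {c: 0 for c in ("stabilizing", "intermediate", "diversifying")}
    for r in results:
        if not r.discarded:
            class_counts[r.selection_class] += 1
    if kept:
        counts, edges = np.histogram(kept, bins=bins)
        median = float(np.median(kept))
        std = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
        hist = (list(map(float, edges)), list(map(int, counts)))
    else:
        median, std, hist = float("nan"), float("nan"), ([], [])
    return KaKsSummary(len(kept), n_disc, median, std, class_counts, hist)
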