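"""I/O layer: FASTA round trips, pileup correctness against brute-force
recounts, the ungapped mapper against an exhaustive scan, and the
VCF/GFF3 coordinate conventions."""

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from estpoly import alnio
from estpoly.alnio import (
    FastaParseError, Placement, PlacementError, Read, build_pileup,
    map_reads_ungapped, read_fasta, revcomp, write_fasta,
)
import oracles


# --- FASTA ------------------------------------------------------------------

def test_fasta_round_trip(tmp_path):
    recs = [SeqRecord(Seq("ACGTACGT"), id="a", description=""),
            SeqRecord(Seq("TTTT"), id="b", description=""),
            SeqRecord(Seq("N" * 100), id="c", description="")]
    path = tmp_path / "x.fasta"
    write_fasta(recs, path)
    back = read_fasta(path)
    assert [(r.id, str(r.seq)) for r in back] == \
        [(r.id, str(r.seq)) for r in recs]


def test_fasta_empty_and_malformed(tmp_path):
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    assert read_fasta(empty) == []
    bad = tmp_path / "bad.fasta"
    bad.write_text("ACGT\n>a\nACGT\n")
    with pytest.raises(FastaParseError) as exc:
        read_fasta(bad)
    assert exc.value.line == 1


def test_fasta_lowercase_normalised(tmp_path, caplog):
    path = tmp_path / "lc.fasta"
    path.write_text(">a\nacgTACgt\n")
    with caplog.at_level("WARNING"):
        (rec,) = read_fasta(path)
    assert str(rec.seq) == "ACGTACGT"
    assert any("lowercase" in m for m in caplog.messages)


def test_reads_fasta_round_trip_keeps_source(tmp_path):
    reads = [Read("r1", "ACGT", "A"), Read("r2", "GGGG", "B"),
             Read("r3", "TTAA", None)]
    path = tmp_path / "reads.fasta"
    alnio.write_reads_fasta(reads, path)
    assert alnio.read_reads_fasta(path) == reads


# --- pileup -----------------------------------------------------------------

def test_single_read_pileup_columns():
    pile = build_pileup({"c": "ACGTACGT"},
                        [Placement("r", "c", 0)],
                        {"r": Read("r", "ACGT", "A")})
    cols = list(pile.columns())
    assert len(cols) == 4
    for col, base in zip(cols, "ACGT"):
        assert col.counts == {"A": {base: 1}}


def test_reverse_strand_placement_uses_revcomp():
    # a '-' placement stacks the reverse complement of the stored read
    contig = "AACCGGTTAA"
    read = Read("r", "AACCGG", "A")   # revcomp = CCGGTT, true site offset 2
    pile = build_pileup({"c": contig}, [Placement("r", "c", 2, "-")],
                        {"r": read})
    for pos, base in zip(range(2, 8), "CCGGTT"):
        assert pile.column("c", pos).counts["A"] == {base: 1}


def test_pileup_matches_brute_force_recount(rng):
    contig = "".join(rng.choice(list("ACGT"), size=300))
    reads, placements = {}, []
    for i in range(120):
        off = int(rng.integers(0, 280))
        length = int(rng.integers(20, 300 - off + 1).clip(20, 60))
        seq = contig[off:off + length]
        strand = "+" if rng.random() < 0.5 else "-"
        rid = f"r{i}"
        src = "A" if rng.random() < 0.5 else "B"
        reads[rid] = Read(rid, seq if strand == "+" else revcomp(seq), src)
        placements.append(Placement(rid, "c", off, strand))
    pile = build_pileup({"c": contig}, placements, reads)
    # brute recount with dictionaries
    expect: dict[tuple, Counter] = {}
    for p in placements:
        r = reads[p.read_id]
        seq = r.seq if p.strand == "+" else revcomp(r.seq)
        for j, b in enumerate(seq):
            expect.setdefault((p.offset + j, r.source), Counter())[b] += 1
    for (pos, src), counter in expect.items():
        col = pile.column("c", pos)
        assert col.counts.get(src, {}) == dict(counter)


def test_out_of_bounds_placement_rejected():
    with pytest.raises(PlacementError, match="r1"):
        build_pileup({"c": "ACGT"}, [Placement("r1", "c", 2)],
                     {"r1": Read("r1", "ACGT", "A")})


# --- ungapped mapper --------------------------------------------------------

def test_exact_substring_maps_with_zero_mismatches(rng):
    contig = "".join(rng.choice(list("ACGT"), size=500))
    read = Read("r", contig[100:180], None)
    result = map_reads_ungapped([read], {"c": contig})
    (hit,) = result.hits
    assert (hit.contig, hit.offset, hit.strand, hit.mismatches) == ("c", 100, "+", 0)


def test_two_mismatches_everywhere_is_unmapped():
    contig = "A" * 200
    read = Read("r", "A" * 30 + "CC" + "A" * 30, None)
    result = map_reads_ungapped([read], {"c": contig}, max_mismatch=1)
    assert result.hits == [] and result.unmapped == ["r"]


def test_repeat_region_read_is_discarded_as_ambiguous():
    contig = "TTTT" + "ACGTACGTACGTACGTACGTACGT" + "GGGG"
    read = Read("r", "ACGTACGTACGT", None)
    result = map_reads_ungapped([read], {"c": contig})
    assert result.ambiguous == ["r"]


def test_mapper_agrees_with_exhaustive_scan(rng):
    contigs = {f"c{i}": "".join(rng.choice(list("ACGT"), size=400))
               for i in range(3)}
    reads = []
    for i in range(60):
        cid = f"c{int(rng.integers(3))}"
        off = int(rng.integers(0, 340))
        seq = list(contigs[cid][off:off + 60])
        n_err = int(rng.integers(0, 3))   # 0-2 planted mismatches
        for pos in rng.choice(60, size=n_err, replace=False):
            seq[pos] = [b for b in "ACGT" if b != seq[pos]][int(rng.integers(3))]
        seq = "".join(seq)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(Read(f"r{i}", seq, None))
    result = map_reads_ungapped(reads, contigs)
    by_id = {h.read_id: h for h in result.hits}
    for read in reads:
        expected, status = oracles.brute_map(read.seq, contigs)
        if status == "mapped":
            hit = by_id[read.read_id]
            assert (hit.contig, hit.offset, hit.strand, hit.mismatches) == expected
        elif status == "ambiguous":
            assert read.read_id in result.ambiguous
        else:
            assert read.read_id in result.unmapped


def test_simulated_error_free_reads_place_at_true_offsets(clean_simulation):
    from estpoly.simulate import simulate_polyploid_reads
    cfg, refset, _, _ = clean_simulation
    reads, origins = simulate_polyploid_reads(refset, cfg)
    reads, origins = reads[:1000], origins[:1000]
    result = map_reads_ungapped(reads, refset.contigs)
    truth = {o.read_id: o for o in origins}
    correct = sum(1 for h in result.hits
                  if (h.contig, h.offset) == (truth[h.read_id].contig,
                                              truth[h.read_id].offset))
    assert correct / len(reads) >= 0.99


# --- VCF / GFF3 -------------------------------------------------------------

def _example_calls():
    from estpoly.snps import SnpCall
    return [SnpCall("c1", 99, "G", "A", 80, 20, 0.26, "transition", "CDS"),
            SnpCall("c1", 5, "C", "G", 10, 12, 0.454545, "transversion", "UTR")]


def test_vcf_positions_are_one_based(tmp_path):
    contigs = {"c1": "A" * 200}
    path = tmp_path / "x.vcf"
    alnio.write_vcf(_example_calls(), contigs, path)
    text = path.read_text()
    assert "\t100\t" in text   # 0-based 99 -> POS 100
    assert "\t6\t" in text


def test_vcf_round_trip(tmp_path):
    contigs = {"c1": "A" * 200}
    path = tmp_path / "x.vcf"
    calls = _example_calls()
    alnio.write_vcf(calls, contigs, path)
    assert alnio.read_vcf(path) == calls


def test_vcf_rejects_out_of_contig_position(tmp_path):
    from estpoly.snps import SnpCall
    bad = SnpCall("c1", 500, "G", "A", 8, 8, 0.5, "transition", "CDS")
    with pytest.raises(ValueError):
        alnio.write_vcf([bad], {"c1": "A" * 200}, tmp_path / "x.vcf")


def test_gff3_spans_are_one_based_inclusive(tmp_path):
    from estpoly.ssrs import SsrLocus, canonical_motif
    ssr = SsrLocus("c1", (10, 28), "AC", canonical_motif("AC"), 9)
    path = tmp_path / "x.gff3"
    alnio.write_gff3([ssr], path)
    line = path.read_text().splitlines()[1].split("\t")
    assert (line[3], line[4]) == ("11", "28")
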