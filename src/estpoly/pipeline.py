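"""End-to-end orchestration: simulate -> pileups -> SNPs -> SSRs ->
tetraploid classification -> Ka/Ks, under one structured configuration
with a single global seed and a reproducible run manifest.

Per-stage seeds are derived from the global seed by fixed offsets, so a
stage re-run in isolation reproduces its outputs.  The manifest records
the package version, all parameters and a SHA-256 digest of every
output file; identical configuration and seed give identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

import estpoly
from estpoly import alnio, kaks, polyploid, simulate, snps, ssrs

log = logging.getLogger("estpoly.pipeline")

STAGES = ("simulate", "snps", "ssrs", "tetraploid", "kaks")
#: stages each stage requires to have run first
DEPENDENCIES = {
    "simulate": (),
    "snps": ("simulate",),
    "ssrs": ("simulate",),
    "tetraploid": ("simulate", "snps"),
    "kaks": ("simulate",),
}


class PipelineDependencyError(RuntimeError):
    """An enabled stage whose prerequisite stage is disabled."""


@dataclass
class RunConfig:
    """One pipeline run: stage toggles, per-stage parameter blocks, the
    output directory and the global seed.  Stage defaults mirror the
    published thresholds (SNPs: depth 8 / MAF 20% / homogeneity 90%;
    SSRs: di=7, tri-octa=5, nona-deca=4, 100 bp interruption; polyploid:
    20x / 10%; Ka/Ks: +1 pseudocount, discard > 2.5, bootstrap at
    alpha = 0.025)."""

    outdir: Path
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)
    snp_params: snps.SnpCallingParams = field(
        default_factory=snps.SnpCallingParams)
    ssr_thresholds: ssrs.SsrThresholds = field(
        default_factory=ssrs.SsrThresholds)
    polyploid_params: polyploid.PolyploidParams = field(
        default_factory=polyploid.PolyploidParams)
    kaks_pseudocount: float = 1.0
    kaks_discard_above: float = kaks.DISCARD_ABOVE
    bootstrap_draws: int = 146744
    bootstrap_alpha: float = 0.025
    log_level: str = "INFO"

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        for stage, enabled in self.stages.items():
            if not enabled:
                continue
            for dep in DEPENDENCIES[stage]:
                if not self.stages.get(dep, False):
                    raise PipelineDependencyError(
                        f"stage '{stage}' requires stage '{dep}', which is disabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        if "simulation" in raw:
            sim = raw.pop("simulation")
            if "contig_length" in sim:
                sim["contig_length"] = tuple(sim["contig_length"])
            if "read_length" in sim:
                sim["read_length"] = tuple(sim["read_length"])
            if "ssr_plant_spec" in sim:
                sim["ssr_plant_spec"] = [tuple(x) for x in sim["ssr_plant_spec"]]
            kwargs["simulation"] = simulate.SimulationConfig(**sim)
        if "snp_params" in raw:
            kwargs["snp_params"] = snps.SnpCallingParams(**raw.pop("snp_params"))
        if "ssr_thresholds" in raw:
            t = raw.pop("ssr_thresholds")
            if "min_units" in t:
                t["min_units"] = {int(k): int(v) for k, v in t["min_units"].items()}
            kwargs["ssr_thresholds"] = ssrs.SsrThresholds(**t)
        if "polyploid_params" in raw:
            kwargs["polyploid_params"] = polyploid.PolyploidParams(
                **raw.pop("polyploid_params"))
        kwargs.update(raw)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    d = {f.name: enc(getattr(config, f.name))
         for f in dataclasses.fields(config)}
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the run
    manifest (also written to ``<outdir>/manifest.json``)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    enabled = [s for s in STAGES if config.stages.get(s, False)]

    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    refset = None
    reads = placements = None
    consensus_reads: dict[str, dict[str, str]] = {}
    pileups_by_source: dict[str, alnio.Pileup] = {}
    snp_calls: list[snps.SnpCall] = []

    def _source_pileups():
        """Per-source pileups on each source's own consensus coordinates."""
        if pileups_by_source:
            return pileups_by_source
        by_source: dict[str, tuple[dict, list]] = {}
        read_map = {r.read_id: r for r in reads}
        for src in (simulate.SOURCE_A, simulate.SOURCE_B):
            pls = [p for p in placements if read_map[p.read_id].source == src]
            pileups_by_source[src] = alnio.build_pileup(
                refset.consensus[src], pls, read_map)
        return pileups_by_source

    def _read_consensus(src: str) -> dict[str, str]:
        if src not in consensus_reads:
            pile = _source_pileups()[src]
            consensus_reads[src] = {
                c: ssrs.source_consensus(pile, src, c)
                for c in sorted(refset.consensus[src])}
        return consensus_reads[src]

    # ----- simulate ----------------------------------------------------
    if "simulate" in enabled:
        log.info("simulate: generating %d contigs (seed %d)",
                 sim_cfg.n_contigs, sim_cfg.seed)
        refset = simulate.generate_reference_set(sim_cfg)
        files.update(simulate.write_reference_set(refset, outdir))
        reads, placements = simulate.simulate_est_reads(refset, sim_cfg)
        files.update(simulate.write_simulated_reads(reads, placements, outdir))

    # ----- SNPs --------------------------------------------------------
    if "snps" in enabled:
        read_map = {r.read_id: r for r in reads}
        equal = {c: s for c, s in refset.contigs.items()
                 if len(refset.consensus[simulate.SOURCE_B][c]) == len(s)}
        pls = [p for p in placements if p.contig in equal]
        pile = alnio.build_pileup(equal, pls, read_map)
        diag = snps.CallDiagnostics()
        snp_calls = snps.call_discriminating_snps(
            pile, config.snp_params, refset.orfs, diag)
        log.info("snps: %d discriminating calls on %d contigs",
                 len(snp_calls), len(equal))
        files["snps_vcf"] = outdir / "snps.vcf"
        alnio.write_vcf(snp_calls, equal, files["snps_vcf"])
        summary = snps.summarize_snps(
            snp_calls, {c: len(s) for c, s in refset.contigs.items()})
        within = {src: len(snps.call_within_source_variants(
            _source_pileups()[src], src, config.snp_params))
            for src in (simulate.SOURCE_A, simulate.SOURCE_B)}
        files["snp_summary"] = outdir / "snp_summary.json"
        with open(files["snp_summary"], "w") as fh:
            json.dump({"summary": summary.to_dict(),
                       "within_source_variants": within,
                       "diagnostics": {
                           "zero_depth_source": diag.zero_depth_source,
                           "modal_tie": diag.modal_tie,
                           "third_base_positions": len(diag.third_base_positions)}},
                      fh, indent=1, sort_keys=True)

    # ----- SSRs --------------------------------------------------------
    if "ssrs" in enabled:
        loci_per_source = {}
        for src in (simulate.SOURCE_A, simulate.SOURCE_B):
            cons = _read_consensus(src)
            loci = [s for c in sorted(cons)
                    for s in ssrs.find_ssrs(cons[c], c, config.ssr_thresholds)]
            loci_per_source[src] = loci
        files["ssrs_gff3"] = outdir / "ssrs_A.gff3"
        alnio.write_gff3(loci_per_source[simulate.SOURCE_A], files["ssrs_gff3"])
        matrix = ssrs.summarize_ssrs(loci_per_source)
        files["ssr_matrix"] = outdir / "ssr_matrix.tsv"
        matrix.to_csv(files["ssr_matrix"], sep="\t")
        poly_rows, unresolved_n = [], 0
        cons_a, cons_b = _read_consensus("A"), _read_consensus("B")
        for c in sorted(cons_a):
            poly, unres = ssrs.compare_ssrs_between_sources(
                cons_a[c], cons_b[c], c, config.ssr_thresholds)
            unresolved_n += len(unres)
            poly_rows += [(p.contig, p.span[0], p.span[1], p.motif,
                           p.units_a, p.units_b, p.difference_type)
                          for p in poly]
        files["polymorphic_ssrs"] = outdir / "polymorphic_ssrs.tsv"
        pd.DataFrame(poly_rows, columns=["contig", "start", "end", "motif",
                                         "units_a", "units_b", "type"]
                     ).to_csv(files["polymorphic_ssrs"], sep="\t", index=False)
        log.info("ssrs: %d polymorphic, %d unresolved", len(poly_rows), unresolved_n)

    # ----- tetraploid --------------------------------------------------
    if "tetraploid" in enabled:
        poly_reads, origins = simulate.simulate_polyploid_reads(refset, sim_cfg)
        mapping = alnio.map_reads_ungapped(poly_reads, refset.contigs)
        read_map = {r.read_id: r for r in poly_reads}
        pile = alnio.build_pileup(refset.contigs, mapping.placements(),
                                  read_map, default_source="polyploid")
        verdicts = polyploid.classify_polyploid_snps(
            pile, snp_calls, config.polyploid_params)
        report = polyploid.summarize_ancestry(verdicts)
        log.info("tetraploid: %d/%d evaluable SNPs show both alleles",
                 report.counts["both"], report.n_evaluable)
        files["tetraploid_verdicts"] = outdir / "tetraploid_verdicts.tsv"
        pd.DataFrame([(v.contig, v.position, v.depth, v.fraction_a,
                       v.fraction_b, v.verdict) for v in verdicts],
                     columns=["contig", "position", "depth", "fraction_a",
                              "fraction_b", "verdict"]
                     ).to_csv(files["tetraploid_verdicts"], sep="\t", index=False)
        files["ancestry"] = outdir / "ancestry.json"
        with open(files["ancestry"], "w") as fh:
            json.dump({**report.to_dict(),
                       "n_reads": len(poly_reads),
                       "n_mapped": len(mapping.hits),
                       "n_ambiguous": len(mapping.ambiguous),
                       "n_unmapped": len(mapping.unmapped)},
                      fh, indent=1, sort_keys=True)

    # ----- Ka/Ks -------------------------------------------------------
    if "kaks" in enabled:
        cons_a, cons_b = _read_consensus("A"), _read_consensus("B")
        results = []
        for orf in refset.orfs:
            aln = kaks.codon_alignment_from_consensus(
                cons_a[orf.contig], cons_b[orf.contig], orf)
            if aln is None:
                continue
            try:
                results.append(kaks.analyze_pair(
                    aln, config.kaks_pseudocount, config.kaks_discard_above))
            except kaks.SaturationError:
                log.warning("kaks: %s saturated, excluded", orf.contig)
        files["kaks_results"] = outdir / "kaks.tsv"
        pd.DataFrame([(r.contig, r.syn_sites, r.nonsyn_sites, r.syn_subs,
                       r.nonsyn_subs, r.ka, r.ks, r.ratio, r.discarded,
                       r.selection_class) for r in results],
                     columns=["contig", "syn_sites", "nonsyn_sites", "syn_subs",
                              "nonsyn_subs", "ka", "ks", "ratio", "discarded",
                              "selection_class"]
                     ).to_csv(files["kaks_results"], sep="\t", index=False)
        summary = kaks.summarize_kaks(results)
        kept = [r.ratio for r in results if not r.discarded]
        interval = None
        if kept:
            interval = kaks.bootstrap_interval(
                kept, config.bootstrap_draws, config.bootstrap_alpha,
                seed=(config.seed + 3) % 2**31)
        files["kaks_summary"] = outdir / "kaks_summary.json"
        with open(files["kaks_summary"], "w") as fh:
            json.dump({"summary": summary.to_dict(),
                       "bootstrap": dataclasses.asdict(interval) if interval else None},
                      fh, indent=1, sort_keys=True)
        log.info("kaks: %d pairs, median %.4f", summary.n_pairs, summary.median)

    manifest = {
        "package": f"estpoly {estpoly.__version__}",
        "seed": config.seed,
        "stages": enabled,
        "parameters": _params_dict(config),
        "outputs": {name: {"path": str(p.relative_to(outdir)),
                           "sha256": _sha256(p)}
                    for name, p in sorted(files.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(outdir: str | Path) -> str:
    """Render the human-readable digest of a completed run: SNP summary,
    SSR matrix, ancestry report and Ka/Ks distribution.  Empty stages
    render as empty but well-formed tables.  The digest is also written
    to ``<outdir>/report.txt``."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    lines = [f"estpoly run report (seed {manifest['seed']})",
             f"stages: {', '.join(manifest['stages'])}", ""]

    snp_path = outdir / "snp_summary.json"
    if snp_path.exists():
        with open(snp_path) as fh:
            s = json.load(fh)["summary"]
        lines += ["== Discriminating SNPs ==",
                  f"total SNPs: {s['n_snps']}"]
        if s["n_snps"]:
            lines.append(f"density: 1 SNP / {s['density_bp_per_snp']:.0f} bp")
            total = s["n_snps"]
            lines.append("mutation type counts (% of total):")
            for cls, n in s["ts_tv_table"].items():
                lines.append(f"  {cls:4s} {n:6d}  {100 * n / total:5.2f}%")
            ts = s["n_transitions"]
            lines.append(f"transitions {ts} ({100 * ts / total:.1f}%), "
                         f"transversions {total - ts} "
                         f"({100 * (total - ts) / total:.1f}%)")
            lines.append("minor-allele-fraction bins: " + ", ".join(
                f"{k}: {v}" for k, v in s["maf_bins"].items()))
            lines.append(f"flagged contigs (>13 SNPs): "
                         f"{len(s['flagged_contigs'])}")
            lines.append("region counts: " + ", ".join(
                f"{k}: {v}" for k, v in sorted(s["region_counts"].items())))
        lines.append("")

    ssr_path = outdir / "ssr_matrix.tsv"
    if ssr_path.exists():
        lines += ["== SSR frequency matrix (rows: motif length; columns: units) =="]
        lines += [ln.rstrip("\n") for ln in open(ssr_path)]
        poly = pd.read_csv(outdir / "polymorphic_ssrs.tsv", sep="\t")
        lines += [f"polymorphic SSRs between sources: {len(poly)}", ""]

    anc_path = outdir / "ancestry.json"
    if anc_path.exists():
        with open(anc_path) as fh:
            a = json.load(fh)
        lines += ["== Tetraploid ancestry ==",
                  "verdict counts: " + ", ".join(
                      f"{k}: {v}" for k, v in sorted(a["counts"].items())),
                  f"both-allele fraction of evaluable SNPs: "
                  f"{a['both_fraction']:.3f} ({a['n_evaluable']} evaluable)",
                  f"contigs with both-verdicts: {a['n_contigs_with_both']}", ""]

    kk_path = outdir / "kaks_summary.json"
    if kk_path.exists():
        with open(kk_path) as fh:
            k = json.load(fh)
        s = k["summary"]
        lines += ["== Ka/Ks ==",
                  f"pairs analysed: {s['n_pairs']} "
                  f"(+{s['n_discarded']} discarded > 2.5)",
                  f"median: {s['median']:.4f}  sd: {s['std']:.4f}",
                  "selection classes: " + ", ".join(
                      f"{c}: {n}" for c, n in s["class_counts"].items())]
        if k.get("bootstrap"):
            b = k["bootstrap"]
            lines.append(f"bootstrap interval (alpha={b['alpha']}, "
                         f"{b['n_draws']} draws): "
                         f"[{b['lower']:.4f}, {b['upper']:.4f}]")
        lines.append("")

    text = "\n".join(lines)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(text)
    return text
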