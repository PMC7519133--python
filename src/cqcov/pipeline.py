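"""End-to-end orchestration: simulate -> count -> cq -> muller -> covmix -> report.

Every stage writes its outputs under a run directory together with a
provenance record (stage name, parameters, seed, tool version, input file
digests).  Outputs carry no timestamps, so re-running a configuration with
the same seed reproduces the run byte for byte.  The report stage combines
whatever stage outputs are present; it refuses to mix outputs whose
provenance seeds disagree.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import mixture as mix
from . import muller as mul
from .cq import CQConfig, CQTable, compute_cq, consensus_x, overlap_proportion, summarize_cq
from .matching import AlignmentCounts, ContigSet, ReadSet, count_exact, count_ident
from .simulate import (GenomeBlueprint, SampleSpec, SegmentSpec, build_genome,
                       make_anchor_table, read_anchor_table, read_truth_table,
                       simulate_reads, write_class_bed, write_table,
                       AUTOSOME, DUP_COLLAPSED, X_LINKED, Y_LINKED)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A run configuration failed validation; the message names the field."""


class StageError(RuntimeError):
    """A pipeline stage failed."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: library depths mirroring the study design: arrhenogenic female (AF),
#: thelygenic female (TF) and male (M) libraries at 43X / 34X / 28X.
STUDY_DEPTHS = {"AF": 43.0, "TF": 34.0, "M": 28.0}


@dataclass
class RunConfig:
    """Everything a pipeline run needs: inputs, thresholds and the seed."""

    outdir: Path
    seed: int = 0
    blueprint: GenomeBlueprint | None = None
    samples: list[SampleSpec] = field(default_factory=list)
    contigs_fasta: Path | None = None       # alternative to a blueprint
    reads_fastq: dict[str, Path] = field(default_factory=dict)
    anchors_tsv: Path | None = None
    cq: CQConfig = field(default_factory=CQConfig)
    band: tuple[float, float] = mul.XLINK_BAND
    flag_threshold: float = 0.5
    pseudocount: float = 0.5
    min_identity: float = 0.8
    max_cov: float = mix.MAX_COVERAGE
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.blueprint is None and self.contigs_fasta is None:
            raise ConfigError("config: one of 'genome' (blueprint) or "
                              "'contigs_fasta' is required")
        if self.blueprint is None:
            if not Path(self.contigs_fasta).exists():
                raise ConfigError(f"contigs_fasta: file not found: {self.contigs_fasta}")
            for sid, p in self.reads_fastq.items():
                if not Path(p).exists():
                    raise ConfigError(f"reads_fastq.{sid}: file not found: {p}")
            if self.anchors_tsv and not Path(self.anchors_tsv).exists():
                raise ConfigError(f"anchors_tsv: file not found: {self.anchors_tsv}")
        if not self.samples and not self.reads_fastq:
            raise ConfigError("samples: at least one sample is required")
        sexes = {s.sex_type for s in self.samples}
        if self.samples and "M" not in sexes:
            raise ConfigError("samples: a male (sex_type 'M') sample is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            cfg = cls._from_dict(raw, base=Path(path).parent)
        except (TypeError, KeyError) as exc:
            raise ConfigError(f"config: malformed field: {exc}") from exc
        cfg.validate()
        return cfg

    @classmethod
    def _from_dict(cls, raw: dict, base: Path) -> "RunConfig":
        if "outdir" not in raw:
            raise ConfigError("outdir: required")
        kw: dict = {"outdir": Path(raw["outdir"]), "seed": int(raw.get("seed", 0))}
        if "genome" in raw:
            g = raw["genome"]
            segments = [SegmentSpec(**s) for s in g["segments"]]
            kw["blueprint"] = GenomeBlueprint(
                segments, g.get("gc", 0.35), int(raw.get("seed", 0)))
        if "contigs_fasta" in raw:
            kw["contigs_fasta"] = base / raw["contigs_fasta"]
        if "reads_fastq" in raw:
            kw["reads_fastq"] = {k: base / v for k, v in raw["reads_fastq"].items()}
        if "anchors_tsv" in raw:
            kw["anchors_tsv"] = base / raw["anchors_tsv"]
        kw["samples"] = [SampleSpec(**s) for s in raw.get("samples", [])]
        if "cq" in raw:
            kw["cq"] = CQConfig(**raw["cq"])
        for key in ("flag_threshold", "pseudocount", "min_identity",
                    "max_cov", "log_level"):
            if key in raw:
                kw[key] = raw[key]
        if "band" in raw:
            kw["band"] = tuple(raw["band"])
        return cls(**kw)


def demo_blueprint(seed: int = 0) -> GenomeBlueprint:
    """The bundled 120-contig demonstration genome.

    90 autosomal contigs anchored across Muller elements A-F, 12 X-linked
    and 8 Y-linked contigs (two Y contigs carry a 10 % repetitive leak into
    the female genome) and 10 collapsed-duplication contigs.
    """
    segments: list[SegmentSpec] = []
    elements = "ABCDEF"
    for i in range(90):
        segments.append(SegmentSpec(f"auto{i:03d}", 3000, AUTOSOME,
                                    muller_element=elements[i % 6]))
    for i in range(12):
        segments.append(SegmentSpec(f"xlin{i:02d}", 4000, X_LINKED))
    for i in range(8):
        segments.append(SegmentSpec(f"ylin{i:02d}", 3000, Y_LINKED,
                                    y_leak=0.1 if i < 2 else 0.0))
    for i in range(10):
        segments.append(SegmentSpec(f"dupc{i:02d}", 4000, DUP_COLLAPSED))
    return GenomeBlueprint(segments, base_composition=0.35, seed=seed)


def demo_config(outdir, seed: int = 0) -> RunConfig:
    """A complete synthetic end-to-end configuration at the study depths."""
    samples = [
        SampleSpec("AF", "AF", STUDY_DEPTHS["AF"], 100, 0.0, seed * 7919 + 1),
        SampleSpec("TF", "TF", STUDY_DEPTHS["TF"], 100, 0.0, seed * 7919 + 2),
        SampleSpec("M", "M", STUDY_DEPTHS["M"], 100, 0.0, seed * 7919 + 3),
    ]
    cfg = RunConfig(outdir=Path(outdir), seed=seed,
                    blueprint=demo_blueprint(seed), samples=samples)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_provenance(outdir: Path, stage: str, seed: int, params: dict,
                      inputs: list[Path], outputs: list[Path]) -> None:
    prov_dir = outdir / "provenance"
    prov_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "parameters": params,
        "inputs": {p.name: _digest(p) for p in sorted(inputs)},
        "outputs": sorted(p.name for p in outputs),
    }
    (prov_dir / f"{stage}.json").write_text(
        json.dumps(record, sort_keys=True, indent=1, default=str) + "\n")


def _check_provenance(outdir: Path) -> int:
    """Return the common seed of all stage records; refuse a mixed bundle."""
    prov_dir = Path(outdir) / "provenance"
    seeds = set()
    for p in sorted(prov_dir.glob("*.json")):
        seeds.add(json.loads(p.read_text())["seed"])
    if len(seeds) > 1:
        raise StageError(f"provenance seeds disagree across stages: {sorted(seeds)}")
    if not seeds:
        raise StageError("no stage provenance found")
    return seeds.pop()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> tuple[ContigSet, pd.DataFrame, dict[str, ReadSet]]:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("stage simulate: building genome and %d read libraries",
             len(cfg.samples))
    genome, truth = build_genome(cfg.blueprint)
    genome.to_fasta(out / "contigs.fasta")
    write_table(truth, out / "truth.tsv")
    write_class_bed(truth, out / "classes.bed")
    anchors = make_anchor_table(truth, seed=cfg.seed)
    write_table(anchors, out / "anchors.tsv")
    reads: dict[str, ReadSet] = {}
    outputs = [out / "contigs.fasta", out / "truth.tsv", out / "classes.bed",
               out / "anchors.tsv"]
    for spec in cfg.samples:
        rs = simulate_reads(genome, truth, spec)
        rs.to_fastq(out / f"reads_{spec.sample_id}.fastq")
        outputs.append(out / f"reads_{spec.sample_id}.fastq")
        reads[spec.sample_id] = rs
    _write_provenance(out, "simulate", cfg.seed,
                      {"samples": [asdict(s) for s in cfg.samples],
                       "n_segments": len(cfg.blueprint.segments),
                       "gc": cfg.blueprint.base_composition},
                      [], outputs)
    return genome, truth, reads


def stage_count(cfg: RunConfig, genome: ContigSet, anchors: pd.DataFrame,
                reads: dict[str, ReadSet]) -> tuple[dict, dict]:
    out = Path(cfg.outdir)
    log.info("stage count: EXACT whole-genome and IDENT80 anchored-contig counts")
    anchored = genome.subset([c for c in anchors["contig"] if c in genome])
    exact: dict[str, AlignmentCounts] = {}
    ident: dict[str, AlignmentCounts] = {}
    outputs = []
    for sid, rs in reads.items():
        exact[sid] = count_exact(rs, genome)
        exact[sid].write_tsv(out / f"counts_exact_{sid}.tsv")
        ident[sid] = count_ident(rs, anchored, cfg.min_identity)
        ident[sid].write_tsv(out / f"counts_ident_{sid}.tsv")
        outputs += [out / f"counts_exact_{sid}.tsv", out / f"counts_ident_{sid}.tsv"]
    _write_provenance(out, "count", cfg.seed,
                      {"min_identity": cfg.min_identity},
                      [out / "contigs.fasta", out / "anchors.tsv"], outputs)
    return exact, ident


def stage_cq(cfg: RunConfig, genome: ContigSet,
             exact: dict[str, AlignmentCounts]) -> dict[str, CQTable]:
    out = Path(cfg.outdir)
    male_ids = [s.sample_id for s in cfg.samples if s.sex_type == "M"]
    female_ids = [s.sample_id for s in cfg.samples if s.sex_type != "M"]
    if not male_ids or not female_ids:
        raise StageError("cq stage needs one male and at least one female library")
    male = exact[male_ids[0]]
    tables: dict[str, CQTable] = {}
    outputs = []
    for fid in female_ids:
        log.info("stage cq: chromosome quotients for %s vs %s", fid, male_ids[0])
        table = compute_cq(exact[fid], male, cfg.cq)
        table.write_tsv(out / f"cq_{fid}.tsv")
        summary = summarize_cq(table)
        write_table(summary, out / f"cq_summary_{fid}.tsv")
        outputs += [out / f"cq_{fid}.tsv", out / f"cq_summary_{fid}.tsv"]
        for call, stem in ((  "PUTATIVE_X", "putative_x"), ("PUTATIVE_Y", "putative_y")):
            names = table.putative(call)
            if names:
                genome.subset(names).to_fasta(out / f"{stem}_{fid}.fasta")
                outputs.append(out / f"{stem}_{fid}.fasta")
        tables[fid] = table
    if len(tables) == 2:
        fa, fb = female_ids
        xa, xb = (tables[f].putative("PUTATIVE_X") for f in (fa, fb))
        if xa and xb:
            reps, pairs = consensus_x(genome.subset(xa), genome.subset(xb))
            if reps is not None:
                reps.to_fasta(out / "consensus_x.fasta")
                outputs.append(out / "consensus_x.fasta")
            write_table(pairs, out / "consensus_x_pairs.tsv")
            outputs.append(out / "consensus_x_pairs.tsv")
        y_overlap = overlap_proportion(tables[fa].putative("PUTATIVE_Y"),
                                       tables[fb].putative("PUTATIVE_Y"))
        (out / "y_overlap.json").write_text(
            json.dumps({"proportion_overlap": y_overlap}, indent=1) + "\n")
        outputs.append(out / "y_overlap.json")
    _write_provenance(out, "cq", cfg.seed, asdict(cfg.cq),
                      [out / "contigs.fasta"], outputs)
    return tables


def stage_muller(cfg: RunConfig, anchors: pd.DataFrame,
                 ident: dict[str, AlignmentCounts]) -> pd.DataFrame:
    out = Path(cfg.outdir)
    male_ids = [s.sample_id for s in cfg.samples if s.sex_type == "M"]
    female_ids = [s.sample_id for s in cfg.samples if s.sex_type != "M"]
    log.info("stage muller: log2(M/F) linkage over %d anchored contigs",
             len(anchors))
    male = ident[male_ids[0]]
    females = [ident[f] for f in female_ids]
    female = mul.pool_counts(females) if len(females) > 1 else females[0]
    linkage = mul.log2_mf(male, female, anchors,
                          pseudocount=cfg.pseudocount, band=cfg.band)
    linkage.write_tsv(out / "muller_linkage.tsv")
    report = mul.element_report(linkage, cfg.flag_threshold)
    write_table(report, out / "muller_elements.tsv")
    # pseudocount sensitivity: X-linked fractions under half/double epsilon
    sens = {}
    for eps in (cfg.pseudocount / 2, cfg.pseudocount * 2):
        alt = mul.log2_mf(male, female, anchors, pseudocount=eps, band=cfg.band)
        sens[f"eps={eps:g}"] = float(alt.table["xlinked"].mean())
    (out / "muller_sensitivity.json").write_text(
        json.dumps({"xlinked_fraction": {f"eps={cfg.pseudocount:g}":
                                         float(linkage.table["xlinked"].mean()),
                                         **sens}}, sort_keys=True, indent=1) + "\n")
    _write_provenance(out, "muller", cfg.seed,
                      {"band": list(cfg.band), "pseudocount": cfg.pseudocount,
                       "flag_threshold": cfg.flag_threshold,
                       "female_pooling": len(females) > 1},
                      [out / "anchors.tsv"],
                      [out / "muller_linkage.tsv", out / "muller_elements.tsv",
                       out / "muller_sensitivity.json"])
    return report


def stage_covmix(cfg: RunConfig, exact: dict[str, AlignmentCounts]) -> dict[str, dict]:
    out = Path(cfg.outdir)
    results: dict[str, dict] = {}
    outputs = []
    for sid, counts in exact.items():
        log.info("stage covmix: coverage mixture for %s", sid)
        hist = mix.build_histogram(counts)
        hist.to_csv(out / f"coverage_{sid}.tsv", sep="\t", index=False,
                    float_format="%.6g")
        fit = mix.fit_mixture(hist, seed=cfg.seed, max_cov=cfg.max_cov)
        est = mix.genome_size(fit, hist)
        payload = {"fit": fit.to_dict(), "genome_size": est.to_dict()}
        (out / f"covmix_{sid}.json").write_text(
            json.dumps(payload, sort_keys=True, indent=1) + "\n")
        outputs += [out / f"coverage_{sid}.tsv", out / f"covmix_{sid}.json"]
        results[sid] = payload
    _write_provenance(out, "covmix", cfg.seed, {"max_cov": cfg.max_cov},
                      [], outputs)
    return results


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def make_report(outdir) -> dict:
    """Combine whatever stage outputs exist into report.json / report.md."""
    out = Path(outdir)
    seed = _check_provenance(out)
    report: dict = {"seed": seed, "version": __version__}

    truth = None
    if (out / "truth.tsv").exists():
        truth = read_truth_table(out / "truth.tsv")

    cq_section = {}
    for path in sorted(out.glob("cq_summary_*.tsv")):
        fid = path.stem.replace("cq_summary_", "")
        cq_section[fid] = pd.read_csv(path, sep="\t").to_dict("records")
        if truth is not None and (out / f"cq_{fid}.tsv").exists():
            table = pd.read_csv(out / f"cq_{fid}.tsv", sep="\t")
            merged = table.merge(truth, left_on="contig", right_on="name")
            conf = pd.crosstab(merged["klass"], merged["call"])
            cq_section[fid + "_confusion"] = {
                str(k): {str(c): int(v) for c, v in row.items()}
                for k, row in conf.to_dict("index").items()}
    if (out / "y_overlap.json").exists():
        cq_section["y_overlap"] = json.loads((out / "y_overlap.json").read_text())
    if cq_section:
        report["cq"] = cq_section

    if (out / "muller_elements.tsv").exists():
        report["muller"] = pd.read_csv(out / "muller_elements.tsv",
                                       sep="\t").to_dict("records")
    covmix = {}
    for path in sorted(out.glob("covmix_*.json")):
        covmix[path.stem.replace("covmix_", "")] = json.loads(path.read_text())
    if covmix:
        report["covmix"] = covmix

    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1) + "\n")
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# Pipeline report", "",
             f"seed: {report['seed']}  |  cqcov {report['version']}", ""]
    if "cq" in report:
        lines.append("## Chromosome quotients")
        for fid, rows in report["cq"].items():
            if fid.endswith("_confusion") or fid == "y_overlap":
                continue
            lines.append(f"\n### female {fid} vs male\n")
            lines.append("| call | contigs | total bases |")
            lines.append("|---|---:|---:|")
            for r in rows:
                lines.append(f"| {r['call']} | {r['n_contigs']} | {r['total_bases']} |")
        if "y_overlap" in report["cq"]:
            p = report["cq"]["y_overlap"]["proportion_overlap"]
            lines.append(f"\nputative-Y overlap between female comparisons: {p:.3f}")
        lines.append("")
    if "muller" in report:
        lines.append("## Muller element X-linkage\n")
        lines.append("| element | contigs | X-linked | fraction | sex-linked |")
        lines.append("|---|---:|---:|---:|---|")
        for r in report["muller"]:
            lines.append(f"| {r['element']} | {r['n_contigs']} | {r['n_xlinked']} "
                         f"| {r['fraction_xlinked']:.3f} | {r['sex_linked']} |")
        lines.append("")
    if "covmix" in report:
        lines.append("## Coverage mixtures and genome size\n")
        lines.append("| sample | modes | means (X) | cutoff | assembled (bp) | estimate (bp) |")
        lines.append("|---|---:|---|---:|---:|---:|")
        for sid, payload in report["covmix"].items():
            fit, est = payload["fit"], payload["genome_size"]
            means = ", ".join(f"{m:.1f}" for m in fit["means"])
            cut = f"{fit['cutoff']:.1f}" if fit["cutoff"] else "-"
            lines.append(f"| {sid} | {fit['n_components']} | {means} | {cut} "
                         f"| {est['assembled_bases']} | {est['estimate']} |")
        lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and return the combined report."""
    cfg.validate()
    logging.getLogger("cqcov").setLevel(cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if cfg.blueprint is not None:
            genome, truth, reads = stage_simulate(cfg)
            anchors = read_anchor_table(out / "anchors.tsv")
        else:
            genome = ContigSet.from_fasta(cfg.contigs_fasta)
            truth = None
            anchors = (read_anchor_table(cfg.anchors_tsv)
                       if cfg.anchors_tsv else pd.DataFrame(columns=["contig", "element"]))
            reads = {sid: ReadSet.from_fastq(p, sid)
                     for sid, p in cfg.reads_fastq.items()}
        stage = "count"
        exact, ident = stage_count(cfg, genome, anchors, reads)
        stage = "cq"
        stage_cq(cfg, genome, exact)
        if len(anchors):
            stage = "muller"
            stage_muller(cfg, anchors, ident)
        stage = "covmix"
        stage_covmix(cfg, exact)
        stage = "report"
        return make_report(out)
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc
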