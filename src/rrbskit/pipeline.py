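"""One-step pipeline orchestration with resume-able stages and QC report.

A single YAML configuration drives every stage: reference preparation,
read trimming, simulation (or externally supplied alignments),
methylation calling, DMC/DMR detection, ASM detection and the summary
report. Each completed stage writes a marker containing a checksum of
its inputs and parameters; re-running skips stages whose marker,
checksum and outputs are intact, so an interrupted run resumes where it
stopped. All stages are deterministic under the configured seed, so a
resumed run reproduces a fresh one byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from rrbskit import asm as asm_mod
from rrbskit import dmr as dmr_mod
from rrbskit import reads as reads_mod
from rrbskit import simulate as sim_mod
from rrbskit.methylation import Methylome, pileup_methylation
from rrbskit.reference import (Genome, RestrictionEnzyme, convert_reference,
                               digest, index_cytosines, write_fragments_bed)

log = logging.getLogger("rrbskit")


class ConfigError(ValueError):
    pass


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see ``example_config`` for the schema."""

    raw: dict
    path: Optional[Path] = None

    def __post_init__(self):
        c = self.raw
        _require(isinstance(c.get("output_dir"), str), "output_dir is required")
        self.output_dir = Path(c["output_dir"])
        self.seed = int(c.get("seed", 1))
        ref = c.get("reference") or {}
        _require("fasta" in ref or "synthetic" in ref,
                 "reference needs 'fasta' or 'synthetic'")
        self.reference = ref
        enz = ref.get("enzymes", ["MspI:CCGG:1"])
        self.enzymes = [RestrictionEnzyme.from_string(e) for e in enz]
        self.min_fragment = int(ref.get("min_fragment", 40))
        self.max_fragment = int(ref.get("max_fragment", 220))
        _require(1 <= self.min_fragment <= self.max_fragment,
                 "fragment length window invalid")
        self.trim = c.get("trim")
        self.simulate = c.get("simulate")
        self.alignments = c.get("alignments", [])
        meth = c.get("methylation") or {}
        self.min_mapq = int(meth.get("min_mapq", 20))
        self.min_baseq = int(meth.get("min_baseq", 13))
        self.dedup = bool(meth.get("dedup", True))
        dmr = c.get("dmr") or {}
        self.alpha = float(dmr.get("alpha", 0.05))
        self.min_delta = float(dmr.get("min_delta", 0.1))
        self.seed_size = int(dmr.get("seed_size", 5))
        self.dmr_samples = dmr.get("samples")
        _require(0 < self.alpha <= 1, "alpha must be in (0, 1]")
        _require(0 <= self.min_delta < 1, "min_delta must be in [0, 1)")
        _require(self.seed_size >= 1, "seed_size must be >= 1")
        asm = c.get("asm") or {}
        self.asm_sample = asm.get("sample")
        self.asm_vcf = asm.get("vcf")
        rep = c.get("report") or {}
        self.islands_bed = rep.get("islands_bed")
        self.thresholds = [int(t) for t in rep.get("thresholds", [1, 4, 10, 20])]
        _require(self.thresholds == sorted(self.thresholds),
                 "report thresholds must be increasing")
        self.max_decay = float(rep.get("max_decay", 0.5))
        if self.simulate:
            rl = int(self.simulate.get("read_length", 90))
            _require(1 <= rl, "read_length must be positive")
            cov = float(self.simulate.get("coverage", 10))
            _require(cov > 0, "coverage must be positive")
            _require(self.simulate.get("samples"),
                     "simulate needs at least one sample")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls(raw, Path(path))


def example_config(output_dir: str = "rrbskit_out") -> dict:
    """A complete configuration with every default filled in."""
    return {
        "seed": 1,
        "output_dir": output_dir,
        "reference": {
            "synthetic": {"length": 200_000, "gc": 0.42, "name": "chrSim"},
            "enzymes": ["MspI:CCGG:1"],
            "min_fragment": 40,
            "max_fragment": 220,
        },
        "simulate": {
            "read_length": 90,
            "coverage": 10,
            "layout": "PE",
            "snp_rate": 0.0005,
            "conversion_rate": 1.0,
            "error_rate": 0.0,
            "samples": [
                {"name": "normal", "segments": "random"},
                {"name": "cancer", "segments": "random"},
            ],
        },
        "methylation": {"min_mapq": 20, "min_baseq": 13, "dedup": True},
        "dmr": {"alpha": 0.05, "min_delta": 0.1, "seed_size": 5,
                "samples": ["cancer", "normal"]},
        "asm": {"sample": "cancer", "vcf": None},
        "report": {"islands_bed": None, "thresholds": [1, 4, 10, 20],
                   "max_decay": 0.5},
    }


# --- resume machinery -----------------------------------------------------

def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_checksum(params: dict, input_files: Sequence[Path]) -> str:
    h = hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode())
    for f in input_files:
        h.update(str(f).encode())
        h.update(_sha256_file(f).encode())
    return h.hexdigest()


class StageRunner:
    def __init__(self, out_dir: Path):
        self.marker_dir = out_dir / ".markers"
        self.marker_dir.mkdir(parents=True, exist_ok=True)

    def should_run(self, name: str, checksum: str,
                   outputs: Sequence[Path]) -> bool:
        marker = self.marker_dir / f"{name}.json"
        if not marker.exists():
            return True
        try:
            recorded = json.loads(marker.read_text())["checksum"]
        except (KeyError, json.JSONDecodeError):
            return True
        if recorded != checksum:
            log.info("stage %s: inputs changed, re-running", name)
            return True
        missing = [p for p in outputs if not p.exists()]
        if missing:
            log.info("stage %s: missing outputs %s, re-running", name,
                     [str(m) for m in missing])
            return True
        log.info("stage %s: up to date, skipped", name)
        return False

    def mark_done(self, name: str, checksum: str) -> None:
        (self.marker_dir / f"{name}.json").write_text(
            json.dumps({"checksum": checksum}))


# --- QC / coverage report -------------------------------------------------

@dataclass
class CoverageSummary:
    sample: str
    n_sites: dict
    mean_depth: float
    island_fractions: dict  # threshold -> fraction of island CpG cytosines
    qc_verdict: str = "pass"

    def as_dict(self) -> dict:
        return {"sample": self.sample, "n_sites": self.n_sites,
                "mean_depth": self.mean_depth,
                "island_fractions": {str(k): v
                                     for k, v in self.island_fractions.items()},
                "qc_verdict": self.qc_verdict}


def read_bed(path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return list(df.itertuples(index=False, name=None))


def coverage_report(methylome: Methylome,
                    islands: Sequence[tuple[str, int, int]],
                    index,
                    thresholds: Sequence[int] = (1, 4, 10, 20),
                    max_decay: float = 0.5) -> Optional[CoverageSummary]:
    """Fraction of CpG-island cytosines covered at each depth threshold.

    The denominator is every CpG-context cytosine of the reference that
    lies in an island; a slowly decaying fraction across thresholds
    indicates sufficient, evenly distributed sequencing, and the QC
    verdict is "warn" when any consecutive relative drop exceeds
    ``max_decay``.
    """
    n_sites: dict[str, int] = {}
    depths = []
    for s in methylome.sites():
        n_sites[s.context] = n_sites.get(s.context, 0) + 1
        depths.append(s.total)
    mean_depth = float(sum(depths) / len(depths)) if depths else 0.0
    if not islands:
        log.warning("empty island set; coverage report skipped")
        return None
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in islands:
        by_chrom.setdefault(chrom, []).append((start, end))
    island_cpgs: list[tuple[str, int, str]] = []
    for chrom, pos, strand, ctx in index:
        if ctx != "CpG":
            continue
        if any(s <= pos < e for s, e in by_chrom.get(chrom, [])):
            island_cpgs.append((chrom, pos, strand))
    fractions: dict[int, float] = {}
    for t in thresholds:
        if island_cpgs:
            covered = sum(1 for (c, p, st) in island_cpgs
                          if (site := methylome.get(c, p, st)) is not None
                          and site.total >= t)
            fractions[t] = covered / len(island_cpgs)
        else:
            fractions[t] = 0.0
    verdict = "pass"
    fr = list(fractions.values())
    for prev, nxt in zip(fr, fr[1:]):
        if prev > 0 and (prev - nxt) / prev > max_decay:
            verdict = "warn"
    return CoverageSummary(methylome.sample, n_sites, mean_depth,
                           fractions, verdict)


def write_coverage_tsv(summary: CoverageSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tfraction_island_cpgs_covered\n")
        for t, f in summary.island_fractions.items():
            fh.write(f"{t}\t{f:.6f}\n")


# --- pipeline -------------------------------------------------------------

def _load_reference(cfg: PipelineConfig) -> Genome:
    ref = cfg.reference
    if "fasta" in ref:
        return Genome.from_fasta(ref["fasta"])
    syn = ref["synthetic"]
    return sim_mod.random_genome(int(syn["length"]), cfg.seed,
                                 float(syn.get("gc", 0.42)),
                                 syn.get("name", "chrSim"))


def _sample_segments(spec, fragments, rng) -> list[sim_mod.SegmentSpec]:
    """Explicit segment list, or a random rate per target fragment."""
    if spec == "random" or spec is None:
        return [sim_mod.SegmentSpec(f.chrom, f.start, f.end,
                                    float(rng.random())) for f in fragments]
    return [sim_mod.SegmentSpec(s["chrom"], int(s["start"]), int(s["end"]),
                                float(s["rate"])) for s in spec]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages in dependency order; returns artifact paths.

    Stage order: reference preparation -> read trimming (optional) ->
    simulation or external alignments -> methylation -> DMC/DMR -> ASM
    -> report. Missing upstream artifacts raise stage-level errors
    naming the file.
    """
    import numpy as np

    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    runner = StageRunner(out)
    artifacts: dict[str, object] = {}
    config_files = [cfg.path] if cfg.path and cfg.path.exists() else []

    # --- reference preparation
    ref_dir = out / "ref"
    ref_dir.mkdir(exist_ok=True)
    targets_bed = ref_dir / "targets.bed"
    ct_fa, ga_fa = ref_dir / "converted_CT.fa", ref_dir / "converted_GA.fa"
    params = {"reference": cfg.reference, "seed": cfg.seed,
              "min_fragment": cfg.min_fragment, "max_fragment": cfg.max_fragment}
    ref_inputs = [Path(cfg.reference["fasta"])] if "fasta" in cfg.reference else []
    for f in ref_inputs:
        if not f.exists():
            raise FileNotFoundError(f"reference stage: missing input {f}")
    checksum = _stage_checksum(params, ref_inputs + config_files)
    genome = _load_reference(cfg)
    fragments = digest(genome, cfg.enzymes, cfg.min_fragment, cfg.max_fragment)
    index = index_cytosines(genome)
    if runner.should_run("prepare_ref", checksum, [targets_bed, ct_fa, ga_fa]):
        ct, ga = convert_reference(genome)
        ct.to_fasta(ct_fa)
        ga.to_fasta(ga_fa)
        write_fragments_bed(fragments, targets_bed)
        runner.mark_done("prepare_ref", checksum)
    artifacts["targets_bed"] = targets_bed
    log.info("reference: %d target fragments", len(fragments))

    # --- read trimming (external-alignment path; hook for the aligner)
    if cfg.trim:
        trim_dir = out / "trim"
        trim_dir.mkdir(exist_ok=True)
        t = cfg.trim
        in1 = Path(t["fastq1"])
        if not in1.exists():
            raise FileNotFoundError(f"trim stage: missing input {in1}")
        in2 = Path(t["fastq2"]) if t.get("fastq2") else None
        if in2 is not None and not in2.exists():
            raise FileNotFoundError(f"trim stage: missing input {in2}")
        out1 = trim_dir / "clean_1.fastq"
        out2 = trim_dir / "clean_2.fastq" if in2 else None
        report = trim_dir / "trim_report.json"
        checksum = _stage_checksum({"trim": t},
                                   [in1] + ([in2] if in2 else []) + config_files)
        outputs = [out1, report] + ([out2] if out2 else [])
        if runner.should_run("trim", checksum, outputs):
            stats = reads_mod.clean_reads(
                in1, out1, in2, out2,
                adaptor=t.get("adaptor"),
                q_threshold=int(t.get("q_threshold", 20)),
                min_len=int(t.get("min_len", 20)))
            report.write_text(json.dumps(stats.as_dict(), indent=1))
            runner.mark_done("trim", checksum)
        artifacts["clean_fastq"] = [out1] + ([out2] if out2 else [])

    # --- alignments: simulate, or take external SAM/BAM
    sample_sams: dict[str, Path] = {}
    truth_vcfs: dict[str, Path] = {}
    if cfg.simulate:
        sim_dir = out / "sim"
        sim_dir.mkdir(exist_ok=True)
        s = cfg.simulate
        for i, sample in enumerate(s["samples"]):
            name = sample["name"]
            prefix = sim_dir / name
            sam_path = Path(str(prefix) + ".truth.sam")
            outputs = [sam_path, Path(str(prefix) + ".truth.vcf"),
                       Path(str(prefix) + ".truth_meth.tsv")]
            params = {"simulate": s, "sample": sample, "seed": cfg.seed,
                      "reference": cfg.reference}
            checksum = _stage_checksum(params, ref_inputs + config_files)
            if runner.should_run(f"simulate_{name}", checksum, outputs):
                sample_seed = cfg.seed * 1000 + i
                rng = np.random.default_rng(sample_seed)
                segments = _sample_segments(sample.get("segments"),
                                            fragments, rng)
                site_rates = sim_mod.assign_methylation(index, segments)
                config = sim_mod.SimulationConfig(
                    seed=sample_seed,
                    snp_rate=float(s.get("snp_rate", 0.0005)),
                    read_length=int(s.get("read_length", 90)),
                    coverage=float(s.get("coverage", 10)),
                    layout=s.get("layout", "PE"),
                    conversion_rate=float(s.get("conversion_rate", 1.0)),
                    error_rate=float(s.get("error_rate", 0.0)))
                asm_segments = [sim_mod.ASMSegmentSpec(
                    a["chrom"], int(a["start"]), int(a["end"]),
                    float(a["rate_ref"]), float(a["rate_alt"]),
                    float(a.get("allele_fraction", 0.5)))
                    for a in sample.get("asm_segments", [])]
                sim_mod.simulate_reads(genome, fragments, config, prefix,
                                       site_rates=site_rates,
                                       asm_segments=asm_segments,
                                       index=index, sample=name, rng=rng)
                runner.mark_done(f"simulate_{name}", checksum)
            sample_sams[name] = sam_path
            truth_vcfs[name] = Path(str(prefix) + ".truth.vcf")
    for entry in cfg.alignments:
        sam = Path(entry["sam"])
        if not sam.exists():
            raise FileNotFoundError(f"methylation stage: missing alignment {sam}")
        sample_sams[entry["name"]] = sam

    # --- methylation calling
    meth_dir = out / "meth"
    meth_dir.mkdir(exist_ok=True)
    methylomes: dict[str, Methylome] = {}
    for name, sam in sample_sams.items():
        tsv = meth_dir / f"{name}.cytosine.tsv"
        bg = meth_dir / f"{name}.bedgraph"
        params = {"min_mapq": cfg.min_mapq, "min_baseq": cfg.min_baseq,
                  "dedup": cfg.dedup}
        checksum = _stage_checksum(params, [sam] + config_files)
        if runner.should_run(f"methylation_{name}", checksum, [tsv, bg]):
            meth = pileup_methylation(str(sam), index, dedup=cfg.dedup,
                                      min_mapq=cfg.min_mapq,
                                      min_baseq=cfg.min_baseq,
                                      fragments=fragments, sample=name)
            meth.write_tsv(tsv)
            meth.write_bedgraph(bg)
            log.info("methylation %s: %d sites, %d discordant overlaps",
                     name, len(meth), meth.discordant_overlaps)
            runner.mark_done(f"methylation_{name}", checksum)
            methylomes[name] = meth
        else:
            methylomes[name] = Methylome.from_tsv(tsv, name)
    artifacts["methylomes"] = methylomes

    # --- DMC / DMR detection
    names = cfg.dmr_samples or list(sample_sams)
    if len(names) >= 2:
        dmr_dir = out / "dmr"
        dmr_dir.mkdir(exist_ok=True)
        n1, n2 = names[0], names[1]
        dmc_tsv, dmr_tsv = dmr_dir / "dmc.tsv", dmr_dir / "dmr.tsv"
        params = {"alpha": cfg.alpha, "min_delta": cfg.min_delta,
                  "seed_size": cfg.seed_size, "samples": [n1, n2]}
        inputs = [meth_dir / f"{n}.cytosine.tsv" for n in (n1, n2)]
        checksum = _stage_checksum(params, inputs + config_files)
        if runner.should_run("dmr", checksum, [dmc_tsv, dmr_tsv]):
            dmcs, regions = dmr_mod.call_dmcs_dmrs(
                methylomes[n1], methylomes[n2], cfg.alpha, cfg.min_delta,
                cfg.seed_size)
            dmr_mod.write_dmc_tsv(dmcs, dmc_tsv)
            dmr_mod.write_dmr_tsv(regions, dmr_tsv)
            log.info("dmr: %d DMCs, %d DMRs",
                     sum(d.is_dmc for d in dmcs), len(regions))
            runner.mark_done("dmr", checksum)
        artifacts["dmr_tsv"] = dmr_tsv

    # --- ASM detection
    asm_sample = cfg.asm_sample or (next(iter(sample_sams)) if sample_sams
                                    else None)
    if asm_sample is not None and asm_sample in sample_sams:
        asm_dir = out / "asm"
        asm_dir.mkdir(exist_ok=True)
        asm_tsv = asm_dir / "asm.tsv"
        vcf = cfg.asm_vcf or truth_vcfs.get(asm_sample)
        sam = sample_sams[asm_sample]
        params = {"alpha": cfg.alpha, "min_delta": cfg.min_delta,
                  "sample": asm_sample, "vcf": str(vcf)}
        inputs = [sam] + ([Path(vcf)] if vcf else [])
        checksum = _stage_checksum(params, inputs + config_files)
        if runner.should_run("asm", checksum, [asm_tsv]):
            if vcf is not None:
                snps = asm_mod.load_het_snps(vcf)
            else:
                snps = asm_mod.screen_het_snps(str(sam), genome)
            events, summary = asm_mod.call_asm(
                str(sam), snps, index, cfg.alpha, cfg.min_delta,
                cfg.min_mapq, cfg.min_baseq, fragments)
            asm_mod.write_asm_tsv(events, summary, asm_tsv)
            log.info("asm: %s", summary)
            runner.mark_done("asm", checksum)
        artifacts["asm_tsv"] = asm_tsv

    # --- summary report
    rep_dir = out / "report"
    rep_dir.mkdir(exist_ok=True)
    summary_json = rep_dir / "summary.json"
    islands = read_bed(cfg.islands_bed) if cfg.islands_bed else \
        [(f.chrom, f.start, f.end) for f in fragments]
    report: dict[str, dict] = {}
    for name, meth in methylomes.items():
        cov = coverage_report(meth, islands, index, cfg.thresholds,
                              cfg.max_decay)
        if cov is not None:
            write_coverage_tsv(cov, rep_dir / f"coverage_{name}.tsv")
            report[name] = cov.as_dict()
    summary_json.write_text(json.dumps(report, indent=1, sort_keys=True))
    artifacts["summary_json"] = summary_json
    return artifacts
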