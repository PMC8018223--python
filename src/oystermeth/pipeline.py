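"""End-to-end pipeline orchestration.

Runs the stages in method order — simulate -> call -> characterize -> diff ->
effects -> enrich -> color — writing TSV/BED outputs into a run directory.
Every output carries the configuration hash in a leading comment line; a
stage whose marker file matches the current hash is skipped on rerun, so
partial reruns resume from cached outputs.  A single seed drives all
randomness; identical config + seed reproduces identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import calling, characterize, color, design, diffmeth, enrichment, synthetic

log = logging.getLogger("oystermeth")

STAGES = ("simulate", "call", "characterize", "diff", "effects", "enrich", "color")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides
    # input paths (used when simulate is False)
    genome: str | None = None
    genes: str | None = None
    reports: list[str] = field(default_factory=list)
    design: str | None = None
    go_map: str | None = None
    go_terms: str | None = None
    expression: str | None = None
    images: dict = field(default_factory=dict)      # group label -> [paths]
    # the analysis constants
    min_coverage: int = 10
    diff_threshold: float = 25.0
    q_threshold: float = 0.05
    flank: int = 3000
    low_cut: float = 0.2
    high_cut: float = 0.5
    stages: tuple = STAGES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("min_coverage", "diff_threshold", "q_threshold", "flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.simulate:
            for name in ("genome", "genes"):
                p = getattr(self, name)
                if p is None or not os.path.exists(p):
                    raise FileNotFoundError(f"config.{name}: {p!r} not found")
            for p in self.reports:
                if not os.path.exists(p):
                    raise FileNotFoundError(f"report {p!r} not found")
        if "enrich" in self.stages and not self.simulate and not self.go_map:
            raise FileNotFoundError("enrich stage requested but no GO map configured")

    def config_hash(self) -> str:
        # identity of the analysis, not of its output location
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


class _Cache:
    def __init__(self, out_dir: str, cfg_hash: str):
        self.dir = os.path.join(out_dir, ".stages")
        os.makedirs(self.dir, exist_ok=True)
        self.hash = cfg_hash

    def done(self, stage: str) -> bool:
        marker = os.path.join(self.dir, stage + ".json")
        if not os.path.exists(marker):
            return False
        with open(marker) as fh:
            return json.load(fh).get("config_hash") == self.hash

    def mark(self, stage: str) -> None:
        with open(os.path.join(self.dir, stage + ".json"), "w") as fh:
            json.dump({"config_hash": self.hash}, fh)


def run_pipeline(config: PipelineConfig) -> str:
    """Execute the configured stages; returns the run directory path."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    cfg_hash = config.config_hash()
    handler = logging.FileHandler(os.path.join(out, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    cache = _Cache(out, cfg_hash)
    try:
        log.info("run start: config_hash=%s seed=%d", cfg_hash, config.seed)
        log.info("parameters: %s", json.dumps(dataclasses.asdict(config), default=str))
        _run_stages(config, out, cfg_hash, cache)
        log.info("run complete")
    except Exception:
        log.exception("stage failure")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _run_stages(config: PipelineConfig, out: str, cfg_hash: str, cache: _Cache) -> None:
    syn_kwargs = dict(config.synthetic)
    syn_kwargs.setdefault("seed", config.seed)
    scfg = synthetic.SyntheticConfig(**syn_kwargs)

    # ---- simulate / load inputs ------------------------------------------
    sim_dir = os.path.join(out, "simulate")
    if config.simulate:
        dataset = synthetic.generate_dataset(scfg)
        if "simulate" in config.stages and not cache.done("simulate"):
            os.makedirs(os.path.join(sim_dir, "reports"), exist_ok=True)
            os.makedirs(os.path.join(sim_dir, "images"), exist_ok=True)
            dataset.genome.write_fasta(os.path.join(sim_dir, "genome.fa"))
            dataset.gene_set.write_gff3(os.path.join(sim_dir, "genes.gff3"))
            dataset.gene_set.write_bed(os.path.join(sim_dir, "genes.bed"))
            dataset.design.write_tsv(os.path.join(sim_dir, "design.tsv"))
            for rep in dataset.reports:
                calling.write_cytosine_report(
                    rep, os.path.join(sim_dir, "reports", f"{rep.sample_id}.CX_report.txt"),
                    genome=dataset.genome,
                )
            dataset.methylome.write_truth_table(os.path.join(sim_dir, "truth_dmcs.tsv"))
            _write_tsv(dataset.expression, os.path.join(sim_dir, "expression.tsv"), cfg_hash)
            _write_tsv(dataset.annotation, os.path.join(sim_dir, "go_map.tsv"), cfg_hash)
            _write_tsv(dataset.term_info, os.path.join(sim_dir, "go_terms.tsv"), cfg_hash)
            for p in [os.path.join(sim_dir, "genome.fa")]:
                log.info("input checksum %s %s", p, _checksum(p))
            cache.mark("simulate")
        genome = dataset.genome
        gene_set = dataset.gene_set
        reports = dataset.reports
        sample_design = dataset.design
        expression = dataset.expression
        annotation = dataset.annotation
        term_info = dataset.term_info
    else:
        genome = synthetic.Genome.read_fasta(config.genome)
        gene_set = (
            synthetic.GeneSet.read_bed(config.genes)
            if str(config.genes).endswith(".bed")
            else synthetic.GeneSet.read_gff3(config.genes)
        )
        reports = [
            calling.read_cytosine_report(p, genome=genome) for p in config.reports
        ]
        sample_design = (
            design.SampleDesign.read_tsv(config.design)
            if config.design
            else design.SampleDesign.full()
        )
        expression = (
            pd.read_csv(config.expression, sep="\t", comment="#")
            if config.expression else None
        )
        annotation = (
            enrichment.read_annotation(config.go_map) if config.go_map else None
        )
        term_info = (
            pd.read_csv(config.go_terms, sep="\t", comment="#")
            if config.go_terms else None
        )
        for p in [config.genome, config.genes, *config.reports]:
            log.info("input checksum %s %s", p, _checksum(p))

    # ---- call -------------------------------------------------------------
    callsets = {
        rep.sample_id: calling.call_methylation(rep, config.min_coverage)
        for rep in reports
    }
    call_dir = os.path.join(out, "call")
    if "call" in config.stages and not cache.done("call"):
        os.makedirs(call_dir, exist_ok=True)
        summaries = []
        for sid, cs in callsets.items():
            s = calling.global_methylation_summary(cs)
            s.insert(0, "sample_id", sid)
            summaries.append(s)
        _write_tsv(pd.concat(summaries, ignore_index=True),
                   os.path.join(call_dir, "global_summary.tsv"), cfg_hash)
        cache.mark("call")
        log.info("call: %d samples, min_coverage=%d", len(callsets), config.min_coverage)

    # ---- characterize -------------------------------------------------------
    char_dir = os.path.join(out, "characterize")
    gene_meth = None
    if "characterize" in config.stages:
        os.makedirs(char_dir, exist_ok=True)
        profile = characterize.metagene_profile(
            list(callsets.values()), gene_set, flank=config.flank
        )
        first = next(iter(callsets.values()))
        gbmr = characterize.gene_body_methylation(first, gene_set)
        gene_meth = characterize.classify_genes_by_rank(
            gbmr, config.low_cut, config.high_cut
        )
        all_ids = list(sample_design.samples["sample_id"])
        united_all = calling.unite_positions(
            [callsets[s] for s in all_ids], context_filter="CpG", label="all-samples"
        )
        Z, labels = characterize.cluster_samples(united_all)
        if not cache.done("characterize"):
            _write_tsv(profile, os.path.join(char_dir, "metagene.tsv"), cfg_hash)
            _write_tsv(gene_meth, os.path.join(char_dir, "gene_methylation.tsv"), cfg_hash)
            with open(os.path.join(char_dir, "clustering.nwk"), "w") as fh:
                fh.write(characterize.linkage_to_newick(Z, united_all.samples) + "\n")
            if expression is not None:
                curve, fixed = characterize.methylation_by_expression_rank(
                    gene_meth, expression
                )
                _write_tsv(curve, os.path.join(char_dir, "meth_by_expression.tsv"), cfg_hash)
                _write_tsv(fixed, os.path.join(char_dir, "meth_by_rpkm_band.tsv"), cfg_hash)
            cache.mark("characterize")
            log.info("characterize: %d genes ranked", len(gene_meth))

    # ---- diff + effects -----------------------------------------------------
    effects = None
    dmc_tables = {}
    if "diff" in config.stages or "effects" in config.stages:
        diff_dir = os.path.join(out, "diff")
        os.makedirs(diff_dir, exist_ok=True)
        specs = design.enumerate_comparisons(sample_design)
        by_family: dict[str, list] = {}
        for spec in specs:
            united = calling.unite_positions(
                [callsets[s] for s in spec.group_a + spec.group_b],
                context_filter=None, label=spec.label,
            )
            dmcs = diffmeth.get_methyl_diff(
                united, spec.group_a, spec.group_b,
                diff_threshold=config.diff_threshold, q_threshold=config.q_threshold,
            )
            by_family.setdefault(spec.family, []).append(dmcs)
            dmc_tables[spec.label] = dmcs
            if not cache.done("diff"):
                safe = spec.label.replace(" ", "_")
                diffmeth.write_dmcs_bed(dmcs, os.path.join(diff_dir, f"{safe}.dmcs.bed"))
            log.info("diff %s: %d DMCs (%d hyper, %d hypo) of %d sites",
                     spec.label, len(dmcs), dmcs.n_hyper, dmcs.n_hypo,
                     len(dmcs.all_sites))
        cache.mark("diff")
        effects = design.disentangle_effects(by_family)
        if "effects" in config.stages and not cache.done("effects"):
            eff_dir = os.path.join(out, "effects")
            os.makedirs(eff_dir, exist_ok=True)
            _write_tsv(design.effect_report(effects),
                       os.path.join(eff_dir, "effect_report.tsv"), cfg_hash)
            _write_tsv(effects.depth_only, os.path.join(eff_dir, "depth_only.tsv"),
                       cfg_hash)
            _write_tsv(effects.time_effect, os.path.join(eff_dir, "time_effect.tsv"),
                       cfg_hash)
            cache.mark("effects")

    # ---- enrich -------------------------------------------------------------
    if "enrich" in config.stages and annotation is not None and effects is not None:
        enr_dir = os.path.join(out, "enrich")
        os.makedirs(enr_dir, exist_ok=True)
        population = list(gene_set.genes["gene_id"])
        study_sets = {}
        per_gene, discarded = enrichment.map_dmcs_to_genes(effects.depth_only, gene_set)
        log.info("enrich: %d DMCs outside gene bodies discarded", discarded)
        if len(per_gene):
            study_sets["dm_genes"] = list(per_gene["gene_id"])
        if gene_meth is not None:
            study_sets["low_genes"] = list(
                gene_meth.loc[gene_meth["meth_class"] == "low", "gene_id"]
            )
            study_sets["high_genes"] = list(
                gene_meth.loc[gene_meth["meth_class"] == "high", "gene_id"]
            )
        if not cache.done("enrich"):
            _write_tsv(per_gene, os.path.join(enr_dir, "dmc_genes.tsv"), cfg_hash)
            for name, study in study_sets.items():
                if not study:
                    continue
                res = enrichment.go_enrichment(study, population, annotation, term_info)
                _write_tsv(res, os.path.join(enr_dir, f"enrichment_{name}.tsv"), cfg_hash)
            cache.mark("enrich")

    # ---- color --------------------------------------------------------------
    if "color" in config.stages and not cache.done("color"):
        col_dir = os.path.join(out, "color")
        os.makedirs(col_dir, exist_ok=True)
        if config.images:
            groups = {k: list(v) for k, v in config.images.items()}
        else:
            # the phenotype run mirrors the darkness response: treatment
            # shells darken at S2 and stay dark at S3
            rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
            groups = {}
            for treat in ("C", "T"):
                for i, time in enumerate(design.TIMES):
                    shift = 0.3 if treat == "T" and time in ("S2", "S3") else 0.0
                    groups[f"{treat}-{time}"] = synthetic.generate_shell_images(
                        10, darkness_shift=shift,
                        seed=int(rng.integers(2**31)),
                    )
        measurements, tests = color.phenotype_pipeline(groups)
        _write_tsv(measurements, os.path.join(col_dir, "color_measurements.tsv"), cfg_hash)
        _write_tsv(tests, os.path.join(col_dir, "color_tests.tsv"), cfg_hash)
        cache.mark("color")
        log.info("color: %d groups measured", len(groups))
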