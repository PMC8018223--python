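"""Synthetic data generator for the depth-variation methylation study.

Emulates the statistical structure the analysis assumes, at desk scale:

* a random genome and non-overlapping gene models;
* a mosaic methylome — CpG-dominant methylation, gene bodies drawn from a
  bimodal low/high distribution (plus an intermediate class filling the
  rank band between them), near-zero CHG/CHH methylation;
* planted depth-responsive DMCs with a truth table for recovery scoring;
* replicated per-cytosine bisulfite count tables for the full 18-sample
  design (3 genotypes x {control, treatment} x 3 sampling times), with
  negative-binomial coverage, binomial methylated counts and a symmetric
  bisulfite conversion error;
* structured sample-to-sample offsets (treatment > genotype > time) so that
  correlation-distance Ward clustering groups samples first by treatment and
  then by genotype;
* gene expression tables optionally coupled to methylation class so the
  methylation-by-expression-rank curve shows the mid-expression hump;
* gene -> GO-term annotation maps with an optionally planted enriched term;
* shell images with a controllable darkness shift.

All randomness flows from ``SyntheticConfig.seed`` through a
``numpy.random.SeedSequence`` tree, so an identical config yields
byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import CytosineReport, assign_contexts_vectorized
from .design import SampleDesign, TIMES


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; defaults are the desk-scale run."""

    n_scaffolds: int = 2
    scaffold_length: int = 50_000
    gc_fraction: float = 0.35
    n_genes: int = 30
    gene_length_range: tuple[int, int] = (1_000, 3_000)
    flank: int = 3_000
    # gene-body methylation classes: low and high are the two bimodal peaks,
    # the remainder of genes form an intermediate class above the gap
    low_gene_fraction: float = 0.2
    high_gene_fraction: float = 0.5
    low_level_range: tuple[float, float] = (0.0000, 0.0019)
    high_level_range: tuple[float, float] = (0.005, 0.4012)
    mid_level_range: tuple[float, float] = (0.005, 0.05)
    intergenic_level: float = 0.07
    chg_level: float = 0.009
    chh_level: float = 0.010
    # sequencing model
    coverage_mean: float = 30.0
    coverage_dispersion: float = 20.0  # negative-binomial size; larger = closer to Poisson
    conversion_error: float = 0.005
    # design and planted truth
    n_genotypes: int = 3
    n_times: int = 3
    treatments: tuple[str, str] = ("C", "T")
    planted_effect_size: float = 30.0  # percentage points
    n_planted_dmcs: int = 50
    affected_times: tuple[str, ...] = ("S2", "S3")
    # sample-structure offsets (per-site Gaussian, clipped at [0,1])
    treatment_effect_sd: float = 0.05
    genotype_sd: float = 0.02
    time_sd: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_scaffolds < 1 or self.scaffold_length < 1000:
            raise ConfigurationError("need >=1 scaffold of >=1000 bp")
        for name in ("low_level_range", "high_level_range", "mid_level_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 1):
                raise ConfigurationError(f"{name} must be an ordered pair in [0,1]")
        for name in ("intergenic_level", "chg_level", "chh_level",
                     "conversion_error", "gc_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0,1]")
        if self.low_level_range[1] >= self.high_level_range[0]:
            raise ConfigurationError(
                "low_level_range max must fall below high_level_range min "
                "(bimodality must be constructible)"
            )
        if self.low_gene_fraction + self.high_gene_fraction > 1:
            raise ConfigurationError("gene class fractions sum above 1")
        if self.n_genes < 0 or self.coverage_mean < 0:
            raise ConfigurationError("negative sizes")

    def rng_tree(self) -> dict[str, np.random.Generator]:
        """Named, order-independent RNG streams derived from the seed."""
        names = ["genome", "genes", "methylome", "plant", "offsets",
                 "counts", "expression", "go", "images"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    sequences: dict[str, str]

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path) -> "Genome":
        return cls({r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")})


@dataclass
class GeneSet:
    """Gene models: 1-based inclusive [start, end]; TSS at start on '+',
    at end on '-'."""

    genes: pd.DataFrame  # gene_id, scaffold, start, end, strand[, meth_class]

    def __len__(self) -> int:
        return len(self.genes)

    def tss(self) -> pd.Series:
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["start"], g["end"]), index=g.index
        )

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in self.genes.itertuples(index=False):
                fh.write(
                    f"{r.scaffold}\toystermeth\tgene\t{r.start}\t{r.end}\t.\t"
                    f"{r.strand}\t.\tID={r.gene_id}\n"
                )

    def write_bed(self, path) -> None:
        out = pd.DataFrame(
            {
                "scaffold": self.genes["scaffold"],
                "start": self.genes["start"] - 1,  # BED is 0-based half-open
                "end": self.genes["end"],
                "name": self.genes["gene_id"],
                "score": 0,
                "strand": self.genes["strand"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_gff3(cls, path) -> "GeneSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                rows.append(
                    (attrs.get("ID", f"{f[0]}:{f[3]}"), f[0], int(f[3]), int(f[4]), f[6])
                )
        return cls(pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"]))

    @classmethod
    def read_bed(cls, path) -> "GeneSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#").iloc[:, :6]
        df.columns = ["scaffold", "start", "end", "name", "score", "strand"]
        genes = pd.DataFrame(
            {
                "gene_id": df["name"],
                "scaffold": df["scaffold"],
                "start": df["start"] + 1,
                "end": df["end"],
                "strand": df["strand"],
            }
        )
        return cls(genes)


def generate_genome(config: SyntheticConfig, rng: np.random.Generator | None = None) -> Genome:
    """Random genome over {A,C,G,T} with the configured GC fraction."""
    config.validate()
    if rng is None:
        rng = config.rng_tree()["genome"]
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {}
    for i in range(config.n_scaffolds):
        bases = rng.choice(np.array(["A", "C", "G", "T"]), size=config.scaffold_length, p=probs)
        seqs[f"scaffold_{i + 1}"] = "".join(bases)
    return Genome(seqs)


def generate_gene_models(genome: Genome, config: SyntheticConfig,
                         rng: np.random.Generator | None = None) -> GeneSet:
    """Place non-overlapping genes, keeping the flank inside the scaffold."""
    config.validate()
    if rng is None:
        rng = config.rng_tree()["genes"]
    lo, hi = config.gene_length_range
    scaffolds = list(genome.sequences)
    per_scaffold = np.zeros(len(scaffolds), dtype=int)
    for i in range(config.n_genes):
        per_scaffold[i % len(scaffolds)] += 1
    rows = []
    gid = 0
    for scaf, n in zip(scaffolds, per_scaffold):
        L = len(genome.sequences[scaf])
        usable = L - 2 * config.flank
        lengths = rng.integers(lo, hi + 1, size=n)
        min_gap = 1
        slack = usable - int(lengths.sum()) - (n - 1) * min_gap if n else usable
        if n and (usable <= 0 or slack < 0):
            raise ConfigurationError(
                f"cannot place {n} genes of {lo}-{hi} bp on {scaf} "
                f"({L} bp with {config.flank} bp flanks)"
            )
        # distribute the slack uniformly over the n+1 gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=n + 1)) if n else []
        extra = np.diff(np.concatenate([[0], cuts]))[:n] if n else []
        cursor = config.flank + 1
        for j in range(n):
            start = cursor + int(extra[j])
            end = start + int(lengths[j]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            rows.append((f"gene_{gid:04d}", scaf, start, end, strand))
            cursor = end + 1 + min_gap
    genes = pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])
    return GeneSet(genes)


# ---------------------------------------------------------------------------
# true methylome
# ---------------------------------------------------------------------------

@dataclass
class TrueMethylome:
    """Per-cytosine ground truth with optional condition-specific overrides.

    ``sites`` has one row per cytosine per strand with its base methylation
    fraction; ``overrides`` maps (treatment, time) to {row index: fraction}
    for planted effects; ``truth_table`` records every planted site.
    """

    sites: pd.DataFrame  # scaffold, pos, strand, context, gene_id, gene_class, fraction
    overrides: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    truth_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def true_fractions(self, treatment: str, time: str) -> np.ndarray:
        f = self.sites["fraction"].to_numpy().copy()
        ov = self.overrides.get((treatment, time))
        if ov:
            idx = np.fromiter(ov.keys(), dtype=int)
            f[idx] = np.fromiter(ov.values(), dtype=float)
        return f

    def write_truth_table(self, path) -> None:
        self.truth_table.to_csv(path, sep="\t", index=False)


def _gene_lookup(gene_set: GeneSet, scaffold: str, positions: np.ndarray):
    """Vectorised gene-body membership: index of covering gene or -1."""
    g = gene_set.genes[gene_set.genes["scaffold"] == scaffold]
    if len(g) == 0:
        return np.full(len(positions), -1), np.full(len(positions), "", dtype=object)
    starts = g["start"].to_numpy()
    ends = g["end"].to_numpy()
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    ids = g["gene_id"].to_numpy()[order]
    k = np.searchsorted(starts, positions, side="right") - 1
    inside = (k >= 0) & (positions <= ends[np.clip(k, 0, None)])
    gene_idx = np.where(inside, k, -1)
    gene_ids = np.where(inside, ids[np.clip(k, 0, None)], "")
    return gene_idx, gene_ids


def assign_methylome(genome: Genome, gene_set: GeneSet, config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> TrueMethylome:
    """Draw per-cytosine true methylation fractions for the mosaic methylome.

    Gene classes (low / mid / high) are drawn per gene; genic CpGs get levels
    from the class's range, intergenic CpGs sit at ``intergenic_level``, and
    CHG/CHH/CN contexts get low levels jittered around their configured means
    everywhere.  The per-gene mean CpG level is bimodal by construction, with
    an empty band between ``low_level_range`` max and the smaller of the mid
    and high range minima.
    """
    config.validate()
    if rng is None:
        rng = config.rng_tree()["methylome"]
    n_genes = len(gene_set)
    # quota assignment: the realised class proportions equal the configured
    # fractions exactly, so rank-based classification cuts are commensurable
    # with the truth
    n_low = int(round(config.low_gene_fraction * n_genes))
    n_high = int(round(config.high_gene_fraction * n_genes))
    classes = np.array(["mid"] * n_genes, dtype=object)
    order = rng.permutation(n_genes)
    classes[order[:n_low]] = "low"
    classes[order[n_genes - n_high:]] = "high"
    gene_class = dict(zip(gene_set.genes["gene_id"], classes))
    gene_set.genes["meth_class"] = classes

    frames = []
    for scaf, seq in genome.sequences.items():
        pos, strand, ctx = assign_contexts_vectorized(seq)
        _, gene_ids = _gene_lookup(gene_set, scaf, pos)
        frames.append(pd.DataFrame(
            {"scaffold": scaf, "pos": pos, "strand": strand,
             "context": ctx, "gene_id": gene_ids}
        ))
    sites = pd.concat(frames, ignore_index=True)
    n = len(sites)
    frac = np.empty(n)
    ctx = sites["context"].to_numpy()
    is_cpg = ctx == "CpG"
    # non-CpG: jitter +-50% around the configured level
    for name, level in [("CHG", config.chg_level), ("CHH", config.chh_level),
                        ("CN/CHN", (config.chg_level + config.chh_level) / 2)]:
        m = ctx == name
        frac[m] = rng.uniform(0.5 * level, 1.5 * level, m.sum())
    frac[is_cpg] = config.intergenic_level
    gene_of = sites["gene_id"].to_numpy()
    sites["gene_class"] = [gene_class.get(g, "") if g else "" for g in gene_of]
    for cls, (lo, hi) in [("low", config.low_level_range),
                          ("mid", config.mid_level_range),
                          ("high", config.high_level_range)]:
        m = is_cpg & (sites["gene_class"].to_numpy() == cls)
        frac[m] = rng.uniform(lo, hi, m.sum())
    sites["fraction"] = frac
    return TrueMethylome(sites=sites)


def plant_dmcs(methylome: TrueMethylome, gene_set: GeneSet, target_gene_ids,
               delta_points: float, affected_group: str, affected_times,
               n_sites: int | None = None,
               rng: np.random.Generator | None = None) -> TrueMethylome:
    """Shift selected genic CpGs by ``delta_points``/100 in one condition set.

    Only samples of ``affected_group`` at ``affected_times`` see the shift.
    Values leaving [0,1] are clipped and flagged in the truth table.  Returns
    a new TrueMethylome sharing the site table, with overrides and truth
    table filled in.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    target = set(target_gene_ids)
    sites = methylome.sites
    candidates = np.nonzero(
        (sites["context"] == "CpG").to_numpy()
        & sites["gene_id"].isin(target).to_numpy()
    )[0]
    if n_sites is None:
        n_sites = len(candidates)
    if n_sites > len(candidates):
        raise ConfigurationError(
            f"{n_sites} planted sites requested but only {len(candidates)} "
            "genic CpGs available in the target genes"
        )
    chosen = np.sort(rng.choice(candidates, size=n_sites, replace=False))
    base = sites["fraction"].to_numpy()[chosen]
    shifted = base + delta_points / 100.0
    clipped = (shifted < 0) | (shifted > 1)
    if clipped.any():
        warnings.warn(f"{clipped.sum()} planted sites clipped to [0,1]")
    shifted = np.clip(shifted, 0.0, 1.0)
    affected_times = tuple(affected_times)
    overrides = {k: dict(v) for k, v in methylome.overrides.items()}
    for t in affected_times:
        ov = overrides.setdefault((affected_group, t), {})
        ov.update(dict(zip(map(int, chosen), shifted)))
    truth = pd.DataFrame(
        {
            "scaffold": sites["scaffold"].to_numpy()[chosen],
            "pos": sites["pos"].to_numpy()[chosen],
            "strand": sites["strand"].to_numpy()[chosen],
            "gene_id": sites["gene_id"].to_numpy()[chosen],
            "base_fraction": base,
            "planted_fraction": shifted,
            "delta_points": delta_points,
            "group": affected_group,
            "times": ",".join(affected_times),
            "clipped": clipped,
        }
    )
    truth_table = (
        pd.concat([methylome.truth_table, truth], ignore_index=True)
        if len(methylome.truth_table)
        else truth
    )
    return TrueMethylome(sites=sites, overrides=overrides, truth_table=truth_table)


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def simulate_counts(methylome: TrueMethylome, config: SyntheticConfig,
                    sample_design: SampleDesign | None = None,
                    rngs: dict[str, np.random.Generator] | None = None
                    ) -> list[CytosineReport]:
    """Per-cytosine count tables for every sample of the design.

    Coverage is negative binomial (mean ``coverage_mean``, size
    ``coverage_dispersion``); methylated counts are binomial in the true
    fraction after sample-structure offsets (treatment, genotype, time) and a
    symmetric conversion error (observed p = p(1-e) + (1-p)e).  Sites with
    zero coverage stay present with 0/0 counts.
    """
    config.validate()
    if sample_design is None:
        sample_design = SampleDesign.full()
    if rngs is None:
        tree = config.rng_tree()
        rngs = {"offsets": tree["offsets"], "counts": tree["counts"]}
    sites = methylome.sites
    n = len(sites)
    rng_off = rngs["offsets"]
    # structure offsets act on CpG sites only: the differential signal in
    # this methylome is CpG-dominant, and non-CpG contexts stay near their
    # configured baseline
    cpg = (sites["context"] == "CpG").to_numpy().astype(float)
    genotypes = sorted(sample_design.samples["genotype"].unique())
    geno_offset = {
        g: rng_off.normal(0.0, config.genotype_sd, n) * cpg for g in genotypes
    }
    treat_offset = rng_off.normal(0.0, config.treatment_effect_sd, n) * cpg
    time_offset = {s: rng_off.normal(0.0, config.time_sd, n) * cpg for s in TIMES}

    rng_counts = rngs["counts"]
    e = config.conversion_error
    nb_size = config.coverage_dispersion
    nb_p = nb_size / (nb_size + config.coverage_mean)
    reports = []
    for row in sample_design.samples.itertuples(index=False):
        p = methylome.true_fractions(row.treatment, row.time)
        p = p + geno_offset[row.genotype]
        if row.treatment == "T":
            p = p + treat_offset
        p = p + time_offset.get(row.time, 0.0)
        p = np.clip(p, 0.0, 1.0)
        p_obs = p * (1 - e) + (1 - p) * e
        cov = rng_counts.negative_binomial(nb_size, nb_p, n)
        m = rng_counts.binomial(cov, p_obs)
        df = pd.DataFrame(
            {
                "scaffold": sites["scaffold"],
                "pos": sites["pos"],
                "strand": sites["strand"],
                "context": sites["context"],
                "count_m": m,
                "count_u": cov - m,
            }
        )
        reports.append(CytosineReport(sample_id=row.sample_id, data=df))
    return reports


def simulate_site_study(n_sites: int = 10_000, n_planted: int = 200,
                        delta_points: float = 30.0, base_planted: float = 0.001,
                        null_level: float | None = None,
                        coverage_mean: float = 30.0, coverage_dispersion: float = 20.0,
                        conversion_error: float = 0.005,
                        n_per_group: int = 3, min_coverage: int = 10,
                        seed: int = 0):
    """Site-level recovery / null study: a united 2-group count matrix.

    Builds ``n_sites`` CpG sites with ``n_per_group`` replicates per group.
    The first ``n_planted`` sites start at ``base_planted`` and are shifted by
    ``delta_points``/100 in group A only; the rest are null.  Null levels are
    drawn from a genome-like mixture of intergenic and low/mid/high gene-body
    levels unless ``null_level`` fixes them.  Coverage is negative binomial
    and sites not reaching ``min_coverage`` in every sample are dropped, as
    :func:`oystermeth.calling.unite_positions` would drop them.

    Returns (united_matrix, truth_positions): the retained matrix and the
    1-based positions of all planted sites (whether retained or not).
    """
    from .calling import UnitedMatrix

    rng = np.random.default_rng(seed)
    cfg = SyntheticConfig()
    if null_level is None:
        comp = rng.choice(4, size=n_sites, p=[0.6, 0.08, 0.12, 0.2])
        base = np.empty(n_sites)
        base[comp == 0] = cfg.intergenic_level
        for code, (lo, hi) in [(1, cfg.low_level_range), (2, cfg.mid_level_range),
                               (3, cfg.high_level_range)]:
            m = comp == code
            base[m] = rng.uniform(lo, hi, m.sum())
    else:
        base = np.full(n_sites, float(null_level))
    base[:n_planted] = base_planted
    p_a = base.copy()
    p_a[:n_planted] = np.clip(base[:n_planted] + delta_points / 100.0, 0.0, 1.0)
    p_b = base

    e = conversion_error
    nb_p = coverage_dispersion / (coverage_dispersion + coverage_mean)
    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    data = {
        "scaffold": np.full(n_sites, "sim"),
        "pos": np.arange(1, n_sites + 1),
        "strand": np.full(n_sites, "+"),
        "context": np.full(n_sites, "CpG"),
    }
    keep = np.ones(n_sites, dtype=bool)
    for sid in samples:
        p = p_a if sid.startswith("A") else p_b
        p_obs = p * (1 - e) + (1 - p) * e
        cov = rng.negative_binomial(coverage_dispersion, nb_p, n_sites)
        m = rng.binomial(cov, p_obs)
        data[f"{sid}.M"] = m
        data[f"{sid}.U"] = cov - m
        keep &= cov >= min_coverage
    df = pd.DataFrame(data).loc[keep].reset_index(drop=True)
    united = UnitedMatrix(samples=samples, min_coverage=min_coverage, data=df,
                          label="site-study")
    truth_positions = np.arange(1, n_planted + 1)
    return united, truth_positions


# ---------------------------------------------------------------------------
# expression, GO map, images
# ---------------------------------------------------------------------------

def simulate_expression(gene_set: GeneSet, gene_meth_class=None,
                        coupling: str = "none", seed: int = 0) -> pd.DataFrame:
    """Gene-level RPKM table, optionally coupled to methylation class.

    ``coupling='hump'`` places mid/high-methylation genes preferentially in
    the moderate 100-1000 RPKM band so the methylation-by-expression curve
    peaks there; ``'none'`` draws expression independently of class.
    """
    if coupling not in ("none", "hump"):
        raise ValueError("coupling must be 'none' or 'hump'")
    rng = np.random.default_rng(seed)
    ids = list(gene_set.genes["gene_id"])
    if not ids:
        return pd.DataFrame(columns=["gene_id", "rpkm"])
    if gene_meth_class is None:
        gene_meth_class = dict(
            zip(gene_set.genes["gene_id"], gene_set.genes.get("meth_class", ""))
        )
    rpkm = np.empty(len(ids))
    for i, gid in enumerate(ids):
        cls = gene_meth_class.get(gid, "") if hasattr(gene_meth_class, "get") else ""
        if coupling == "hump" and cls in ("mid", "high"):
            # moderately expressed: log-uniform inside 100-1000 RPKM
            rpkm[i] = 10 ** rng.uniform(2.0, 3.0)
        elif coupling == "hump":
            # low-methylation genes land outside the moderate band
            rpkm[i] = 10 ** (rng.uniform(-1.0, 1.8) if rng.random() < 0.5
                             else rng.uniform(3.2, 4.5))
        else:
            rpkm[i] = 10 ** rng.normal(1.5, 1.0)
    return pd.DataFrame({"gene_id": ids, "rpkm": rpkm})


def generate_go_annotation(gene_set: GeneSet, n_terms: int = 20,
                           terms_per_gene: float = 3.0,
                           enriched_term: str | None = None,
                           enriched_gene_ids=None,
                           seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random gene->GO map plus term metadata (name, namespace BP/MF).

    When ``enriched_term``/``enriched_gene_ids`` are given, that term is
    attached to every listed gene, creating a true over-representation signal
    for enrichment tests.  Returns (annotation, term_info).
    """
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    namespaces = ["BP" if i % 2 == 0 else "MF" for i in range(n_terms)]
    rows = []
    for gid in gene_set.genes["gene_id"]:
        k = min(rng.poisson(terms_per_gene), n_terms)
        for t in rng.choice(terms, size=k, replace=False):
            rows.append((gid, t))
    if enriched_term is not None and enriched_gene_ids is not None:
        for gid in enriched_gene_ids:
            rows.append((gid, enriched_term))
        if enriched_term not in terms:
            terms.append(enriched_term)
            namespaces.append("BP")
    annotation = pd.DataFrame(rows, columns=["gene_id", "go_id"]).drop_duplicates(
        ignore_index=True
    )
    term_info = pd.DataFrame(
        {"go_id": terms, "name": [f"synthetic term {t}" for t in terms],
         "namespace": namespaces}
    )
    return annotation, term_info


def generate_shell_images(n_images: int, base_hsv=(0.6, 0.3, 0.7),
                          darkness_shift: float = 0.0, noise_sd: float = 0.02,
                          seed: int = 0, shape=(32, 32),
                          quantize: bool = True) -> list[np.ndarray]:
    """Shell-colour image stack: HSV base with a brightness (value) shift.

    Returns RGB arrays whose mean brightness is ``base value -
    darkness_shift`` plus pixel noise, clipped to [0,1].  With ``quantize``
    (the default) arrays are 8-bit and PNG-writable; ``quantize=False``
    keeps float RGB, which preserves continuous darkness values (no
    quantisation ties between images).
    """
    from skimage.color import hsv2rgb

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    h, s, v = base_hsv
    if not (0 <= h <= 1 and 0 <= s <= 1 and 0 <= v <= 1):
        raise ValueError("base_hsv components must lie in [0,1]")
    rng = np.random.default_rng(seed)
    images = []
    for _ in range(n_images):
        hsv = np.empty(shape + (3,))
        hsv[..., 0] = h
        hsv[..., 1] = s
        hsv[..., 2] = np.clip(
            v - darkness_shift + rng.normal(0.0, noise_sd, shape), 0.0, 1.0
        )
        rgb = hsv2rgb(hsv)
        images.append(np.round(rgb * 255).astype(np.uint8) if quantize else rgb)
    return images


def write_images(images, directory, prefix="img") -> list[str]:
    from PIL import Image

    paths = []
    for i, arr in enumerate(images):
        p = f"{directory}/{prefix}_{i:03d}.png"
        Image.fromarray(arr, mode="RGB").save(p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# one-call generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: Genome
    gene_set: GeneSet
    methylome: TrueMethylome
    design: SampleDesign
    reports: list[CytosineReport]
    expression: pd.DataFrame
    annotation: pd.DataFrame
    term_info: pd.DataFrame


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Full synthetic study: genome, genes, methylome with planted DMCs,
    18 count tables, expression, and GO annotation."""
    if config is None:
        config = SyntheticConfig()
    config.validate()
    tree = config.rng_tree()
    genome = generate_genome(config, tree["genome"])
    gene_set = generate_gene_models(genome, config, tree["genes"])
    methylome = assign_methylome(genome, gene_set, config, tree["methylome"])
    low_genes = gene_set.genes.loc[
        gene_set.genes["meth_class"] == "low", "gene_id"
    ].tolist()
    if config.n_planted_dmcs > 0 and low_genes:
        methylome = plant_dmcs(
            methylome, gene_set, low_genes, config.planted_effect_size,
            affected_group="T", affected_times=config.affected_times,
            n_sites=config.n_planted_dmcs, rng=tree["plant"],
        )
    design = SampleDesign.full()
    reports = simulate_counts(
        methylome, config, design,
        rngs={"offsets": tree["offsets"], "counts": tree["counts"]},
    )
    gene_cls = dict(zip(gene_set.genes["gene_id"], gene_set.genes["meth_class"]))
    expression = simulate_expression(
        gene_set, gene_cls, coupling="hump",
        seed=int(tree["expression"].integers(2**31)),
    )
    dm_genes = (
        sorted(set(methylome.truth_table["gene_id"])) if len(methylome.truth_table) else []
    )
    annotation, term_info = generate_go_annotation(
        gene_set, enriched_term="GO:9999999", enriched_gene_ids=dm_genes,
        seed=int(tree["go"].integers(2**31)),
    )
    return SyntheticDataset(
        config=config, genome=genome, gene_set=gene_set, methylome=methylome,
        design=design, reports=reports, expression=expression,
        annotation=annotation, term_info=term_info,
    )
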