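"""DMC-to-gene mapping and Fisher-exact GO-term over-representation.

DMCs falling outside every gene body are counted and discarded; genes
carrying at least one DMC form the study set.  Enrichment of each GO term in
a study set against the gene population uses the one-sided (greater) Fisher
exact test — the hypergeometric upper tail of the 2x2 table — with
Benjamini-Hochberg adjustment within each GO namespace (BP and MF
separately).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import adjust_qvalues
from .synthetic import GeneSet


def read_annotation(path) -> pd.DataFrame:
    """Two-column TSV: gene_id, GO id (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if str(df.iloc[0, 1]).startswith("GO:") is False and df.iloc[0, 0] in ("gene_id",):
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "go_id"]
    return df.drop_duplicates(ignore_index=True)


def map_dmcs_to_genes(dmc_table: pd.DataFrame, gene_set: GeneSet) -> tuple[pd.DataFrame, int]:
    """Assign DMCs to overlapping gene bodies (inclusive ends, strand-agnostic).

    ``dmc_table`` needs scaffold/pos/strand/direction columns.  A DMC under
    two overlapping genes is assigned to both and flagged.  Returns the
    per-gene table (hyper/hypo DMC counts) and the count of discarded
    intergenic DMCs.
    """
    genes = gene_set.genes
    rows = []
    discarded = 0
    for r in dmc_table.itertuples(index=False):
        hits = genes[
            (genes["scaffold"] == r.scaffold)
            & (genes["start"] <= r.pos)
            & (genes["end"] >= r.pos)
        ]
        if len(hits) == 0:
            discarded += 1
            continue
        for g in hits.itertuples(index=False):
            rows.append((g.gene_id, r.scaffold, r.pos, r.strand,
                         getattr(r, "direction", ""), len(hits) > 1))
    assigned = pd.DataFrame(
        rows, columns=["gene_id", "scaffold", "pos", "strand", "direction", "multi_gene"]
    )
    if len(assigned):
        per_gene = (
            assigned.groupby("gene_id")
            .agg(
                n_dmcs=("pos", "size"),
                n_hyper=("direction", lambda d: int((d == "hyper").sum())),
                n_hypo=("direction", lambda d: int((d == "hypo").sum())),
                multi_gene=("multi_gene", "any"),
            )
            .reset_index()
        )
    else:
        per_gene = pd.DataFrame(
            columns=["gene_id", "n_dmcs", "n_hyper", "n_hypo", "multi_gene"]
        )
    return per_gene, discarded


def go_enrichment(study_genes, population_genes, annotation: pd.DataFrame,
                  term_info: pd.DataFrame | None = None) -> pd.DataFrame:
    """One-sided Fisher enrichment of GO terms in the study set.

    For each term annotated to at least one study gene, p is the
    hypergeometric upper tail P(X >= study_count) drawing ``study_n`` genes
    from a population with ``pop_count`` term-annotated genes.  q values are
    BH-adjusted within each namespace when term metadata is supplied,
    otherwise across all tested terms.  Sorted by p.
    """
    study = set(study_genes)
    population = set(population_genes)
    if not study:
        raise ValueError("empty study set")
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")
    ann = annotation[annotation["gene_id"].isin(population)]
    pop_n = len(population)
    study_n = len(study)
    rows = []
    for term, genes in ann.groupby("go_id")["gene_id"]:
        gset = set(genes)
        study_count = len(gset & study)
        if study_count < 1:
            continue
        pop_count = len(gset)
        # P(X >= study_count), X ~ Hypergeom(pop_n, pop_count, study_n)
        p = float(stats.hypergeom.sf(study_count - 1, pop_n, pop_count, study_n))
        rows.append((term, study_count, study_n, pop_count, pop_n, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["go_id", "study_count", "study_n", "pop_count", "pop_n", "p"]
    )
    if term_info is not None and len(out):
        out = out.merge(term_info[["go_id", "name", "namespace"]], on="go_id", how="left")
        out["namespace"] = out["namespace"].fillna("NA")
        out["q"] = np.nan
        for ns, idx in out.groupby("namespace").groups.items():
            out.loc[idx, "q"] = adjust_qvalues(out.loc[idx, "p"].to_numpy())
    elif len(out):
        out["q"] = adjust_qvalues(out["p"].to_numpy())
    else:
        out["q"] = []
    return out.sort_values(["p", "go_id"], ignore_index=True)
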