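"""Per-cytosine methylation calling.

Reads Bismark-style per-cytosine count files, assigns sequence context from
the genome, applies the minimum-coverage filter (default 10 reads) and
intersects positions across samples so that every retained site is covered in
every sample of a comparison.

Coordinates are 1-based inclusive throughout (Bismark convention); BED output
is converted to 0-based half-open at write time.  CpG calls on the two
strands of a dyad are kept separate by default; :func:`destrand` merges the
symmetric pair by summing counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("CpG", "CHG", "CHH", "CN/CHN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file; message carries path and line number."""


@dataclass
class CytosineReport:
    """Per-cytosine methylated/unmethylated read counts for one sample."""

    sample_id: str
    data: pd.DataFrame  # scaffold, pos, strand, context, count_m, count_u

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MethylationCallSet:
    """Sites passing the minimum-coverage filter, with methylation fractions."""

    sample_id: str
    min_coverage: int
    data: pd.DataFrame  # scaffold, pos, strand, context, coverage, fraction

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class UnitedMatrix:
    """Positions covered >= min_coverage in every sample of a comparison.

    ``data`` holds one row per (scaffold, pos, strand) with context and, for
    each sample, columns ``<sample>.M`` and ``<sample>.U``.
    """

    samples: list[str]
    min_coverage: int
    data: pd.DataFrame
    label: str = ""

    def __len__(self) -> int:
        return len(self.data)

    def counts(self, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.data[f"{sample_id}.M"].to_numpy(),
            self.data[f"{sample_id}.U"].to_numpy(),
        )

    def fractions(self, sample_id: str) -> np.ndarray:
        m, u = self.counts(sample_id)
        return m / (m + u)


# ---------------------------------------------------------------------------
# context assignment
# ---------------------------------------------------------------------------

def assign_context(genome, scaffold: str, position: int, strand: str) -> str:
    """Sequence context of a cytosine: CpG, CHG, CHH or CN/CHN.

    ``position`` is 1-based.  On the minus strand the cytosine sits on the
    reverse complement, so the context is read 3'->5' along the plus strand
    and complemented.  Any required base that is N or beyond the scaffold end
    yields CN/CHN.
    """
    seq = genome.sequences[scaffold] if hasattr(genome, "sequences") else genome[scaffold]
    i = position - 1
    if strand == "+":
        if seq[i] != "C":
            raise ValueError(
                f"base at {scaffold}:{position}(+) is {seq[i]!r}, not C"
            )
        b1 = seq[i + 1] if i + 1 < len(seq) else "N"
        b2 = seq[i + 2] if i + 2 < len(seq) else "N"
    elif strand == "-":
        if seq[i] != "G":
            raise ValueError(
                f"base at {scaffold}:{position}(-) is {seq[i]!r}, not C on the minus strand"
            )
        b1 = seq[i - 1].translate(_COMPLEMENT) if i - 1 >= 0 else "N"
        b2 = seq[i - 2].translate(_COMPLEMENT) if i - 2 >= 0 else "N"
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if b1 == "G":
        return "CpG"
    if b1 not in "ACT":
        return "CN/CHN"
    if b2 == "G":
        return "CHG"
    if b2 in "ACT":
        return "CHH"
    return "CN/CHN"


def assign_contexts_vectorized(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All cytosine positions (1-based), strands and contexts of one scaffold.

    Returns (positions, strands, contexts) covering both strands, sorted by
    position then strand.  Used by the simulator and by coverage-dialect
    context back-filling; agrees with :func:`assign_context` site by site.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)
    pad = np.full(2, b"N", dtype="S1")
    nxt = np.concatenate([arr[1:], pad[:1]])
    nxt2 = np.concatenate([arr[2:], pad])
    prv = np.concatenate([pad[:1], arr[:-1]])
    prv2 = np.concatenate([pad, arr[:-2]])

    def ctx(b1_is_g, b1_is_h, b2_is_g, b2_is_h):
        out = np.full(n, "CN/CHN", dtype=object)
        out[b1_is_g] = "CpG"
        out[b1_is_h & b2_is_g] = "CHG"
        out[b1_is_h & b2_is_h] = "CHH"
        return out

    is_h = lambda b: (b == b"A") | (b == b"C") | (b == b"T")
    plus = arr == b"C"
    ctx_plus = ctx(nxt == b"G", is_h(nxt), nxt2 == b"G", is_h(nxt2))
    # minus strand: C on revcomp where plus base is G; neighbours are the
    # complements of the preceding plus-strand bases
    # complement of a plus base is G iff the base is C, and is H (A/C/T) iff
    # the base is A, G or T
    minus = arr == b"G"
    comp_is_h = lambda b: (b == b"A") | (b == b"G") | (b == b"T")
    ctx_minus = ctx(prv == b"C", comp_is_h(prv), prv2 == b"C", comp_is_h(prv2))
    pos_p = np.nonzero(plus)[0]
    pos_m = np.nonzero(minus)[0]
    positions = np.concatenate([pos_p, pos_m]) + 1
    strands = np.concatenate([np.full(len(pos_p), "+"), np.full(len(pos_m), "-")])
    contexts = np.concatenate([ctx_plus[pos_p], ctx_minus[pos_m]])
    order = np.lexsort((strands, positions))
    return positions[order], strands[order], contexts[order]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cytosine_report(path, dialect: str = "cx_report", sample_id: str | None = None,
                         genome=None) -> CytosineReport:
    """Read a per-cytosine count file.

    ``cx_report``: scaffold, 1-based position, strand, count_M, count_U,
    context, trinucleotide (Bismark CX report).  ``coverage``: scaffold,
    start, end (both 1-based, equal), percent methylated, count_M, count_U
    (Bismark coverage file); context is looked up from ``genome`` when given,
    otherwise recorded as CN/CHN.
    """
    if dialect not in ("cx_report", "coverage"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if sample_id is None:
        sample_id = os.path.basename(str(path)).split(".")[0]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "cx_report":
                    if len(parts) < 6:
                        raise ValueError("expected >=6 tab-separated fields")
                    scaf, pos, strand, m, u, context = parts[:6]
                else:
                    if len(parts) < 6:
                        raise ValueError("expected 6 tab-separated fields")
                    scaf, pos, _end, _pct, m, u = parts[:6]
                    strand = parts[6] if len(parts) > 6 else "+"
                    context = None
                pos_i, m_i, u_i = int(pos), int(m), int(u)
                if m_i < 0 or u_i < 0:
                    raise ValueError(f"negative count ({m_i}, {u_i})")
                if strand not in ("+", "-"):
                    raise ValueError(f"unknown strand symbol {strand!r}")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if context is None:
                if genome is not None:
                    context = assign_context(genome, scaf, pos_i, strand)
                else:
                    context = "CN/CHN"
            rows.append((scaf, pos_i, strand, context, m_i, u_i))
    data = pd.DataFrame(
        rows, columns=["scaffold", "pos", "strand", "context", "count_m", "count_u"]
    )
    return CytosineReport(sample_id=sample_id, data=data)


def write_cytosine_report(report: CytosineReport, path, genome=None) -> None:
    """Write a report in Bismark CX-report layout (7 columns, no header)."""
    df = report.data
    tri = []
    for scaf, pos, strand in zip(df["scaffold"], df["pos"], df["strand"]):
        if genome is None:
            tri.append("NNN")
            continue
        seq = genome.sequences[scaf]
        i = pos - 1
        if strand == "+":
            s = seq[i : i + 3]
        else:
            s = seq[max(i - 2, 0) : i + 1][::-1].translate(_COMPLEMENT)
        tri.append(s.ljust(3, "N"))
    out = df.assign(tri=tri)[
        ["scaffold", "pos", "strand", "count_m", "count_u", "context", "tri"]
    ]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_callset(callset: MethylationCallSet, path) -> None:
    callset.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# calling and uniting
# ---------------------------------------------------------------------------

def call_methylation(report: CytosineReport, min_coverage: int = 10) -> MethylationCallSet:
    """Drop sites below ``min_coverage`` and compute methylation fractions."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    df = report.data
    cov = df["count_m"] + df["count_u"]
    keep = df.loc[cov >= min_coverage].copy()
    keep["coverage"] = (keep["count_m"] + keep["count_u"]).astype(int)
    keep["fraction"] = keep["count_m"] / keep["coverage"]
    out = keep[["scaffold", "pos", "strand", "context", "coverage", "fraction"]]
    out = out.reset_index(drop=True)
    return MethylationCallSet(report.sample_id, min_coverage, out)


def destrand(report: CytosineReport, genome) -> CytosineReport:
    """Merge symmetric CpG dyads by summing counts onto the plus-strand C.

    Only CpG-context sites are merged; other contexts pass through unchanged.
    """
    df = report.data
    cpg = df[df["context"] == "CpG"].copy()
    rest = df[df["context"] != "CpG"]
    # the minus-strand member of a dyad sits one base downstream of the plus C
    key_pos = np.where(cpg["strand"] == "-", cpg["pos"] - 1, cpg["pos"])
    cpg["_key"] = key_pos
    merged = (
        cpg.groupby(["scaffold", "_key"], as_index=False)
        .agg(count_m=("count_m", "sum"), count_u=("count_u", "sum"))
        .rename(columns={"_key": "pos"})
    )
    merged["strand"] = "+"
    merged["context"] = "CpG"
    out = pd.concat(
        [merged[["scaffold", "pos", "strand", "context", "count_m", "count_u"]], rest],
        ignore_index=True,
    ).sort_values(["scaffold", "pos", "strand"], kind="mergesort", ignore_index=True)
    return CytosineReport(report.sample_id, out)


def unite_positions(callsets, context_filter: str | None = "CpG",
                    label: str = "") -> UnitedMatrix:
    """Intersect positions covered in every call set (methylKit-style unite).

    Restricts to ``context_filter`` when given.  Column order follows the
    input order of the call sets; the retained row set does not depend on it.
    """
    callsets = list(callsets)
    if len(callsets) < 2:
        raise ValueError("unite_positions needs at least two call sets")
    ids = [cs.sample_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in {ids}")
    min_cov = min(cs.min_coverage for cs in callsets)
    merged = None
    for cs in callsets:
        df = cs.data
        if context_filter is not None:
            df = df[df["context"] == context_filter]
        m = (df["fraction"].astype(float) * df["coverage"].astype(float)).round().astype(int)
        part = pd.DataFrame(
            {
                "scaffold": df["scaffold"].to_numpy(),
                "pos": df["pos"].to_numpy(),
                "strand": df["strand"].to_numpy(),
                "context": df["context"].to_numpy(),
                f"{cs.sample_id}.M": m.to_numpy(),
                f"{cs.sample_id}.U": (df["coverage"] - m).to_numpy(),
            }
        )
        if merged is None:
            merged = part
        else:
            merged = merged.merge(
                part.drop(columns=["context"]),
                on=["scaffold", "pos", "strand"],
                how="inner",
            )
    merged = merged.sort_values(
        ["scaffold", "pos", "strand"], kind="mergesort", ignore_index=True
    )
    return UnitedMatrix(samples=ids, min_coverage=min_cov, data=merged, label=label)


def global_methylation_summary(callset: MethylationCallSet) -> pd.DataFrame:
    """Per-context pooled methylation rate and mean of per-site fractions.

    The pooled rate is total methylated reads over total reads; the mean of
    fractions weights every covered site equally.  Only contexts present in
    the call set appear.
    """
    if len(callset) == 0:
        raise ValueError("empty call set")
    df = callset.data
    m_reads = df["fraction"] * df["coverage"]
    grp = df.assign(m_reads=m_reads).groupby("context")
    out = pd.DataFrame(
        {
            "n_sites": grp.size(),
            "pooled_rate": grp["m_reads"].sum() / grp["coverage"].sum(),
            "mean_fraction": grp["fraction"].mean(),
        }
    ).reset_index()
    return out
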