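"""The yo-yo experimental design and effect disentangling.

Three genotypes (families) each contribute one control and one treatment
individual; the treatment animals are moved 8 m -> 30 m -> 8 m at monthly
intervals while controls stay at 8 m, and mantle is sampled at each transfer
(times S1, S2, S3).  Nine pairwise comparisons of 3-vs-3 sample groups
partition into three effect families:

* time effect          — controls across times (C-S1 vs C-S2, C-S2 vs C-S3,
                         C-S1 vs C-S3)
* depth+time effect    — treatment across times (T-S1 vs T-S2, ...)
* depth+genotype effect— treatment vs control at each time (T-S1 vs C-S1, ...)

The depth-only set is the non-redundant depth+time set minus any site that is
also time-affected (subtraction by genomic position, regardless of
direction).  The depth+genotype family is reported but takes no part in the
subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffmeth import DMCSet

GENOTYPES = (1, 2, 3)
TREATMENTS = ("C", "T")
TIMES = ("S1", "S2", "S3")

SITE_KEY = ["scaffold", "pos", "strand"]


@dataclass(frozen=True)
class ComparisonSpec:
    label: str
    family: str  # time | depth_time | depth_genotype
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]


@dataclass
class SampleDesign:
    """Sample sheet: one row per (sample_id, genotype, treatment, time)."""

    samples: pd.DataFrame

    @classmethod
    def full(cls) -> "SampleDesign":
        """The complete 18-sample factorial: 3 genotypes x {C,T} x 3 times."""
        rows = [
            (f"{t}{g}-{s}", g, t, s)
            for t in TREATMENTS
            for g in GENOTYPES
            for s in TIMES
        ]
        return cls(pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment", "time"]))

    @classmethod
    def read_tsv(cls, path) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t", comment="#")
        need = {"sample_id", "genotype", "treatment", "time"}
        if not need.issubset(df.columns):
            raise ValueError(f"design file must have columns {sorted(need)}")
        return cls(df)

    def write_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)

    def group(self, treatment: str, time: str) -> tuple[str, ...]:
        df = self.samples
        sel = df[(df["treatment"] == treatment) & (df["time"] == time)]
        return tuple(sel["sample_id"])

    def validate_full(self) -> None:
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        missing = [
            f"{t}-{s}"
            for t in TREATMENTS
            for s in TIMES
            if len(self.group(t, s)) != len(GENOTYPES)
        ]
        if missing:
            raise ValueError(f"incomplete design; missing or short cells: {missing}")


def enumerate_comparisons(design: SampleDesign) -> list[ComparisonSpec]:
    """The nine pairwise comparisons, three per effect family."""
    design.validate_full()
    specs = []
    pairs = [("S1", "S2"), ("S2", "S3"), ("S1", "S3")]
    for a, b in pairs:
        specs.append(ComparisonSpec(
            f"C-{a} vs C-{b}", "time", design.group("C", a), design.group("C", b)))
    for a, b in pairs:
        specs.append(ComparisonSpec(
            f"T-{a} vs T-{b}", "depth_time", design.group("T", a), design.group("T", b)))
    for s in TIMES:
        specs.append(ComparisonSpec(
            f"T-{s} vs C-{s}", "depth_genotype", design.group("T", s), design.group("C", s)))
    return specs


def _as_frame(dmc_set) -> pd.DataFrame:
    if isinstance(dmc_set, DMCSet):
        df = dmc_set.data.copy()
        df["comparison"] = dmc_set.label
        return df
    return dmc_set.copy()


def nonredundant_union(dmc_sets) -> pd.DataFrame:
    """Union of DMC sets keyed by (scaffold, pos, strand, direction).

    A site found in several comparisons of a family counts once per
    direction.  Sites that are hyper in one comparison and hypo in another
    keep both entries, marked ``discordant``.
    """
    frames = [_as_frame(s) for s in dmc_sets]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(
            columns=SITE_KEY + ["context", "direction", "discordant", "comparison"]
        )
    cat = pd.concat(frames, ignore_index=True)
    keep_cols = [c for c in ["context", "comparison", "meth_diff", "q"] if c in cat.columns]
    dedup = cat.drop_duplicates(subset=SITE_KEY + ["direction"])[
        SITE_KEY + ["direction"] + keep_cols
    ].reset_index(drop=True)
    n_dir = dedup.groupby(SITE_KEY)["direction"].transform("nunique")
    dedup["discordant"] = n_dir > 1
    return dedup.sort_values(SITE_KEY + ["direction"], ignore_index=True)


def subtract_time_effect(depth_time: pd.DataFrame, time: pd.DataFrame) -> pd.DataFrame:
    """Depth-only DMCs: depth+time sites not time-affected at any direction.

    Subtraction is keyed by genomic site alone, so a position that moved in
    either direction over time in the controls is removed.
    """
    if len(depth_time) == 0:
        return depth_time.copy()
    if len(time) == 0:
        return depth_time.copy()
    time_keys = set(map(tuple, time[SITE_KEY].itertuples(index=False)))
    mask = [
        tuple(row) not in time_keys
        for row in depth_time[SITE_KEY].itertuples(index=False)
    ]
    return depth_time.loc[mask].reset_index(drop=True)


@dataclass
class EffectSets:
    time_effect: pd.DataFrame
    depth_time_effect: pd.DataFrame
    depth_genotype_effect: pd.DataFrame
    depth_only: pd.DataFrame


def disentangle_effects(dmc_sets_by_family: dict[str, list]) -> EffectSets:
    """Non-redundant unions per family plus the time-subtracted depth set."""
    time = nonredundant_union(dmc_sets_by_family.get("time", []))
    depth_time = nonredundant_union(dmc_sets_by_family.get("depth_time", []))
    depth_gen = nonredundant_union(dmc_sets_by_family.get("depth_genotype", []))
    depth_only = subtract_time_effect(depth_time, time)
    return EffectSets(time, depth_time, depth_gen, depth_only)


def effect_report(effects: EffectSets) -> pd.DataFrame:
    """Counts of non-redundant hyper/hypo sites per effect family and context."""
    rows = []
    for family, df in [
        ("time", effects.time_effect),
        ("depth_time", effects.depth_time_effect),
        ("depth_genotype", effects.depth_genotype_effect),
        ("depth_only", effects.depth_only),
    ]:
        for context in ("CpG", "CHG", "CHH", "CN/CHN"):
            sub = df[df.get("context", pd.Series(dtype=object)) == context] if len(df) else df
            n_hyper = int((sub["direction"] == "hyper").sum()) if len(sub) else 0
            n_hypo = int((sub["direction"] == "hypo").sum()) if len(sub) else 0
            if n_hyper or n_hypo or context == "CpG":
                rows.append((family, context, n_hyper, n_hypo, n_hyper + n_hypo))
    return pd.DataFrame(
        rows, columns=["effect", "context", "n_hyper", "n_hypo", "n_total"]
    )
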