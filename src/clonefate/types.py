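"""Domain types for the PDX clonal-fidelity analysis.

Tabular values are held as pandas DataFrames wrapped in light dataclasses
that validate the invariants the downstream algorithms rely on (tree shape,
CCF bounds, segment ordering, key uniqueness).  Coordinates are 0-based
half-open internally; the TSV interchange layer (:mod:`clonefate.io`)
converts to and from the 1-based end-inclusive convention of ASCAT-style
segment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

__all__ = [
    "ValidationError",
    "CloneTree",
    "CCFTable",
    "SampleMeta",
    "SampleSheet",
    "SegmentProfile",
    "VariantTable",
    "CohortOutcomes",
    "StrainSNPSet",
    "normalize_chrom",
    "is_autosome",
]

SEX_CHROMS = {"X", "Y"}


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant.

    ``problems`` lists every violation found, not just the first.
    """

    def __init__(self, problems: Iterable[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix; ``chr1``/``1`` both become ``1``."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) not in SEX_CHROMS


@dataclass(frozen=True)
class CloneTree:
    """Rooted phylogeny of mutation clusters for one tumor.

    ``parent_of`` maps every non-root cluster to its parent; the root
    (truncal cluster) is absent from the mapping.
    """

    tumor_id: str
    parent_of: Mapping[str, str]
    root: str = field(init=False)

    def __post_init__(self) -> None:
        problems = []
        children = set(self.parent_of)
        parents = set(self.parent_of.values())
        nodes = children | parents
        roots = parents - children
        if not self.parent_of:
            raise ValidationError(["tree has no edges and no declared root"])
        if len(roots) == 0:
            raise ValidationError(["cycle detected: no root-connected cluster"])
        if len(roots) > 1:
            problems.append(f"multiple roots: {sorted(roots)}")
        root = min(roots)
        # cycle check: every node must reach the root
        for node in nodes:
            seen = set()
            cur = node
            while cur in self.parent_of:
                if cur in seen:
                    problems.append(f"cycle detected at cluster {cur!r}")
                    break
                seen.add(cur)
                cur = self.parent_of[cur]
        if problems:
            raise ValidationError(problems)
        object.__setattr__(self, "parent_of", dict(self.parent_of))
        object.__setattr__(self, "root", root)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.parent_of) | {self.root}

    def children(self, cluster: str) -> list[str]:
        return sorted(c for c, p in self.parent_of.items() if p == cluster)

    def parent(self, cluster: str) -> Optional[str]:
        return self.parent_of.get(cluster)

    def ancestors(self, cluster: str) -> list[str]:
        """Ancestors ordered from parent to root (cluster excluded)."""
        out = []
        cur = self.parent_of.get(cluster)
        while cur is not None:
            out.append(cur)
            cur = self.parent_of.get(cur)
        return out

    def subtree(self, cluster: str) -> set[str]:
        out = {cluster}
        stack = [cluster]
        while stack:
            for c in self.children(stack.pop()):
                out.add(c)
                stack.append(c)
        return out

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children(node)))

    def to_newick(self) -> str:
        def rec(node: str) -> str:
            kids = self.children(node)
            if not kids:
                return node
            return "(" + ",".join(rec(k) for k in kids) + ")" + node

        return rec(self.root) + ";"


CCF_COLUMNS = ["tumor_id", "cluster_id", "sample_id", "ccf", "clonal_flag"]


@dataclass
class CCFTable:
    """Cluster-by-sample cancer cell fractions (phyloCCF).

    A cluster missing from a sample is interpreted as absent (CCF 0).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        problems = []
        for col in CCF_COLUMNS[:4]:
            if col not in df.columns:
                problems.append(f"missing column {col!r}")
        if problems:
            raise ValidationError(problems)
        if "clonal_flag" not in df.columns:
            df["clonal_flag"] = pd.NA
        df = df[CCF_COLUMNS]
        df["ccf"] = df["ccf"].astype(float)
        bad = df[(df["ccf"] < 0) | (df["ccf"] > 1)]
        for _, r in bad.iterrows():
            problems.append(
                f"ccf out of [0,1] for cluster {r.cluster_id!r} "
                f"sample {r.sample_id!r}: {r.ccf}"
            )
        dup = df.duplicated(subset=["cluster_id", "sample_id"])
        for _, r in df[dup].iterrows():
            problems.append(
                f"duplicate (cluster, sample) key: ({r.cluster_id!r}, {r.sample_id!r})"
            )
        if problems:
            raise ValidationError(problems)
        self.df = df.reset_index(drop=True)

    def sample_ccfs(self, sample_id: str) -> dict[str, float]:
        sub = self.df[self.df["sample_id"] == sample_id]
        return dict(zip(sub["cluster_id"], sub["ccf"]))

    def sample_clonal_flags(self, sample_id: str) -> dict[str, bool]:
        sub = self.df[self.df["sample_id"] == sample_id]
        return {
            c: bool(f)
            for c, f in zip(sub["cluster_id"], sub["clonal_flag"])
            if pd.notna(f)
        }

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced sample (primary region or PDX)."""

    sample_id: str
    patient_id: str
    tumor_id: str
    region_label: str
    sample_kind: str  # "primary_region" | "pdx"
    passage: Optional[int] = None
    histology: str = "other"
    purity: Optional[float] = None
    region_of_origin: Optional[str] = None

    def __post_init__(self) -> None:
        problems = []
        if self.sample_kind not in ("primary_region", "pdx"):
            problems.append(f"unknown sample_kind {self.sample_kind!r}")
        if self.sample_kind == "pdx":
            if self.passage is None:
                problems.append(f"pdx sample {self.sample_id!r} lacks passage")
            if self.region_of_origin is None:
                problems.append(f"pdx sample {self.sample_id!r} lacks region_of_origin")
        else:
            if self.passage is not None or self.region_of_origin is not None:
                problems.append(
                    f"primary region {self.sample_id!r} must not set "
                    "passage/region_of_origin"
                )
        if problems:
            raise ValidationError(problems)


@dataclass
class SampleSheet:
    """Collection of :class:`SampleMeta`, keyed by sample id."""

    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError([f"duplicate sample_id: {d!r}" for d in dupes])
        self._by_id = {s.sample_id: s for s in self.samples}

    def __getitem__(self, sample_id: str) -> SampleMeta:
        return self._by_id[sample_id]

    def __iter__(self) -> Iterator[SampleMeta]:
        return iter(self.samples)

    def primary_regions(self, tumor_id: str) -> list[SampleMeta]:
        return [
            s
            for s in self.samples
            if s.tumor_id == tumor_id and s.sample_kind == "primary_region"
        ]

    def pdx_samples(self, tumor_id: str) -> list[SampleMeta]:
        return [
            s for s in self.samples if s.tumor_id == tumor_id and s.sample_kind == "pdx"
        ]

    @property
    def tumors(self) -> list[str]:
        return sorted({s.tumor_id for s in self.samples})


SEGMENT_COLUMNS = ["chrom", "start", "end", "cn_a", "cn_b", "n_het_snps"]


@dataclass
class SegmentProfile:
    """Allele-specific copy-number segments for one sample.

    Segments use 0-based half-open coordinates, are sorted and
    non-overlapping within each chromosome.  ``genome`` maps chromosome
    name to length in bp and defines the denominator of genome-wide
    fractions.
    """

    sample_id: str
    segments: pd.DataFrame
    ploidy: float
    genome: Mapping[str, int]

    def __post_init__(self) -> None:
        df = self.segments.copy()
        problems = []
        for col in SEGMENT_COLUMNS:
            if col not in df.columns:
                problems.append(f"missing column {col!r}")
        if problems:
            raise ValidationError(problems)
        df["chrom"] = df["chrom"].map(normalize_chrom)
        for col in ("start", "end", "n_het_snps"):
            df[col] = df[col].astype(int)
        # allele CN may be real-valued (subclonal fits); keep float
        for col in ("cn_a", "cn_b"):
            df[col] = df[col].astype(float)
        if (df[["cn_a", "cn_b"]] < 0).any().any():
            problems.append("negative allele copy number")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]]
            for _, r in bad.iterrows():
                problems.append(f"empty segment {r.chrom}:{r.start}-{r.end}")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom"):
            ends = sub["end"].to_numpy()
            starts = sub["start"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                problems.append(f"overlapping segments on chromosome {chrom}")
            genome = {normalize_chrom(c): int(l) for c, l in self.genome.items()}
            if chrom not in genome:
                problems.append(f"segment chromosome {chrom!r} absent from genome")
            elif ends.max() > genome[chrom]:
                problems.append(f"segment exceeds length of chromosome {chrom}")
        if self.ploidy <= 0:
            problems.append(f"non-positive ploidy {self.ploidy}")
        if problems:
            raise ValidationError(problems)
        self.segments = df[SEGMENT_COLUMNS]
        self.genome = {normalize_chrom(c): int(l) for c, l in self.genome.items()}

    @property
    def total_cn(self) -> pd.Series:
        return self.segments["cn_a"] + self.segments["cn_b"]

    @property
    def minor_cn(self) -> pd.Series:
        return self.segments[["cn_a", "cn_b"]].min(axis=1)

    @property
    def major_cn(self) -> pd.Series:
        return self.segments[["cn_a", "cn_b"]].max(axis=1)

    @property
    def lengths(self) -> pd.Series:
        return self.segments["end"] - self.segments["start"]

    def genome_length(self, autosomes_only: bool = False) -> int:
        return sum(
            l for c, l in self.genome.items() if not autosomes_only or is_autosome(c)
        )


VARIANT_COLUMNS = [
    "patient_id",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "vaf",
    "depth",
    "alt_reads",
    "germline_alt_reads",
    "germline_vaf",
    "called_varscan",
    "called_mutect",
    "somatic_p",
    "is_driver",
]

VARIANT_CLASSES = {"SNV", "indel", "dinucleotide"}


@dataclass
class VariantTable:
    """Caller-style somatic variant evidence, one row per variant per sample."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        problems = []
        for col in VARIANT_COLUMNS:
            if col == "is_driver" and col not in df.columns:
                df[col] = pd.NA
                continue
            if col not in df.columns:
                problems.append(f"missing column {col!r}")
        if problems:
            raise ValidationError(problems)
        df["chrom"] = df["chrom"].map(normalize_chrom)
        for col in ("vaf", "germline_vaf", "somatic_p"):
            df[col] = df[col].astype(float)
        for col in ("pos", "depth", "alt_reads", "germline_alt_reads"):
            df[col] = df[col].astype(int)
        for col in ("called_varscan", "called_mutect"):
            df[col] = df[col].astype(bool)
        bad_class = ~df["variant_class"].isin(VARIANT_CLASSES)
        for vc in df.loc[bad_class, "variant_class"].unique():
            problems.append(f"unknown variant_class {vc!r}")
        if ((df["vaf"] < 0) | (df["vaf"] > 1)).any():
            problems.append("vaf out of [0,1]")
        over = df["alt_reads"] > df["depth"]
        for _, r in df[over].iterrows():
            problems.append(
                f"alt_reads > depth at {r.chrom}:{r.pos} in {r.sample_id!r}"
            )
        key = ["sample_id", "chrom", "pos", "ref", "alt"]
        dup = df.duplicated(subset=key)
        for _, r in df[dup].iterrows():
            problems.append(f"duplicate variant row {r.chrom}:{r.pos} {r.sample_id!r}")
        if problems:
            raise ValidationError(problems)
        self.df = df[VARIANT_COLUMNS].reset_index(drop=True)


OUTCOME_COLUMNS = [
    "patient_id",
    "region_label",
    "histology",
    "engrafted",
    "is_lymphoproliferation",
]


@dataclass
class CohortOutcomes:
    """Per patient x region engraftment outcome.

    Lymphoproliferative (hCD45+) outgrowths are xenografts but never count
    as successful engraftments.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        problems = [f"missing column {c!r}" for c in OUTCOME_COLUMNS if c not in df.columns]
        if problems:
            raise ValidationError(problems)
        for col in ("engrafted", "is_lymphoproliferation"):
            df[col] = df[col].astype(bool)
        dup = df.duplicated(subset=["patient_id", "region_label"])
        for _, r in df[dup].iterrows():
            problems.append(
                f"duplicate (patient, region): ({r.patient_id!r}, {r.region_label!r})"
            )
        both = df["engrafted"] & df["is_lymphoproliferation"]
        for _, r in df[both].iterrows():
            problems.append(
                f"lymphoproliferation marked engrafted: "
                f"({r.patient_id!r}, {r.region_label!r})"
            )
        if problems:
            raise ValidationError(problems)
        self.df = df[OUTCOME_COLUMNS].reset_index(drop=True)


SNP_GENOTYPE_CLASSES = {"homozygous", "heterozygous", "non_reference_heterozygous"}


@dataclass
class StrainSNPSet:
    """Strain-specific SNPs relative to a companion reference genome.

    ``alt_alleles`` is an ordered tuple; the spike-in substitutes the first
    alternate allele of every retained record.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        problems = []
        for col in ("chrom", "pos", "ref_allele", "alt_alleles", "genotype_class"):
            if col not in df.columns:
                problems.append(f"missing column {col!r}")
        if problems:
            raise ValidationError(problems)
        df["pos"] = df["pos"].astype(int)
        df["alt_alleles"] = df["alt_alleles"].map(tuple)
        empty = df["alt_alleles"].map(len) == 0
        for _, r in df[empty].iterrows():
            problems.append(f"SNP at {r.chrom}:{r.pos} has no alternate alleles")
        bad = ~df["genotype_class"].isin(SNP_GENOTYPE_CLASSES)
        for gc in df.loc[bad, "genotype_class"].unique():
            problems.append(f"unknown genotype_class {gc!r}")
        if problems:
            raise ValidationError(problems)
        self.df = df.reset_index(drop=True)

    def retained(self) -> pd.DataFrame:
        """Records kept for reference adaptation: homozygous-alt and
        non-reference heterozygous; plain ref/alt heterozygous are dropped."""
        keep = self.df["genotype_class"].isin(
            ["homozygous", "non_reference_heterozygous"]
        )
        return self.df[keep].reset_index(drop=True)
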