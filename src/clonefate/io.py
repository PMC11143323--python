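"""Readers and writers for the TSV interchange formats.

All interchange tables are tab-separated with a header row.  Segment
coordinates on disk are 1-based end-inclusive (the convention of
ASCAT-style segment tables); the converters in this module are the only
place the shift to the internal 0-based half-open convention happens.
FASTA/VCF handling lives in :mod:`clonefate.seq_qc`.
"""

from __future__ import annotations

import os
from typing import Mapping, Union

import pandas as pd

from .types import (
    CCFTable,
    CloneTree,
    CohortOutcomes,
    SampleMeta,
    SampleSheet,
    SegmentProfile,
    ValidationError,
    VariantTable,
    normalize_chrom,
)

PathLike = Union[str, os.PathLike]


def _read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def _write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


# -- clone trees -------------------------------------------------------------

def read_clone_tree(path: PathLike, tumor_id: str | None = None) -> CloneTree:
    """Read a parent/child TSV into a validated :class:`CloneTree`.

    The root row has an empty parent field.  Structural defects (cycles,
    multiple roots, orphan rows) raise :class:`ValidationError` naming the
    offending row.
    """
    df = _read_tsv(path, dtype=str, keep_default_na=False)
    problems = [f"missing column {c!r}" for c in ("parent", "child") if c not in df.columns]
    if problems:
        raise ValidationError(problems)
    parent_of: dict[str, str] = {}
    roots = []
    for i, row in df.iterrows():
        child = row["child"].strip()
        parent = row["parent"].strip()
        if not child:
            raise ValidationError([f"row {i + 2}: empty child field"])
        if child in parent_of or child in roots:
            raise ValidationError([f"row {i + 2}: cluster {child!r} listed twice"])
        if parent == "":
            roots.append(child)
        else:
            parent_of[child] = parent
    if not roots and not parent_of:
        raise ValidationError(["tree file has no rows"])
    if len(roots) > 1:
        raise ValidationError([f"multiple root rows: {sorted(roots)}"])
    # every parent must be declared as a child somewhere or be the root
    declared = set(parent_of) | set(roots)
    orphans = sorted(set(parent_of.values()) - declared)
    if orphans:
        raise ValidationError([f"orphan cluster referenced as parent: {o!r}" for o in orphans])
    if tumor_id is None:
        tumor_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    if not parent_of:  # single-node tree: root only
        tree = CloneTree.__new__(CloneTree)
        object.__setattr__(tree, "tumor_id", tumor_id)
        object.__setattr__(tree, "parent_of", {})
        object.__setattr__(tree, "root", roots[0])
        return tree
    tree = CloneTree(tumor_id=tumor_id, parent_of=parent_of)
    if roots and tree.root != roots[0]:
        raise ValidationError(
            [f"declared root {roots[0]!r} is not the structural root {tree.root!r}"]
        )
    return tree


def write_clone_tree(tree: CloneTree, path: PathLike) -> None:
    rows = [{"parent": "", "child": tree.root}]
    for node in tree.preorder():
        for child in tree.children(node):
            rows.append({"parent": node, "child": child})
    _write_tsv(pd.DataFrame(rows, columns=["parent", "child"]), path)


def write_newick(tree: CloneTree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# -- CCF tables --------------------------------------------------------------

def read_ccf_table(path: PathLike) -> CCFTable:
    df = _read_tsv(path)
    if "clonal_flag" in df.columns:
        df["clonal_flag"] = df["clonal_flag"].map(
            lambda v: pd.NA if pd.isna(v) or v == "" else bool(v)
        )
    return CCFTable(df)


def write_ccf_table(table: CCFTable, path: PathLike) -> None:
    _write_tsv(table.df, path)


# -- genomes and segments ----------------------------------------------------

def read_genome(path: PathLike) -> dict[str, int]:
    df = _read_tsv(path, dtype={"chrom": str, "length": int})
    problems = [f"missing column {c!r}" for c in ("chrom", "length") if c not in df.columns]
    if problems:
        raise ValidationError(problems)
    return {normalize_chrom(c): int(l) for c, l in zip(df["chrom"], df["length"])}


def write_genome(genome: Mapping[str, int], path: PathLike) -> None:
    df = pd.DataFrame(
        {"chrom": list(genome.keys()), "length": list(genome.values())}
    )
    _write_tsv(df, path)


def read_segments(
    path: PathLike, genome: Mapping[str, int], ploidy: float | Mapping[str, float] = 2.0
) -> dict[str, SegmentProfile]:
    """Read a multi-sample segment TSV (1-based inclusive coordinates).

    ``ploidy`` may be a single value or a per-sample mapping.  Returns one
    :class:`SegmentProfile` per sample id found in the file.
    """
    df = _read_tsv(path, dtype={"chrom": str})
    problems = [
        f"missing column {c!r}"
        for c in ("sample_id", "chrom", "start", "end", "cn_a", "cn_b", "n_het_snps")
        if c not in df.columns
    ]
    if problems:
        raise ValidationError(problems)
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    profiles = {}
    for sample_id, sub in df.groupby("sample_id"):
        p = ploidy[sample_id] if isinstance(ploidy, Mapping) else ploidy
        profiles[str(sample_id)] = SegmentProfile(
            sample_id=str(sample_id),
            segments=sub.drop(columns=["sample_id"]).reset_index(drop=True),
            ploidy=float(p),
            genome=genome,
        )
    return profiles


def write_segments(profiles: Mapping[str, SegmentProfile] | SegmentProfile, path: PathLike) -> None:
    if isinstance(profiles, SegmentProfile):
        profiles = {profiles.sample_id: profiles}
    frames = []
    for sample_id in sorted(profiles):
        prof = profiles[sample_id]
        sub = prof.segments.copy()
        sub.insert(0, "sample_id", sample_id)
        sub["start"] = sub["start"] + 1  # back to 1-based inclusive
        frames.append(sub)
    _write_tsv(pd.concat(frames, ignore_index=True), path)


def write_segments_bed(profile: SegmentProfile, path: PathLike) -> None:
    """BED export (0-based half-open): chrom, start, end, name=cnA|cnB."""
    sub = profile.segments
    with open(path, "w") as fh:
        for _, r in sub.iterrows():
            name = f"{r.cn_a:g}|{r.cn_b:g}"
            fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{name}\n")


# -- variants, outcomes, metadata -------------------------------------------

def read_variants(path: PathLike) -> VariantTable:
    df = _read_tsv(path, dtype={"chrom": str})
    return VariantTable(df)


def write_variants(table: VariantTable, path: PathLike) -> None:
    _write_tsv(table.df, path)


def read_outcomes(path: PathLike) -> CohortOutcomes:
    return CohortOutcomes(_read_tsv(path))


def write_outcomes(outcomes: CohortOutcomes, path: PathLike) -> None:
    _write_tsv(outcomes.df, path)


META_COLUMNS = [
    "sample_id",
    "patient_id",
    "tumor_id",
    "region_label",
    "sample_kind",
    "passage",
    "histology",
    "purity",
    "region_of_origin",
]


def read_sample_sheet(path: PathLike) -> SampleSheet:
    df = _read_tsv(path, dtype=str, keep_default_na=False)
    problems = [f"missing column {c!r}" for c in META_COLUMNS[:5] if c not in df.columns]
    if problems:
        raise ValidationError(problems)
    samples = []
    for _, r in df.iterrows():
        samples.append(
            SampleMeta(
                sample_id=r["sample_id"],
                patient_id=r["patient_id"],
                tumor_id=r["tumor_id"],
                region_label=r["region_label"],
                sample_kind=r["sample_kind"],
                passage=int(r["passage"]) if r.get("passage", "") != "" else None,
                histology=r.get("histology", "other") or "other",
                purity=float(r["purity"]) if r.get("purity", "") != "" else None,
                region_of_origin=r.get("region_of_origin") or None,
            )
        )
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: PathLike) -> None:
    rows = []
    for s in sheet:
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "tumor_id": s.tumor_id,
                "region_label": s.region_label,
                "sample_kind": s.sample_kind,
                "passage": "" if s.passage is None else s.passage,
                "histology": s.histology,
                "purity": "" if s.purity is None else s.purity,
                "region_of_origin": s.region_of_origin or "",
            }
        )
    _write_tsv(pd.DataFrame(rows, columns=META_COLUMNS), path)
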