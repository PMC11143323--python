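"""Variant-level filtering, dinucleotide/indel harmonization, strain-SNP
reference spike-in, and the recurrent PDX-unique mutation audit.

SNV filter: a call is a true positive when VAF > 2% with support from both
VarScan2 (somatic p <= 0.01) and MuTect, or VAF >= 5% when called by
VarScan2 alone (again p <= 0.01); additionally depth >= 30x, >= 10 reads
supporting the variant, < 5 supporting reads in the germline and germline
VAF <= 1%.  Multi-region power is leveraged through a rescue step: a
variant passing in at least one region of a patient is re-queried in the
other regions with the VAF requirement relaxed to >= 1%.

Indels use the same rules except somatic p <= 0.001, depth >= 50x, and no
minimum alt-read count.  Adjacent SNVs whose allele frequencies a
two-sample proportion test cannot distinguish are merged into a single
dinucleotide substitution with averaged coverage and counts.

The spike-in builds a strain-adapted reference by substituting the first
alternate allele of every retained (homozygous-alt or non-reference
heterozygous) SNP into the reference FASTA; plain ref/alt heterozygous
records are dropped.  The audit flags non-driver variants private to PDX
samples that recur across two or more tumors — the signature of residual
host-read contamination rather than convergent evolution.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .types import SampleSheet, StrainSNPSet, ValidationError, VariantTable

PathLike = Union[str, os.PathLike]

# SNV rule constants
SNV_DUAL_CALLER_VAF = 0.02  # strict: VAF must exceed this
SNV_SINGLE_CALLER_VAF = 0.05  # inclusive
SNV_SOMATIC_P = 0.01
SNV_MIN_DEPTH = 30
SNV_MIN_ALT_READS = 10
GERMLINE_MAX_ALT_READS = 5  # strict: must be below this
GERMLINE_MAX_VAF = 0.01
RESCUE_MIN_VAF = 0.01

# indel deviations
INDEL_SOMATIC_P = 0.001
INDEL_MIN_DEPTH = 50

DINUCLEOTIDE_ALPHA = 0.05

PASS = "pass"
RESCUED = "rescued"
FAIL = "fail"

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class FilterDecision:
    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    verdict: str
    reasons: list[str] = field(default_factory=list)


def _row_reasons_snv(row: pd.Series, cfg: Mapping[str, float]) -> list[str]:
    reasons = []
    dual = bool(row["called_varscan"] and row["called_mutect"])
    varscan_only = bool(row["called_varscan"] and not row["called_mutect"])
    p_ok = row["somatic_p"] <= cfg["somatic_p"]
    if dual:
        if not (row["vaf"] > cfg["dual_caller_vaf"]):
            reasons.append("dual-caller VAF <= 2%")
        if not p_ok:
            reasons.append("somatic p-value above threshold")
    elif varscan_only:
        if not (row["vaf"] >= cfg["single_caller_vaf"]):
            reasons.append("single-caller VAF < 5%")
        if not p_ok:
            reasons.append("somatic p-value above threshold")
    else:
        reasons.append("not called by VarScan2")
    if row["depth"] < cfg["min_depth"]:
        reasons.append(f"depth < {cfg['min_depth']}x")
    if cfg["min_alt_reads"] and row["alt_reads"] < cfg["min_alt_reads"]:
        reasons.append(f"fewer than {cfg['min_alt_reads']} supporting reads")
    if not (row["germline_alt_reads"] < GERMLINE_MAX_ALT_READS):
        reasons.append("5 or more germline supporting reads")
    if not (row["germline_vaf"] <= GERMLINE_MAX_VAF):
        reasons.append("germline VAF > 1%")
    return reasons


def _filter_class(
    variants: VariantTable,
    variant_class: str,
    cfg: Mapping[str, float],
    rescue_min_vaf: float,
) -> list[FilterDecision]:
    df = variants.df
    df = df[df["variant_class"] == variant_class]
    decisions: list[FilterDecision] = []
    for _, patient_df in df.groupby("patient_id"):
        verdicts: dict[tuple, FilterDecision] = {}
        passed_keys = set()
        for _, row in patient_df.iterrows():
            reasons = _row_reasons_snv(row, cfg)
            key = (row["sample_id"], row["chrom"], row["pos"], row["ref"], row["alt"])
            verdicts[key] = FilterDecision(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                sample_id=row["sample_id"],
                verdict=PASS if not reasons else FAIL,
                reasons=reasons,
            )
            if not reasons:
                passed_keys.add((row["chrom"], row["pos"], row["ref"], row["alt"]))
        # rescue: failed calls at sites passing elsewhere in the patient
        for _, row in patient_df.iterrows():
            vkey = (row["chrom"], row["pos"], row["ref"], row["alt"])
            skey = (row["sample_id"],) + vkey
            d = verdicts[skey]
            if d.verdict == FAIL and vkey in passed_keys and row["vaf"] >= rescue_min_vaf:
                d.verdict = RESCUED
                d.reasons = []
        decisions.extend(verdicts.values())
    return decisions


def filter_snvs(
    variants: VariantTable, rescue_min_vaf: float = RESCUE_MIN_VAF
) -> list[FilterDecision]:
    """Apply the SNV true-positive rules per patient, with multi-region
    rescue of low-VAF calls at sites passing in a sibling region."""
    if variants.df[["germline_alt_reads", "germline_vaf"]].isna().any().any():
        raise ValidationError(["missing germline fields"])
    cfg = {
        "dual_caller_vaf": SNV_DUAL_CALLER_VAF,
        "single_caller_vaf": SNV_SINGLE_CALLER_VAF,
        "somatic_p": SNV_SOMATIC_P,
        "min_depth": SNV_MIN_DEPTH,
        "min_alt_reads": SNV_MIN_ALT_READS,
    }
    return _filter_class(variants, "SNV", cfg, rescue_min_vaf)


def filter_indels(
    variants: VariantTable, rescue_min_vaf: float = RESCUE_MIN_VAF
) -> list[FilterDecision]:
    """Indel rules: stricter somatic p (<= 0.001) and depth (>= 50x), no
    minimum supporting-read count."""
    if variants.df[["germline_alt_reads", "germline_vaf"]].isna().any().any():
        raise ValidationError(["missing germline fields"])
    cfg = {
        "dual_caller_vaf": SNV_DUAL_CALLER_VAF,
        "single_caller_vaf": SNV_SINGLE_CALLER_VAF,
        "somatic_p": INDEL_SOMATIC_P,
        "min_depth": INDEL_MIN_DEPTH,
        "min_alt_reads": 0,
    }
    return _filter_class(variants, "indel", cfg, rescue_min_vaf)


def decisions_to_frame(decisions: Sequence[FilterDecision]) -> pd.DataFrame:
    rows = [
        {
            "chrom": d.chrom,
            "pos": d.pos,
            "ref": d.ref,
            "alt": d.alt,
            "sample_id": d.sample_id,
            "verdict": d.verdict,
            "reasons": ";".join(d.reasons),
        }
        for d in decisions
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample_id", "verdict", "reasons"]
    )


def harmonize_indels(calls: pd.DataFrame) -> pd.DataFrame:
    """Unify discordant indel calls at one locus across regions.

    ``calls`` holds per-region indel records (columns ``sample_id``,
    ``chrom``, ``pos``, ``ref``, ``alt``, ``depth``, ``alt_reads``,
    ``vaf``).  Calls on the same chromosome whose reference spans overlap
    are treated as one event: the longest predicted indel is reported with
    the maximum of each sequence-related value (depth, alt reads, VAF).
    """
    out_rows = []
    for chrom, sub in calls.groupby("chrom"):
        sub = sub.sort_values("pos")
        spans = [
            (int(r["pos"]), int(r["pos"]) + max(len(r["ref"]), len(r["alt"])))
            for _, r in sub.iterrows()
        ]
        cluster_ids = []
        current = -1
        cur_end = -1
        for start, end in spans:
            if start >= cur_end:
                current += 1
                cur_end = end
            else:
                cur_end = max(cur_end, end)
            cluster_ids.append(current)
        sub = sub.assign(_cluster=cluster_ids)
        for _, grp in sub.groupby("_cluster"):
            longest = grp.loc[
                (grp["ref"].str.len() + grp["alt"].str.len()).idxmax()
            ]
            out_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(longest["pos"]),
                    "ref": longest["ref"],
                    "alt": longest["alt"],
                    "depth": int(grp["depth"].max()),
                    "alt_reads": int(grp["alt_reads"].max()),
                    "vaf": float(grp["vaf"].max()),
                    "n_regions": len(grp),
                }
            )
    return pd.DataFrame(
        out_rows,
        columns=["chrom", "pos", "ref", "alt", "depth", "alt_reads", "vaf", "n_regions"],
    )


def merge_dinucleotides(
    snvs: pd.DataFrame, alpha: float = DINUCLEOTIDE_ALPHA
) -> pd.DataFrame:
    """Merge adjacent passed SNVs into dinucleotide records when a
    two-sided two-sample proportion test cannot reject equality of their
    allele frequencies (p >= ``alpha``).

    The merged record spans both positions; coverage and variant counts
    become the pair means.  Input rows must belong to a single sample.
    """
    req = {"chrom", "pos", "ref", "alt", "depth", "alt_reads"}
    missing = req - set(snvs.columns)
    if missing:
        raise ValidationError([f"missing column {c!r}" for c in sorted(missing)])
    df = snvs.sort_values(["chrom", "pos"]).reset_index(drop=True)
    merged_rows = []
    consumed = set()
    for i in range(len(df) - 1):
        if i in consumed:
            continue
        a, b = df.iloc[i], df.iloc[i + 1]
        if a["chrom"] != b["chrom"] or b["pos"] != a["pos"] + 1:
            continue
        counts = np.array([a["alt_reads"], b["alt_reads"]])
        nobs = np.array([a["depth"], b["depth"]])
        _, p = proportions_ztest(counts, nobs, alternative="two-sided")
        if np.isnan(p):  # identical degenerate proportions (0/n vs 0/n)
            p = 1.0
        if p >= alpha:
            depth = (a["depth"] + b["depth"]) / 2
            alt_reads = (a["alt_reads"] + b["alt_reads"]) / 2
            merged_rows.append(
                {
                    "chrom": a["chrom"],
                    "pos": int(a["pos"]),
                    "end": int(b["pos"]),
                    "ref": str(a["ref"]) + str(b["ref"]),
                    "alt": str(a["alt"]) + str(b["alt"]),
                    "variant_class": "dinucleotide",
                    "depth": depth,
                    "alt_reads": alt_reads,
                    "vaf": alt_reads / depth,
                    "merged": True,
                }
            )
            consumed.update({i, i + 1})
    for i in range(len(df)):
        if i in consumed:
            continue
        r = df.iloc[i]
        merged_rows.append(
            {
                "chrom": r["chrom"],
                "pos": int(r["pos"]),
                "end": int(r["pos"]),
                "ref": r["ref"],
                "alt": r["alt"],
                "variant_class": "SNV",
                "depth": r["depth"],
                "alt_reads": r["alt_reads"],
                "vaf": r["alt_reads"] / r["depth"],
                "merged": False,
            }
        )
    out = pd.DataFrame(
        merged_rows,
        columns=[
            "chrom", "pos", "end", "ref", "alt", "variant_class",
            "depth", "alt_reads", "vaf", "merged",
        ],
    )
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


# -- strain SNPs and reference spike-in -------------------------------------

def read_strain_snps(vcf_path: PathLike) -> StrainSNPSet:
    """Read a strain SNP VCF (first sample's genotype classifies each
    record as homozygous / heterozygous / non-reference heterozygous)."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(os.fspath(vcf_path)):
        if not v.ALT:
            continue
        if not len(v.genotypes):
            raise ValidationError([f"record {v.CHROM}:{v.POS} has no genotype"])
        alleles = [a for a in v.genotypes[0][:-1] if a >= 0]
        non_ref = [a for a in alleles if a > 0]
        if not non_ref:
            continue  # hom-ref carries no strain difference
        if all(a > 0 for a in alleles):
            gclass = (
                "homozygous" if len(set(alleles)) == 1 else "non_reference_heterozygous"
            )
        else:
            gclass = "heterozygous"
        # order alt alleles by the genotype's allele indices, then the rest
        ordered = [v.ALT[a - 1] for a in dict.fromkeys(non_ref)]
        ordered += [a for a in v.ALT if a not in ordered]
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,  # 1-based as in VCF
                "ref_allele": v.REF,
                "alt_alleles": tuple(ordered),
                "genotype_class": gclass,
            }
        )
    return StrainSNPSet(pd.DataFrame(
        rows, columns=["chrom", "pos", "ref_allele", "alt_alleles", "genotype_class"]
    ))


def spike_snps_into_reference(
    fasta_path: PathLike, snps: StrainSNPSet, out_path: PathLike
) -> int:
    """Write a strain-adapted FASTA with retained SNPs substituted.

    Only homozygous-alt and non-reference heterozygous records are
    applied, substituting the *first* alternate allele; all other bases
    are copied byte-identically and the input's line wrapping is
    preserved.  Returns the number of substitutions made.
    """
    from pyfaidx import Fasta

    fasta = Fasta(os.fspath(fasta_path))
    retained = snps.retained()
    problems = []
    seen: set[tuple[str, int]] = set()
    edits: dict[str, list[tuple[int, str]]] = {}
    for _, r in retained.iterrows():
        chrom, pos = r["chrom"], int(r["pos"])
        if chrom not in fasta:
            problems.append(f"SNP chromosome {chrom!r} absent from FASTA")
            continue
        if (chrom, pos) in seen:
            problems.append(f"overlapping SNP records at {chrom}:{pos}")
            continue
        seen.add((chrom, pos))
        if not 1 <= pos <= len(fasta[chrom]):
            problems.append(f"SNP position {chrom}:{pos} outside sequence")
            continue
        ref = str(fasta[chrom][pos - 1 : pos])
        if ref.upper() != str(r["ref_allele"]).upper():
            problems.append(
                f"reference mismatch at {chrom}:{pos}: FASTA has {ref!r}, "
                f"SNP record expects {r['ref_allele']!r}"
            )
            continue
        alt = str(r["alt_alleles"][0])
        if len(alt) != 1 or len(str(r["ref_allele"])) != 1:
            problems.append(f"non-SNP record at {chrom}:{pos}")
            continue
        edits.setdefault(chrom, []).append((pos - 1, alt))
    if problems:
        raise ValidationError(problems)
    n_sub = 0
    with open(out_path, "w") as out:
        for name in fasta.keys():
            seq = list(str(fasta[name][:]))
            for idx, alt in edits.get(name, []):
                seq[idx] = alt
                n_sub += 1
            width = fasta.faidx.index[name].lenc or len(seq)
            out.write(f">{fasta[name].long_name}\n")
            for i in range(0, len(seq), width):
                out.write("".join(seq[i : i + width]) + "\n")
    fasta.close()
    return n_sub


# -- recurrent PDX-unique mutation audit -------------------------------------

def recurrent_pdx_unique_audit(
    variants: VariantTable, meta: SampleSheet, min_tumors: int = 2
) -> pd.DataFrame:
    """Flag non-driver variants private to PDX samples that recur across
    ``min_tumors`` or more tumors.

    A variant is PDX-unique within a patient when it is called in at least
    one PDX sample and in no primary region of that patient.  Recurrence of
    such variants across unrelated tumors indicates contaminating host
    reads escaping deconvolution, not biology.  Returns rows of (variant,
    n_tumors, n_instances) sorted by decreasing recurrence.
    """
    df = variants.df
    kind = {s.sample_id: s.sample_kind for s in meta}
    tumor = {s.sample_id: s.tumor_id for s in meta}
    unknown = set(df["sample_id"]) - set(kind)
    if unknown:
        raise ValidationError([f"sample {s!r} missing from metadata" for s in sorted(unknown)])
    df = df.assign(
        _kind=df["sample_id"].map(kind), _tumor=df["sample_id"].map(tumor)
    )
    records: dict[tuple, dict] = {}
    for (tumor_id, chrom, pos, ref, alt), grp in df.groupby(
        ["_tumor", "chrom", "pos", "ref", "alt"]
    ):
        if (grp["_kind"] == "primary_region").any():
            continue  # present in the matched primary: not PDX-unique
        if (grp["is_driver"] == True).any():  # noqa: E712 (nullable bool)
            continue
        key = (chrom, pos, ref, alt)
        rec = records.setdefault(
            key, {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                  "tumors": set(), "n_instances": 0}
        )
        rec["tumors"].add(tumor_id)
        rec["n_instances"] += int((grp["_kind"] == "pdx").sum())
    rows = [
        {
            "chrom": r["chrom"],
            "pos": r["pos"],
            "ref": r["ref"],
            "alt": r["alt"],
            "n_tumors": len(r["tumors"]),
            "n_instances": r["n_instances"],
        }
        for r in records.values()
        if len(r["tumors"]) >= min_tumors
    ]
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "n_tumors", "n_instances"]
    )
    return out.sort_values(
        ["n_tumors", "n_instances", "chrom", "pos"],
        ascending=[False, False, True, True],
    ).reset_index(drop=True)
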