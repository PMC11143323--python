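"""Allele-specific copy-number summary metrics.

Gains and losses are called relative to the sample's rounded ploidy (so a
genome-doubled sample is scored against a reference of 4).  LOH is a minor
allele copy number of zero; allelic imbalance (AI) is any difference
between the two allele copy numbers; mirrored subclonal allelic imbalance
(MSAI) is AI present in two samples but favoring opposite parental
alleles.  wFLOH is the unweighted mean over autosomes of the per-
chromosome fraction of length under LOH.  A sample is whole-genome
doubled (WGD) when the major allele has >= 2 copies over at least half of
the genome.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._intervals import common_intervals
from .types import SegmentProfile, is_autosome

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"

LOH_MINOR_CN_THRESHOLD = 0.1
LOH_MIN_HET_SNPS = 10
WGD_MAJOR_CN = 2
WGD_GENOME_FRACTION = 0.5


def classify_segments(profile: SegmentProfile) -> pd.DataFrame:
    """Per-segment state calls: gain/loss/neutral, LOH, AI, major allele."""
    seg = profile.segments.copy()
    ref = round(profile.ploidy)
    total = seg["cn_a"] + seg["cn_b"]
    seg["state"] = np.select(
        [total > ref, total < ref], [GAIN, LOSS], default=NEUTRAL
    )
    seg["loh"] = seg[["cn_a", "cn_b"]].min(axis=1) == 0
    seg["allelic_imbalance"] = seg["cn_a"] != seg["cn_b"]
    seg["major_allele_label"] = np.where(seg["cn_a"] >= seg["cn_b"], "A", "B")
    return seg


def _heterogeneous_mask(
    profiles: Sequence[SegmentProfile],
) -> pd.DataFrame:
    """Common intervals of a tumor's samples annotated with, per sample,
    whether the interval is aberrant, and whether the event is heterogeneous
    (not shared by all samples in the same direction)."""
    iv = common_intervals(profiles)
    n = len(profiles)
    gains, losses = [], []
    for k, p in enumerate(profiles):
        ref = round(p.ploidy)
        cn = iv[f"cn_a_{k}"] + iv[f"cn_b_{k}"]
        gains.append((cn > ref).to_numpy())
        losses.append((cn < ref).to_numpy())
    gain_all = np.logical_and.reduce(gains)
    loss_all = np.logical_and.reduce(losses)
    for k in range(n):
        aberrant = gains[k] | losses[k]
        # an event is homogeneous only when every sample shares it in the
        # same direction
        homogeneous = (gains[k] & gain_all) | (losses[k] & loss_all)
        iv[f"aberrant_{k}"] = aberrant
        iv[f"heterogeneous_{k}"] = aberrant & ~homogeneous
    return iv


def proportion_genome_aberrant(
    profile: SegmentProfile,
    subclonal_only: bool = False,
    tumor_profiles: Optional[Sequence[SegmentProfile]] = None,
) -> float:
    """Fraction of the genome with a gain or loss in this sample.

    With ``subclonal_only`` the event must additionally be heterogeneous
    within the tumor (absent, or in the other direction, in at least one
    of ``tumor_profiles``).
    """
    genome_len = profile.genome_length()
    if not subclonal_only:
        calls = classify_segments(profile)
        ab = calls["state"] != NEUTRAL
        return float((calls.loc[ab, "end"] - calls.loc[ab, "start"]).sum() / genome_len)
    if not tumor_profiles:
        raise ValueError("subclonal_only requires all tumor samples")
    profiles = list(tumor_profiles)
    k = next(
        i for i, p in enumerate(profiles) if p.sample_id == profile.sample_id
    )
    iv = _heterogeneous_mask(profiles)
    het = iv[iv[f"heterogeneous_{k}"]]
    return float(het["length"].sum() / genome_len)


def scna_ith(tumor_profiles: Sequence[SegmentProfile]) -> float:
    """Tumor-level copy-number heterogeneity: genome fraction with
    heterogeneous events divided by genome fraction with any event."""
    profiles = list(tumor_profiles)
    iv = _heterogeneous_mask(profiles)
    n = len(profiles)
    any_ab = np.logical_or.reduce([iv[f"aberrant_{k}"] for k in range(n)])
    any_het = np.logical_or.reduce([iv[f"heterogeneous_{k}"] for k in range(n)])
    len_ab = iv.loc[any_ab, "length"].sum()
    len_het = iv.loc[any_het, "length"].sum()
    if len_ab == 0:
        warnings.warn("no copy-number aberrations in tumor; SCNA ITH set to 0")
        return 0.0
    return float(len_het / len_ab)


def proportion_identical(
    profile_i: SegmentProfile, profile_j: SegmentProfile
) -> float:
    """Fraction of compared length where both samples have the same total
    copy number."""
    iv = common_intervals([profile_i, profile_j])
    if iv["length"].sum() == 0:
        raise ValueError("profiles share no covered genome")
    equal = (iv["cn_a_0"] + iv["cn_b_0"]) == (iv["cn_a_1"] + iv["cn_b_1"])
    return float(iv.loc[equal, "length"].sum() / iv["length"].sum())


def wfloh(profile: SegmentProfile) -> float:
    """Weighted fraction of the genome under LOH: mean over autosomes of
    per-chromosome LOH length / chromosome length; sex chromosomes are
    excluded."""
    autosomes = [c for c in profile.genome if is_autosome(c)]
    if not autosomes:
        raise ValueError("no autosomes in genome definition")
    calls = classify_segments(profile)
    fractions = []
    for chrom in autosomes:
        sub = calls[(calls["chrom"] == chrom) & calls["loh"]]
        fractions.append((sub["end"] - sub["start"]).sum() / profile.genome[chrom])
    return float(np.mean(fractions))


def msai_fraction(
    profile_i: SegmentProfile,
    profile_j: SegmentProfile,
    denominator: str = "both",
) -> float:
    """Fraction of allelic-imbalance length that is mirrored between the
    samples (opposite major allele).

    The denominator is the length with AI in both samples (``"both"``,
    default — MSAI is defined only where both samples show imbalance) or
    in either (``"either"``).  Allele labels must be phased consistently
    between the samples.
    """
    if denominator not in ("both", "either"):
        raise ValueError("denominator must be 'both' or 'either'")
    iv = common_intervals([profile_i, profile_j])
    ai_i = iv["cn_a_0"] != iv["cn_b_0"]
    ai_j = iv["cn_a_1"] != iv["cn_b_1"]
    major_i = iv["cn_a_0"] >= iv["cn_b_0"]
    major_j = iv["cn_a_1"] >= iv["cn_b_1"]
    mirrored = ai_i & ai_j & (major_i != major_j)
    denom_mask = (ai_i & ai_j) if denominator == "both" else (ai_i | ai_j)
    denom_len = iv.loc[denom_mask, "length"].sum()
    if denom_len == 0:
        return 0.0
    return float(iv.loc[mirrored, "length"].sum() / denom_len)


def loh_reversion_fraction(
    origin_profile: SegmentProfile,
    pdx_profile: SegmentProfile,
    min_het_snps: int = LOH_MIN_HET_SNPS,
    minor_cn_threshold: float = LOH_MINOR_CN_THRESHOLD,
) -> float:
    """Fraction of the region-of-origin's LOH length at which the PDX shows
    a restored minor allele.

    LOH at the single-cell level is irreversible, so apparent reversion
    flags outgrowth of a minor non-LOH population.  Only origin segments
    supported by more than ``min_het_snps`` heterozygous SNPs and with
    minor allele copy number below ``minor_cn_threshold`` are eligible;
    within their PDX-covered extent, length where the PDX minor copy
    number reaches the threshold counts as reverted.
    """
    org = origin_profile.segments
    eligible = org[
        (org["n_het_snps"] > min_het_snps)
        & (org[["cn_a", "cn_b"]].min(axis=1) < minor_cn_threshold)
    ]
    if eligible.empty:
        return 0.0
    elig_profile = SegmentProfile(
        sample_id=origin_profile.sample_id,
        segments=eligible.reset_index(drop=True),
        ploidy=origin_profile.ploidy,
        genome=origin_profile.genome,
    )
    iv = common_intervals([elig_profile, pdx_profile])
    total = iv["length"].sum()
    if total == 0:
        return 0.0
    pdx_minor = iv[["cn_a_1", "cn_b_1"]].min(axis=1)
    reverted = pdx_minor >= minor_cn_threshold
    return float(iv.loc[reverted, "length"].sum() / total)


def detect_wgd(
    profile: SegmentProfile,
    major_cn: float = WGD_MAJOR_CN,
    genome_fraction: float = WGD_GENOME_FRACTION,
) -> bool:
    """Whole-genome doubling: major allele copy number >= 2 over at least
    50% of the genome (inclusive bound)."""
    seg = profile.segments
    major = seg[["cn_a", "cn_b"]].max(axis=1)
    doubled_len = (seg.loc[major >= major_cn, "end"] - seg.loc[major >= major_cn, "start"]).sum()
    return bool(doubled_len / profile.genome_length() >= genome_fraction)


def sample_metrics(
    profile: SegmentProfile,
    tumor_profiles: Optional[Sequence[SegmentProfile]] = None,
) -> dict[str, float | bool]:
    """One-row summary of the per-sample metrics."""
    out: dict[str, float | bool] = {
        "proportion_aberrant": proportion_genome_aberrant(profile),
        "wfloh": wfloh(profile),
        "wgd": detect_wgd(profile),
        "ploidy": profile.ploidy,
    }
    if tumor_profiles and len(tumor_profiles) > 1:
        out["proportion_aberrant_subclonal"] = proportion_genome_aberrant(
            profile, subclonal_only=True, tumor_profiles=tumor_profiles
        )
    return out
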