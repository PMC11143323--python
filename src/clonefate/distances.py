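"""Between-sample divergence scores and the diversity classification.

Mutational distance between regions *i* and *j*: with *M* the mutations
present in either region, excluding truncal mutations,

    d_mut = (1/M) * sum_m |CCF_{i,m} - CCF_{j,m}|

which is large when few mutations are shared or shared mutations sit at
very different cellular frequencies, and lies in [0, 1].

Copy-number distance: with *S* the minimal common intervals aberrant
(gain or loss relative to ploidy) in either sample, excluding truncal
copy-number alterations,

    d_cn = sum_s l_s * |CN_{i,s} - CN_{j,s}| / sum_s l_s

with CN the total copy number and l_s the interval length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._intervals import common_intervals
from .clonal import DEFAULT_CLONAL_THRESHOLD, DEFAULT_DETECT_THRESHOLD
from .types import SegmentProfile

HIGHER_MUTATION = "higher_mutation"
HIGHER_COPY_NUMBER = "higher_copy_number"
INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class PairwiseDistance:
    sample_i: str
    sample_j: str
    metric: str  # "mutational" | "copy_number"
    value: float
    n_items: int
    warning: Optional[str] = None


def truncal_clusters(
    ccf_by_region: Mapping[str, Mapping[str, float]],
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
) -> set[str]:
    """Clusters clonal in every primary region of the tumor.

    These carry the truncal mutations excluded from the mutational
    distance.
    """
    regions = list(ccf_by_region)
    if not regions:
        return set()
    clusters = set().union(*(set(c) for c in ccf_by_region.values()))
    return {
        c
        for c in clusters
        if all(ccf_by_region[r].get(c, 0.0) >= clonal_threshold for r in regions)
    }


def mutational_distance(
    ccf_i: Mapping[str, float],
    ccf_j: Mapping[str, float],
    truncal: Iterable[str] = (),
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
    sample_i: str = "i",
    sample_j: str = "j",
) -> PairwiseDistance:
    """Mean absolute CCF difference over non-truncal mutations present in
    either sample.  An empty item set yields value 0 with a warning."""
    truncal = set(truncal)
    items = sorted(
        m
        for m in set(ccf_i) | set(ccf_j)
        if m not in truncal
        and max(ccf_i.get(m, 0.0), ccf_j.get(m, 0.0)) >= detect_threshold
    )
    if not items:
        msg = "no non-truncal mutations present in either sample"
        warnings.warn(msg)
        return PairwiseDistance(sample_i, sample_j, "mutational", 0.0, 0, msg)
    diffs = [abs(ccf_i.get(m, 0.0) - ccf_j.get(m, 0.0)) for m in items]
    return PairwiseDistance(
        sample_i, sample_j, "mutational", float(np.mean(diffs)), len(items)
    )


def copy_number_distance(
    seg_i: SegmentProfile,
    seg_j: SegmentProfile,
    truncal_cna: Optional[pd.DataFrame] = None,
    sample_i: Optional[str] = None,
    sample_j: Optional[str] = None,
) -> PairwiseDistance:
    """Length-weighted total-copy-number difference over aberrant intervals.

    The two segmentations are intersected into minimal common intervals
    (breakpoint union); an interval enters the sum when it is aberrant
    (gain or loss relative to the sample's own rounded ploidy) in at least
    one sample and is not listed in ``truncal_cna`` (a frame with
    ``chrom``/``start``/``end`` of intervals to exclude).
    """
    sample_i = sample_i or seg_i.sample_id
    sample_j = sample_j or seg_j.sample_id
    if not set(seg_i.segments["chrom"]) & set(seg_j.segments["chrom"]):
        raise ValueError("profiles share no chromosomes")
    iv = common_intervals([seg_i, seg_j])
    cn_i = iv["cn_a_0"] + iv["cn_b_0"]
    cn_j = iv["cn_a_1"] + iv["cn_b_1"]
    ref_i = round(seg_i.ploidy)
    ref_j = round(seg_j.ploidy)
    aberrant = (cn_i != ref_i) | (cn_j != ref_j)
    if truncal_cna is not None and len(truncal_cna):
        excl = np.zeros(len(iv), dtype=bool)
        for _, t in truncal_cna.iterrows():
            excl |= (
                (iv["chrom"] == t["chrom"])
                & (iv["start"] < t["end"])
                & (iv["end"] > t["start"])
            ).to_numpy()
        aberrant &= ~excl
    sel = iv[aberrant]
    total_len = sel["length"].sum()
    if total_len == 0:
        msg = "no non-truncal aberrant intervals between samples"
        warnings.warn(msg)
        return PairwiseDistance(sample_i, sample_j, "copy_number", 0.0, 0, msg)
    diff = (cn_i[aberrant] - cn_j[aberrant]).abs()
    value = float((sel["length"] * diff).sum() / total_len)
    return PairwiseDistance(sample_i, sample_j, "copy_number", value, len(sel))


def truncal_cna_intervals(profiles: Sequence[SegmentProfile]) -> pd.DataFrame:
    """Intervals aberrant with identical total copy number in all primary
    regions: the truncal copy-number alterations excluded from the
    copy-number distance."""
    if len(profiles) < 2:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    iv = common_intervals(profiles)
    cns = [
        iv[f"cn_a_{k}"] + iv[f"cn_b_{k}"] for k in range(len(profiles))
    ]
    refs = [round(p.ploidy) for p in profiles]
    aberrant_all = np.ones(len(iv), dtype=bool)
    for cn, ref in zip(cns, refs):
        aberrant_all &= (cn != ref).to_numpy()
    identical = np.ones(len(iv), dtype=bool)
    for cn in cns[1:]:
        identical &= (cn == cns[0]).to_numpy()
    return iv.loc[aberrant_all & identical, ["chrom", "start", "end"]].reset_index(
        drop=True
    )


def region_average_distance(
    distances: Mapping[str, float] | Sequence[float],
) -> float:
    """Arithmetic mean of a focal sample's pairwise distances."""
    values = list(distances.values()) if isinstance(distances, Mapping) else list(distances)
    if not values:
        raise ValueError("empty comparison set")
    return float(np.mean(values))


def zscore_diversity_classification(
    mut_dists: Sequence[float], cn_dists: Sequence[float]
) -> list[str]:
    """Classify each PDX by which divergence dominates its bottleneck.

    Both distance vectors are z-transformed across the cohort; models in
    the upper quartile of (z_mut - z_cn) are ``higher_mutation``, lower
    quartile ``higher_copy_number``, the rest ``intermediate``.
    """
    mut = np.asarray(mut_dists, dtype=float)
    cn = np.asarray(cn_dists, dtype=float)
    if mut.shape != cn.shape or mut.ndim != 1:
        raise ValueError("need matched 1-d distance vectors")
    if len(mut) < 4:
        raise ValueError("need at least 4 matched pairs")
    if mut.std() == 0 or cn.std() == 0:
        warnings.warn("zero variance in a distance metric; all intermediate")
        return [INTERMEDIATE] * len(mut)
    z = (mut - mut.mean()) / mut.std() - (cn - cn.mean()) / cn.std()
    lo, hi = np.percentile(z, [25, 75])
    out = []
    for d in z:
        if d >= hi:
            out.append(HIGHER_MUTATION)
        elif d <= lo:
            out.append(HIGHER_COPY_NUMBER)
        else:
            out.append(INTERMEDIATE)
    return out
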