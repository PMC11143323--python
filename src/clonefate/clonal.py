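"""Clone proportions, presence/clonality calls, and tumor splitting.

The clone proportion of cluster ``v`` in a sample is its cancer cell
fraction minus the CCF of its direct descendants: the fraction of cancer
cells whose most specific cluster is ``v``.  Proportions over the clusters
present in a sample sum to 1; a leaf's proportion equals its CCF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .types import CloneTree

DEFAULT_DETECT_THRESHOLD = 0.01
DEFAULT_CLONAL_THRESHOLD = 0.9
DEFAULT_PROPORTION_TOLERANCE = 0.05
UBIQUITOUS_VAF_THRESHOLD = 0.01
MIN_UBIQUITOUS_MUTATIONS = 10  # strictly more than this => genomically related


class PigeonholeViolationError(ValueError):
    """A cluster's CCF exceeds its parent's by more than the tolerance."""


@dataclass
class CloneProportions:
    """Per-sample clone proportions; absent clusters have proportion 0."""

    sample_id: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(v for v in self.proportions.values() if v > 0)
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"proportions for sample {self.sample_id!r} sum to {total}, not 1"
            )

    def present(self) -> dict[str, float]:
        return {c: p for c, p in self.proportions.items() if p > 0}


@dataclass
class TumorPartition:
    patient_id: str
    groups: list[set[str]]

    def __post_init__(self) -> None:
        if not 1 <= len(self.groups) <= 4:
            raise ValueError(f"expected 1-4 tumor groups, got {len(self.groups)}")
        all_regions = [r for g in self.groups for r in g]
        if len(all_regions) != len(set(all_regions)):
            raise ValueError("groups are not disjoint")


def compute_clone_proportions(
    tree: CloneTree,
    ccfs: Mapping[str, float],
    sample_id: str = "",
    tol: float = DEFAULT_PROPORTION_TOLERANCE,
) -> CloneProportions:
    """Invert subtree-sum CCFs into clone proportions.

    ``proportion(v) = ccf(v) - sum(ccf(children(v)))``.  Small negative
    values (|p| <= ``tol``, CCF noise) are clipped to zero and the vector is
    renormalized to sum 1; larger violations raise
    :class:`PigeonholeViolationError` naming the cluster.
    """
    ccf = {c: float(ccfs.get(c, 0.0)) for c in tree.nodes}
    props: dict[str, float] = {}
    for node in tree.nodes:
        p = ccf[node] - sum(ccf[c] for c in tree.children(node))
        if p < -tol:
            raise PigeonholeViolationError(
                f"cluster {node!r}: descendant CCFs exceed own CCF by {-p:.4g} "
                f"(tolerance {tol})"
            )
        props[node] = max(p, 0.0)
    total = sum(props.values())
    if total > 0:
        props = {c: p / total for c, p in props.items()}
    return CloneProportions(sample_id=sample_id, proportions=props)


def call_presence(
    ccfs: Mapping[str, float], detect_threshold: float = DEFAULT_DETECT_THRESHOLD
) -> set[str]:
    """Clusters detected in the sample: CCF >= ``detect_threshold``."""
    if not 0 < detect_threshold < 1:
        raise ValueError("detect_threshold must be in (0,1)")
    return {c for c, v in ccfs.items() if v >= detect_threshold}


def call_clonality(
    ccfs: Mapping[str, float],
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
    clonal_flags: Optional[Mapping[str, bool]] = None,
) -> dict[str, str]:
    """Label each present cluster ``clonal`` or ``subclonal``.

    A cluster is clonal when its CCF reaches ``clonal_threshold`` or the
    upstream clustering flagged it clonal in the input.
    """
    if not detect_threshold < clonal_threshold < 1:
        raise ValueError("require detect_threshold < clonal_threshold < 1")
    flags = clonal_flags or {}
    out = {}
    for c in call_presence(ccfs, detect_threshold):
        clonal = ccfs[c] >= clonal_threshold or bool(flags.get(c, False))
        out[c] = "clonal" if clonal else "subclonal"
    return out


def _cluster_two_groups(
    vaf: pd.DataFrame, regions: Sequence[str], method: str, scale: bool
) -> tuple[list[str], list[str]]:
    mat = vaf[list(regions)].fillna(0.0).to_numpy(dtype=float).T
    if scale:
        sd = mat.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mat = (mat - mat.mean(axis=0)) / sd
    z = linkage(pdist(mat, metric="euclidean"), method=method)
    labels = fcluster(z, t=2, criterion="maxclust")
    g1 = [r for r, l in zip(regions, labels) if l == labels[0]]
    g2 = [r for r, l in zip(regions, labels) if l != labels[0]]
    return g1, g2


def split_independent_tumors(
    vaf: pd.DataFrame,
    patient_id: str = "",
    min_shared: int = MIN_UBIQUITOUS_MUTATIONS,
    ubiquitous_vaf: float = UBIQUITOUS_VAF_THRESHOLD,
    linkage_method: str = "complete",
    scale: bool = False,
) -> TumorPartition:
    """Decide whether a patient's regions represent one tumor or several.

    ``vaf`` is a mutation x region matrix of variant allele frequencies
    (absent calls as 0 or NaN).  Mutations with VAF > ``ubiquitous_vaf`` in
    every region are counted; strictly more than ``min_shared`` such
    ubiquitous mutations means the regions are genomically related.
    Otherwise the regions are split in two by complete-linkage hierarchical
    clustering of their VAF vectors, and each half is re-examined once,
    yielding at most four groups.
    """
    regions = list(vaf.columns)
    if len(regions) < 2:
        warnings.warn(f"patient {patient_id!r}: single region, trivial partition")
        return TumorPartition(patient_id, [set(regions)])

    def related(cols: Sequence[str]) -> bool:
        sub = vaf[list(cols)].fillna(0.0)
        n_ubiq = int((sub > ubiquitous_vaf).all(axis=1).sum())
        return n_ubiq > min_shared

    def split_once(cols: Sequence[str]) -> list[list[str]]:
        if len(cols) < 2 or related(cols):
            return [list(cols)]
        g1, g2 = _cluster_two_groups(vaf, cols, linkage_method, scale)
        return [g1, g2]

    groups: list[list[str]] = []
    for top in split_once(regions):
        if len(top) == len(regions):  # no split happened
            groups.append(top)
        else:
            groups.extend(split_once(top))
    return TumorPartition(patient_id, [set(g) for g in groups])


def proportions_to_frame(per_sample: Sequence[CloneProportions]) -> pd.DataFrame:
    rows = []
    for cp in per_sample:
        for cluster, p in sorted(cp.proportions.items()):
            rows.append(
                {"sample_id": cp.sample_id, "cluster_id": cluster, "proportion": p}
            )
    return pd.DataFrame(rows, columns=["sample_id", "cluster_id", "proportion"])
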