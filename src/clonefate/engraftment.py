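"""Engraftment clonality classification and engrafting-clone identification.

A PDX model founded by a single primary-tumor clone is a *monoclonal*
engraftment; one founded by several clones is *polyclonal*.  Operationally:
if every mutation cluster shared between the primary tumor and the PDX
sample is clonal within the PDX, the engraftment is monoclonal; if any
PDX-subclonal cluster is also present in the primary tumor, it is
polyclonal.  Clusters private to the PDX (acquired in the mouse) never
affect the call.

The engrafting clones are found by a leaf-up walk over the shared clusters
mapped onto the clone tree: the most recent (deepest) shared cluster of a
branch always engrafts; while it is subclonal in the PDX, ancestors are
considered iteratively until the first PDX-clonal cluster, which anchors
the branch and engrafts; an intermediate ancestor on the path engrafts
when its phyloCCF strictly exceeds that of its child on the path.  Where
several branches meet at a shared parent, the branch CCFs are summed
before the comparison and the walk continues from the merge point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .clonal import (
    DEFAULT_CLONAL_THRESHOLD,
    DEFAULT_DETECT_THRESHOLD,
    CloneProportions,
    call_presence,
)
from .types import CloneTree

MONOCLONAL = "monoclonal"
POLYCLONAL = "polyclonal"

SUM_CCF_TOLERANCE = 0.05
# phyloCCF differences below this are ties, not "strictly greater"
CCF_EPS = 1e-9


class UnrelatedSamplePairError(ValueError):
    """Primary tumor and PDX sample share no mutation cluster."""


@dataclass(frozen=True)
class ClusterOriginLabel:
    cluster_id: str
    label: str  # primary_specific | pdx_specific | shared


@dataclass
class EngraftmentResult:
    pdx_sample_id: str
    pattern: str
    engrafting_clusters: set[str]
    labels: list[ClusterOriginLabel]
    tumor_level_pattern: Optional[str] = None


def label_cluster_origins(
    primary_presence: set[str], pdx_presence: set[str]
) -> list[ClusterOriginLabel]:
    """Partition clusters into primary-specific / PDX-specific / shared."""
    labels = []
    for c in sorted(primary_presence | pdx_presence):
        if c in primary_presence and c in pdx_presence:
            lab = "shared"
        elif c in primary_presence:
            lab = "primary_specific"
        else:
            lab = "pdx_specific"
        labels.append(ClusterOriginLabel(c, lab))
    return labels


def _is_clonal(
    cluster: str,
    pdx_ccfs: Mapping[str, float],
    clonal_threshold: float,
    clonal_flags: Optional[Mapping[str, bool]],
) -> bool:
    if clonal_flags and clonal_flags.get(cluster):
        return True
    return pdx_ccfs.get(cluster, 0.0) >= clonal_threshold


def classify_sample_engraftment(
    tree: CloneTree,
    primary_presence: set[str],
    pdx_ccfs: Mapping[str, float],
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    clonal_flags: Optional[Mapping[str, bool]] = None,
) -> str:
    """Monoclonal iff every shared cluster is clonal in the PDX sample."""
    pdx_presence = call_presence(pdx_ccfs, detect_threshold)
    shared = (primary_presence & pdx_presence) & tree.nodes
    if not shared:
        raise UnrelatedSamplePairError(
            "no mutation cluster shared between primary tumor and PDX sample"
        )
    for c in shared:
        if not _is_clonal(c, pdx_ccfs, clonal_threshold, clonal_flags):
            return POLYCLONAL
    return MONOCLONAL


def classify_tumor_engraftment(
    patterns: Sequence[str], shared_sets: Sequence[set[str]]
) -> str:
    """Aggregate per-PDX patterns to the tumor level.

    Any polyclonal PDX makes the tumor polyclonal; all-monoclonal PDX
    samples give a monoclonal tumor only when their shared-cluster sets are
    identical (otherwise some PDX shares additional clusters with the
    primary tumor and multiple clones engrafted across models).
    """
    if len(patterns) != len(shared_sets) or not patterns:
        raise ValueError("need matched, non-empty patterns and shared sets")
    if len(patterns) == 1:
        return patterns[0]
    if any(p == POLYCLONAL for p in patterns):
        return POLYCLONAL
    first = shared_sets[0]
    if all(s == first for s in shared_sets[1:]):
        return MONOCLONAL
    return POLYCLONAL


def identify_engrafting_clones(
    tree: CloneTree,
    primary_presence: set[str],
    pdx_ccfs: Mapping[str, float],
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    clonal_flags: Optional[Mapping[str, bool]] = None,
    include_subclonal_tip: bool = True,
) -> tuple[set[str], list[ClusterOriginLabel]]:
    """Leaf-up identification of the engrafting clusters.

    The shared clusters form a forest under the clone tree's ancestry.  The
    walk proceeds bottom-up: each branch tip engrafts; a branch whose
    current cluster is PDX-clonal terminates there; otherwise it moves to
    the nearest shared ancestor, which engrafts when its phyloCCF strictly
    exceeds the summed phyloCCF of the active child branches arriving at
    it.

    ``include_subclonal_tip=False`` reports only the clonal anchors and the
    qualifying intermediate ancestors, omitting subclonal starting tips.
    """
    pdx_presence = call_presence(pdx_ccfs, detect_threshold)
    shared = (primary_presence & pdx_presence) & tree.nodes
    if not shared:
        raise UnrelatedSamplePairError(
            "no mutation cluster shared between primary tumor and PDX sample"
        )
    labels = label_cluster_origins(
        primary_presence & tree.nodes, pdx_presence & tree.nodes
    )

    def clonal(c: str) -> bool:
        return _is_clonal(c, pdx_ccfs, clonal_threshold, clonal_flags)

    def shared_children(c: str) -> list[str]:
        """Nearest shared descendants of ``c`` (children in the shared forest)."""
        out = []
        stack = list(tree.children(c))
        while stack:
            node = stack.pop()
            if node in shared:
                out.append(node)
            else:
                stack.extend(tree.children(node))
        return sorted(out)

    engrafting: set[str] = set()

    def walk(c: str) -> tuple[bool, float]:
        """Returns (terminated, branch_ccf).

        ``terminated`` means a PDX-clonal cluster was found at or below
        ``c`` on every path, so no branch continues upward; ``branch_ccf``
        is the phyloCCF the active branch carries to the next ancestor.
        """
        kids = shared_children(c)
        ccf_c = pdx_ccfs.get(c, 0.0)
        if not kids:  # branch tip: the most recent shared cluster
            if include_subclonal_tip or clonal(c):
                engrafting.add(c)
            return (True, ccf_c) if clonal(c) else (False, ccf_c)
        results = [walk(k) for k in kids]
        active = [ccf for term, ccf in results if not term]
        if not active:
            # all deeper branches found their clonal anchor; ancestors above
            # are not engrafting
            return True, ccf_c
        child_sum = sum(active)
        if child_sum > 1.0 + SUM_CCF_TOLERANCE:
            raise ValueError(
                f"summed branch phyloCCF {child_sum:.3f} exceeds 1 at "
                f"cluster {c!r}"
            )
        if clonal(c):
            engrafting.add(c)
            return True, ccf_c
        if ccf_c > child_sum + CCF_EPS:
            engrafting.add(c)
        return False, ccf_c

    roots = [c for c in shared if not any(a in shared for a in tree.ancestors(c))]
    for r in sorted(roots):
        walk(r)
    return engrafting, labels


def engrafting_clone_proportions(
    region_proportions: CloneProportions, engrafting_clusters: set[str]
) -> pd.DataFrame:
    """Tabulate detected clones of the region of origin with an engrafting
    flag; ancestral clones undetected in the region (proportion 0) are
    excluded."""
    rows = []
    for cluster, p in sorted(region_proportions.proportions.items()):
        if p <= 0:
            continue
        rows.append(
            {
                "cluster_id": cluster,
                "proportion": p,
                "engrafting": cluster in engrafting_clusters,
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "proportion", "engrafting"])
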