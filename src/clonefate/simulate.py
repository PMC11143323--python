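"""Synthetic cohort generator with ground-truth labels.

Emulates the statistical structure the analysis assumes: clone trees with
pigeonhole-consistent regional CCFs (CCF of a cluster is the sum of the
clone proportions over its subtree, so the root is 1 wherever tumor cells
are present), engraftment bottlenecks drawing one or more founding clones
weighted by their regional proportion, passage drift adding PDX-private
clusters, clone-specific copy-number events that respect LOH
irreversibility along lineages, binomial read-count variant tables with
injectable mouse-artifact false positives shared across tumors, and
per-patient multi-region engraftment outcomes by histology.

All generators are deterministic given a seed.  Defaults mirror the study
conditions: 44 patients, ~3 regions each, region-level engraftment
probabilities of 0.24 (LUAD), 0.32 (LUSC) and 0.43 (other), a polyclonal
bottleneck in about a third of models, and ~400x sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clonal import CloneProportions, compute_clone_proportions
from .types import CCFTable, CloneTree, CohortOutcomes, SegmentProfile, VariantTable

DEFAULT_GENOME: dict[str, int] = {str(i): 100_000_000 for i in range(1, 23)}
DEFAULT_GENOME["X"] = 100_000_000


@dataclass
class SimulationConfig:
    seed: int = 0
    # cohort
    n_patients: int = 44
    regions_per_patient: int = 3
    histology_weights: dict[str, float] = field(
        default_factory=lambda: {"LUAD": 20 / 44, "LUSC": 15 / 44, "other": 9 / 44}
    )
    engraftment_prob: dict[str, float] = field(
        default_factory=lambda: {"LUAD": 0.244, "LUSC": 0.321, "other": 0.432}
    )
    lymphoproliferation_prob: float = 0.11  # among attempts, conditional on failure
    # clonal structure
    clusters_per_tumor: int = 8
    ccf_concentration: float = 1.0  # symmetric Dirichlet over present clones
    clone_dropout: float = 0.3  # per-region probability a non-root clone is absent
    # bottleneck
    p_polyclonal: float = 1 / 3  # two founding clones instead of one
    weight_exponent: float = 1.0  # sampling weight = proportion ** w; w=0 lets minor clones in
    # passage drift
    pdx_clusters_per_passage: int = 1
    pdx_cluster_ccf: float = 0.2  # fraction of the host clone's proportion
    ccf_jitter_sd: float = 0.0
    # copy-number events
    segments_per_chrom: int = 4
    n_cn_events: int = 20
    p_wgd: float = 0.3
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    # variant tables
    depth: int = 400
    variants_per_patient: int = 30
    artifact_rate: float = 0.0  # per-site probability of a shared PDX-only artifact
    n_artifact_sites: int = 5

    def __post_init__(self) -> None:
        for name in (
            "clone_dropout", "p_polyclonal", "lymphoproliferation_prob",
            "pdx_cluster_ccf", "p_wgd", "artifact_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for h, p in self.engraftment_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"engraftment_prob[{h!r}] out of [0,1]")


# -- clone trees and CCFs ----------------------------------------------------

def simulate_clone_tree(
    n_clusters: int, rng: np.random.Generator, tumor_id: str = "T1"
) -> CloneTree:
    """Random recursive attachment: cluster k+1 attaches to a uniformly
    chosen earlier cluster."""
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    names = [f"C{i + 1}" for i in range(n_clusters)]
    if n_clusters == 1:
        tree = CloneTree.__new__(CloneTree)
        object.__setattr__(tree, "tumor_id", tumor_id)
        object.__setattr__(tree, "parent_of", {})
        object.__setattr__(tree, "root", names[0])
        return tree
    parent_of = {}
    for k in range(1, n_clusters):
        parent_of[names[k]] = names[int(rng.integers(0, k))]
    return CloneTree(tumor_id=tumor_id, parent_of=parent_of)


def _ccfs_from_proportions(
    tree: CloneTree, proportions: Mapping[str, float]
) -> dict[str, float]:
    # clip the float error of the simplex sum at the root
    return {
        v: min(1.0, float(sum(proportions.get(u, 0.0) for u in tree.subtree(v))))
        for v in tree.nodes
    }


def simulate_regional_ccfs(
    tree: CloneTree,
    n_regions: int,
    rng: np.random.Generator,
    concentration: float = 1.0,
    clone_dropout: float = 0.3,
) -> tuple[CCFTable, dict[str, CloneProportions]]:
    """Draw per-region clone proportions from a symmetric Dirichlet over a
    random subset of clones and emit the implied subtree-sum CCFs.

    By construction parent CCF >= child CCF and the root CCF is 1 in every
    region; :func:`clonefate.clonal.compute_clone_proportions` inverts the
    output exactly.
    """
    nodes = sorted(tree.nodes)
    rows = []
    truth: dict[str, CloneProportions] = {}
    for r in range(n_regions):
        sample_id = f"{tree.tumor_id}_R{r + 1}"
        keep = [n for n in nodes if rng.random() >= clone_dropout]
        if not keep:
            keep = [nodes[int(rng.integers(0, len(nodes)))]]
        alpha = np.full(len(keep), concentration)
        props = dict(zip(keep, rng.dirichlet(alpha)))
        ccfs = _ccfs_from_proportions(tree, props)
        truth[sample_id] = CloneProportions(
            sample_id=sample_id,
            proportions={n: float(props.get(n, 0.0)) for n in nodes},
        )
        for n in nodes:
            if ccfs[n] > 0:
                rows.append(
                    {
                        "tumor_id": tree.tumor_id,
                        "cluster_id": n,
                        "sample_id": sample_id,
                        "ccf": ccfs[n],
                        "clonal_flag": pd.NA,
                    }
                )
    return CCFTable(pd.DataFrame(rows)), truth


# -- PDX bottleneck ----------------------------------------------------------

@dataclass
class PdxSimulation:
    tree: CloneTree  # extended with PDX-private clusters
    region_sample_id: str
    p0_sample_id: str
    p3_sample_id: str
    p0_ccfs: dict[str, float]
    p3_ccfs: dict[str, float]
    p0_proportions: dict[str, float]
    drawn_clones: set[str]
    true_pattern: str
    expected_engrafting: set[str]
    pdx_private_clusters: set[str]


_CCF_EPS = 1e-9


def _expected_engrafting_set(
    tree: CloneTree,
    drawn: set[str],
    ccfs: Mapping[str, float],
    clonal_threshold: float,
) -> set[str]:
    """Ground-truth engrafting labels implied by the construction.

    Under a noise-free bottleneck the clusters shared between region and
    PDX are exactly the founding clones and their ancestors, and a
    non-founding ancestor's CCF equals the summed CCF of the founders
    below it.  The expected label set therefore follows directly from the
    exact construction values: founder tips engraft; a lineage terminates
    at the first cluster whose CCF reaches the clonal threshold (a founder
    hidden above an effectively-clonal descendant is invisible to the
    leaf-up definition); an ancestor engrafts when its CCF exceeds the
    summed CCF of the active lineages below it, which under the
    construction happens exactly at founders carrying their own cell mass.
    """
    shared = set(drawn)
    for c in drawn:
        shared |= set(tree.ancestors(c))
    expected: set[str] = set()

    def nearest_shared_children(c: str) -> list[str]:
        out = []
        stack = list(tree.children(c))
        while stack:
            node = stack.pop()
            if node in shared:
                out.append(node)
            else:
                stack.extend(tree.children(node))
        return out

    def walk(c: str) -> tuple[bool, float]:
        ccf_c = ccfs.get(c, 0.0)
        kids = nearest_shared_children(c)
        if not kids:
            expected.add(c)
            return ccf_c >= clonal_threshold, ccf_c
        active = [v for term, v in (walk(k) for k in kids) if not term]
        if not active:
            return True, ccf_c
        if ccf_c >= clonal_threshold:
            expected.add(c)
            return True, ccf_c
        if ccf_c > sum(active) + _CCF_EPS:
            expected.add(c)
        return False, ccf_c

    roots = [c for c in shared if not any(a in shared for a in tree.ancestors(c))]
    for r in sorted(roots):
        walk(r)
    return expected


def _extend_tree(tree: CloneTree, parent_of_new: Mapping[str, str]) -> CloneTree:
    merged = dict(tree.parent_of)
    merged.update(parent_of_new)
    return CloneTree(tumor_id=tree.tumor_id, parent_of=merged)


def simulate_pdx(
    tree: CloneTree,
    region_proportions: CloneProportions,
    rng: np.random.Generator,
    config: Optional[SimulationConfig] = None,
    clonal_threshold: float = 0.9,
) -> PdxSimulation:
    """Simulate an engraftment bottleneck from one primary region.

    One founding clone is drawn (two with probability ``p_polyclonal``)
    with probability proportional to its regional proportion raised to
    ``weight_exponent`` (an exponent of zero lets minor clones found the
    model).  P0 proportions are the renormalized founder proportions; CCFs
    are subtree sums, so every common ancestor of the founders is clonal.
    Passage drift appends PDX-private clusters nested under a founder and
    optionally jitters CCFs; ground-truth labels are exact only without
    jitter.
    """
    cfg = config or SimulationConfig()
    present = {c: p for c, p in region_proportions.proportions.items() if p > 0}
    if not present:
        raise ValueError("region contains no clones")
    clones = sorted(present)
    k = 2 if (len(clones) > 1 and rng.random() < cfg.p_polyclonal) else 1
    weights = np.array([present[c] ** cfg.weight_exponent for c in clones])
    weights = weights / weights.sum()
    drawn = set(
        rng.choice(clones, size=k, replace=False, p=weights).tolist()
    )
    total = sum(present[c] for c in drawn)
    p0_props = {c: present[c] / total for c in drawn}
    p0_ccfs = _ccfs_from_proportions(tree, p0_props)
    # the pattern the bottleneck implies under the clonal threshold: a
    # second founder contributing less than 1 - threshold of the graft is
    # indistinguishable from monoclonal engraftment by construction
    shared = set(drawn)
    for c in drawn:
        shared |= set(tree.ancestors(c))
    true_pattern = (
        "polyclonal"
        if any(p0_ccfs.get(c, 0.0) < clonal_threshold for c in shared)
        else "monoclonal"
    )
    expected = _expected_engrafting_set(tree, drawn, p0_ccfs, clonal_threshold)

    region_id = region_proportions.sample_id
    p0_id = f"{region_id}_PDX_P0"
    p3_id = f"{region_id}_PDX_P3"

    # passage drift: new PDX-private clusters carved out of a founder clone
    extended = tree
    private: set[str] = set()
    props_now = dict(p0_props)
    ccfs_by_passage: dict[str, dict[str, float]] = {}
    host_pool = sorted(drawn)
    counter = 0
    for passage, sid in ((0, p0_id), (3, p3_id)):
        for _ in range(cfg.pdx_clusters_per_passage):
            host = host_pool[int(rng.integers(0, len(host_pool)))]
            counter += 1
            new = f"{tree.tumor_id}_PDXC{counter}"
            extended = _extend_tree(extended, {new: host})
            carved = props_now[host] * cfg.pdx_cluster_ccf
            props_now[host] -= carved
            props_now[new] = carved
            private.add(new)
            host_pool.append(new)
        ccfs = _ccfs_from_proportions(extended, props_now)
        if cfg.ccf_jitter_sd > 0:
            for c in list(ccfs):
                if c == extended.root or ccfs[c] == 0:
                    continue
                ccfs[c] = float(
                    np.clip(ccfs[c] + rng.normal(0, cfg.ccf_jitter_sd), 0, 1)
                )
        ccfs_by_passage[sid] = {c: v for c, v in ccfs.items() if v > 0}

    return PdxSimulation(
        tree=extended,
        region_sample_id=region_id,
        p0_sample_id=p0_id,
        p3_sample_id=p3_id,
        p0_ccfs=ccfs_by_passage[p0_id],
        p3_ccfs=ccfs_by_passage[p3_id],
        p0_proportions={c: v for c, v in p0_props.items()},
        drawn_clones=drawn,
        true_pattern=true_pattern,
        expected_engrafting=expected,
        pdx_private_clusters=private,
    )


# -- copy-number profiles ----------------------------------------------------

@dataclass
class SegmentSimulation:
    profiles: dict[str, SegmentProfile]
    events: pd.DataFrame  # clone-level ground truth
    wgd_clones: set[str]
    clone_states: dict[str, pd.DataFrame]


def _segment_grid(genome: Mapping[str, int], per_chrom: int) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.items():
        bounds = np.linspace(0, length, per_chrom + 1, dtype=int)
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append({"chrom": chrom, "start": int(s), "end": int(e)})
    df = pd.DataFrame(rows)
    df["n_het_snps"] = (df["end"] - df["start"]) // 1_000_000
    return df


def simulate_segments(
    tree: CloneTree,
    proportions_by_sample: Mapping[str, CloneProportions],
    rng: np.random.Generator,
    config: Optional[SimulationConfig] = None,
    mirrored_event: bool = False,
) -> SegmentSimulation:
    """Assign clone-level copy-number events and mix them into per-sample
    integer profiles.

    Events (single-allele gains and losses, including losses to zero, i.e.
    LOH) attach to random clones and are inherited by the whole subtree;
    an allele already lost in an ancestor can never be regained
    (irreversibility), and gains never target a zero-copy allele.  A WGD
    clone doubles both alleles of every segment.  ``mirrored_event``
    plants an opposite-allele loss of one segment in two sibling clones to
    create mirrored subclonal allelic imbalance between samples they
    dominate.  Sample-level allele copy numbers are the rounded
    proportion-weighted means of the clone states.
    """
    cfg = config or SimulationConfig()
    grid = _segment_grid(cfg.genome, cfg.segments_per_chrom)
    n_seg = len(grid)
    clones = sorted(tree.nodes)
    order = list(tree.preorder())

    # per-clone private events; inherited states resolved along root->leaf
    events: list[dict] = []
    wgd_clones: set[str] = set()
    if rng.random() < cfg.p_wgd:
        wgd_clones.add(tree.root)  # doubling on the trunk, inherited by all
    for _ in range(cfg.n_cn_events):
        clone = clones[int(rng.integers(0, len(clones)))]
        seg = int(rng.integers(0, n_seg))
        etype = "gain" if rng.random() < 0.5 else "loss"
        allele = "A" if rng.random() < 0.5 else "B"
        events.append({"clone": clone, "segment": seg, "type": etype, "allele": allele})
    if mirrored_event:
        sibling_pairs = [
            (a, b)
            for p in clones
            for a in tree.children(p)
            for b in tree.children(p)
            if a < b
        ]
        if sibling_pairs:
            a, b = sibling_pairs[int(rng.integers(0, len(sibling_pairs)))]
            seg = int(rng.integers(0, n_seg))
            events.append({"clone": a, "segment": seg, "type": "loss", "allele": "A"})
            events.append({"clone": b, "segment": seg, "type": "loss", "allele": "B"})

    by_clone: dict[str, list[dict]] = {c: [] for c in clones}
    for e in events:
        by_clone[e["clone"]].append(e)

    states: dict[str, np.ndarray] = {}
    applied_events: list[dict] = []
    for clone in order:
        parent = tree.parent(clone)
        base = states[parent].copy() if parent else np.ones((n_seg, 2), dtype=int)
        if clone in wgd_clones:
            base *= 2
        for e in by_clone[clone]:
            ai = 0 if e["allele"] == "A" else 1
            s = e["segment"]
            if e["type"] == "loss":
                if base[s, ai] == 0:
                    continue  # allele already fully lost on this lineage
                base[s, ai] -= 1
            else:
                if base[s, ai] == 0:
                    continue  # cannot regain a lost allele
                base[s, ai] += 1
            applied_events.append({**e, "chrom": grid.loc[s, "chrom"],
                                   "start": grid.loc[s, "start"],
                                   "end": grid.loc[s, "end"]})
        states[clone] = base

    clone_states = {
        c: grid.assign(cn_a=states[c][:, 0], cn_b=states[c][:, 1]) for c in clones
    }

    profiles: dict[str, SegmentProfile] = {}
    for sample_id, cp in proportions_by_sample.items():
        props = {c: p for c, p in cp.proportions.items() if p > 0 and c in states}
        total = sum(props.values())
        mix = np.zeros((n_seg, 2))
        for c, p in props.items():
            mix += (p / total) * states[c]
        cn = np.rint(mix).astype(int)
        seg_df = grid.assign(cn_a=cn[:, 0], cn_b=cn[:, 1])
        lengths = (seg_df["end"] - seg_df["start"]).to_numpy()
        ploidy = float(
            ((seg_df["cn_a"] + seg_df["cn_b"]) * lengths).sum() / lengths.sum()
        )
        profiles[sample_id] = SegmentProfile(
            sample_id=sample_id, segments=seg_df, ploidy=ploidy, genome=cfg.genome
        )
    return SegmentSimulation(
        profiles=profiles,
        events=pd.DataFrame(applied_events),
        wgd_clones=wgd_clones,
        clone_states=clone_states,
    )


# -- variant tables and outcomes ---------------------------------------------

BASES = np.array(list("ACGT"))


def simulate_variant_calls(
    rng: np.random.Generator,
    config: Optional[SimulationConfig] = None,
    n_patients: int = 4,
    primaries_per_patient: int = 2,
    pdx_per_patient: int = 1,
) -> tuple[VariantTable, pd.DataFrame]:
    """Binomial read-count variant tables with injectable artifacts.

    Genuine somatic variants are patient-private and appear in primary and
    PDX samples alike; artifact sites (rate ``artifact_rate``) are shared
    across patients but appear only in PDX samples, mimicking residual
    mouse reads.  Returns the table and a frame of injected artifact sites.
    """
    cfg = config or SimulationConfig()
    rows = []
    artifact_truth = []
    artifact_sites = []
    if cfg.artifact_rate > 0:
        for a in range(cfg.n_artifact_sites):
            pos = int(rng.integers(1_000_000, 50_000_000))
            ref, alt = rng.choice(BASES, size=2, replace=False)
            artifact_sites.append(
                {"chrom": str(int(rng.integers(1, 23))), "pos": pos,
                 "ref": str(ref), "alt": str(alt)}
            )
    for pi in range(n_patients):
        patient = f"P{pi + 1}"
        samples = [
            (f"{patient}_R{r + 1}", "primary_region")
            for r in range(primaries_per_patient)
        ] + [(f"{patient}_PDX{x + 1}", "pdx") for x in range(pdx_per_patient)]
        for vi in range(cfg.variants_per_patient):
            chrom = str(int(rng.integers(1, 23)))
            pos = int(rng.integers(1_000_000, 100_000_000))
            ref, alt = rng.choice(BASES, size=2, replace=False)
            true_vaf = float(rng.uniform(0.05, 0.5))
            for sample_id, _kind in samples:
                depth = int(rng.poisson(cfg.depth))
                alt_reads = int(rng.binomial(depth, true_vaf))
                if alt_reads == 0:
                    continue
                rows.append(
                    {
                        "patient_id": patient,
                        "sample_id": sample_id,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": str(ref),
                        "alt": str(alt),
                        "variant_class": "SNV",
                        "vaf": alt_reads / depth,
                        "depth": depth,
                        "alt_reads": alt_reads,
                        "germline_alt_reads": 0,
                        "germline_vaf": 0.0,
                        "called_varscan": True,
                        "called_mutect": True,
                        "somatic_p": 1e-4,
                        "is_driver": False,
                    }
                )
        for site in artifact_sites:
            if rng.random() >= cfg.artifact_rate:
                continue
            for sample_id, kind in samples:
                if kind != "pdx":
                    continue
                depth = int(rng.poisson(cfg.depth))
                alt_reads = max(int(rng.binomial(depth, 0.08)), 1)
                rows.append(
                    {
                        "patient_id": patient,
                        "sample_id": sample_id,
                        "chrom": site["chrom"],
                        "pos": site["pos"],
                        "ref": site["ref"],
                        "alt": site["alt"],
                        "variant_class": "SNV",
                        "vaf": alt_reads / depth,
                        "depth": depth,
                        "alt_reads": alt_reads,
                        "germline_alt_reads": 0,
                        "germline_vaf": 0.0,
                        "called_varscan": True,
                        "called_mutect": True,
                        "somatic_p": 1e-4,
                        "is_driver": False,
                    }
                )
                artifact_truth.append({**site, "patient_id": patient,
                                       "sample_id": sample_id})
    table = VariantTable(pd.DataFrame(rows))
    return table, pd.DataFrame(
        artifact_truth, columns=["chrom", "pos", "ref", "alt", "patient_id", "sample_id"]
    )


def simulate_cohort_outcomes(
    rng: np.random.Generator, config: Optional[SimulationConfig] = None
) -> CohortOutcomes:
    """Per-region Bernoulli engraftment outcomes with per-histology rates;
    a fraction of failed attempts become lymphoproliferative outgrowths."""
    cfg = config or SimulationConfig()
    hists = list(cfg.histology_weights)
    weights = np.array([cfg.histology_weights[h] for h in hists])
    weights = weights / weights.sum()
    rows = []
    for pi in range(cfg.n_patients):
        patient = f"P{pi + 1}"
        hist = str(rng.choice(hists, p=weights))
        for r in range(cfg.regions_per_patient):
            engrafted = bool(rng.random() < cfg.engraftment_prob.get(hist, 0.3))
            lympho = (not engrafted) and bool(
                rng.random() < cfg.lymphoproliferation_prob
            )
            rows.append(
                {
                    "patient_id": patient,
                    "region_label": f"R{r + 1}",
                    "histology": hist,
                    "engrafted": engrafted,
                    "is_lymphoproliferation": lympho,
                }
            )
    return CohortOutcomes(pd.DataFrame(rows))
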