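"""Cohort-level procedures: downsampling, accounting, bin recurrence tests.

The downsampling experiment asks what the patient-level engraftment yield
would have been under single-region sampling: each iteration draws one
region uniformly per patient and counts patients whose drawn region
engrafted (lymphoproliferative outgrowths count as failures).

The recurrence scan tiles the genome into fixed-size bins (default 5 Mb),
marks a sample gained/lost in a bin when any overlapping segment is, and
tests event-by-group 2x2 tables with a two-sided exact conditional
(Fisher) test, Benjamini-Hochberg corrected across tested bins.  Bins
whose total event count falls outside [min_count, max_count] are reported
untested with a reason; the bounds come from the study design (power
considerations) and are plain configuration here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .cn_metrics import GAIN, LOSS, classify_segments
from .types import CohortOutcomes, SegmentProfile

DEFAULT_N_ITER = 5000
DEFAULT_BIN_SIZE = 5_000_000
DEFAULT_MIN_COUNT = 5


@dataclass
class DownsampleResult:
    counts: np.ndarray  # per-iteration success counts
    median: float
    by_histology: Optional[dict[str, float]] = None  # histology -> median

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))


def downsample_engraftment(
    outcomes: CohortOutcomes,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    by_histology: bool = False,
) -> DownsampleResult:
    """Monte-Carlo single-region downsampling of engraftment attempts.

    Deterministic given ``seed``.  The expected per-iteration count is
    ``sum_i s_i / r_i`` over patients with ``s_i`` engrafted of ``r_i``
    attempted regions.
    """
    df = outcomes.df
    rng = np.random.default_rng(seed)
    patients = df["patient_id"].unique()
    # per patient: array of region outcomes (lymphoproliferations are
    # already engrafted=False by the type invariant)
    per_patient = [
        df.loc[df["patient_id"] == p, "engrafted"].to_numpy() for p in patients
    ]
    histology = [
        df.loc[df["patient_id"] == p, "histology"].iloc[0] for p in patients
    ]
    draws = np.empty((n_iter, len(patients)), dtype=bool)
    for j, outcomes_j in enumerate(per_patient):
        idx = rng.integers(0, len(outcomes_j), size=n_iter)
        draws[:, j] = outcomes_j[idx]
    counts = draws.sum(axis=1)
    result = DownsampleResult(counts=counts, median=float(np.median(counts)))
    if by_histology:
        medians = {}
        for h in sorted(set(histology)):
            cols = [j for j, hj in enumerate(histology) if hj == h]
            medians[h] = float(np.median(draws[:, cols].sum(axis=1)))
        result.by_histology = medians
    return result


def downsample_expectation(outcomes: CohortOutcomes) -> float:
    """Analytic expectation of the downsampled success count."""
    df = outcomes.df
    g = df.groupby("patient_id")["engrafted"]
    return float((g.sum() / g.count()).sum())


def cohort_accounting(outcomes: CohortOutcomes) -> dict[str, float | int]:
    """Headline cohort numbers and engraftment rates.

    Xenografts include lymphoproliferative outgrowths; the NSCLC PDX count
    excludes them.  Rates are percentages rounded to one decimal.
    """
    df = outcomes.df
    if df.empty:
        raise ValueError("no engraftment attempts in outcome table")
    n_patients = df["patient_id"].nunique()
    n_regions = len(df)
    n_lympho = int(df["is_lymphoproliferation"].sum())
    n_pdx = int(df["engrafted"].sum())
    n_xenografts = n_pdx + n_lympho
    patient_success = df.groupby("patient_id")["engrafted"].any()
    n_patients_engrafted = int(patient_success.sum())
    out: dict[str, float | int] = {
        "patients_attempted": n_patients,
        "regions_attempted": n_regions,
        "xenografts": n_xenografts,
        "lymphoproliferations_excluded": n_lympho,
        "nsclc_pdx_models": n_pdx,
        "patients_with_pdx": n_patients_engrafted,
        "patient_level_rate": round(100.0 * n_patients_engrafted / n_patients, 1),
        "region_level_rate": round(100.0 * n_pdx / n_regions, 1),
    }
    for h, sub in df.groupby("histology"):
        psub = sub.groupby("patient_id")["engrafted"].any()
        out[f"patient_level_rate_{h}"] = round(100.0 * psub.sum() / len(psub), 1)
        out[f"region_level_rate_{h}"] = round(
            100.0 * sub["engrafted"].sum() / len(sub), 1
        )
    return out


def cohort_from_marginals(
    marginals: Mapping[str, Mapping[str, int]], n_lymphoproliferations: int = 0
) -> CohortOutcomes:
    """Deterministically reconstruct an outcome table from per-histology
    marginal counts.

    ``marginals[histology]`` supplies ``patients``, ``regions``,
    ``region_successes`` and ``patient_successes``.  Regions are spread as
    evenly as possible over patients; successes are packed into exactly
    ``patient_successes`` patients (those with the most regions), spread as
    evenly as possible among them — the least-committal layout consistent
    with the marginals.
    Lymphoproliferations are assigned to failed regions round-robin.
    Useful for reproducing published cohort-level rates from printed
    attempt/success numbers.
    """
    rows = []
    for hist, m in marginals.items():
        n_pat, n_reg = m["patients"], m["regions"]
        n_reg_s, n_pat_s = m["region_successes"], m["patient_successes"]
        base, extra = divmod(n_reg, n_pat)
        regions_per_patient = [base + 1] * extra + [base] * (n_pat - extra)
        if n_reg_s < n_pat_s or sum(regions_per_patient[:n_pat_s]) < n_reg_s:
            raise ValueError(f"infeasible marginals for histology {hist!r}")
        # one success to each engrafting patient, remainder round-robin
        successes = [1 if i < n_pat_s else 0 for i in range(n_pat)]
        left = n_reg_s - n_pat_s
        while left > 0:
            progress = False
            for i in range(n_pat_s):
                if left == 0:
                    break
                if successes[i] < regions_per_patient[i]:
                    successes[i] += 1
                    left -= 1
                    progress = True
            if not progress:
                raise ValueError(f"infeasible marginals for histology {hist!r}")
        for i, (r, s) in enumerate(zip(regions_per_patient, successes)):
            patient = f"{hist}_{i + 1:02d}"
            for j in range(r):
                rows.append(
                    {
                        "patient_id": patient,
                        "region_label": f"R{j + 1}",
                        "histology": hist,
                        "engrafted": j < s,
                        "is_lymphoproliferation": False,
                    }
                )
    df = pd.DataFrame(rows)
    failed = df.index[~df["engrafted"]]
    if n_lymphoproliferations > len(failed):
        raise ValueError("more lymphoproliferations than failed regions")
    step = max(len(failed) // max(n_lymphoproliferations, 1), 1)
    chosen = failed[::step][:n_lymphoproliferations]
    df.loc[chosen, "is_lymphoproliferation"] = True
    return CohortOutcomes(df)


def _bin_events(
    profile: SegmentProfile, direction: str, bin_size: int
) -> set[tuple[str, int]]:
    """Bins (chrom, index) in which the sample has an event of ``direction``.
    A bin is affected when any overlapping segment is."""
    calls = classify_segments(profile)
    hits = calls[calls["state"] == direction]
    out: set[tuple[str, int]] = set()
    for _, r in hits.iterrows():
        first = int(r["start"]) // bin_size
        last = (int(r["end"]) - 1) // bin_size
        for b in range(first, last + 1):
            out.add((r["chrom"], b))
    return out


def bin_recurrence_test(
    profiles: Mapping[str, SegmentProfile],
    groups: Mapping[str, str],
    direction: str,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_count: int = DEFAULT_MIN_COUNT,
    max_count: Optional[int] = None,
) -> pd.DataFrame:
    """Per-bin exact test of event frequency between two sample groups.

    ``groups`` maps sample id to one of exactly two group labels (e.g.
    engrafted / not).  Returns one row per genomic bin with event counts,
    odds ratio, two-sided exact p, BH-adjusted q, and a ``tested`` flag
    with a reason for untested bins.
    """
    if direction not in (GAIN, LOSS):
        raise ValueError(f"direction must be '{GAIN}' or '{LOSS}'")
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    g1, g2 = labels
    members = {g1: [], g2: []}
    for s, g in groups.items():
        members[g].append(s)
    if not members[g1] or not members[g2]:
        raise ValueError("a group has no samples")

    genome = profiles[next(iter(profiles))].genome
    bins = [
        (chrom, b)
        for chrom, length in genome.items()
        for b in range((length + bin_size - 1) // bin_size)
    ]
    events = {s: _bin_events(profiles[s], direction, bin_size) for s in groups}

    rows = []
    for chrom, b in bins:
        n1 = sum((chrom, b) in events[s] for s in members[g1])
        n2 = sum((chrom, b) in events[s] for s in members[g2])
        total = n1 + n2
        rows.append(
            {
                "chrom": chrom,
                "start": b * bin_size,
                "end": min((b + 1) * bin_size, genome[chrom]),
                f"n_{direction}_{g1}": n1,
                f"n_{direction}_{g2}": n2,
                "n_total": total,
            }
        )
    table = pd.DataFrame(rows)
    reasons = np.where(
        table["n_total"] < min_count,
        "below minimum event count",
        np.where(
            (max_count is not None) & (table["n_total"] > (max_count or np.inf)),
            "above maximum event count",
            "",
        ),
    )
    table["tested"] = reasons == ""
    table["reason"] = reasons
    ors, ps = [], []
    for _, r in table.iterrows():
        if not r["tested"]:
            ors.append(np.nan)
            ps.append(np.nan)
            continue
        a = r[f"n_{direction}_{g1}"]
        c = r[f"n_{direction}_{g2}"]
        m = [[a, len(members[g1]) - a], [c, len(members[g2]) - c]]
        odds, p = fisher_exact(m, alternative="two-sided")
        ors.append(odds)
        ps.append(p)
    table["odds_ratio"] = ors
    table["p"] = ps
    table["q"] = np.nan
    tested = table["tested"].to_numpy()
    if tested.any():
        _, q, _, _ = multipletests(table.loc[tested, "p"], method="fdr_bh")
        table.loc[tested, "q"] = q
    return table
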