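"""Breakpoint-union intersection of segment profiles.

Pairwise copy-number comparisons are defined on the minimal common
intervals of two (or more) segmentations: within each chromosome the union
of all breakpoints is taken and every resulting atomic interval that is
covered by *all* profiles is annotated with each profile's segment values.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import SegmentProfile


def common_intervals(
    profiles: Sequence[SegmentProfile], columns: Sequence[str] = ("cn_a", "cn_b")
) -> pd.DataFrame:
    """Intersect profiles into minimal common intervals.

    Returns a frame with ``chrom``, ``start``, ``end``, ``length`` and, for
    each profile index ``k`` and requested column ``c``, a column ``{c}_{k}``.
    Intervals not covered by every profile are dropped.
    """
    chroms = set(profiles[0].segments["chrom"].unique())
    for p in profiles[1:]:
        chroms &= set(p.segments["chrom"].unique())
    rows = []
    for chrom in sorted(chroms):
        subs = [
            p.segments[p.segments["chrom"] == chrom].sort_values("start")
            for p in profiles
        ]
        cuts = np.unique(
            np.concatenate([s[["start", "end"]].to_numpy().ravel() for s in subs])
        )
        starts, ends = cuts[:-1], cuts[1:]
        mids = (starts + ends) // 2
        # locate the covering segment of each profile at each atomic interval
        cover = np.ones(len(mids), dtype=bool)
        values = []
        for s in subs:
            seg_starts = s["start"].to_numpy()
            seg_ends = s["end"].to_numpy()
            idx = np.searchsorted(seg_starts, mids, side="right") - 1
            ok = (idx >= 0) & (mids < seg_ends[np.clip(idx, 0, None)])
            cover &= ok
            values.append((s, idx))
        for i in np.flatnonzero(cover):
            row = {
                "chrom": chrom,
                "start": int(starts[i]),
                "end": int(ends[i]),
                "length": int(ends[i] - starts[i]),
            }
            for k, (s, idx) in enumerate(values):
                seg = s.iloc[idx[i]]
                for c in columns:
                    row[f"{c}_{k}"] = seg[c]
            rows.append(row)
    cols = ["chrom", "start", "end", "length"] + [
        f"{c}_{k}" for k in range(len(profiles)) for c in columns
    ]
    return pd.DataFrame(rows, columns=cols)
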