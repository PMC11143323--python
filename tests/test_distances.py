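"""Mutational and copy-number distances against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonefate.distances import (
    copy_number_distance,
    mutational_distance,
    region_average_distance,
    truncal_clusters,
    zscore_diversity_classification,
)
from conftest import MB, make_profile


def brute_force_mutational(ccf_i, ccf_j, truncal, detect=0.01):
    """Independent loop implementation of the mean absolute CCF difference."""
    total, m = 0.0, 0
    for mut in set(ccf_i) | set(ccf_j):
        if mut in truncal:
            continue
        a, b = ccf_i.get(mut, 0.0), ccf_j.get(mut, 0.0)
        if max(a, b) < detect:
            continue
        total += abs(a - b)
        m += 1
    return (total / m if m else 0.0), m


def brute_force_cn(prof_i, prof_j):
    """Independent per-base-pair loop over a coarse grid (100 kb steps)."""
    num = den = 0.0
    step = MB // 10
    ref_i, ref_j = round(prof_i.ploidy), round(prof_j.ploidy)
    for chrom in set(prof_i.segments["chrom"]) & set(prof_j.segments["chrom"]):
        si = prof_i.segments[prof_i.segments["chrom"] == chrom]
        sj = prof_j.segments[prof_j.segments["chrom"] == chrom]

        def cn_at(sub, pos):
            hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
            if hit.empty:
                return None
            return float(hit.iloc[0]["cn_a"] + hit.iloc[0]["cn_b"])

        end = max(si["end"].max(), sj["end"].max())
        for pos in range(0, int(end), step):
            a, b = cn_at(si, pos), cn_at(sj, pos)
            if a is None or b is None:
                continue
            if a != ref_i or b != ref_j:
                num += step * abs(a - b)
                den += step
    return num / den if den else 0.0


class TestMutationalDistance:
    def test_identical_profiles_zero(self):
        ccf = {"m1": 0.8, "m2": 0.3}
        assert mutational_distance(ccf, ccf).value == 0.0

    def test_worked_example(self):
        i = {"m1": 1.0, "m2": 0.5, "m3": 0.0, "m4": 0.2}
        j = {"m1": 1.0, "m2": 0.0, "m3": 0.4, "m4": 0.2}
        d = mutational_distance(i, j)
        assert d.value == pytest.approx(0.225)
        assert d.n_items == 4

    def test_maximum_attained_on_disjoint_private(self):
        d = mutational_distance({"m1": 1.0, "m2": 1.0}, {})
        assert d.value == pytest.approx(1.0)

    def test_truncal_excluded(self):
        d = mutational_distance(
            {"t": 1.0, "m": 0.5}, {"t": 1.0, "m": 0.1}, truncal={"t"}
        )
        assert d.n_items == 1
        assert d.value == pytest.approx(0.4)

    def test_empty_item_set_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            d = mutational_distance({"t": 1.0}, {"t": 1.0}, truncal={"t"})
        assert d.value == 0.0 and d.n_items == 0

    def test_truncal_cluster_definition(self):
        ccf_by_region = {
            "R1": {"A": 1.0, "B": 0.95, "C": 0.4},
            "R2": {"A": 1.0, "B": 0.92, "C": 0.9},
        }
        assert truncal_clusters(ccf_by_region) == {"A", "B"}


class TestCopyNumberDistance:
    def test_identical_profiles_zero(self):
        p = make_profile("i", [("1", 0, 50, 2, 1, 5)], {"1": 50})
        q = make_profile("j", [("1", 0, 50, 2, 1, 5)], {"1": 50})
        assert copy_number_distance(p, q).value == 0.0

    def test_worked_example_mixed_aberrant(self):
        g = {"1": 50}
        p = make_profile("i", [("1", 0, 10, 2, 1, 5), ("1", 10, 50, 1, 0, 5)], g)
        q = make_profile("j", [("1", 0, 10, 1, 1, 5), ("1", 10, 50, 1, 0, 5)], g)
        d = copy_number_distance(p, q)
        assert d.value == pytest.approx(0.2)

    def test_breakpoint_union_handling(self):
        g = {"1": 20}
        p = make_profile("i", [("1", 0, 20, 2, 1, 5)], g)
        q = make_profile("j", [("1", 0, 10, 2, 1, 5), ("1", 10, 20, 1, 1, 5)], g)
        assert copy_number_distance(p, q).value == pytest.approx(0.5)

    def test_disjoint_chromosomes_error(self):
        p = make_profile("i", [("1", 0, 10, 2, 1, 5)], {"1": 10, "2": 10})
        q = make_profile("j", [("2", 0, 10, 2, 1, 5)], {"1": 10, "2": 10})
        with pytest.raises(ValueError, match="chromosomes"):
            copy_number_distance(p, q)

    def test_symmetry_and_oracle_on_random_pairs(self, rng):
        for _ in range(30):
            genome = {"1": 100, "2": 60}
            profs = []
            for name in ("i", "j"):
                rows = []
                for chrom, L in genome.items():
                    cuts = sorted(
                        set([0, L] + list(rng.integers(1, L, size=3)))
                    )
                    for s, e in zip(cuts[:-1], cuts[1:]):
                        rows.append(
                            (chrom, s, e, int(rng.integers(0, 4)), int(rng.integers(0, 3)), 5)
                        )
                profs.append(make_profile(name, rows, genome))
            d_ij = copy_number_distance(profs[0], profs[1]).value
            d_ji = copy_number_distance(profs[1], profs[0]).value
            assert d_ij == d_ji
            assert d_ij == pytest.approx(brute_force_cn(profs[0], profs[1]), abs=1e-12)

    def test_mutational_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            muts = [f"m{k}" for k in range(int(rng.integers(1, 30)))]
            ci = {m: float(rng.random()) for m in muts if rng.random() < 0.8}
            cj = {m: float(rng.random()) for m in muts if rng.random() < 0.8}
            truncal = {m for m in muts if rng.random() < 0.2}
            d = mutational_distance(ci, cj, truncal)
            exp_val, exp_n = brute_force_mutational(ci, cj, truncal)
            assert d.value == pytest.approx(exp_val, abs=1e-12)
            assert d.n_items == exp_n
            assert 0.0 <= d.value <= 1.0
            d_rev = mutational_distance(cj, ci, truncal)
            assert d.value == d_rev.value


ccf_dicts = st.dictionaries(
    st.sampled_from([f"m{k}" for k in range(12)]),
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    max_size=12,
)


class TestMutationalDistanceProperties:
    @settings(max_examples=200, derandomize=True)
    @given(ci=ccf_dicts, cj=ccf_dicts)
    def test_symmetry_bounds_and_identity(self, ci, cj):
        d = mutational_distance(ci, cj)
        assert 0.0 <= d.value <= 1.0
        assert d.value == mutational_distance(cj, ci).value
        if d.n_items:
            assert mutational_distance(ci, ci).value == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(ci=ccf_dicts, cj=ccf_dicts)
    def test_truncal_exclusion_never_increases_item_count(self, ci, cj):
        full = mutational_distance(ci, cj)
        reduced = mutational_distance(ci, cj, truncal=set(list(ci)[:1]))
        assert reduced.n_items <= full.n_items


class TestAveragesAndClassification:
    def test_region_average(self):
        assert region_average_distance([0.2, 0.4]) == pytest.approx(0.3)
        assert region_average_distance([0.7]) == 0.7
        with pytest.raises(ValueError):
            region_average_distance([])

    def test_quartile_classification(self):
        mut = [1.0, 0.1, 0.2, 0.3, 0.15, 0.25, 0.2, 0.1]
        cn = [0.01, 0.5, 0.4, 0.45, 0.5, 0.42, 0.48, 0.9]
        classes = zscore_diversity_classification(mut, cn)
        assert classes[0] == "higher_mutation"
        assert classes[-1] == "higher_copy_number"

    def test_degenerate_variance_all_intermediate(self):
        with pytest.warns(UserWarning):
            classes = zscore_diversity_classification([0.3] * 6, [0.1, 0.2] * 3)
        assert set(classes) == {"intermediate"}

    def test_affine_invariance(self, rng):
        mut = rng.random(12)
        cn = rng.random(12)
        ref = zscore_diversity_classification(mut, cn)
        scaled = zscore_diversity_classification(mut * 7 + 2, cn * 0.3 - 1)
        assert ref == scaled

    def test_coupled_divergence_positively_correlated(self, rng):
        """When one bottleneck severity drives both mutation and CN
        divergence, the two distances correlate positively."""
        from scipy.stats import pearsonr

        mut_d, cn_d = [], []
        for _ in range(50):
            severity = float(rng.uniform(0, 1))
            ci = {f"m{k}": 1.0 for k in range(10)}
            cj = {
                f"m{k}": max(0.0, 1.0 - severity * float(rng.uniform(0.5, 1.5)))
                for k in range(10)
            }
            genome = {"1": 100}
            n_changed = int(severity * 10)
            rows_i = [("1", k * 10, (k + 1) * 10, 2, 1, 5) for k in range(10)]
            rows_j = [
                ("1", k * 10, (k + 1) * 10, 2 + (1 if k < n_changed else 0), 1, 5)
                for k in range(10)
            ]
            pi = make_profile("i", rows_i, genome)
            pj = make_profile("j", rows_j, genome)
            mut_d.append(mutational_distance(ci, cj).value)
            cn_d.append(copy_number_distance(pi, pj).value)
        r, p = pearsonr(mut_d, cn_d)
        assert r > 0 and p < 0.05
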