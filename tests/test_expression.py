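from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from looptopo.core import Interval
from looptopo.expression import (
    call_degs,
    classify_rescue,
    exclude_iaa_responsive,
    flag_promoter_ctcf,
    intersect_deg_sets,
    mean_by_condition,
    partition_deg_by_mechanism,
    percent_report,
)


class TestPercentReport:
    @pytest.mark.parametrize("num,den,dec,want", [
        (106, 128, 1, 82.8),
        (194, 11_777, 2, 1.65),
        (12_006, 29_656, 1, 40.5),
        (3811, 4284, 0, 89.0),
        (0, 100, 2, 0.0),
    ])
    def test_printed_fractions(self, num, den, dec, want):
        val, s = percent_report(num, den, dec)
        assert val == want
        assert s.endswith(f"({num}/{den})")

    def test_round_half_up_not_bankers(self):
        # 1/16 = 6.25% -> 6.3 under half-up (bankers would give 6.2)
        assert percent_report(1, 16, 1)[0] == 6.3
        assert percent_report(1, 8, 1)[0] == 12.5

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            percent_report(1, 0)

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            den = int(rng.integers(1, 100_000))
            num = int(rng.integers(0, den + 1))
            dec = int(rng.integers(0, 4))
            val, _ = percent_report(num, den, dec)
            scale = 10 ** dec
            frac = Fraction(num * 100 * scale, den)
            # round half up on the exact rational
            want = (frac.numerator // frac.denominator
                    + (1 if 2 * (frac.numerator % frac.denominator)
                       >= frac.denominator else 0)) / scale
            assert val == pytest.approx(want, abs=0)


def make_counts(means: dict, n_reps=3, rng=None, size=80.0):
    rng = rng or np.random.default_rng(1)
    genes = list(range(len(next(iter(means.values())))))
    data, design = {}, {}
    for cond, m in means.items():
        m = np.asarray(m, dtype=float)
        for r in range(n_reps):
            col = f"{cond}_rep{r + 1}"
            p = size / (size + np.maximum(m, 1e-9))
            data[col] = np.where(m <= 0, 0, rng.negative_binomial(size, p))
            design[col] = cond
    counts = pd.DataFrame(data, index=pd.Index([f"g{i}" for i in genes],
                                               name="gene_id"))
    return counts, design


class TestCallDegs:
    def test_identical_groups_no_calls(self):
        rng = np.random.default_rng(2)
        base = rng.integers(20, 500, 300).astype(float)
        counts, design = make_counts({"a": base, "b": base}, rng=rng)
        res = call_degs(counts, design, "a", "b")
        assert (res["deg_status"] == "unchanged").all() or \
            (res["deg_status"] != "unchanged").sum() <= 3

    def test_planted_recall(self):
        rng = np.random.default_rng(3)
        base = np.maximum(rng.lognormal(4.5, 0.8, 2000), 40.0)
        post = base.copy()
        post[:150] *= 2 ** -1.5
        counts, design = make_counts({"pre": base, "post": post}, rng=rng)
        res = call_degs(counts, design, "pre", "post", min_lfc=1.0)
        down = set(res.loc[res["deg_status"] == "down", "gene_id"])
        recall = len(down & {f"g{i}" for i in range(150)}) / 150
        assert recall >= 0.7

    def test_single_gene_closed_form(self):
        counts = pd.DataFrame(
            {"pre_rep1": [60, 1000], "pre_rep2": [40, 1000],
             "post_rep1": [15, 1000], "post_rep2": [10, 1000]},
            index=pd.Index(["g0", "bal"], name="gene_id"))
        design = {"pre_rep1": "pre", "pre_rep2": "pre",
                  "post_rep1": "post", "post_rep2": "post"}
        res = call_degs(counts, design, "pre", "post")
        share = 2025 / (2100 + 2025)
        k, n = 25, 125
        pmf = [stats.binom.pmf(i, n, share) for i in range(n + 1)]
        want = sum(p for p in pmf if p <= pmf[k] * (1 + 1e-9))
        assert res.set_index("gene_id").loc["g0", "pvalue"] == \
            pytest.approx(want, rel=1e-6)

    def test_replicate_requirement(self):
        counts = pd.DataFrame({"a_rep1": [1], "b_rep1": [1]},
                              index=pd.Index(["g"], name="gene_id"))
        with pytest.raises(ValueError, match="replicates"):
            call_degs(counts, {"a_rep1": "a", "b_rep1": "b"}, "a", "b")


class TestIntersect:
    def test_simple(self):
        common, table = intersect_deg_sets(
            {"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3, 5}})
        assert common == {3}
        assert table.loc[3, "in_all"]

    def test_empty_set(self):
        common, _ = intersect_deg_sets({"A": {1}, "B": set()})
        assert common == set()

    def test_order_and_duplication_invariant(self):
        s = {"A": {1, 2}, "B": {2, 3}}
        c1, _ = intersect_deg_sets(s)
        c2, _ = intersect_deg_sets(dict(reversed(list(s.items()))))
        assert c1 == c2

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            intersect_deg_sets({"A": {1}})

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        sets = {f"S{i}": set(rng.choice(100, 40, replace=False)) for i in range(4)}
        common, table = intersect_deg_sets(sets)
        universe = set().union(*sets.values())
        brute = {g for g in universe if all(g in s for s in sets.values())}
        assert common == brute
        assert set(table.index[table["in_all"]]) == brute


class TestPromoterCtcf:
    def test_counts(self):
        promw = pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
            "start": [0, 10_000], "end": [2000, 12_000], "strand": ["+", "+"]})
        peaks = [Interval("chr1", 500, 700)]
        flags, frac = flag_promoter_ctcf(["g1", "g2"], promw, peaks)
        assert flags["g1"] and not flags["g2"]
        assert frac == 0.5

    def test_no_peaks(self):
        promw = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                              "start": [0], "end": [2000], "strand": ["+"]})
        flags, frac = flag_promoter_ctcf(["g1"], promw, [])
        assert not flags["g1"] and frac == 0.0


class TestRescue:
    def build(self, base, iaa, wt, mut):
        counts = pd.DataFrame({
            "untreated_rep1": [base, 1000], "untreated_rep2": [base, 1000],
            "IAA_rep1": [iaa, 1000], "IAA_rep2": [iaa, 1000],
            "oeCTCFwt_IAA_rep1": [wt, 1000], "oeCTCFwt_IAA_rep2": [wt, 1000],
            "oeCTCFmut_IAA_rep1": [mut, 1000], "oeCTCFmut_IAA_rep2": [mut, 1000],
        }, index=pd.Index(["g", "bal"], name="gene_id"))
        design = {c: c.rsplit("_rep", 1)[0] for c in counts.columns}
        return counts, design

    def test_both_restored_loop_independent(self):
        counts, design = self.build(100, 25, 95, 105)
        assert classify_rescue(counts, design, ["g"])["g"] == "loop_independent"

    def test_wt_only_loop_dependent(self):
        counts, design = self.build(100, 25, 95, 26)
        assert classify_rescue(counts, design, ["g"])["g"] == "loop_dependent"

    def test_neither_not_rescued(self):
        counts, design = self.build(100, 25, 24, 26)
        assert classify_rescue(counts, design, ["g"])["g"] == "not_rescued"

    def test_depth_scaling_invariance(self):
        counts, design = self.build(100, 25, 95, 26)
        scaled = counts.copy()
        wt_cols = [c for c in counts.columns if c.startswith("oeCTCFwt")]
        scaled[wt_cols] = scaled[wt_cols] * 17  # uniform depth change
        a = classify_rescue(counts, design, ["g"])
        b = classify_rescue(scaled, design, ["g"])
        assert a["g"] == b["g"]

    def test_missing_condition_errors(self):
        counts, design = self.build(100, 25, 95, 105)
        bad = {k: v for k, v in design.items() if not v.startswith("oeCTCFmut")}
        counts = counts[[c for c in counts.columns if not c.startswith("oeCTCFmut")]]
        with pytest.raises(KeyError):
            classify_rescue(counts, bad, ["g"])


class TestMechanismPartition:
    def test_buckets(self):
        part = partition_deg_by_mechanism(
            ["a", "b", "c", "d"],
            {"a": True, "b": True, "c": False, "d": False},
            {"b", "c"})
        by = part.set_index("gene_id")["bucket"]
        assert by["a"] == "loop_independent_candidate"
        assert by["b"] == "cooperative"
        assert by["c"] == "loop_only"
        assert by["d"] == "neither"

    def test_true_partition(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(100)]
        flags = {g: bool(rng.integers(0, 2)) for g in genes}
        down = set(rng.choice(genes, 30, replace=False))
        part = partition_deg_by_mechanism(genes, flags, down)
        assert len(part) == 100
        assert part["bucket"].isin(
            ["loop_independent_candidate", "cooperative", "loop_only", "neither"]).all()

    def test_empty(self):
        assert partition_deg_by_mechanism([], {}, set()).empty


class TestIaaResponsive:
    def test_artifact_gene_flagged(self):
        rng = np.random.default_rng(6)
        base = np.full(50, 200.0)
        iaa = base.copy()
        iaa[0] = 40.0  # down in every IAA condition -> artifact
        counts, design = make_counts(
            {"untreated": base, "IAA": iaa, "oeCTCFwt_IAA": iaa,
             "oeCTCFmut_IAA": iaa}, rng=rng)
        out = exclude_iaa_responsive(
            counts, design, "untreated", ["IAA", "oeCTCFwt_IAA", "oeCTCFmut_IAA"])
        assert "g0" in out
        assert len(out) <= 3


def test_mean_by_condition_normalizes():
    counts = pd.DataFrame({"a_rep1": [10, 90], "a_rep2": [20, 180],
                           "b_rep1": [1, 9]},
                          index=pd.Index(["x", "y"], name="gene_id"))
    design = {"a_rep1": "a", "a_rep2": "a", "b_rep1": "b"}
    m = mean_by_condition(counts, design)
    assert m.loc["x", "a"] == pytest.approx(1e5)
    assert m.loc["x", "b"] == pytest.approx(1e5)
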