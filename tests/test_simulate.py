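import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from looptopo.atac import call_differential_accessibility
from looptopo.core import intervals_overlap, loop_span
from looptopo.simulate import (
    CONDITIONS,
    DEFAULT_CLASS_MIX,
    SimConfig,
    plant_h3k27ac_interactions,
    simulate_atac,
    simulate_ctcf_architecture,
    simulate_expression,
    simulate_genes,
    simulate_study,
    write_study,
)
from looptopo.topology import classify_all

from .conftest import SMALL_SIM


def small(**over):
    return SimConfig(**{**dict(seed=5, **SMALL_SIM), **over})


class TestConfig:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(class_mix={"outside": 0.5})

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown topology"):
            SimConfig(class_mix={"bogus": 1.0})

    def test_nonpositive_effect_rejected(self):
        bad = dict(DEFAULT_CLASS_MIX)
        with pytest.raises(ValueError, match="> 0"):
            SimConfig(depletion_effect={**bad, "cross": 0.0})

    def test_round_trip_dict(self):
        cfg = small()
        again = SimConfig.from_dict(cfg.to_dict())
        assert again == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError, match="bogus_key"):
            SimConfig.from_dict({"bogus_key": 1})


class TestArchitecture:
    def test_zero_loops(self):
        cfg = small(n_ctcf_loops=0, n_h3k27ac_interactions=0)
        motifs, peaks, loops = simulate_ctcf_architecture(cfg)
        assert loops == [] and peaks == []

    def test_determinism(self):
        a = simulate_ctcf_architecture(small())
        b = simulate_ctcf_architecture(small())
        assert a == b

    def test_infeasible_density_names_parameter(self):
        with pytest.raises(ValueError, match="n_ctcf_loops"):
            simulate_ctcf_architecture(small(chrS_length=100_000, n_ctcf_loops=50))

    def test_convergent_motifs(self):
        motifs, _, loops = simulate_ctcf_architecture(small())
        plus = [m for m in motifs if m.strand == "+"]
        minus = [m for m in motifs if m.strand == "-"]
        assert len(plus) == len(minus) == len(loops)
        for l, mp, mm in zip(loops, plus, minus):
            assert intervals_overlap(l.anchorL, mp)
            assert intervals_overlap(l.anchorR, mm)

    def test_log_strength_mean_within_3se(self):
        cfg = small(n_ctcf_loops=200, chrS_length=20_000_000,
                    n_h3k27ac_interactions=0)
        _, _, loops = simulate_ctcf_architecture(cfg)
        logs = np.log([l.strength for l in loops])
        mu, sigma = cfg.strength_lognormal
        se = sigma / np.sqrt(len(logs))
        assert abs(logs.mean() - mu) <= 3 * se

    def test_counts_scale_with_strength(self):
        _, _, loops = simulate_ctcf_architecture(small())
        s = np.array([l.strength for l in loops])
        c = np.array([l.counts["untreated"] for l in loops])
        assert np.corrcoef(s, c)[0, 1] > 0.9


class TestPlanting:
    def test_all_outside_disjoint_from_spans(self):
        mix = {k: 0.0 for k in DEFAULT_CLASS_MIX}
        mix["outside"] = 1.0
        cfg = small(class_mix=mix, n_h3k27ac_interactions=100)
        _, _, loops = simulate_ctcf_architecture(cfg)
        inter, truth = plant_h3k27ac_interactions(cfg, loops)
        assert (truth["class"] == "outside").all()
        for h in inter:
            hspan = loop_span(h, "midpoint")
            for c in loops:
                assert not intervals_overlap(hspan, loop_span(c, "midpoint"))

    def test_all_contain_iii_shares_both_anchors(self):
        mix = {k: 0.0 for k in DEFAULT_CLASS_MIX}
        mix["contain_III"] = 1.0
        cfg = small(class_mix=mix, n_h3k27ac_interactions=100)
        _, _, loops = simulate_ctcf_architecture(cfg)
        inter, _ = plant_h3k27ac_interactions(cfg, loops)
        by_id = {l.id: l for l in loops}
        for h in inter:
            assert any(h.anchorL == c.anchorL and h.anchorR == c.anchorR
                       for c in loops)

    def test_no_loops_with_nonoutside_classes_errors(self):
        cfg = small(n_ctcf_loops=0)
        with pytest.raises(ValueError, match="no CTCF loops"):
            plant_h3k27ac_interactions(cfg, [])

    def test_classifier_recovers_planted(self):
        cfg = small(seed=17)
        _, _, loops = simulate_ctcf_architecture(cfg)
        inter, truth = plant_h3k27ac_interactions(cfg, loops)
        labels = classify_all(inter, loops)
        t = truth.set_index("id")
        for lab in labels:
            row = t.loc[lab.loop_id]
            if row["ambiguous"]:
                continue
            assert lab.category == row["category"]

    def test_ambiguous_placements_marked(self):
        cfg = small(ambiguous_fraction=0.05)
        _, _, loops = simulate_ctcf_architecture(cfg)
        inter, truth = plant_h3k27ac_interactions(cfg, loops)
        amb = truth[truth["ambiguous"]]
        assert len(amb) == round(0.05 * cfg.n_h3k27ac_interactions)
        # ambiguous contain placements get a deterministic category
        labels = classify_all(inter, loops)
        by_id = {l.loop_id: l for l in labels}
        for iid in amb["id"]:
            assert by_id[iid].category == "contain"
            subs = {r.contain_subtype for r in by_id[iid].relations}
            assert subs == {"I", "II"}

    def test_class_proportions_multinomial(self):
        pvals = []
        for seed in range(3):
            cfg = small(seed=100 + seed)
            _, _, loops = simulate_ctcf_architecture(cfg)
            _, truth = plant_h3k27ac_interactions(cfg, loops)
            obs = truth["class"].value_counts()
            classes = sorted(cfg.class_mix)
            f_obs = [obs.get(c, 0) for c in classes]
            f_exp = [cfg.class_mix[c] * len(truth) for c in classes]
            keep = [i for i, e in enumerate(f_exp) if e > 0]
            res = stats.chisquare([f_obs[i] for i in keep],
                                  [f_exp[i] for i in keep])
            pvals.append(res.pvalue)
        # largest-remainder apportionment is near-exact by construction
        assert min(pvals) > 0.001


class TestAtacSim:
    def test_effect_fraction_zero(self):
        cfg = small(atac_affected_fraction=0.0, n_weak_sites=0)
        _, peaks, _ = simulate_ctcf_architecture(cfg)
        _, truth = simulate_atac(cfg, peaks)
        assert not truth["affected"].any()

    def test_effect_one_is_null(self):
        cfg = small(atac_effect=1.0)
        _, peaks, _ = simulate_ctcf_architecture(cfg)
        df, truth = simulate_atac(cfg, peaks)
        res = call_differential_accessibility(df, "untreated", "IAA")
        assert (res["call"] != "unchanged").sum() <= 0.02 * len(res)

    def test_power_at_planted_effect(self):
        cfg = small(atac_effect=0.3, atac_affected_fraction=0.4,
                    n_background_windows=1000)
        _, peaks, _ = simulate_ctcf_architecture(cfg)
        df, truth = simulate_atac(cfg, peaks)
        res = call_differential_accessibility(df, "untreated", "IAA", alpha=0.05)
        down = set(res.loc[res["call"] == "down", "window_id"])
        affected = set(truth.loc[truth["affected"], "window_id"])
        assert len(down & affected) / len(affected) >= 0.8

    def test_rescue_conditions_restored(self):
        cfg = small()
        _, peaks, _ = simulate_ctcf_architecture(cfg)
        df, truth = simulate_atac(cfg, peaks)
        aff = df[truth["affected"].to_numpy()]
        for cond in ("oeCTCFwt_IAA", "oeCTCFmut_IAA"):
            assert aff[cond].mean() > 2.5 * aff["IAA"].mean()


class TestExpressionSim:
    def test_deg_fraction_zero(self):
        cfg = small(deg_fraction=0.0, deg_up_n=0)
        genes, _, _ = simulate_genes(cfg, [], pd.DataFrame(
            columns=["id", "class", "slot"]))
        assert (genes["deg"] == "none").all()

    def test_determinism(self):
        cfg = small()
        study1 = simulate_study(cfg)
        study2 = simulate_study(cfg)
        pd.testing.assert_frame_equal(study1.expression_counts,
                                      study2.expression_counts)

    def test_planted_rescue_structure(self, small_study):
        truth = small_study.truth.genes
        counts = small_study.expression_counts
        design = small_study.design

        def cond_mean(gene, cond):
            cols = [c for c, k in design.items() if k == cond]
            return counts.loc[gene, cols].mean()

        li = truth[(truth["rescue"] == "loop_independent") & (truth["deg"] == "down")]
        for g in li["gene_id"].head(5):
            assert cond_mean(g, "IAA") < 0.6 * cond_mean(g, "untreated")
            assert cond_mean(g, "oeCTCFmut_IAA") > 0.6 * cond_mean(g, "untreated")
        ld = truth[truth["rescue"] == "loop_dependent"]
        for g in ld["gene_id"].head(5):
            assert cond_mean(g, "oeCTCFwt_IAA") > 0.6 * cond_mean(g, "untreated")
            assert cond_mean(g, "oeCTCFmut_IAA") < 0.6 * cond_mean(g, "untreated")

    def test_loop_dependent_genes_sit_on_depleted_interactions(self, small_study):
        truth = small_study.truth.genes
        ld = truth[truth["rescue"] == "loop_dependent"]
        assert (ld["chrom"] == "chrS").all()
        anchors = {(l.anchorL.chrom, l.anchorL.midpoint)
                   for l in small_study.h3k27ac_interactions}
        for r in ld.itertuples(index=False):
            assert ("chrS", int(r.tss)) in anchors


class TestStudyDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = small(seed=99)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_study(simulate_study(cfg), d1)
        write_study(simulate_study(cfg), d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seeds_differ(self, tmp_path):
        s1 = simulate_study(small(seed=1))
        s2 = simulate_study(small(seed=2))
        c1 = [l.counts["untreated"] for l in s1.ctcf_loops]
        c2 = [l.counts["untreated"] for l in s2.ctcf_loops]
        assert c1 != c2

    def test_design_covers_all_conditions(self, small_study):
        assert set(small_study.design.values()) == set(CONDITIONS)
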