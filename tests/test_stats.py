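"""Descriptives, ART factorial ANOVA, Wilcoxon posthocs — with independent
brute-force and reference-implementation oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegtrp import (ArtAnova, art_anova, art_transform, bonferroni_adjust,
                    med_mad, normality_check, posthoc_decomposition,
                    wilcoxon_signed_rank)


class TestMedMad:
    def test_hand_example(self):
        d = med_mad([1, 2, 3], scaled=False)
        assert (d.med, d.mad, d.n) == (2.0, 1.0, 3)

    def test_constant_vector_zero_mad(self):
        assert med_mad([4.2] * 10).mad == 0.0

    def test_scaled_mad_consistent_for_normal(self, rng):
        x = rng.normal(0, 1, 1000)
        assert med_mad(x, scaled=True).mad == pytest.approx(1.0, rel=0.10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            med_mad([])


class TestNormalityCheck:
    def test_heavy_tailed_mixture_rejected(self, rng):
        x = np.concatenate([rng.normal(0, 1, 450), rng.normal(0, 12, 50)])
        _w, p = normality_check(x)
        assert p < 0.05

    def test_gaussian_rejection_rate_calibrated(self):
        rej = 0
        reps = 200
        for i in range(reps):
            x = np.random.default_rng(500 + i).normal(size=50)
            if normality_check(x)[1] < 0.05:
                rej += 1
        assert 0.01 <= rej / reps <= 0.11

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0] * 20)

    def test_out_of_range_n_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])


def _toy_2x2(n_subj=4, seed=0, effect_a=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        for a in ("a0", "a1"):
            for b in ("b0", "b1"):
                y = rng.normal() + (effect_a if a == "a1" else 0.0)
                rows.append({"subject": f"s{s}", "A": a, "B": b, "y": y})
    return pd.DataFrame(rows)


class TestArtTransform:
    def test_alignment_matches_hand_computation(self):
        df = _toy_2x2()
        out = art_transform(df, "y", ["A", "B"])
        # independent oracle: plain loops over the definition
        y = df["y"].to_numpy()
        cells = {}
        for (a, b), grp in df.groupby(["A", "B"]):
            cells[(a, b)] = grp["y"].mean()
        grand = np.mean(list(cells.values()))
        m_a = {a: np.mean([cells[(a, b)] for b in ("b0", "b1")])
               for a in ("a0", "a1")}
        expected = [yi - cells[(r.A, r.B)] + (m_a[r.A] - grand)
                    for yi, r in zip(y, df.itertuples())]
        np.testing.assert_allclose(out["aligned(A)"], expected, atol=1e-12)

    def test_other_effects_stripped_after_alignment(self):
        df = _toy_2x2(seed=3, effect_a=1.0)
        out = art_transform(df, "y", ["A", "B"])
        aligned = out["aligned(A)"]
        # B marginal means and the A:B interaction pattern vanish
        mb = out.groupby("B")[["aligned(A)"]].mean().to_numpy()
        assert np.max(np.abs(mb - mb.mean())) < 1e-10
        cell = out.groupby(["A", "B"])[["aligned(A)"]].mean().to_numpy().reshape(2, 2)
        inter = cell - cell.mean(0) - cell.mean(1)[:, None] + cell.mean()
        assert np.max(np.abs(inter)) < 1e-10

    def test_ranks_are_permutation_without_ties(self):
        df = _toy_2x2(seed=5)
        out = art_transform(df, "y", ["A", "B"])
        n = len(df)
        for eff in ("A", "B", "A:B"):
            assert sorted(out[f"rank({eff})"]) == list(range(1, n + 1))


class TestArtAnova:
    def test_rank_data_matches_reference_rm_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        rows = []
        for s in range(10):
            for a in range(4):
                rows.append({"subject": f"s{s}", "A": f"a{a}",
                             "y": rng.normal(0.3 * a, 1)})
        df = pd.DataFrame(rows)
        # data already ranks, single factor, no ties: ART = ANOVA on ranks
        df["y"] = sps.rankdata(df["y"])
        mine = art_anova(df, "y", ["A"]).iloc[0]
        ref = pg.rm_anova(data=df, dv="y", within="A", subject="subject")
        assert mine["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-10)
        assert mine["p"] == pytest.approx(float(ref["p_unc"].iloc[0]),
                                          rel=1e-10)

    def test_shift_and_scale_invariance(self):
        df = _toy_2x2(seed=9, effect_a=0.5)
        base = art_anova(df, "y", ["A", "B"])
        for transform in (lambda y: y + 13.7, lambda y: y * 3.1):
            df2 = df.assign(y=transform(df["y"]))
            other = art_anova(df2, "y", ["A", "B"])
            pd.testing.assert_frame_equal(base, other, atol=1e-10)

    def test_eta_p_sq_consistent_with_f_and_dfs(self):
        df = _toy_2x2(n_subj=6, seed=1, effect_a=0.8)
        t = art_anova(df, "y", ["A", "B"])
        for _, r in t.iterrows():
            expected = r["F"] * r["df_effect"] / (
                r["F"] * r["df_effect"] + r["df_error"])
            assert r["eta_p_sq"] == pytest.approx(expected, abs=1e-12)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in range(18):
            for i, proj in enumerate(["isometric", "orthographic"]):
                for e in range(14):
                    rows.append({"subject": f"s{s:02d}", "projection": proj,
                                 "electrode": f"e{e:02d}",
                                 "y": rng.normal(0.3 * i, 0.1)})
        t = art_anova(pd.DataFrame(rows), "y", ["projection", "electrode"])
        p_proj = t.set_index("effect").loc["projection", "p"]
        assert p_proj < 1e-3

    def test_unbalanced_design_rejected(self):
        df = _toy_2x2().iloc[:-1]
        with pytest.raises(ValueError):
            art_anova(df, "y", ["A", "B"])

    def test_model_results_summary(self):
        df = _toy_2x2(seed=6)
        res = ArtAnova(df, dv="y", within=["A", "B"]).fit()
        text = res.summary()
        assert "A:B" in text and "eta_p^2" in text
        assert res.n_subjects == 4


class TestWilcoxon:
    def test_hand_example_v(self):
        # differences +1 +2 +3 +4 -5: positive ranks 1..4 sum to 10
        res = wilcoxon_signed_rank([1, 2, 3, 4, 0], [0, 0, 0, 0, 5])
        assert res.V == 10.0

    def test_identical_samples_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate and res.p == 1.0 and res.V == 0.0 and res.r == 0.0

    @pytest.mark.parametrize("n", [3, 5, 6])
    def test_exact_p_matches_sign_enumeration(self, n):
        mags = np.arange(1.0, n + 1)
        vmax = n * (n + 1) / 2
        dist = np.zeros(int(vmax) + 1)
        for signs in itertools.product([1, -1], repeat=n):
            v = sum(m for m, s in zip(mags, signs) if s > 0)
            dist[int(v)] += 1
        dist /= 2 ** n
        for signs in itertools.product([1, -1], repeat=n):
            d = mags * np.array(signs)
            res = wilcoxon_signed_rank(d, np.zeros(n))
            v = int(res.V)
            p_oracle = min(1.0, 2 * min(dist[:v + 1].sum(), dist[v:].sum()))
            assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_symmetry_of_v(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        n = 15
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(y, x)
        assert a.V + b.V == n * (n + 1) / 2

    def test_effect_size_uses_z_over_sqrt_n(self, rng):
        x = rng.normal(1.0, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        res = wilcoxon_signed_rank(x, y)
        assert res.r == pytest.approx(abs(res.Z) / math.sqrt(res.n_effective))
        lit = wilcoxon_signed_rank(x, y, literal_r=True)
        assert lit.r == pytest.approx(lit.V / math.sqrt(lit.n_effective))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.01], m=3) == [pytest.approx(0.03)]
        assert bonferroni_adjust([0.5], m=4) == [1.0]
        assert bonferroni_adjust([0.2], m=1) == [pytest.approx(0.2)]

    def test_order_preserving(self, rng):
        p = sorted(rng.uniform(0, 0.2, 6))
        adj = bonferroni_adjust(p, m=10)
        assert adj == sorted(adj)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], m=1)
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5])


def _trp_table_with_interaction(seed=0, delta=0.4):
    """Synthetic one-band table: projection effect confined to the RH."""
    from eegtrp import default_montage
    montage = default_montage()
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(18):
        for proj in ("isometric", "orthographic"):
            for e in montage.electrodes:
                hemi = montage.hemisphere_of[e]
                mu = delta if (proj == "orthographic" and hemi == "RH") else 0.0
                rows.append({"subject": f"s{s:02d}", "projection": proj,
                             "electrode": e, "hemisphere": hemi,
                             "area": montage.area_of[e],
                             "trp": rng.normal(mu, 0.15)})
    return pd.DataFrame(rows)


class TestPosthoc:
    def test_planted_interaction_decomposed(self):
        table = _trp_table_with_interaction()
        res = ArtAnova(table, dv="trp",
                       within=["projection", "hemisphere"]).fit()
        sig = res.significant_effects()
        assert "projection:hemisphere" in sig
        ph = posthoc_decomposition(table, sig)
        within_h = ph[ph["family"] == "projection_within_hemisphere"]
        rh = within_h[within_h["scope"] == "RH"].iloc[0]
        lh = within_h[within_h["scope"] == "LH"].iloc[0]
        assert rh["p_adj"] < 0.01      # effect lives in the right hemisphere
        assert lh["p_adj"] > rh["p_adj"]

    def test_homologous_pair_family_size(self):
        table = _trp_table_with_interaction(seed=1)
        ph = posthoc_decomposition(table, ["projection:hemisphere"])
        fam = ph[ph["family"] == "pairs_within_isometric"]
        assert len(fam) == 7           # one comparison per homologous pair
        # Bonferroni within the family of 7
        np.testing.assert_allclose(fam["p_adj"],
                                   np.minimum(1.0, fam["p"] * 7))

    def test_no_significant_effects_empty_output(self):
        table = _trp_table_with_interaction(seed=2, delta=0.0)
        ph = posthoc_decomposition(table, [])
        assert ph.empty
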