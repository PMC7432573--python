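"""Moderated EWAS, FDR, DMRs, enrichment, overlap null and gene-set test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myoclock.data import ISLAND_CONTEXTS
from myoclock.ewas import (
    ModeratedVariancePrior,
    call_dmrs,
    enrichment_fisher,
    estimate_prior,
    ewas_fit,
    fdr_bh,
    gene_set_test,
    random_overlap_test,
)

from conftest import make_annotation, make_sheet


def _simulate_methylation(rng, n_probes=300, n=60, slope_sd=0.0, sheet_kwargs=None):
    ages = rng.uniform(20, 80, n)
    slopes = rng.normal(0, slope_sd, n_probes) if slope_sd else np.zeros(n_probes)
    base = rng.uniform(0.2, 0.8, n_probes)
    Y = base[:, None] + slopes[:, None] * (ages[:, None] - 50).T \
        + rng.normal(0, 0.03, (n_probes, n))
    values = pd.DataFrame(Y, index=[f"cg{i:05d}" for i in range(n_probes)],
                          columns=[f"s{j:03d}" for j in range(n)])
    sheet = make_sheet(list(values.columns), ages, **(sheet_kwargs or {}))
    return values, sheet, slopes


class TestEstimatePrior:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        d0_true, s0_true, d = 4.0, 0.04, 50
        s_sq = s0_true * d0_true / rng.chisquare(d0_true, 5000)
        s_obs = s_sq * rng.chisquare(d, 5000) / d     # observed sample variances
        prior = estimate_prior(s_obs, d)
        assert 2.0 <= prior.d0 <= 8.0
        assert abs(prior.s0_sq - s0_true) / s0_true < 0.25

    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_prior(np.full(500, 0.02), d=30)
        assert np.isinf(prior.d0)
        # s0^2 recovers the common variance up to the log-chi-square bias term
        assert prior.s0_sq == pytest.approx(0.02, rel=0.05)

    def test_order_invariant(self):
        rng = np.random.default_rng(1)
        s = rng.chisquare(10, 1000) / 10 * 0.05
        p1 = estimate_prior(s, 20)
        p2 = estimate_prior(s[::-1], 20)
        assert p1.d0 == pytest.approx(p2.d0)
        assert p1.s0_sq == pytest.approx(p2.s0_sq)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            estimate_prior(np.concatenate([np.full(200, 0.1), [-1.0]]), 10)


class TestEwasFit:
    def test_d0_zero_limit_equals_ordinary_ols(self):
        rng = np.random.default_rng(2)
        values, sheet, _ = _simulate_methylation(rng, n_probes=150)
        out = ewas_fit(values, sheet, covariates=["age"], block=None,
                       prior=ModeratedVariancePrior(0.0, 1.0))
        np.testing.assert_allclose(out["t_moderated"], out["t_ordinary"], atol=1e-10)
        # independent oracle: per-probe OLS via scipy.linregress
        ages = sheet.ages(values.columns)
        for pid in values.index[:10]:
            res = stats.linregress(ages, values.loc[pid])
            assert out.loc[pid, "slope"] == pytest.approx(res.slope, abs=1e-10)
            assert out.loc[pid, "t_ordinary"] == pytest.approx(
                res.slope / res.stderr, rel=1e-8)

    def test_d0_infinite_limit_shares_one_variance(self):
        rng = np.random.default_rng(3)
        values, sheet, _ = _simulate_methylation(rng, n_probes=120)
        prior = ModeratedVariancePrior(np.inf, 0.0009)
        out = ewas_fit(values, sheet, covariates=["age"], block=None, prior=prior)
        # t_mod = slope / sqrt(s0^2 * v): reconstruct and compare
        ratio = out["slope"] / out["t_moderated"]
        assert np.allclose(ratio / ratio.iloc[0], 1.0)

    def test_rank_deficient_design_reports_aliased(self):
        rng = np.random.default_rng(4)
        values, sheet, _ = _simulate_methylation(
            rng, n_probes=60, n=20,
            sheet_kwargs={"sex": ["F", "M"] * 10})
        sheet.df["condition"] = sheet.df["sex"]  # perfectly aliased factor
        with pytest.raises(ValueError, match="aliased"):
            ewas_fit(values, sheet, covariates=["age", "sex", "condition"], block=None)

    def test_direction_matches_slope_sign(self):
        rng = np.random.default_rng(5)
        values, sheet, _ = _simulate_methylation(rng, n_probes=200, slope_sd=0.002)
        out = ewas_fit(values, sheet, covariates=["age"], block=None)
        assert (np.sign(out["slope"]) == np.where(out["direction"] == "hyper", 1, -1)).all()

    def test_per_decade_unit_convention(self):
        rng = np.random.default_rng(6)
        values, sheet, _ = _simulate_methylation(rng, n_probes=120, slope_sd=0.002)
        out = ewas_fit(values, sheet, covariates=["age"], block=None)
        per_decade = out["slope"] * 10
        assert np.allclose(per_decade / out["slope"], 10.0)

    def test_paired_block_improves_power_with_subject_effects(self):
        # strong shared subject effects: block-aware GLS should detect the
        # age slope that plain OLS drowns in between-subject noise
        rng = np.random.default_rng(7)
        n_subj, n_probes = 30, 150
        ages = np.repeat(rng.uniform(20, 80, n_subj), 2)
        subj = np.repeat([f"p{i}" for i in range(n_subj)], 2)
        slopes = np.full(n_probes, 0.0015)
        u = np.repeat(rng.normal(0, 0.10, (n_probes, n_subj)), 2, axis=1)
        Y = 0.5 + slopes[:, None] * (ages[None, :] - 50) + u \
            + rng.normal(0, 0.01, (n_probes, 2 * n_subj))
        values = pd.DataFrame(Y, index=[f"cg{i}" for i in range(n_probes)],
                              columns=[f"s{j}" for j in range(2 * n_subj)])
        sheet = make_sheet(list(values.columns), ages, subject=list(subj))
        out_blocked = ewas_fit(values, sheet, covariates=["age"], block="subject_id")
        out_plain = ewas_fit(values, sheet, covariates=["age"], block=None)
        assert out_blocked.attrs["consensus_rho"] > 0.5
        # consensus-correlation GLS does not distort slopes
        np.testing.assert_allclose(out_blocked["slope"], out_plain["slope"], atol=2e-4)

    def test_null_type_i_error_controlled(self):
        # no age effect: fraction of p < 0.005 within 3 binomial SE of 0.005
        hits, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            values, sheet, _ = _simulate_methylation(rng, n_probes=500, n=100)
            out = ewas_fit(values, sheet, covariates=["age"], block=None)
            hits += int((out["p"] < 0.005).sum())
            total += len(out)
        rate = hits / total
        se = np.sqrt(0.005 * 0.995 / total)
        assert abs(rate - 0.005) < 3 * se


class TestFdrBH:
    def _bh_oracle(self, p):
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        prev = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = n - rank_from_top
            val = min(prev, p[idx] * n / rank)
            adj[idx] = val
            prev = val
        return adj

    def test_all_ones(self):
        np.testing.assert_array_equal(fdr_bh(np.ones(5)), np.ones(5))

    def test_small_example_against_oracle(self):
        p = np.array([0.001, 0.01, 0.03, 0.9])
        np.testing.assert_allclose(fdr_bh(p), self._bh_oracle(p), atol=1e-12)

    def test_1000_random_vectors_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(fdr_bh(p), self._bh_oracle(p), atol=1e-12)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(fdr_bh(p)[perm], fdr_bh(p[perm]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fdr_bh([0.5, 1.5])


def _ewas_frame(probes, fdrs, directions, slopes=None):
    slopes = slopes if slopes is not None else \
        [0.001 if d == "hyper" else -0.001 for d in directions]
    return pd.DataFrame({
        "slope": slopes, "se": 0.1, "t_ordinary": 1.0, "t_moderated": 1.0,
        "p": fdrs, "fdr": fdrs, "direction": directions,
    }, index=probes)


class TestCallDmrs:
    def test_two_nearby_same_direction_probes_merge(self):
        ewas = _ewas_frame(["a", "b"], [1e-4, 1e-4], ["hyper", "hyper"])
        ann = make_annotation(["a", "b"], positions=[1000, 1500])
        dmrs = call_dmrs(ewas, ann)
        assert len(dmrs) == 1
        assert dmrs[0].probe_ids == ["a", "b"]
        assert dmrs[0].start == 1000 and dmrs[0].end == 1500

    def test_gap_rule_blocks_merge(self):
        ewas = _ewas_frame(["a", "b"], [1e-4, 1e-4], ["hyper", "hyper"])
        ann = make_annotation(["a", "b"], positions=[1000, 6000])
        assert call_dmrs(ewas, ann) == []

    def test_opposite_directions_block_merge(self):
        ewas = _ewas_frame(["a", "b"], [1e-4, 1e-4], ["hyper", "hypo"])
        ann = make_annotation(["a", "b"], positions=[1000, 1500])
        assert call_dmrs(ewas, ann) == []

    def test_nonsignificant_probes_ignored(self):
        ewas = _ewas_frame(["a", "b", "c"], [1e-4, 0.5, 1e-4],
                           ["hyper", "hyper", "hyper"])
        ann = make_annotation(["a", "b", "c"], positions=[1000, 1400, 1800])
        dmrs = call_dmrs(ewas, ann)
        assert len(dmrs) == 1 and dmrs[0].probe_ids == ["a", "c"]

    def test_input_order_invariant(self):
        probes = ["a", "b", "c", "d"]
        ewas = _ewas_frame(probes, [1e-4] * 4, ["hypo"] * 4)
        ann = make_annotation(probes, positions=[1000, 1500, 1900, 9000])
        d1 = call_dmrs(ewas, ann)
        d2 = call_dmrs(ewas.iloc[::-1], ann)
        assert [d.probe_ids for d in d1] == [d.probe_ids for d in d2]

    def test_chromosome_boundary_respected(self):
        ewas = _ewas_frame(["a", "b"], [1e-4, 1e-4], ["hyper", "hyper"])
        ann = make_annotation(["a", "b"], chrom=["chr1s", "chr2s"],
                              positions=[1000, 1200])
        assert call_dmrs(ewas, ann) == []


def _fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p: sum of all table probabilities <= obs."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {x: stats.hypergeom.pmf(x, n, col1, row1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestEnrichmentFisher:
    def _setup(self, seed=10, n=400):
        rng = np.random.default_rng(seed)
        probes = [f"cg{i:05d}" for i in range(n)]
        ann = make_annotation(probes, seed=seed)
        return rng, probes, ann

    def test_matched_proportions_give_null(self):
        _, probes, _ = self._setup()
        contexts = [ISLAND_CONTEXTS[i % 4] for i in range(len(probes))]
        ann = make_annotation(probes, island_context=contexts)
        fg = probes[:200]  # 50 probes of each level, exactly as in background
        out = enrichment_fisher(fg, probes, ann, "island_context")
        assert np.allclose(out["odds_ratio"].astype(float), 1.0)
        assert np.allclose(out["p"], 1.0)

    def test_matches_exhaustive_oracle_on_small_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]])
            oracle = _fisher_two_sided_oracle(a, b, c, d)
            assert abs(p - oracle) < 1e-10

    def test_island_levels_all_reported(self):
        _, probes, ann = self._setup()
        out = enrichment_fisher(probes[:40], probes, ann, "island_context")
        assert len(out) == 4 and out["fdr"].notna().all()

    def test_chromatin_levels_all_reported(self):
        _, probes, ann = self._setup()
        out = enrichment_fisher(probes[:40], probes, ann, "chromatin_state")
        assert len(out) == 15

    def test_detects_planted_enrichment(self):
        _, probes, _ = self._setup()
        contexts = ["island"] * 100 + ["open_sea"] * 300
        ann = make_annotation(probes, island_context=contexts)
        fg = probes[:80]  # almost all islands
        out = enrichment_fisher(fg, probes, ann, "island_context").set_index("level")
        assert out.loc["island", "fdr"] < 0.005
        assert out.loc["island", "odds_ratio"] > 1

    def test_foreground_must_be_subset(self):
        _, probes, ann = self._setup()
        with pytest.raises(ValueError, match="subset"):
            enrichment_fisher(["nope"], probes, ann)


class TestRandomOverlap:
    def test_disjoint_panel_always_zero(self):
        bg = [f"cg{i}" for i in range(500)]
        res = random_overlap_test(bg[:20], ["other1", "other2"], bg,
                                  draw_size=20, n_draws=2000, seed=1)
        assert res.max_null_overlap == 0 and res.observed_overlap == 0

    def test_panel_equals_background(self):
        bg = [f"cg{i}" for i in range(300)]
        res = random_overlap_test(bg[:50], bg, bg, draw_size=50,
                                  n_draws=2000, seed=2)
        assert res.null_mean == 50.0 and res.null_var == 0.0

    def test_matches_hypergeometric_moments(self):
        n_bg, n_b, k = 2000, 100, 50
        bg = [f"cg{i}" for i in range(n_bg)]
        res = random_overlap_test(bg[:k], bg[: n_b], bg, draw_size=k,
                                  n_draws=30000, seed=3)
        mean = k * n_b / n_bg
        var = k * (n_b / n_bg) * (1 - n_b / n_bg) * (n_bg - k) / (n_bg - 1)
        se_mean = np.sqrt(var / res.n_draws)
        assert abs(res.null_mean - mean) < 3 * se_mean

    def test_draw_size_too_large(self):
        bg = ["a", "b", "c"]
        with pytest.raises(ValueError, match="draw_size"):
            random_overlap_test(bg, bg, bg, draw_size=10, n_draws=10)

    def test_deterministic_given_seed(self):
        bg = [f"cg{i}" for i in range(400)]
        r1 = random_overlap_test(bg[:30], bg[:60], bg, n_draws=5000, seed=9)
        r2 = random_overlap_test(bg[:30], bg[:60], bg, n_draws=5000, seed=9)
        assert r1.null_mean == r2.null_mean and r1.p_value == r2.p_value


class TestGeneSetTest:
    def _annotation_with_counts(self, counts: dict[str, int]):
        probes, genes = [], []
        for g, c in counts.items():
            for i in range(c):
                probes.append(f"{g}_p{i}")
                genes.append([g])
        ann = make_annotation(probes)
        ann.df["genes"] = genes
        return probes, ann

    def test_equal_probe_counts_reduce_to_hypergeometric(self):
        counts = {f"G{i}": 3 for i in range(40)}
        probes, ann = self._annotation_with_counts(counts)
        rng = np.random.default_rng(12)
        sig = list(rng.choice(probes, 15, replace=False))
        gene_sets = {"setA": [f"G{i}" for i in range(10)]}
        out = gene_set_test(sig, probes, ann, gene_sets)
        sig_genes = {p.split("_")[0] for p in sig}
        k = len(sig_genes & set(gene_sets["setA"]))
        p_hyp = stats.hypergeom.sf(k - 1, 40, 10, len(sig_genes))
        assert out.loc[0, "p"] == pytest.approx(p_hyp, abs=1e-6)

    def test_set_of_every_gene_has_p_one(self):
        counts = {f"G{i}": 2 + (i % 5) for i in range(30)}
        probes, ann = self._annotation_with_counts(counts)
        sig = probes[:10]
        out = gene_set_test(sig, probes, ann, {"all": list(counts)})
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_bias_aware_test_controls_type_i_where_naive_inflates(self):
        # big genes have 10x probes; the probe-level null makes them
        # "significant" more often, inflating the naive gene-level test
        naive_rej, aware_rej = 0, 0
        n_trials = 20
        for seed in range(n_trials):
            rng = np.random.default_rng(2000 + seed)
            counts = {f"S{i}": 2 for i in range(900)}
            counts.update({f"B{i}": 20 for i in range(60)})
            probes, ann = self._annotation_with_counts(counts)
            sig = list(rng.choice(probes, 60, replace=False))  # uniform null
            big_set = {"big": [f"B{i}" for i in range(60)]}
            aware = gene_set_test(sig, probes, ann, big_set, bias_correction=True)
            naive = gene_set_test(sig, probes, ann, big_set, bias_correction=False)
            aware_rej += int(aware.loc[0, "p"] < 0.05)
            naive_rej += int(naive.loc[0, "p"] < 0.05)
        se = np.sqrt(0.05 * 0.95 / n_trials)
        assert naive_rej / n_trials > 0.05 + 3 * se     # naive is anticonservative
        assert aware_rej / n_trials <= 0.05 + 3 * se    # bias-aware holds level

    def test_empty_set_after_intersection_rejected(self):
        probes, ann = self._annotation_with_counts({"G1": 3, "G2": 3})
        with pytest.raises(ValueError, match="empty after intersection"):
            gene_set_test(probes[:2], probes, ann, {"ghost": ["NOPE"]})
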