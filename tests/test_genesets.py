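"""FDR, gene-set intersection, enrichment, PSG counts, PGLS and overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

import halcyon as h
from halcyon.io import GeneTestResult


class TestBhFdr:
    def test_single_p(self):
        assert h.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        """p=(.01,.02,.03,.04): q_(i) = min_{j>=i} p_(j)*4/j = 0.04 for all."""
        assert np.allclose(h.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)
        got = h.bh_fdr([0.005, 0.04, 0.02, 1.0])
        want = [0.02, 0.0533333333, 0.04, 1.0]
        assert np.allclose(got, want)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_dominates_p_and_is_monotone(self, ps):
        q = h.bh_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-12).all() and (q <= 1).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            h.bh_fdr([])


def _mk(gene, test, score, branch=None):
    return GeneTestResult(gene, test, score, branch_id=branch)


class TestAdaptiveConvergentSet:
    def _toy(self):
        """BS∩RELAX = {g1,g2,g3}; multi-lineage = {g2,g3,g4}; residue = {g3}."""
        recs = []
        for g in ("g1", "g2", "g3"):
            recs.append(_mk(g, "branch_site", 1e-6))
            recs.append(_mk(g, "relax", 1e-6))
        recs.append(_mk("g4", "branch_site", 0.9))
        recs.append(_mk("g4", "relax", 1e-6))
        for g in ("g2", "g3", "g4"):
            for br in ("spA", "spB"):
                recs.append(_mk(g, "branch_adaptive", 1e-6, br))
        recs.append(_mk("g1", "branch_adaptive", 1e-6, "spA"))
        recs.append(_mk("g1", "branch_adaptive", 0.9, "spB"))
        recs.append(_mk("g3", "residue_convergence", 0.95))
        for g in ("g1", "g2", "g4"):
            recs.append(_mk(g, "residue_convergence", 0.2))
        return recs

    def test_toy_set_algebra(self):
        rep = h.adaptive_convergent_set(self._toy(), ["spA", "spB"])
        assert rep.confirmed_set == {"g1", "g2", "g3"}
        assert rep.multi_lineage_set == {"g2", "g3", "g4"}
        assert rep.residue_set == {"g3"}
        assert rep.final_set == {"g3"}
        assert rep.euler_counts["confirmed&multi_lineage"] == 2

    def test_confirmation_percentage_arithmetic(self):
        """308 confirmed of 1426 branch-site genes reports 21.6%."""
        recs = []
        for i in range(1426):
            recs.append(_mk(f"g{i}", "branch_site", 1e-8))
        for i in range(308):
            recs.append(_mk(f"g{i}", "relax", 1e-8))
        for i in range(308, 1426):
            recs.append(_mk(f"g{i}", "relax", 0.999))
        recs.append(_mk("g0", "branch_adaptive", 1e-8, "spA"))
        recs.append(_mk("g0", "residue_convergence", 0.9))
        rep = h.adaptive_convergent_set(recs, ["spA"], min_lineages=1)
        assert rep.confirmation_pct == 21.6

    def test_monotone_in_thresholds(self, sim_world):
        cfg, tree, traits, _ = sim_world
        recs, _, _, _ = h.simulate_gene_tests_and_psgs(tree, traits, cfg, 42)
        focal = [t for t, v in traits.plunge.items() if v == 1]
        loose = h.adaptive_convergent_set(recs, focal, fdr_threshold=0.10,
                                          residue_posterior=0.7)
        tight = h.adaptive_convergent_set(recs, focal, fdr_threshold=0.01,
                                          residue_posterior=0.9)
        assert tight.final_set <= loose.final_set

    def test_randomized_tables_match_brute_force(self):
        """Set membership equals an independent per-gene re-evaluation."""
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(500)]
        recs = []
        for g in genes:
            recs.append(_mk(g, "branch_site", float(rng.uniform())))
            recs.append(_mk(g, "relax", float(rng.uniform())))
            recs.append(_mk(g, "residue_convergence", float(rng.uniform())))
            for br in ("s1", "s2", "s3"):
                recs.append(_mk(g, "branch_adaptive",
                               float(rng.uniform()), br))
        rep = h.adaptive_convergent_set(recs, ["s1", "s2", "s3"])
        q = {}
        for t in ("branch_site", "relax", "branch_adaptive"):
            sub = [r for r in recs if r.test_name == t]
            for r, qv in zip(sub, h.bh_fdr([r.score for r in sub])):
                q[(t, r.gene_id, r.branch_id)] = qv
        for g in genes:
            in_conf = (q[("branch_site", g, None)] < 0.05
                       and q[("relax", g, None)] < 0.05)
            n_br = sum(q[("branch_adaptive", g, b)] < 0.05
                       for b in ("s1", "s2", "s3"))
            res = any(r.test_name == "residue_convergence"
                      and r.gene_id == g and r.score >= 0.8 for r in recs)
            assert (g in rep.final_set) == (in_conf and n_br >= 2 and res)

    def test_missing_test_named(self):
        recs = [_mk("g1", "branch_site", 0.01), _mk("g1", "relax", 0.01),
                _mk("g1", "residue_convergence", 0.9)]
        with pytest.raises(ValueError, match="branch_adaptive"):
            h.adaptive_convergent_set(recs, ["spA"])


class TestHypergeometric:
    def test_maximal_draw_closed_form(self):
        """N=20, K=5, n=5, k=5: p = 1/C(20,5) = 1/15504."""
        bg = [f"g{i}" for i in range(20)]
        target = bg[:5]
        res = h.hypergeom_enrichment(target, {"T": set(bg[:5])}, bg)
        assert res[0].p == pytest.approx(1 / comb(20, 5, exact=True),
                                         rel=1e-12)

    def test_term_covering_background(self):
        bg = [f"g{i}" for i in range(30)]
        res = h.hypergeom_enrichment(bg[:10], {"ALL": set(bg)}, bg)
        assert res[0].p == pytest.approx(1.0)

    def test_expected_overlap_not_flagged(self):
        rng = np.random.default_rng(3)
        bg = [f"g{i}" for i in range(1000)]
        term = set(rng.choice(bg, 200, replace=False))
        target = list(rng.choice(bg, 100, replace=False))
        res = h.hypergeom_enrichment(target, {"T": term}, bg)
        if res:  # k likely near n*K/N = 20
            assert res[0].q > 0.05

    def test_exact_sum_matches_monte_carlo(self):
        rng = np.random.default_rng(5)
        bg = [f"g{i}" for i in range(60)]
        for _ in range(5):
            K = int(rng.integers(5, 30))
            n = int(rng.integers(5, 30))
            term = set(rng.choice(bg, K, replace=False))
            target = list(rng.choice(bg, n, replace=False))
            res = h.hypergeom_enrichment(target, {"T": term}, bg)
            if not res:
                continue
            k_obs = res[0].k
            draws = np.array([
                len(term & set(rng.choice(bg, n, replace=False)))
                for _ in range(20000)])
            mc = (draws >= k_obs).mean()
            sd = np.sqrt(max(mc * (1 - mc), 1e-6) / 20000)
            assert abs(res[0].p - mc) < max(3 * sd, 0.01)

    def test_target_outside_background(self):
        with pytest.raises(ValueError):
            h.hypergeom_enrichment(["zz"], {"T": {"g1"}}, ["g1", "g2"])


class TestPsgCounts:
    def test_thresholding(self):
        recs = [GeneTestResult("g1", "branch_adaptive", 0.001, "s1", 0.001),
                GeneTestResult("g2", "branch_adaptive", 0.9, "s1", 0.9),
                GeneTestResult("g1", "branch_adaptive", 0.7, "s2", 0.7),
                GeneTestResult("g2", "branch_adaptive", 0.8, "s2", 0.8)]
        tab = h.psg_counts(recs)
        assert tab.totals["s1"] == 1 and tab.totals["s2"] == 0
        assert h.psg_counts(recs, q_threshold=1.1).totals.sum() == 4

    def test_matches_brute_force_filter(self, sim_world):
        cfg, tree, traits, _ = sim_world
        recs, indicator, _, _ = h.simulate_gene_tests_and_psgs(
            tree, traits, cfg, 13)
        ba = [r for r in recs if r.test_name == "branch_adaptive"]
        tab = h.psg_counts(ba)
        # planted indicator genes have p ~ 1e-5; they must dominate totals
        for sp, genes in indicator.items():
            got = tab.genes_of(sp)
            assert len(got & genes) / len(genes) > 0.95


class TestPgls:
    def _bm_world(self, n=50, seed=0, lam_star=False):
        rng = np.random.default_rng(seed)
        from conftest import random_ultrametric
        if lam_star:
            tree = h.Phylogeny.from_newick(
                "(" + ",".join(f"t{i}:1" for i in range(n)) + ");")
        else:
            tree = random_ultrametric(n, rng)
        traits = h.TraitMap(
            plunge={t: int(rng.random() < 0.4) for t in tree.tip_labels},
            island={t: int(rng.random() < 0.4) for t in tree.tip_labels},
            ln_mass={t: float(rng.normal(4, 1)) for t in tree.tip_labels})
        return tree, traits, rng

    def test_lambda_zero_equals_ols(self):
        tree, traits, rng = self._bm_world(20, 1)
        totals = pd.Series(rng.poisson(100, 20).astype(float),
                           index=tree.tip_labels)
        fit = h.fit_pgls_lambda(totals, traits, tree, lam=0.0)
        X = np.column_stack([
            np.ones(20),
            [traits.plunge[t] for t in tree.tip_labels],
            [traits.ln_mass[t] for t in tree.tip_labels],
            [traits.island[t] for t in tree.tip_labels],
            [traits.ln_mass[t] * traits.island[t] for t in tree.tip_labels]])
        # lambda=0 leaves a diagonal covariance: weighted least squares
        w = 1.0 / np.diag(tree.phylo_covariance(tree.tip_labels))
        Xw = X * np.sqrt(w)[:, None]
        yw = totals.to_numpy() * np.sqrt(w)
        ols = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        assert np.allclose(fit.coef["estimate"].to_numpy(), ols, atol=1e-8)

    def test_fixed_lambda_matches_matrix_oracle(self):
        """Coefficients equal a hand-run GLS at the same lambda."""
        tree, traits, rng = self._bm_world(15, 2)
        totals = pd.Series(rng.normal(100, 10, 15), index=tree.tip_labels)
        lam = 0.6
        fit = h.fit_pgls_lambda(totals, traits, tree,
                                terms=("plunge", "ln_mass"), lam=lam)
        C = tree.phylo_covariance(tree.tip_labels)
        V = lam * C + (1 - lam) * np.diag(np.diag(C))
        X = np.column_stack([
            np.ones(15),
            [traits.plunge[t] for t in tree.tip_labels],
            [traits.ln_mass[t] for t in tree.tip_labels]])
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ totals.to_numpy())
        assert np.allclose(fit.coef["estimate"].to_numpy(), beta, atol=1e-8)

    def test_lambda_recovery_brownian_vs_star(self):
        """Brownian data on a structured tree should give high lambda-hat;
        on a star tree (no shared history, lambda unidentifiable) the flat
        profile must resolve to the lower boundary."""
        hi = lo = 0
        reps = 20
        for r in range(reps):
            tree, traits, rng = self._bm_world(50, 100 + r)
            bm = tree.simulate_bm(400.0, rng)
            totals = pd.Series({t: 300 + bm[t] for t in tree.tip_labels})
            fit = h.fit_pgls_lambda(totals, traits, tree,
                                    terms=("plunge", "ln_mass"))
            hi += fit.lam >= 0.8
            star, straits, srng = self._bm_world(50, 200 + r, lam_star=True)
            iid = pd.Series(srng.normal(300, 20, 50),
                            index=star.tip_labels)
            sfit = h.fit_pgls_lambda(iid, straits, star,
                                     terms=("plunge", "ln_mass"))
            lo += sfit.lam <= 0.2
        assert hi >= 0.9 * reps and lo >= 0.9 * reps


class TestStepwise:
    def test_hierarchy_enforced_and_deterministic(self):
        tree, traits, rng = TestPgls()._bm_world(40, 7)
        y = pd.Series(
            [100 + 20 * traits.ln_mass[t] + rng.normal(0, 5)
             for t in tree.tip_labels], index=tree.tip_labels)
        sel1 = h.stepwise_aic(y, traits, tree)
        sel2 = h.stepwise_aic(y, traits, tree)
        assert sel1.terms == sel2.terms
        assert "ln_mass" in sel1.terms
        if "ln_mass:island" in sel1.terms:
            assert {"ln_mass", "island"} <= set(sel1.terms)

    def test_mass_only_signal_drops_interaction(self):
        keep = 0
        reps = 20
        for r in range(reps):
            tree, traits, rng = TestPgls()._bm_world(50, 300 + r)
            y = pd.Series(
                [100.0 + 25 * traits.ln_mass[t] + rng.normal(0, 5)
                 for t in tree.tip_labels], index=tree.tip_labels)
            sel = h.stepwise_aic(y, traits, tree)
            ok = "ln_mass" in sel.terms and "ln_mass:island" not in sel.terms
            keep += ok
        assert keep >= 0.8 * reps

    def test_full_model_kept_when_minimal(self):
        tree, traits, rng = TestPgls()._bm_world(60, 9)
        y = pd.Series(
            [50.0 + 30 * traits.plunge[t] + 10 * traits.ln_mass[t]
             + 25 * traits.island[t]
             + 15 * traits.ln_mass[t] * traits.island[t]
             + rng.normal(0, 2) for t in tree.tip_labels],
            index=tree.tip_labels)
        sel = h.stepwise_aic(y, traits, tree)
        assert set(sel.terms) == {"plunge", "ln_mass", "island",
                                  "ln_mass:island"}


class TestOverlap:
    def test_identical_rows_share_one_letter(self, sim_world):
        _, tree, traits, _ = sim_world
        genes = [f"g{i}" for i in range(40)]
        ind = pd.DataFrame(1, index=tree.tip_labels, columns=genes)
        tab = h.PSGTable(ind)

        def grp(tm, a, b):
            return "focal" if tm.plunge[a] and tm.plunge[b] else "other"

        out = h.overlap_comparison(tab, traits, tree, grp, seed=0)
        assert out.group_stats["letter"].nunique() == 1
        assert (out.group_stats["mean"] == 40).all()

    def test_separated_groups_get_distinct_letters(self, sim_world):
        """Overlap means 5 vs 35 of 40 genes must separate."""
        _, tree, traits, _ = sim_world
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        core = genes[:35]
        rows = {}
        for t in tree.tip_labels:
            if traits.plunge[t]:
                rows[t] = {g: 1 if g in core else 0 for g in genes}
            else:
                mine = set(rng.choice(genes, 5, replace=False))
                rows[t] = {g: int(g in mine) for g in genes}
        tab = h.PSGTable(pd.DataFrame.from_dict(rows, orient="index"))

        def grp(tm, a, b):
            return "focal" if tm.plunge[a] and tm.plunge[b] else "other"

        out = h.overlap_comparison(tab, traits, tree, grp, seed=1)
        s = out.group_stats.set_index("group")
        assert s.loc["focal", "mean"] > s.loc["other", "mean"]
        assert s.loc["focal", "letter"] != s.loc["other", "letter"]

    def test_overlap_counts_match_set_oracle(self, sim_world):
        _, tree, traits, _ = sim_world
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        ind = pd.DataFrame(rng.integers(0, 2, (tree.n_tips, 30)),
                           index=tree.tip_labels, columns=genes)
        tab = h.PSGTable(ind)
        for a, b in h.enumerate_pairs(tree.tip_labels)[:10]:
            expect = len(tab.genes_of(a) & tab.genes_of(b))
            assert tab.overlap(a, b) == expect
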