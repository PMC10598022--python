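"""Positive-selection gene-set logic and downstream comparative models.

Combines externally computed per-gene/per-branch test scores (branch-site
foreground test, relaxed-selection confirmation, per-branch adaptive test,
residue-convergence posterior) into an adaptively-convergent gene set;
tabulates positively selected gene (PSG) counts per species; fits PGLS
models of counts on covariates with Pagel's λ profiled by maximum
likelihood; compares pairwise PSG overlap between groups with the pairwise
mixed model; and tests term enrichment by exact hypergeometric tails with
Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import GeneTestResult
from .tree import Phylogeny, TraitMap, enumerate_pairs
from . import pairlmm

__all__ = [
    "EnrichmentResult",
    "PGLSFit",
    "PSGTable",
    "adaptive_convergent_set",
    "bh_fdr",
    "fit_pgls_lambda",
    "hypergeom_enrichment",
    "overlap_comparison",
    "psg_counts",
    "stepwise_aic",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, original order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------ set intersection
@dataclass
class ConvergentSetReport:
    """Intersection of the four selection/convergence evidence sets."""

    branch_site_set: set
    confirmed_set: set          # branch-site ∩ relaxed-selection confirmation
    multi_lineage_set: set      # per-branch adaptive, ≥ k focal lineages
    residue_set: set            # residue-convergence posterior ≥ threshold
    final_set: set
    euler_counts: dict
    confirmation_pct: float     # 100·|BS ∩ RELAX| / |BS|, one decimal


def _qvalues_by_test(results):
    """Fill in missing q-values by BH within each test's score family."""
    out = {}
    by_test: dict = {}
    for r in results:
        by_test.setdefault(r.test_name, []).append(r)
    for name, recs in by_test.items():
        if all(r.qvalue is not None for r in recs):
            qs = [r.qvalue for r in recs]
        elif name == "residue_convergence":
            qs = [r.score for r in recs]  # posterior; no FDR step
        else:
            qs = bh_fdr([r.score for r in recs])
        for r, q in zip(recs, qs):
            out[(r.test_name, r.gene_id, r.branch_id)] = float(q)
    return out


def adaptive_convergent_set(results, focal_branches,
                            fdr_threshold: float = 0.05,
                            residue_posterior: float = 0.8,
                            min_lineages: int = 2) -> ConvergentSetReport:
    """Intersect the four evidence streams into the final convergent set.

    * set 1 — genes significant in the branch-site foreground test
      (q < threshold) *and* confirmed by the relaxed-selection test;
    * set 2 — genes whose per-branch adaptive test is significant on at
      least ``min_lineages`` focal branches;
    * set 3 — genes with residue-convergence posterior ≥ threshold.

    The final set is the triple intersection.  The report also carries all
    pairwise/overall intersection counts and the confirmation percentage
    100·|BS ∩ RELAX|/|BS| rounded to one decimal.
    """
    present = {r.test_name for r in results}
    for need in ("branch_site", "relax", "branch_adaptive",
                 "residue_convergence"):
        if need not in present:
            raise ValueError(f"missing required test: {need!r}")
    q = _qvalues_by_test(results)
    bs = {r.gene_id for r in results if r.test_name == "branch_site"
          and q[(r.test_name, r.gene_id, r.branch_id)] < fdr_threshold}
    relax = {r.gene_id for r in results if r.test_name == "relax"
             and q[(r.test_name, r.gene_id, r.branch_id)] < fdr_threshold}
    focal = set(focal_branches)
    hits: dict = {}
    for r in results:
        if (r.test_name == "branch_adaptive" and r.branch_id in focal
                and q[(r.test_name, r.gene_id, r.branch_id)] < fdr_threshold):
            hits.setdefault(r.gene_id, set()).add(r.branch_id)
    multi = {g for g, br in hits.items() if len(br) >= min_lineages}
    residue = {r.gene_id for r in results
               if r.test_name == "residue_convergence"
               and r.score >= residue_posterior}
    confirmed = bs & relax
    final = confirmed & multi & residue
    sets = {"confirmed": confirmed, "multi_lineage": multi,
            "residue": residue}
    euler = {}
    for k in (1, 2, 3):
        for combo in itertools.combinations(sorted(sets), k):
            inter = set.intersection(*(sets[c] for c in combo))
            euler["&".join(combo)] = len(inter)
    pct = round(100.0 * len(confirmed) / len(bs), 1) if bs else float("nan")
    return ConvergentSetReport(
        branch_site_set=bs, confirmed_set=confirmed, multi_lineage_set=multi,
        residue_set=residue, final_set=final, euler_counts=euler,
        confirmation_pct=pct,
    )


# ---------------------------------------------------------------- enrichment
@dataclass
class EnrichmentResult:
    term_id: str
    k: int          # overlap with target
    n: int          # target size
    K: int          # term size in background
    N: int          # background size
    fold: float
    p: float
    q: float = float("nan")

    def __post_init__(self):
        if self.k > min(self.n, self.K):
            raise ValueError("overlap exceeds set sizes")


def hypergeom_enrichment(target_genes, term_map: dict, background) -> list:
    """Upper-tail hypergeometric enrichment against a custom background.

    For each term with k ≥ 1 target members, p = P(X ≥ k) for X
    hypergeometric(N, K, n); q-values by BH over the tested terms.
    """
    target = set(target_genes)
    bg = set(background)
    outside = target - bg
    if outside:
        raise ValueError(f"target genes outside background: {sorted(outside)[:5]}")
    n, N = len(target), len(bg)
    out = []
    for term in sorted(term_map):
        members = set(term_map[term]) & bg
        K = len(members)
        k = len(members & target)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        out.append(EnrichmentResult(term, k, n, K, N, fold, min(p, 1.0)))
    if out:
        qs = bh_fdr([r.p for r in out])
        for r, qv in zip(out, qs):
            r.q = float(qv)
    return out


# ---------------------------------------------------------------- PSG counts
@dataclass
class PSGTable:
    """Species/branch × gene binary indicator of positive selection."""

    indicator: pd.DataFrame  # index species, columns genes, values 0/1

    def __post_init__(self):
        vals = self.indicator.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("indicator entries must be 0/1")

    @property
    def totals(self) -> pd.Series:
        return self.indicator.sum(axis=1)

    def genes_of(self, species: str) -> set:
        row = self.indicator.loc[species]
        return set(row.index[row == 1])

    def overlap(self, a: str, b: str) -> int:
        return int((self.indicator.loc[a] & self.indicator.loc[b]).sum())


def psg_counts(per_branch_results, q_threshold: float = 0.05) -> PSGTable:
    """FDR-threshold per-branch adaptive results into a PSG table."""
    recs = [r for r in per_branch_results if r.test_name == "branch_adaptive"]
    if not recs:
        return PSGTable(pd.DataFrame(dtype=int))
    q = _qvalues_by_test(recs)
    species = sorted({r.branch_id for r in recs})
    genes = sorted({r.gene_id for r in recs})
    ind = pd.DataFrame(0, index=species, columns=genes, dtype=int)
    for r in recs:
        if q[(r.test_name, r.gene_id, r.branch_id)] < q_threshold:
            ind.loc[r.branch_id, r.gene_id] = 1
    return PSGTable(ind)


# ---------------------------------------------------------------------- PGLS
@dataclass
class PGLSFit:
    """PGLS fit with Pagel's λ profiled by maximum likelihood."""

    coef: pd.DataFrame      # term, estimate, se, t, p
    lam: float
    sigma2: float
    adj_r2: float
    aic: float
    loglik: float
    terms: tuple

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")


def _pgls_design(totals: pd.Series, trait_map: TraitMap, terms):
    species = list(totals.index)
    cols = {"intercept": np.ones(len(species))}
    base = {
        "plunge": np.array([trait_map.plunge[s] for s in species], float),
        "island": np.array([trait_map.island[s] for s in species], float),
        "ln_mass": np.array([trait_map.ln_mass[s] for s in species], float),
    }
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols[t] = base[a] * base[b]
        else:
            cols[t] = base[t]
    X = np.column_stack(list(cols.values()))
    return X, ["intercept"] + list(terms), np.asarray(totals, float)


def _gls_ml(y, X, C, lam):
    n, p = X.shape
    V = lam * C + (1 - lam) * np.diag(np.diag(C))
    cF = np.linalg.cholesky(V)
    logdetV = 2 * np.log(np.diag(cF)).sum()
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    rss = float(r @ np.linalg.solve(V, r))
    sigma2_ml = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdetV + n)
    return ll, beta, XtViX, rss, V


def fit_pgls_lambda(totals: pd.Series, trait_map: TraitMap, tree: Phylogeny,
                    terms=("plunge", "ln_mass", "island", "ln_mass:island"),
                    lam: float | None = None) -> PGLSFit:
    """Phylogenetic GLS of per-species counts on trait covariates.

    The residual covariance is Pagel's λ-transform of the tip covariance
    (off-diagonals scaled by λ); λ is estimated by profile ML on [0, 1]
    with a bounded golden-section search (tolerance 1e-6) unless fixed.
    """
    if len(totals) < 8:
        raise ValueError("need totals for at least 8 species")
    X, names, y = _pgls_design(totals, trait_map, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("non-identifiable design (collinear terms)")
    C = tree.phylo_covariance(list(totals.index))
    if lam is None:
        res = optimize.minimize_scalar(
            lambda l: -_gls_ml(y, X, C, l)[0],
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6})
        lam_hat = float(res.x)
        # boundaries can beat the interior optimum; on a flat profile
        # (lambda unidentifiable, e.g. a star tree) prefer the smaller value
        cand = [(lam_hat, _gls_ml(y, X, C, lam_hat)[0]),
                (0.0, _gls_ml(y, X, C, 0.0)[0]),
                (1.0, _gls_ml(y, X, C, 1.0)[0])]
        best_ll = max(ll for _, ll in cand)
        lam_hat = min(l for l, ll in cand if ll >= best_ll - 1e-9)
    else:
        lam_hat = float(lam)
    ll, beta, XtViX, rss, V = _gls_ml(y, X, C, lam_hat)
    n, p = X.shape
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), n - p)
    # GLS R^2 against the intercept-only model under the same covariance
    X0 = np.ones((n, 1))
    _, _, _, rss0, _ = _gls_ml(y, X0, C, lam_hat)
    r2 = 1.0 - rss / rss0 if rss0 > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else float("nan")
    k = p + 2  # sigma2 and lambda
    aic = -2 * ll + 2 * k
    coef = pd.DataFrame({"term": names, "estimate": beta, "se": se,
                         "t": tstat, "p": pvals})
    return PGLSFit(coef=coef, lam=lam_hat, sigma2=float(sigma2),
                   adj_r2=float(adj), aic=float(aic), loglik=float(ll),
                   terms=tuple(terms))


def _hierarchy_ok(terms) -> bool:
    ts = set(terms)
    for t in ts:
        if ":" in t and not set(t.split(":")) <= ts:
            return False
    return True


def stepwise_aic(totals: pd.Series, trait_map: TraitMap, tree: Phylogeny,
                 full_terms=("plunge", "ln_mass", "island",
                             "ln_mass:island")) -> PGLSFit:
    """Bi-directional greedy AIC selection over the PGLS fixed terms.

    Interactions require both main effects; ties resolve by term order, so
    the procedure is deterministic.  Stops when no single add or drop
    lowers the AIC.
    """
    full = tuple(full_terms)
    current = full
    fit = fit_pgls_lambda(totals, trait_map, tree, current)
    while True:
        moves = []
        for t in current:  # drops
            cand = tuple(x for x in current if x != t)
            if _hierarchy_ok(cand):
                moves.append(cand)
        for t in full:  # adds
            if t not in current:
                cand = current + (t,)
                if _hierarchy_ok(cand):
                    moves.append(cand)
        best = None
        for cand in moves:
            try:
                f = fit_pgls_lambda(totals, trait_map, tree, cand)
            except ValueError:
                continue
            if f.aic < fit.aic - 1e-9 and (best is None or f.aic < best.aic):
                best = f
        if best is None:
            return fit
        fit = best
        current = fit.terms


# ------------------------------------------------------------------- overlap
@dataclass
class OverlapComparison:
    """Group means of pairwise PSG overlap with compact letter display."""

    group_stats: pd.DataFrame   # group, n_pairs, mean, lsmean, letter
    contrasts: pd.DataFrame     # group_a, group_b, estimate, se, p
    fit: "pairlmm.LMMFit | None"
    pair_table: pd.DataFrame


def overlap_comparison(psg_table: PSGTable, trait_map: TraitMap,
                       tree: Phylogeny, groups, seed=None
                       ) -> OverlapComparison:
    """Compare pairwise PSG-overlap counts between groups of species pairs.

    ``groups`` assigns each unordered pair a label: either a callable
    ``(trait_map, tip_a, tip_b) -> label`` or a dict keyed by frozensets.
    The response |PSG_a ∩ PSG_b| is fit with group fixed effects and the
    pairwise mixed-model random effects (both lineages plus the MRCA node
    with phylogenetic covariance); groups are compared by Wald contrasts at
    α = 0.05 and lettered greedily by descending mean.
    """
    species = list(psg_table.indicator.index)
    rows = []
    for a, b in enumerate_pairs(species):
        if callable(groups):
            g = groups(trait_map, a, b)
        else:
            g = groups.get(frozenset((a, b)))
        if g is None:
            continue
        rows.append(dict(tip_a=a, tip_b=b, group=str(g),
                         mrca_id=tree.mrca(a, b),
                         overlap=psg_table.overlap(a, b)))
    df = pd.DataFrame(rows)
    if df.empty or df["group"].nunique() < 2:
        raise ValueError("need at least two pair groups")
    sizes = df.groupby("group").size()
    small = sizes[sizes < 3]
    if len(small):
        raise ValueError(f"groups with < 3 pairs: {list(small.index)}")
    levels = sorted(df["group"].unique())
    y = df["overlap"].to_numpy(float)
    X = np.column_stack([(df["group"] == g).to_numpy(float) for g in levels])
    lin_levels = sorted(set(df["tip_a"]) | set(df["tip_b"]))
    Za, _ = pairlmm._indicator(df["tip_a"].tolist(), lin_levels)
    Zb, _ = pairlmm._indicator(df["tip_b"].tolist(), lin_levels)
    Zm, mlev = pairlmm._indicator(df["mrca_id"].tolist())
    K = pairlmm._node_covariance(tree, mlev)
    Zl = Za + Zb
    comps = [("lineage", Zl @ Zl.T), ("mrca", Zm @ K @ Zm.T)]
    fixed, vc, _ = pairlmm._fit_reml(y, X, comps, names=levels)
    means = fixed["estimate"].to_numpy()
    # covariance of the group means under the fitted V
    n = len(y)
    V = vc["residual"] * np.eye(n)
    for (nm, G) in comps:
        V += vc[nm] * G
    covb = np.linalg.inv(X.T @ np.linalg.solve(V, X))
    dfree = n - len(levels)
    con = []
    sig = {}
    for i, j in itertools.combinations(range(len(levels)), 2):
        est = means[i] - means[j]
        se = float(np.sqrt(covb[i, i] + covb[j, j] - 2 * covb[i, j]))
        p = float(2 * stats.t.sf(abs(est) / se, dfree)) if se > 0 else 0.0
        con.append(dict(group_a=levels[i], group_b=levels[j],
                        estimate=est, se=se, p=p))
        sig[frozenset((levels[i], levels[j]))] = p < 0.05
    # greedy compact letters, descending mean
    order = sorted(range(len(levels)), key=lambda i: -means[i])
    letter_sets: list = []
    for i in order:
        placed = False
        for s in letter_sets:
            if all(not sig[frozenset((levels[i], levels[j]))] for j in s):
                s.add(i)
                placed = True
        if not placed:
            letter_sets.append({i})
    letters = {i: "" for i in range(len(levels))}
    for li, s in enumerate(letter_sets):
        ch = chr(ord("a") + li)
        for i in s:
            letters[i] += ch
    stats_df = pd.DataFrame({
        "group": levels,
        "n_pairs": [int(sizes[g]) for g in levels],
        "mean": [float(df.loc[df["group"] == g, "overlap"].mean())
                 for g in levels],
        "lsmean": means,
        "letter": ["".join(sorted(letters[i])) for i in range(len(levels))],
    })
    contrasts = pd.DataFrame(con)
    return OverlapComparison(group_stats=stats_df, contrasts=contrasts,
                             fit=None, pair_table=df)
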