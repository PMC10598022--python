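"""Genome-wide convergence regression on lineage pairs.

The response (convergent substitution count per pair, total or per gene) is
modeled with fixed effects [intercept, divergent count D, divergence time,
plunge-focal, island-focal, D×time] and three random intercepts: the two
lineages of the pair (exchangeable after role shuffling) and the pair's
MRCA node, the latter with covariance proportional to the phylogenetic
shared-path-length matrix of the internal nodes involved.  Default
estimation is REML with profiled variance components; a Gibbs-sampler mode
with inverse-gamma variance priors reports posterior means, credible
intervals and pMCMC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tree import Phylogeny

__all__ = [
    "FIXED_EFFECTS",
    "LMMFit",
    "effect_size_eta2",
    "fit_pair_lmm",
    "shuffle_pair_roles",
]

FIXED_EFFECTS = ("intercept", "divergent", "time", "plunge", "island",
                 "divergent_x_time")


def shuffle_pair_roles(pair_records: pd.DataFrame, seed) -> pd.DataFrame:
    """Randomize which lineage of each pair is 'a' and which is 'b'.

    A fair, seed-reproducible coin per record; every other column is
    role-symmetric and left untouched.
    """
    if len(pair_records) == 0:
        raise ValueError("empty pair table")
    rng = np.random.default_rng(seed)
    out = pair_records.copy().reset_index(drop=True)
    flip = rng.random(len(out)) < 0.5
    a = out["tip_a"].to_numpy().copy()
    b = out["tip_b"].to_numpy().copy()
    out["tip_a"] = np.where(flip, b, a)
    out["tip_b"] = np.where(flip, a, b)
    return out


def _design(pair_records: pd.DataFrame):
    D = pair_records["D"].to_numpy(float)
    t = pair_records["divergence_time"].to_numpy(float)
    X = np.column_stack([
        np.ones(len(pair_records)), D, t,
        pair_records["plunge_focal"].to_numpy(float),
        pair_records["island_focal"].to_numpy(float),
        D * t,
    ])
    return X


def _check_design(X: np.ndarray):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full complement
        bad = []
        for j in range(X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(FIXED_EFFECTS[j])
        raise ValueError(f"singular design; collinear columns: {bad}")


def _indicator(values, levels=None):
    levels = sorted(set(values)) if levels is None else list(levels)
    idx = {v: i for i, v in enumerate(levels)}
    Z = np.zeros((len(values), len(levels)))
    for r, v in enumerate(values):
        Z[r, idx[v]] = 1.0
    return Z, levels


@dataclass
class LMMFit:
    """Pairwise mixed-model fit summary.

    ``fixed`` has one row per effect: estimate, ci_low, ci_high, p.
    ``varcomp`` maps lineage_a / lineage_b / mrca / residual to variances.
    ``signal`` is σ²_mrca over the sum of all components (latent-scale
    variant adds π²/3 to the denominator); ``eta2`` is the OLS effect size
    of the plunge term.
    """

    fixed: pd.DataFrame
    varcomp: dict
    signal: float
    eta2: float
    method: str
    reml_loglik: float | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.varcomp.values()):
            raise ValueError("variance components must be nonnegative")
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("phylogenetic signal must lie in [0, 1]")


def _phylo_signal(vc: dict, latent_scale: bool) -> float:
    tot = sum(vc.values()) + (np.pi ** 2 / 3 if latent_scale else 0.0)
    return vc["mrca"] / tot if tot > 0 else 0.0


def _node_covariance(tree: Phylogeny, mrca_levels):
    K = tree.phylo_covariance(mrca_levels)
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("node covariance is not positive semidefinite")
    # normalize so sigma2_mrca is on the same scale as the other components
    sc = np.mean(np.diag(K))
    if sc > 0:
        K = K / sc
    return K + 1e-8 * np.eye(len(K))  # root-adjacent nodes have ~0 depth


def fit_pair_lmm(pair_records: pd.DataFrame, tree: Phylogeny,
                 method: str = "reml", latent_scale_signal: bool = False,
                 iterations: int = 1_000_000, burnin_frac: float = 0.25,
                 seed: int | None = None,
                 fixed_varcomp: dict | None = None,
                 lineage_effect: str = "shared") -> LMMFit:
    """Fit the pairwise convergence mixed model.

    ``method='reml'`` (default) profiles the variance components by
    restricted maximum likelihood; ``method='mcmc'`` runs a Gibbs sampler
    (``iterations`` draws, first ``burnin_frac`` discarded) with weakly
    informative inverse-gamma variance priors, reporting posterior means,
    95% credible intervals and two-sided pMCMC.

    ``lineage_effect='shared'`` (default) gives every lineage one random
    intercept that enters through whichever role it occupies, which makes
    the fit exactly invariant to role shuffling; ``'separate'`` estimates
    independent role-a and role-b effect vectors (the literal two-term
    formulation, only approximately shuffle-invariant).  ``fixed_varcomp``
    pins any of lineage_a / lineage_b / mrca / residual instead of
    estimating it (all non-residual terms at 0 reduces the fit to
    ordinary least squares).
    """
    if len(pair_records) < 20:
        raise ValueError("need at least 20 pair records")
    if lineage_effect not in ("shared", "separate"):
        raise ValueError("lineage_effect must be 'shared' or 'separate'")
    y = pair_records["response"].to_numpy(float)
    X = _design(pair_records)
    _check_design(X)
    lineage_levels = sorted(set(pair_records["tip_a"])
                            | set(pair_records["tip_b"]))
    Za, _ = _indicator(pair_records["tip_a"].tolist(), lineage_levels)
    Zb, _ = _indicator(pair_records["tip_b"].tolist(), lineage_levels)
    Zm, mrca_levels = _indicator(pair_records["mrca_id"].tolist())
    K = _node_covariance(tree, mrca_levels)
    fixed_varcomp = dict(fixed_varcomp or {})
    if lineage_effect == "shared":
        Zl = Za + Zb
        comps = [("lineage", Zl @ Zl.T), ("mrca", Zm @ K @ Zm.T)]
        pins = {}
        la, lb = (fixed_varcomp.get("lineage_a"),
                  fixed_varcomp.get("lineage_b"))
        if la is not None or lb is not None:
            if la is not None and lb is not None and la != lb:
                raise ValueError("shared lineage effect: lineage_a and "
                                 "lineage_b pins must agree")
            pins["lineage"] = la if la is not None else lb
        for k in ("mrca", "residual"):
            if k in fixed_varcomp:
                pins[k] = fixed_varcomp[k]
    else:
        comps = [("lineage_a", Za @ Za.T), ("lineage_b", Zb @ Zb.T),
                 ("mrca", Zm @ K @ Zm.T)]
        pins = fixed_varcomp

    if method == "reml":
        fixed, vc, ll = _fit_reml(y, X, comps, fixed_varcomp=pins)
    elif method == "mcmc":
        fixed, vc, ll = _fit_gibbs(y, X, Za, Zb, Zm, K, iterations,
                                   burnin_frac, seed, lineage_effect)
    else:
        raise ValueError("method must be 'reml' or 'mcmc'")
    if "lineage" in vc:  # report the shared component under both roles
        vc["lineage_a"] = vc["lineage_b"] = vc.pop("lineage")
    signal = _phylo_signal(vc, latent_scale_signal)
    eta2 = effect_size_eta2(pair_records)
    return LMMFit(fixed=fixed, varcomp=vc, signal=signal, eta2=eta2,
                  method=method, reml_loglik=ll)


def _reml_neg2(logv: np.ndarray, y, X, Gs):
    n, p = X.shape
    V = np.exp(logv[-1]) * np.eye(n)
    for lv, G in zip(logv[:-1], Gs):
        V += np.exp(lv) * G
    try:
        cF = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    logdetV = 2.0 * np.log(np.diag(cF)).sum()
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    quad = resid @ np.linalg.solve(V, resid)
    return logdetV + logdetX + quad


def _fit_reml(y, X, comps, names=None, fixed_varcomp=None):
    """REML over components ``comps`` = [(name, G), ...] plus a residual.

    Variances are profiled on the log scale with L-BFGS-B from two starts;
    ``fixed_varcomp`` pins components (by name, 'residual' included)."""
    n, p = X.shape
    names = list(names) if names is not None else list(FIXED_EFFECTS[:p])
    comp_names = [c[0] for c in comps] + ["residual"]
    Gs = [c[1] for c in comps]
    nc = len(comp_names)
    vy = np.var(y)
    vy = vy if vy > 0 else 1.0
    pinned = {comp_names.index(k): float(v)
              for k, v in (fixed_varcomp or {}).items()}
    free = [i for i in range(nc) if i not in pinned]

    def expand(logv_free):
        full = np.empty(nc)
        for j, i in enumerate(free):
            full[i] = logv_free[j]
        for i, v in pinned.items():
            full[i] = np.log(v) if v > 0 else -700.0
        return full

    def obj(logv_free):
        return _reml_neg2(expand(logv_free), y, X, Gs)

    x0_full = np.log(np.full(nc, 0.3 * vy))
    x0_full[-1] = np.log(0.7 * vy)
    bounds = [(np.log(vy) - 18, np.log(vy) + 6)] * len(free)
    best = None
    if free:
        for shift in (0.0, 1.5):
            res = optimize.minimize(
                obj, x0_full[free] + shift, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        full = expand(best.x)
        fun = best.fun
    else:
        full = expand(np.empty(0))
        fun = obj(np.empty(0))
    v = np.exp(full)
    V = v[-1] * np.eye(n)
    for vi, G in zip(v[:-1], Gs):
        V += vi * G
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ np.linalg.solve(V, y))
    cov = np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    df = n - p
    tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    tq = stats.t.ppf(0.975, df)
    fixed = pd.DataFrame({
        "term": names, "estimate": beta, "se": se,
        "ci_low": beta - tq * se, "ci_high": beta + tq * se, "p": pvals,
    })
    vc = dict(zip(comp_names, v))
    for k, val in (fixed_varcomp or {}).items():
        vc[k] = val  # report pinned components exactly
    return fixed, vc, -0.5 * fun


def _fit_gibbs(y, X, Za, Zb, Zm, K, iterations, burnin_frac, seed,
               lineage_effect="shared"):
    rng = np.random.default_rng(seed)
    n, p = X.shape
    Ki = np.linalg.inv(K)
    XtX = X.T @ X
    shared = lineage_effect == "shared"
    if shared:
        Zl = Za + Zb
        nl = Zl.shape[1]
        ZltZl = Zl.T @ Zl  # lineages co-occur within a pair: not diagonal
    else:
        na, nb = Za.shape[1], Zb.shape[1]
        ca, cb = Za.sum(axis=0), Zb.sum(axis=0)
        ia, ib = np.argmax(Za, axis=1), np.argmax(Zb, axis=1)
        ua, ub = np.zeros(na), np.zeros(nb)
    nm = Zm.shape[1]
    cm_d = Zm.sum(axis=0)
    im = np.argmax(Zm, axis=1)
    a0, b0 = 0.001, 0.001  # weakly informative inverse-gamma prior
    vy = max(np.var(y), 1e-8)
    se2, sa2, sb2, sm2 = vy * 0.7, vy * 0.1, vy * 0.1, vy * 0.1
    sl2 = vy * 0.1
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    ul = np.zeros(Za.shape[1])
    um = np.zeros(nm)
    keep_from = int(iterations * burnin_frac)
    betas = np.empty((iterations - keep_from, p))
    vcs = np.empty((iterations - keep_from, 4))
    for it in range(iterations):
        lin = Zl @ ul if shared else ua[ia] + ub[ib]
        r_beta = y - lin - um[im]
        prec = XtX / se2
        mean = np.linalg.solve(prec, X.T @ r_beta / se2)
        beta = mean + np.linalg.solve(np.linalg.cholesky(prec).T,
                                      rng.standard_normal(p))
        xb = X @ beta
        if shared:
            r = y - xb - um[im]
            prec_l = ZltZl / se2 + np.eye(nl) / sl2
            cf = np.linalg.cholesky(prec_l)
            mu = np.linalg.solve(prec_l, Zl.T @ r / se2)
            ul = mu + np.linalg.solve(cf.T, rng.standard_normal(nl))
            lin = Zl @ ul
        else:
            # separate role effects: diagonal conditional precisions
            r = y - xb - ub[ib] - um[im]
            d = ca / se2 + 1.0 / sa2
            mu = (np.bincount(ia, weights=r, minlength=na) / se2) / d
            ua = mu + rng.standard_normal(na) / np.sqrt(d)
            r = y - xb - ua[ia] - um[im]
            d = cb / se2 + 1.0 / sb2
            mu = (np.bincount(ib, weights=r, minlength=nb) / se2) / d
            ub = mu + rng.standard_normal(nb) / np.sqrt(d)
            lin = ua[ia] + ub[ib]
        r = y - xb - lin
        prec_m = np.diag(cm_d / se2) + Ki / sm2
        cf = np.linalg.cholesky(prec_m)
        rhs = np.bincount(im, weights=r, minlength=nm) / se2
        mu = np.linalg.solve(prec_m, rhs)
        um = mu + np.linalg.solve(cf.T, rng.standard_normal(nm))
        resid = y - xb - lin - um[im]
        se2 = 1.0 / rng.gamma(a0 + n / 2, 1.0 / (b0 + resid @ resid / 2))
        if shared:
            sl2 = 1.0 / rng.gamma(a0 + nl / 2, 1.0 / (b0 + ul @ ul / 2))
            sa2 = sb2 = sl2
        else:
            sa2 = 1.0 / rng.gamma(a0 + na / 2, 1.0 / (b0 + ua @ ua / 2))
            sb2 = 1.0 / rng.gamma(a0 + nb / 2, 1.0 / (b0 + ub @ ub / 2))
        sm2 = 1.0 / rng.gamma(a0 + nm / 2, 1.0 / (b0 + um @ Ki @ um / 2))
        if it >= keep_from:
            betas[it - keep_from] = beta
            vcs[it - keep_from] = (sa2, sb2, sm2, se2)
    est = betas.mean(axis=0)
    lo = np.quantile(betas, 0.025, axis=0)
    hi = np.quantile(betas, 0.975, axis=0)
    pos = (betas > 0).mean(axis=0)
    pmcmc = 2 * np.minimum(pos, 1 - pos)
    pmcmc = np.clip(pmcmc, 1.0 / len(betas), 1.0)
    fixed = pd.DataFrame({
        "term": FIXED_EFFECTS, "estimate": est,
        "se": betas.std(axis=0, ddof=1),
        "ci_low": lo, "ci_high": hi, "p": pmcmc,
    })
    vm = vcs.mean(axis=0)
    vc = {"lineage_a": vm[0], "lineage_b": vm[1], "mrca": vm[2],
          "residual": vm[3]}
    return fixed, vc, None


def effect_size_eta2(pair_records: pd.DataFrame) -> float:
    """η² of the plunge term from an ordinary least squares fit.

    Sequential sums of squares with plunge entered after divergent count,
    time and island: η² = SS(plunge) / SS(total).
    """
    y = pair_records["response"].to_numpy(float)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("zero total sum of squares")
    D = pair_records["D"].to_numpy(float)
    t = pair_records["divergence_time"].to_numpy(float)
    base = np.column_stack([np.ones_like(y), D, t, D * t,
                            pair_records["island_focal"].to_numpy(float)])
    full = np.column_stack([base,
                            pair_records["plunge_focal"].to_numpy(float)])

    def rss(M):
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    ss_plunge = rss(base) - rss(full)
    return float(ss_plunge / ss_tot)
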