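"""Convergent shifts in relative rates of molecular evolution.

Per-gene branch lengths are regressed (after a square-root transform) on
the master-tree branch lengths over shared branches; the centered
residuals are relative evolutionary rates (RERs).  Association of RERs
with a binary foreground set uses a tie-corrected Wilcoxon rank-sum
standardized score, and empirical significance comes from permulations:
phylogenetically simulated reassignments of the foreground tips, each
mapped to its implied foreground branch set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import bh_fdr
from .tree import Phylogeny, permulate_binary

__all__ = [
    "compute_rers",
    "foreground_association",
    "foreground_branches",
    "permulation_pvalues",
]

logger = logging.getLogger(__name__)


def _clades(tree: Phylogeny) -> dict:
    """Map each non-root node id to the frozenset of tip labels below it."""
    below: dict = {}
    out = {}
    for i in range(tree.n_nodes):
        if tree.is_tip(i):
            below[i] = frozenset([tree.labels[i]])
        else:
            below[i] = frozenset().union(*(below[c] for c in tree.children[i]))
        if tree.parent[i] != -1:
            out[tree.labels[i]] = below[i]
    return out


def compute_rers(gene_trees: dict, master_tree: Phylogeny,
                 min_branch_length: float = 1e-6) -> pd.DataFrame:
    """Branch × gene matrix of relative evolutionary rates.

    Branches are matched between gene and master trees by the tip clade
    they subtend.  For each gene the square-root branch lengths are
    regressed on the master's; the RER is the centered residual.  Genes
    sharing fewer than 5 usable branches are skipped.  Missing entries
    are NaN.
    """
    master_clades = _clades(master_tree)
    branch_ids = sorted(master_clades, key=lambda b: master_tree.index(b))
    usable = [b for b in branch_ids
              if master_tree.blen[master_tree.index(b)] >= min_branch_length]
    m_len = {b: master_tree.blen[master_tree.index(b)] for b in usable}
    clade_to_branch = {master_clades[b]: b for b in usable}
    cols = {}
    for gene in sorted(gene_trees):
        gt = gene_trees[gene]
        pairs = []
        for gb, clade in _clades(gt).items():
            mb = clade_to_branch.get(clade)
            if mb is not None:
                pairs.append((mb, gt.blen[gt.index(gb)]))
        if len(pairs) < 5:
            logger.warning("gene %s shares only %d branches with the master "
                           "tree: skipped", gene, len(pairs))
            continue
        mb_ids = [p[0] for p in pairs]
        x = np.sqrt([m_len[b] for b in mb_ids])
        yv = np.sqrt([max(p[1], 0.0) for p in pairs])
        A = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
        resid = yv - A @ beta
        resid = resid - resid.mean()
        col = pd.Series(np.nan, index=branch_ids)
        col[mb_ids] = resid
        cols[gene] = col
    if not cols:
        raise ValueError("no gene shared enough branches with the master tree")
    return pd.DataFrame(cols)


class _RankSumEngine:
    """Per-gene rank precomputation so each foreground assignment costs one
    matrix-vector product.  Ranks (and tie corrections) depend only on the
    RER values, not on which branches are foreground."""

    def __init__(self, rers: pd.DataFrame):
        self.branches = list(rers.index)
        self.genes = list(rers.columns)
        R = rers.to_numpy(float)
        self.notna = np.isfinite(R)
        self.ranks = np.zeros_like(R)
        self.tie = np.zeros(R.shape[1])
        for j in range(R.shape[1]):
            v = R[self.notna[:, j], j]
            self.ranks[self.notna[:, j], j] = stats.rankdata(v)
            _, counts = np.unique(v, return_counts=True)
            self.tie[j] = (counts ** 3 - counts).sum()
        self.ntot = self.notna.sum(axis=0)

    def zscores(self, fg_mask: np.ndarray, return_cc: bool = False):
        """Standardized rank-sum score per gene for a foreground mask over
        branches; NaN where a side has < 2 usable branches.  With
        ``return_cc`` also returns the 0.5-unit continuity correction on
        the z scale (for normal-approximation p-values)."""
        m = fg_mask.astype(float)
        n1 = m @ self.notna
        n2 = self.ntot - n1
        W = m @ self.ranks
        n = self.ntot.astype(float)
        mu = n1 * (n + 1) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            var = n1 * n2 / 12.0 * ((n + 1) - self.tie / (n * (n - 1)))
            z = (W - mu) / np.sqrt(var)
            cc = 0.5 / np.sqrt(var)
        bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(z)
        z[bad] = np.nan
        if return_cc:
            cc[bad] = np.nan
            return z, cc
        return z

    def mask(self, fg_branches) -> np.ndarray:
        fg = set(fg_branches)
        return np.array([b in fg for b in self.branches])


def foreground_association(rers: pd.DataFrame, fg_branches) -> pd.DataFrame:
    """Per-gene foreground-vs-background rank-sum statistic.

    Returns columns gene, stat (tie-corrected standardized score; positive
    = foreground rates elevated) and p_param (normal-approximation
    two-sided p).  Genes with < 2 usable branches on either side are
    skipped.
    """
    eng = _RankSumEngine(rers)
    fgm = eng.mask(fg_branches)
    if fgm.sum() < 2 or (~fgm).sum() < 2:
        raise ValueError("need ≥ 2 foreground and ≥ 2 background branches")
    z, cc = eng.zscores(fgm, return_cc=True)
    keep = np.isfinite(z)
    if (~keep).any():
        for g in np.array(eng.genes)[~keep]:
            logger.warning("gene %s lacks foreground/background data: "
                           "skipped", g)
    p = 2 * stats.norm.sf(np.maximum(np.abs(z[keep]) - cc[keep], 0.0))
    return pd.DataFrame({
        "gene": np.array(eng.genes)[keep],
        "stat": z[keep],
        "p_param": np.minimum(p, 1.0),
    })


def foreground_branches(tree: Phylogeny, foreground_tips) -> set:
    """Branches on the paths from each trait origin to its foreground tips.

    An origin is the stem branch of a maximal foreground-only clade; the
    set contains that branch and every branch inside the clade.
    """
    fg = set(foreground_tips)
    pure = {}
    out = set()
    for i in range(tree.n_nodes):
        if tree.is_tip(i):
            pure[i] = tree.labels[i] in fg
        else:
            pure[i] = all(pure[c] for c in tree.children[i])
        if pure[i] and tree.parent[i] != -1:
            out.add(tree.labels[i])
    return out


def permulation_pvalues(rers: pd.DataFrame, foreground_tips,
                        tree: Phylogeny, n_perm: int = 500,
                        seed=None, side: str = "two",
                        match_origins: bool = False) -> pd.DataFrame:
    """Permulation-based empirical p (and BH q) per gene.

    Each of the ``n_perm`` permulations redraws the foreground tip set
    from a Brownian ranking, derives its implied foreground branches, and
    recomputes every gene's statistic; empirical p is the smoothed tail
    proportion (1 + hits) / (n_perm + 1), two-sided on |stat| by default
    (``side='greater'`` targets accelerations only).
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permulations")
    if side not in ("two", "greater"):
        raise ValueError("side must be 'two' or 'greater'")
    eng = _RankSumEngine(rers)
    z_obs, cc_obs = eng.zscores(
        eng.mask(foreground_branches(tree, foreground_tips)), return_cc=True)
    keep = np.isfinite(z_obs)
    if not keep.any():
        raise ValueError("no gene with usable foreground data")
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(eng.genes))
    valid = np.zeros(len(eng.genes))
    for _ in range(n_perm):
        fg_tips = permulate_binary(tree, foreground_tips, rng,
                                   match_origins=match_origins)
        z = eng.zscores(eng.mask(foreground_branches(tree, fg_tips)))
        ok = np.isfinite(z)
        valid += ok
        if side == "two":
            hits += ok & (np.abs(z) >= np.abs(z_obs) - 1e-12)
        else:
            hits += ok & (z >= z_obs - 1e-12)
    p_emp = (1 + hits) / (1 + np.maximum(valid, 1))
    pp = 2 * stats.norm.sf(np.maximum(np.abs(z_obs[keep]) - cc_obs[keep], 0.0))
    out = pd.DataFrame({
        "gene": np.array(eng.genes)[keep],
        "stat": z_obs[keep],
        "p_param": np.minimum(pp, 1.0),
        "p_perm": p_emp[keep],
    })
    out["q"] = bh_fdr(out["p_perm"].to_numpy())
    return out
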