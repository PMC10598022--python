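"""Comparison of demographic-history curve shapes between species groups.

Ne-versus-time step functions (e.g. PSMC output) are evaluated on a shared
log-spaced time grid, log-transformed, and compared between groups with a
distance-based phylogenetic generalized least squares model: responses and
design are premultiplied by C^{−1/2} (inverse square root of the tip
covariance), the group effect is summarized by the trace of its hypothesis
cross-product, and significance comes from residual randomization under
the reduced (intercept-only) model (RRPP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NeTrajectory
from .tree import Phylogeny

__all__ = ["CurveMatrix", "RRPPResult", "common_grid", "dpgls_rrpp"]


@dataclass
class CurveMatrix:
    """Species × time-grid matrix of log(Ne) values on a shared grid."""

    species: tuple
    grid: np.ndarray        # strictly increasing times, years
    values: np.ndarray      # (n_species, n_grid) natural-log Ne

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.values.shape != (len(self.species), len(self.grid)):
            raise ValueError("values shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve matrix has missing cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.species),
                            columns=self.grid)


@dataclass
class RRPPResult:
    """Permutation test summary for one predictor."""

    ss_effect: float
    f_ratio: float
    n_perm: int
    p_rand: float
    df_effect: int
    df_resid: int

    def __post_init__(self):
        if not self.p_rand >= 1.0 / (self.n_perm + 1):
            raise ValueError("p_rand below its permutation floor")


def common_grid(trajectories, n_points: int = 64) -> CurveMatrix:
    """Evaluate all trajectories on a shared log-spaced time grid.

    The grid spans the intersection of every species' support,
    [max of minima, min of maxima]; a zero lower edge (PSMC's first knot)
    is replaced by the largest first-positive knot so the log spacing is
    defined.  Step functions are evaluated right-continuously and values
    are natural-log transformed.
    """
    trajectories = list(trajectories)
    if len(trajectories) < 2:
        raise ValueError("need at least two trajectories")
    lo = max(t.times[0] for t in trajectories)
    hi = min(t.times[-1] for t in trajectories)
    if lo <= 0:
        pos = []
        for t in trajectories:
            p = t.times[t.times > 0]
            if len(p) == 0:
                raise ValueError(
                    f"trajectory {t.species_label!r} has no positive times")
            pos.append(p[0])
        lo = max(pos)
    if not lo < hi:
        bad = [t.species_label for t in trajectories
               if t.times[0] >= hi or t.times[-1] <= lo]
        raise ValueError(f"no common time support; offending species: {bad}")
    grid = np.geomspace(lo, hi, n_points)
    vals = np.vstack([np.log(t.at(grid)) for t in trajectories])
    return CurveMatrix(tuple(t.species_label for t in trajectories),
                       grid, vals)


def _inv_sqrt(C: np.ndarray, floor_frac: float = 1e-12) -> np.ndarray:
    w, U = np.linalg.eigh(C)
    floor = floor_frac * w.max()
    if w.max() <= 0:
        raise ValueError("covariance matrix is singular")
    w = np.maximum(w, floor)
    return U @ np.diag(1.0 / np.sqrt(w)) @ U.T


def dpgls_rrpp(curves: CurveMatrix, group_labels: dict,
               tree: Phylogeny | None, n_perm: int = 999,
               seed: int | None = None) -> RRPPResult:
    """Distance-based phylogenetic GLS of curve shape on group membership.

    ``group_labels`` maps every species in ``curves`` to a group; with
    ``tree=None`` the tip covariance is the identity (ordinary multivariate
    permutation ANOVA).  P_rand = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    species = list(curves.species)
    missing = [s for s in species if s not in group_labels]
    if missing:
        raise ValueError(f"group labels missing for: {missing}")
    labels = [group_labels[s] for s in species]
    levels = sorted(set(labels))
    counts = {g: labels.count(g) for g in levels}
    single = [g for g, c in counts.items() if c < 2]
    if len(levels) < 2 or single:
        raise ValueError(f"each group needs ≥ 2 members; offending: {single}")
    n = len(species)
    Y = curves.values
    X = np.column_stack([np.ones(n)] +
                        [[1.0 if l == g else 0.0 for l in labels]
                         for g in levels[1:]])
    if tree is not None:
        C = tree.phylo_covariance(species)
        T = _inv_sqrt(C)
        Yt, Xt = T @ Y, T @ X
    else:
        Yt, Xt = Y, X
    Xr = Xt[:, :1]  # reduced: intercept only

    def hat(M):
        return M @ np.linalg.pinv(M.T @ M) @ M.T

    H_full, H_red = hat(Xt), hat(Xr)
    df_eff = np.linalg.matrix_rank(Xt) - np.linalg.matrix_rank(Xr)
    df_res = n - np.linalg.matrix_rank(Xt)
    A = H_full - H_red
    Q = np.eye(n) - H_full
    R = Yt - H_red @ Yt  # reduced-model residuals, randomized under the null

    def f_stat(Ystar):
        ss_eff = float(np.sum((A @ Ystar) * Ystar))
        ss_res = float(np.sum((Q @ Ystar) * Ystar))
        if ss_res <= 0:
            return ss_eff, np.inf if ss_eff > 0 else 0.0
        return ss_eff, (ss_eff / df_eff) / (ss_res / df_res)

    ss_obs, f_obs = f_stat(Yt)
    if ss_obs <= 1e-10 * float(np.sum(Yt * Yt)):  # zero up to roundoff
        return RRPPResult(0.0, 0.0, n_perm, 1.0, df_eff, df_res)
    rng = np.random.default_rng(seed)
    base = H_red @ Yt
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, f_p = f_stat(base + R[perm])
        if f_p >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return RRPPResult(ss_obs, f_obs, n_perm, p, df_eff, df_res)
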