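"""Ancestral amino-acid states and convergent/divergent substitution counts.

Reconstruction runs under a 20-state equal-exchangeability model with
uniform stationary frequencies (the amino-acid analogue of Jukes–Cantor,
unit-rate normalized), by Felsenstein pruning with marginal posteriors, or
by Fitch parsimony as a cheap alternative; externally computed states can
also be supplied.  Counting follows path semantics: for a pair of tips and
their MRCA's reconstructed state m, a site is *convergent* when both tips
independently show the same state ≠ m, *divergent* when both changed but to
different states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS
from .tree import Phylogeny, TraitMap, enumerate_pairs, fitch_binary_trait

__all__ = [
    "AncestralStates",
    "EqualRatesModel",
    "build_pair_table",
    "count_pair_substitutions",
    "encode_alignment",
    "fitch_parsimony_states",
    "marginal_ancestral_states",
    "site_log_likelihood",
]

logger = logging.getLogger(__name__)

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MISSING = -1  # gap / ambiguity code: uninformative in likelihoods


@dataclass(frozen=True)
class EqualRatesModel:
    """Equal-exchangeability amino-acid model, uniform frequencies.

    With unit-rate normalization (one expected substitution per site per
    unit branch length), P_ii(t) = 1/20 + (19/20)·exp(−20t/19) and all
    off-diagonal entries are equal.
    """

    n_states: int = 20

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        k = self.n_states
        e = np.exp(-k * t / (k - 1))
        P = np.full((k, k), (1.0 - e) / k)
        np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
        return P

    @property
    def stationary(self) -> np.ndarray:
        return np.full(self.n_states, 1.0 / self.n_states)


@dataclass
class AncestralStates:
    """Maximum-posterior state and posterior support per internal node and
    site.  ``states`` codes index :data:`halcyon.io.AMINO_ACIDS`."""

    node_ids: tuple
    states: np.ndarray      # (n_nodes_listed, n_sites) int codes
    posterior: np.ndarray   # same shape, in [0, 1]
    method: str             # marginal-ML | parsimony | supplied
    _row: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self._row:
            self._row = {nid: i for i, nid in enumerate(self.node_ids)}
        if np.any(self.posterior < 0) or np.any(self.posterior > 1):
            raise ValueError("posteriors must lie in [0, 1]")

    def node_states(self, node_id: str) -> np.ndarray:
        return self.states[self._row[node_id]]

    def node_posterior(self, node_id: str) -> np.ndarray:
        return self.posterior[self._row[node_id]]


def encode_alignment(tree: Phylogeny, alignment: dict) -> np.ndarray:
    """Integer-code tip rows in the tree's postorder tip order; gaps and
    ambiguity codes map to −1."""
    tips = tree.tip_labels
    missing = sorted(set(tips) - set(alignment))
    if missing:
        raise ValueError(f"alignment lacks tree tips: {missing}")
    L = len(next(iter(alignment.values())))
    codes = np.full((tree.n_nodes, L), MISSING, dtype=np.int16)
    for i in tree.tip_indices:
        seq = alignment[tree.labels[i]]
        codes[i] = [_CODE.get(c, MISSING) for c in seq]
    return codes


def _up_partials(tree: Phylogeny, codes: np.ndarray, model: EqualRatesModel):
    """Postorder conditional likelihoods, per-site log-scaled.

    Returns (partials[n_nodes, L, 20], logscale[n_nodes, L]) where
    partials are normalized to max 1 per node and site.
    """
    n, L, k = tree.n_nodes, codes.shape[1], model.n_states
    up = np.ones((n, L, k))
    logscale = np.zeros((n, L))
    for i in range(n):
        if tree.is_tip(i):
            obs = codes[i]
            row = np.ones((L, k))
            known = obs >= 0
            row[known] = 0.0
            row[known, obs[known]] = 1.0
            up[i] = row
        else:
            prod = np.ones((L, k))
            for c in tree.children[i]:
                P = model.transition_matrix(tree.blen[c])
                prod *= up[c] @ P.T
                logscale[i] += logscale[c]
            mx = prod.max(axis=1)
            mx[mx == 0] = 1.0
            up[i] = prod / mx[:, None]
            logscale[i] += np.log(mx)
    return up, logscale


def site_log_likelihood(tree: Phylogeny, column: str,
                        model: EqualRatesModel | None = None) -> float:
    """Log-probability of one alignment column under the model, internal
    nodes marginalized by postorder pruning.  Gaps are uninformative."""
    model = model or EqualRatesModel()
    tips = tree.tip_labels
    if len(column) != len(tips):
        raise ValueError("column length must equal number of tips")
    aln = {t: c for t, c in zip(tips, column)}
    codes = encode_alignment(tree, {t: aln[t] for t in tips})
    if np.all(codes[tree.tip_indices] == MISSING):
        raise ValueError("all-gap column has no likelihood")
    up, logscale = _up_partials(tree, codes, model)
    r = tree.root
    lik = up[r, 0] @ model.stationary
    return float(np.log(lik) + logscale[r, 0])


def _down_messages(tree: Phylogeny, up: np.ndarray, model: EqualRatesModel):
    """Preorder 'outside' messages: A[v][s] ∝ P(data above v | state s at v),
    normalized per site (constants cancel in posteriors)."""
    n, L, k = up.shape
    down = np.ones((n, L, k))
    down[tree.root] = model.stationary
    for i in range(n - 1, -1, -1):
        if tree.is_tip(i):
            continue
        # cache child up-messages through their branches
        msgs = {}
        for c in tree.children[i]:
            P = model.transition_matrix(tree.blen[c])
            msgs[c] = up[c] @ P.T  # (L, k): message from child c to node i
        for c in tree.children[i]:
            sib = np.copy(down[i])
            for w in tree.children[i]:
                if w != c:
                    sib *= msgs[w]
            P = model.transition_matrix(tree.blen[c])
            m = sib @ P
            mx = m.max(axis=1)
            mx[mx == 0] = 1.0
            down[c] = m / mx[:, None]
    return down


def marginal_ancestral_states(tree: Phylogeny, alignment: dict,
                              model: EqualRatesModel | None = None
                              ) -> AncestralStates:
    """Marginal (empirical-Bayes) reconstruction at every internal node.

    Posterior over states = normalized product of inside and outside
    messages; the stored state is the argmax, ties broken alphabetically
    (the amino-acid code order is alphabetical).
    """
    model = model or EqualRatesModel()
    codes = encode_alignment(tree, alignment)
    up, _ = _up_partials(tree, codes, model)
    down = _down_messages(tree, up, model)
    internal = [i for i in range(tree.n_nodes) if not tree.is_tip(i)]
    node_ids = tuple(tree.labels[i] for i in internal)
    L = codes.shape[1]
    states = np.empty((len(internal), L), dtype=np.int16)
    post = np.empty((len(internal), L))
    for r, i in enumerate(internal):
        joint = up[i] * down[i]
        tot = joint.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        p = joint / tot
        # alphabetical tie-break: first state within tolerance of the max
        pmax = p.max(axis=1, keepdims=True)
        states[r] = np.argmax(p >= pmax - 1e-10, axis=1)
        post[r] = p[np.arange(L), states[r]]
    return AncestralStates(node_ids, states, post, method="marginal-ML")


def fitch_parsimony_states(tree: Phylogeny, alignment: dict) -> AncestralStates:
    """Fitch parsimony reconstruction: first-pass state sets, second pass
    inheriting the parent state when in the set, else the alphabetical
    minimum.  Posteriors are set to 1."""
    codes = encode_alignment(tree, alignment)
    n, L = codes.shape
    FULL = (1 << 20) - 1
    sets = np.zeros((n, L), dtype=np.int64)
    for i in range(n):
        if tree.is_tip(i):
            s = np.where(codes[i] >= 0, 1 << codes[i].astype(np.int64), FULL)
            sets[i] = s
        else:
            inter = np.full(L, FULL, dtype=np.int64)
            union = np.zeros(L, dtype=np.int64)
            for c in tree.children[i]:
                inter &= sets[c]
                union |= sets[c]
            sets[i] = np.where(inter != 0, inter, union)
    # lowest set bit = alphabetical minimum state
    low = np.zeros((n, L), dtype=np.int16)
    for i in range(n):
        lb = sets[i] & -sets[i]
        low[i] = np.round(np.log2(lb)).astype(np.int16)
    resolved = np.zeros((n, L), dtype=np.int16)
    for i in range(n - 1, -1, -1):
        if tree.parent[i] == -1:
            resolved[i] = low[i]
        else:
            ps = resolved[tree.parent[i]]
            inset = (sets[i] >> ps.astype(np.int64)) & 1
            resolved[i] = np.where(inset == 1, ps, low[i])
    internal = [i for i in range(n) if not tree.is_tip(i)]
    node_ids = tuple(tree.labels[i] for i in internal)
    states = resolved[internal]
    return AncestralStates(node_ids, states,
                           np.ones_like(states, dtype=float),
                           method="parsimony")


def count_pair_substitutions(states: AncestralStates, alignment: dict,
                             tree: Phylogeny, tip_a: str, tip_b: str,
                             posterior_floor: float = 0.0,
                             loose_divergent: bool = False):
    """Convergent and divergent substitution counts for one tip pair.

    Per scored site (MRCA state m with posterior ≥ floor; both tip states
    unambiguous amino acids): convergent iff s_a = s_b ≠ m; divergent iff
    s_a ≠ s_b and both differ from m (with ``loose_divergent``, any
    s_a ≠ s_b).  Single-lineage changes count as neither.
    """
    if tip_a == tip_b:
        raise ValueError("pair must be two distinct tips")
    mrca = tree.mrca(tip_a, tip_b)
    m = states.node_states(mrca)
    pp = states.node_posterior(mrca)
    codes = encode_alignment(tree, alignment)
    sa = codes[tree.index(tip_a)]
    sb = codes[tree.index(tip_b)]
    ok = (sa >= 0) & (sb >= 0) & (m >= 0) & (pp >= posterior_floor)
    conv = ok & (sa == sb) & (sa != m)
    if loose_divergent:
        div = ok & (sa != sb)
    else:
        div = ok & (sa != sb) & (sa != m) & (sb != m)
    return int(conv.sum()), int(div.sum())


def build_pair_table(tree: Phylogeny, states_by_gene: dict,
                     alignments: dict, trait_map: TraitMap,
                     response: str = "total",
                     posterior_floor: float = 0.0,
                     loose_divergent: bool = False) -> pd.DataFrame:
    """One row per unordered tip pair with counts summed over genes.

    A pair is *focal* for a trait when both tips carry it and their MRCA's
    parsimony reconstruction does not (independent origins).  Columns:
    tip_a, tip_b, mrca_id, divergence_time, C, D, plunge_focal,
    island_focal, n_genes, response.
    """
    if response not in ("total", "per_gene"):
        raise ValueError("response must be 'total' or 'per_gene'")
    genes = sorted(states_by_gene)
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    trait_map.validate_against(tree)
    plunge_anc, _ = fitch_binary_trait(tree, trait_map.plunge)
    island_anc, _ = fitch_binary_trait(tree, trait_map.island)
    rows = []
    for tip_a, tip_b in enumerate_pairs(tree.tip_labels):
        mrca = tree.mrca(tip_a, tip_b)
        C = D = 0
        n_genes = 0
        for g in genes:
            aln = alignments[g]
            if tip_a not in aln or tip_b not in aln:
                logger.warning("gene %s lacks %s or %s: skipped for pair",
                               g, tip_a, tip_b)
                continue
            c, d = count_pair_substitutions(
                states_by_gene[g], aln, tree, tip_a, tip_b,
                posterior_floor=posterior_floor,
                loose_divergent=loose_divergent)
            C += c
            D += d
            n_genes += 1
        pf = int(trait_map.plunge[tip_a] == trait_map.plunge[tip_b] == 1
                 and plunge_anc[mrca] == 0)
        isf = int(trait_map.island[tip_a] == trait_map.island[tip_b] == 1
                  and island_anc[mrca] == 0)
        resp = C if response == "total" else (C / n_genes if n_genes else 0.0)
        rows.append(dict(tip_a=tip_a, tip_b=tip_b, mrca_id=mrca,
                         divergence_time=tree.divergence_time(tip_a, tip_b),
                         C=C, D=D, plunge_focal=pf, island_focal=isf,
                         n_genes=n_genes, response=float(resp)))
    return pd.DataFrame(rows)
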