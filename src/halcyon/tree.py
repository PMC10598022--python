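"""Rooted phylogeny with deterministic node ids and the tree algebra shared
by every analysis: MRCA lookups, divergence times, root-to-tip paths,
phylogenetic covariance matrices, Brownian-motion simulation, binary-trait
parsimony reconstruction, and phylogenetically informed permutations
("permulations") of binary foreground sets.

The tree is stored as flat postorder arrays.  Node ids are assigned on the
canonical ladderized form (children sorted by clade size, then by smallest
descendant label), so the same Newick string always yields the same ids:
tips keep their labels, internal nodes are named ``n<postorder index>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TraitMap",
    "count_foreground_clades",
    "enumerate_pairs",
    "fitch_binary_trait",
    "permulate_binary",
]


class PhylogenyError(ValueError):
    pass


@dataclass
class Phylogeny:
    """Rooted tree in postorder arrays.

    ``parent[i]`` is the postorder index of node *i*'s parent (−1 at the
    root), ``blen[i]`` the length of the branch above *i* (0 at the root).
    Tips come with labels; internal nodes are addressed as ``n<index>``.
    Branch lengths are nonnegative: time (My) for species trees, expected
    substitutions per site for gene trees.
    """

    parent: np.ndarray
    blen: np.ndarray
    children: tuple
    labels: tuple          # node id per postorder index
    _index: dict = field(repr=False)

    # ------------------------------------------------------------------ build
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            dt = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises various parse errors
            raise PhylogenyError(f"unreadable Newick: {exc}") from exc
        root = dt.seed_node
        if len(root.child_nodes()) == 0:
            raise PhylogenyError("tree has no tips")

        # canonical ladderization: sort children by (clade tip count, min label)
        def key(nd):
            tips = [lf.taxon.label for lf in nd.leaf_iter()]
            return (len(tips), min(tips))

        for nd in dt.preorder_node_iter():
            kids = nd.child_nodes()
            if kids:
                nd.set_child_nodes(sorted(kids, key=key))

        order = list(dt.postorder_node_iter())
        pos = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n, dtype=float)
        children: list[tuple[int, ...]] = [() for _ in range(n)]
        labels: list[str] = [""] * n
        seen = set()
        for i, nd in enumerate(order):
            if nd.parent_node is not None:
                parent[i] = pos[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise PhylogenyError(
                        f"missing branch length above node {i}"
                    )
                if nd.edge.length < 0:
                    raise PhylogenyError(f"negative branch length at node {i}")
                blen[i] = float(nd.edge.length)
            kids = nd.child_nodes()
            if kids:
                children[i] = tuple(pos[id(k)] for k in kids)
                labels[i] = f"n{i}"
            else:
                lab = nd.taxon.label if nd.taxon is not None else None
                if not lab:
                    raise PhylogenyError(f"tip without label at node {i}")
                if lab in seen:
                    raise PhylogenyError(f"duplicate tip label {lab!r}")
                seen.add(lab)
                labels[i] = lab
        return cls(
            parent=parent, blen=blen, children=tuple(children),
            labels=tuple(labels), _index={l: i for i, l in enumerate(labels)},
        )

    # ------------------------------------------------------------- basic ops
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tip_indices(self) -> list:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def index(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise PhylogenyError(f"unknown node id {node_id!r}") from None

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def depths(self) -> np.ndarray:
        """Distance from the root to every node (preorder accumulation)."""
        d = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 2, -1, -1):
            d[i] = d[self.parent[i]] + self.blen[i]
        return d

    @property
    def height(self) -> float:
        d = self.depths()
        return float(max(d[i] for i in self.tip_indices))

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths()
        td = np.array([d[i] for i in self.tip_indices])
        h = td.max()
        return bool(h == 0 or (td.max() - td.min()) <= rel_tol * h)

    def ancestors(self, i: int) -> list:
        """Strict ancestors of node *i*, nearest first."""
        out = []
        j = self.parent[i]
        while j != -1:
            out.append(int(j))
            j = self.parent[j]
        return out

    def mrca(self, tip_a: str, tip_b: str) -> str:
        """Node id of the most recent common ancestor of two distinct tips."""
        if tip_a == tip_b:
            raise PhylogenyError("MRCA requires two distinct tips")
        ia, ib = self.index(tip_a), self.index(tip_b)
        anc_a = set([ia] + self.ancestors(ia))
        j = ib
        while j not in anc_a:
            j = int(self.parent[j])
        return self.labels[j]

    def divergence_time(self, tip_a: str, tip_b: str,
                        rel_tol: float = 1e-6) -> float:
        """Depth of the pair's MRCA below the present (ultrametric trees)."""
        if not self.is_ultrametric(rel_tol):
            raise PhylogenyError(
                "divergence_time requires an ultrametric tree "
                f"(tolerance {rel_tol} of tree height exceeded)"
            )
        m = self.index(self.mrca(tip_a, tip_b))
        d = self.depths()
        return float(self.height - d[m])

    def path_branches(self, ancestor_id: str, tip: str) -> list:
        """Node indices whose branches lie on the path ancestor→tip
        (ancestor exclusive, tip inclusive)."""
        ia, it = self.index(ancestor_id), self.index(tip)
        path = [it]
        j = it
        while True:
            j = int(self.parent[j])
            if j == ia:
                return list(reversed(path))
            if j == -1:
                raise PhylogenyError(
                    f"{ancestor_id!r} is not ancestral to {tip!r}"
                )
            path.append(j)

    # ------------------------------------------------------ covariance / BM
    def phylo_covariance(self, node_ids) -> np.ndarray:
        """Shared root-path-length matrix over the given nodes.

        Entry (i, j) is the length of the root-to-MRCA(i, j) path; the
        diagonal holds node depths.  Symmetric positive semidefinite.
        """
        node_ids = list(node_ids)
        if not node_ids:
            raise PhylogenyError("empty node set")
        idx = [self.index(x) for x in node_ids]
        d = self.depths()
        # shared path length = depth of the MRCA of the two nodes
        anc = [dict.fromkeys([i] + self.ancestors(i)) for i in idx]
        m = len(idx)
        C = np.empty((m, m))
        for a in range(m):
            C[a, a] = d[idx[a]]
            for b in range(a + 1, m):
                j = idx[b]
                while j != -1 and j not in anc[a]:
                    j = int(self.parent[j])
                # j == -1 can only happen for disjoint roots; root is shared
                C[a, b] = C[b, a] = d[j] if j != -1 else 0.0
        return C

    def simulate_bm(self, sigma2: float, seed) -> dict:
        """Brownian tip values: child = parent + N(0, sigma2 * branch)."""
        if not sigma2 > 0:
            raise PhylogenyError("sigma2 must be positive")
        rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator) else seed
        vals = np.zeros(self.n_nodes)
        steps = rng.standard_normal(self.n_nodes) * np.sqrt(sigma2 * self.blen)
        for i in range(self.n_nodes - 2, -1, -1):
            vals[i] = vals[self.parent[i]] + steps[i]
        return {self.labels[i]: float(vals[i]) for i in self.tip_indices}

    # --------------------------------------------------------------- output
    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if self.is_tip(i):
                body = self.labels[i]
            else:
                body = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if self.parent[i] == -1:
                return body
            return f"{body}:{self.blen[i]:.10g}"
        return rec(self.root) + ";"


@dataclass
class TraitMap:
    """Per-tip binary states (plunge-diving, insularity) and optional
    continuous covariates (ln body mass, grams)."""

    plunge: dict
    island: dict
    ln_mass: dict = field(default_factory=dict)

    def validate_against(self, tree: Phylogeny) -> None:
        missing = sorted(set(tree.tip_labels) - set(self.plunge))
        if missing:
            raise PhylogenyError(f"tips absent from trait map: {missing}")
        extra = sorted(set(self.plunge) - set(tree.tip_labels))
        if extra:
            raise PhylogenyError(f"trait species absent from tree: {extra}")


def enumerate_pairs(tips) -> list:
    """All unordered distinct pairs, lexicographic order; n(n−1)/2 of them."""
    tips = sorted(tips)
    if len(tips) < 2:
        raise PhylogenyError("need at least two tips to form pairs")
    return [(a, b) for k, a in enumerate(tips) for b in tips[k + 1:]]


def fitch_binary_trait(tree: Phylogeny, trait: dict):
    """Minimum-change (Fitch) reconstruction of a binary trait.

    Ties resolve toward state 0 at the root and by parent-state inheritance
    below it.  Returns ``(states_by_node_id, n_origins)`` where origins are
    0→1 transitions on branches (a root already in state 1 counts as one).
    """
    for t in tree.tip_labels:
        if t not in trait:
            raise PhylogenyError(f"trait missing for tip {t!r}")
        if trait[t] not in (0, 1):
            raise PhylogenyError(f"non-binary trait value for {t!r}")
    n = tree.n_nodes
    sets = [0] * n  # bitmask: 1 -> {0}, 2 -> {1}, 3 -> {0,1}
    for i in range(n):
        if tree.is_tip(i):
            sets[i] = 1 << trait[tree.labels[i]]
        else:
            inter = 3
            union = 0
            for c in tree.children[i]:
                inter &= sets[c]
                union |= sets[c]
            sets[i] = inter if inter else union
    states = np.zeros(n, dtype=int)
    for i in range(n - 1, -1, -1):
        s = sets[i]
        if s == 3:
            if tree.parent[i] == -1:
                states[i] = 0
            else:
                states[i] = states[tree.parent[i]]
        else:
            states[i] = 0 if s == 1 else 1
    origins = int(states[tree.root] == 1)
    for i in range(n - 1):
        if states[i] == 1 and states[tree.parent[i]] == 0:
            origins += 1
    return {tree.labels[i]: int(states[i]) for i in range(n)}, origins


def count_foreground_clades(tree: Phylogeny, fg) -> int:
    """Number of maximal clades whose descendant tips are all foreground."""
    fg = set(fg)
    n = tree.n_nodes
    pure = [False] * n
    for i in range(n):
        if tree.is_tip(i):
            pure[i] = tree.labels[i] in fg
        else:
            pure[i] = all(pure[c] for c in tree.children[i])
    return sum(
        1 for i in range(n)
        if pure[i] and (tree.parent[i] == -1 or not pure[tree.parent[i]])
    )


def permulate_binary(tree: Phylogeny, observed_foreground_tips, seed,
                     match_origins: bool = False,
                     max_tries: int = 10000) -> set:
    """Phylogenetically informed permutation of a binary foreground set.

    Simulates a Brownian trait on the tree and assigns foreground status to
    the tips with the k largest simulated values, preserving the observed
    foreground count exactly.  With ``match_origins`` the draw is rejected
    until its parsimony origin count equals the observed one.
    """
    fg = set(observed_foreground_tips)
    k = len(fg)
    if not 1 <= k < tree.n_tips:
        raise PhylogenyError("foreground size must be in [1, n_tips)")
    for t in fg:
        tree.index(t)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    target = count_foreground_clades(tree, fg) if match_origins else None
    achieved = []
    for _ in range(max_tries):
        bm = tree.simulate_bm(1.0, rng)
        ranked = sorted(bm, key=lambda t: (-bm[t], t))
        cand = set(ranked[:k])
        if target is None:
            return cand
        got = count_foreground_clades(tree, cand)
        achieved.append(got)
        if got == target:
            return cand
    raise PhylogenyError(
        f"could not match {target} origins in {max_tries} tries "
        f"(achieved counts ranged {min(achieved)}–{max(achieved)})"
    )
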