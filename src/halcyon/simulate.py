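"""Synthetic inputs with the statistical structure the analyses assume.

Everything the pipeline consumes can be generated here with controllable
effect sizes: an ultrametric Yule species tree with a fixed number of
independent origins of plunge-diving and of island dwelling; amino-acid
alignments in which a fraction of sites is attracted toward a site-specific
target state on foreground branches (producing an excess of convergent
substitutions at matched divergent counts); island-vs-continental Ne
trajectories differing in fluctuation scale and a recent island decline;
and gene-test tables with a planted adaptively-convergent gene subset,
per-species positively-selected-gene counts driven by trait covariates,
and a term map containing one genuinely enriched term.

Every generator is a pure function of its configuration and seed, and
returns the ground truth alongside the data so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AMINO_ACIDS, GeneTestResult, NeTrajectory
from .tree import Phylogeny, TraitMap, fitch_binary_trait

__all__ = [
    "SimConfig",
    "simulate_alignment_with_convergence",
    "simulate_gene_tests_and_psgs",
    "simulate_ne_trajectories",
    "simulate_tree_and_traits",
]


@dataclass
class SimConfig:
    """Knobs of the synthetic world; defaults are the reference conditions.

    Tree/trait: ``n_tips`` species on a Yule tree scaled to height 1 (time
    units), with ``plunge_origins`` / ``island_origins`` independent trait
    origins on non-nested edges.  Sequence: ``n_genes`` × ``sites_per_gene``
    amino-acid sites at ``tree_scale_subs`` expected substitutions per site
    root-to-tip; ``convergent_fraction`` of sites feel an attraction of
    strength ``attraction`` toward a site-specific target on foreground
    branches.  Demography: log-Ne random walks with island/continental
    fluctuation SDs and a recent island decline fraction.  Gene tests:
    ``n_test_genes`` genes with ``n_planted`` passing all four selection
    tests; PSG counts with log-linear trait effects.
    """

    # tree and traits
    n_tips: int = 16
    yule_rate: float = 1.0
    plunge_origins: int = 4
    island_origins: int = 5
    mass_root: float = 4.0       # ln grams; ~55 g, a mid-sized kingfisher
    mass_bm_var: float = 0.5
    # alignments
    n_genes: int = 60
    sites_per_gene: int = 150
    tree_scale_subs: float = 0.5
    convergent_fraction: float = 0.05
    attraction: float = 0.5
    # demography (years; grid log-spaced)
    ne_t_min: float = 1e3
    ne_t_max: float = 1e6
    ne_grid: int = 64
    baseline_log_ne: float = float(np.log(2e5))
    fluct_sd_island: float = 0.6
    fluct_sd_continental: float = 0.3
    island_decline_frac: float = 0.8
    # gene tests and PSG counts
    n_test_genes: int = 500
    n_planted: int = 20
    n_terms: int = 20
    term_size: int = 30
    psg_beta0: float = float(np.log(150))
    psg_beta_plunge: float = 0.3
    psg_beta_mass: float = -0.2
    psg_beta_island: float = 0.3
    psg_beta_interaction: float = 0.0
    psg_dispersion: float = 0.15


# ------------------------------------------------------------ tree and traits
def _yule_newick(n_tips: int, rate: float, rng) -> str:
    """Forward Yule simulation, tips extended to the present, height 1."""
    active = ["t1", "t2"]
    birth = {"t1": 0.0, "t2": 0.0}
    t = 0.0
    k = 2
    nxt = 3
    structure: dict = {}  # lineage label -> (child_a, child_b, split_time)
    while k < n_tips:
        t += rng.exponential(1.0 / (rate * k))
        i = rng.integers(k)
        lab = active[i]
        a, b = f"t{nxt}", f"t{nxt+1}"
        # children inherit; the split lineage's pending branch ends at t
        structure[lab] = (a, b, t)
        birth[a] = birth[b] = t
        active[i] = a
        active.append(b)
        nxt += 2
        k += 1
    T = t + rng.exponential(1.0 / (rate * k))

    def render(lab: str) -> str:
        if lab in structure:
            a, b, ts = structure[lab]
            return f"({render(a)},{render(b)}):{_blen(lab, ts)}"
        return f"{lab}:{_blen(lab, T)}"

    def _blen(lab: str, end: float) -> float:
        return (end - birth[lab]) / T  # scale height to 1

    return f"({render('t1')},{render('t2')});"


def _descendant_tips(tree: Phylogeny, i: int) -> set:
    if tree.is_tip(i):
        return {tree.labels[i]}
    out: set = set()
    for c in tree.children[i]:
        out |= _descendant_tips(tree, c)
    return out


def _place_origins(tree: Phylogeny, k: int, rng, max_tries: int = 200):
    """k pairwise non-nested, non-root edges; tips below them become
    foreground; at least one background tip must remain."""
    if k == 0:
        return [], set()
    edges = [i for i in range(tree.n_nodes) if tree.parent[i] != -1]
    for _ in range(max_tries):
        chosen = list(rng.choice(len(edges), size=k, replace=False))
        nodes = [edges[c] for c in chosen]
        anc = [set(tree.ancestors(i)) for i in nodes]
        if any(nodes[a] in anc[b] or nodes[b] in anc[a]
               for a in range(k) for b in range(a + 1, k)):
            continue
        fg: set = set()
        for i in nodes:
            fg |= _descendant_tips(tree, i)
        if len(fg) == tree.n_tips:
            continue
        # sister foreground clades would collapse under parsimony; require
        # that the minimum-change reconstruction sees exactly k origins
        _, got = fitch_binary_trait(
            tree, {t: int(t in fg) for t in tree.tip_labels})
        if got == k:
            return nodes, fg
    raise ValueError(f"could not place {k} non-nested origins")


def simulate_tree_and_traits(config: SimConfig, seed):
    """Ultrametric Yule tree (height 1) plus binary traits and ln-mass.

    Returns ``(tree, trait_map, truth)`` where truth records the origin
    edge node ids per trait.
    """
    if config.n_tips < 8:
        raise ValueError("need at least 8 tips")
    rng = np.random.default_rng(seed)
    for _ in range(50):
        tree = Phylogeny.from_newick(
            _yule_newick(config.n_tips, config.yule_rate, rng))
        try:
            p_nodes, p_fg = _place_origins(tree, config.plunge_origins, rng)
            i_nodes, i_fg = _place_origins(tree, config.island_origins, rng)
            break
        except ValueError:
            continue
    else:
        raise ValueError("origin placement failed across topology resamples")
    mass = tree.simulate_bm(config.mass_bm_var, rng)
    traits = TraitMap(
        plunge={t: int(t in p_fg) for t in tree.tip_labels},
        island={t: int(t in i_fg) for t in tree.tip_labels},
        ln_mass={t: config.mass_root + mass[t] for t in tree.tip_labels},
    )
    truth = {
        "plunge_origin_nodes": [tree.labels[i] for i in p_nodes],
        "island_origin_nodes": [tree.labels[i] for i in i_nodes],
    }
    return tree, traits, truth


# ----------------------------------------------------------------- alignments
def _foreground_nodes(tree: Phylogeny, foreground_tips) -> np.ndarray:
    """Boolean per node: inside a maximal foreground clade (stem included)."""
    fg = set(foreground_tips)
    pure = np.zeros(tree.n_nodes, dtype=bool)
    for i in range(tree.n_nodes):
        if tree.is_tip(i):
            pure[i] = tree.labels[i] in fg
        else:
            pure[i] = all(pure[c] for c in tree.children[i])
    return pure


def simulate_alignment_with_convergence(tree: Phylogeny, trait_map: TraitMap,
                                        config: SimConfig, seed):
    """One gene alignment under the equal-rates model plus attraction.

    Background sites evolve neutrally (states sampled from the exact
    transition probabilities branch by branch, root to tips).  A fraction
    of sites is *convergent*: on foreground branches, with probability
    ``attraction`` the end-of-branch state is replaced by the site's
    target amino acid.  Returns ``(alignment, truth)`` with per-node true
    states, per-site class and targets.
    """
    rng = np.random.default_rng(seed)
    L = config.sites_per_gene
    k = 20
    n = tree.n_nodes
    fg_node = _foreground_nodes(tree, [t for t, v in trait_map.plunge.items()
                                       if v == 1])
    is_conv = rng.random(L) < config.convergent_fraction
    target = rng.integers(k, size=L)
    states = np.empty((n, L), dtype=np.int16)
    states[tree.root] = rng.integers(k, size=L)
    ee = np.exp(-k * (tree.blen * config.tree_scale_subs) / (k - 1))
    for i in range(n - 2, -1, -1):
        p_same = 1.0 / k + (k - 1) / k * ee[i]
        stay = rng.random(L) < p_same
        parent = states[tree.parent[i]]
        # change: uniform over the 19 other states
        shift = rng.integers(1, k, size=L)
        states[i] = np.where(stay, parent, (parent + shift) % k)
        if fg_node[i] and config.attraction > 0:
            pull = is_conv & (rng.random(L) < config.attraction)
            states[i, pull] = target[pull]
    aln = {tree.labels[i]: "".join(AMINO_ACIDS[s] for s in states[i])
           for i in tree.tip_indices}
    truth = {"node_states": states, "site_is_convergent": is_conv,
             "site_target": target, "node_order": list(tree.labels)}
    return aln, truth


# ----------------------------------------------------------------- demography
def simulate_ne_trajectories(tree: Phylogeny, trait_map: TraitMap,
                             config: SimConfig, seed):
    """Per-species step-function Ne histories on a log-spaced grid.

    log-Ne = baseline + random walk (island SD > continental SD) + an
    island-only linear-in-log-time decline over the most recent decade,
    scaling present-day Ne down to (1 − decline fraction) of its
    undeclined value.
    """
    rng = np.random.default_rng(seed)
    grid = np.geomspace(config.ne_t_min, config.ne_t_max, config.ne_grid)
    lg = np.log10(grid)
    decade = lg <= lg[0] + 1.0
    ramp = np.zeros_like(lg)
    if config.island_decline_frac > 0:
        drop = np.log(1.0 - config.island_decline_frac)
        ramp[decade] = drop * (lg[0] + 1.0 - lg[decade])  # 0 at decade edge
    out = []
    for sp in tree.tip_labels:
        isl = trait_map.island[sp] == 1
        sd = config.fluct_sd_island if isl else config.fluct_sd_continental
        steps = rng.standard_normal(config.ne_grid) * sd / np.sqrt(config.ne_grid)
        walk = np.cumsum(steps[::-1])[::-1]  # anchored at the oldest point
        logne = config.baseline_log_ne + walk - walk[-1]
        if isl:
            logne = logne + ramp
        out.append(NeTrajectory(sp, grid, np.exp(logne)))
    return out


# ----------------------------------------------------------- gene-test tables
def simulate_gene_tests_and_psgs(tree: Phylogeny, trait_map: TraitMap,
                                 config: SimConfig, seed):
    """Gene-test tables, PSG indicator matrix and term map with truth.

    A planted subset of genes passes all four selection/convergence
    filters; all other scores are null (uniform p, sub-threshold
    posteriors).  Per-species PSG totals follow a log-linear model in
    plunge, centered ln-mass, insularity and their interaction, with
    log-normal dispersion; plunge species preferentially include the
    planted genes so focal pairs share more PSGs.  One term of the term
    map covers the planted subset (the enriched term).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(config.n_test_genes)]
    planted = list(rng.choice(genes, size=config.n_planted, replace=False))
    planted_set = set(planted)
    records: list = []
    for g in genes:
        hot = g in planted_set
        records.append(GeneTestResult(
            g, "branch_site",
            float(rng.uniform(0, 1e-5)) if hot else float(rng.uniform())))
        records.append(GeneTestResult(
            g, "relax",
            float(rng.uniform(0, 1e-5)) if hot else float(rng.uniform())))
        records.append(GeneTestResult(
            g, "residue_convergence",
            float(rng.uniform(0.85, 1.0)) if hot
            else float(rng.uniform(0.0, 0.6))))
    # per-branch adaptive test scores on every (gene, plunge branch)
    mass = trait_map.ln_mass
    mbar = float(np.mean(list(mass.values())))
    logmean = {}
    for sp in tree.tip_labels:
        m = mass[sp] - mbar
        pl = trait_map.plunge[sp]
        isl = trait_map.island[sp]
        logmean[sp] = (config.psg_beta0 + config.psg_beta_plunge * pl
                       + config.psg_beta_mass * m
                       + config.psg_beta_island * isl
                       + config.psg_beta_interaction * m * isl)
    indicator = {}
    for sp in tree.tip_labels:
        total = int(np.round(np.exp(
            logmean[sp] + config.psg_dispersion * rng.standard_normal())))
        total = max(1, min(total, config.n_test_genes))
        chosen: set = set()
        if trait_map.plunge[sp] == 1:
            chosen |= set(rng.choice(
                planted, size=min(len(planted), total), replace=False))
        rest = [g for g in genes if g not in chosen]
        extra = total - len(chosen)
        if extra > 0:
            chosen |= set(rng.choice(rest, size=extra, replace=False))
        indicator[sp] = chosen
    for sp in tree.tip_labels:
        for g in genes:
            hot = g in indicator[sp]
            records.append(GeneTestResult(
                g, "branch_adaptive",
                float(rng.uniform(0, 1e-5)) if hot else float(rng.uniform()),
                branch_id=sp))
    term_map = {}
    term_map["TERM_ENRICHED"] = set(planted) | set(
        rng.choice([g for g in genes if g not in planted_set],
                   size=max(0, config.term_size - config.n_planted),
                   replace=False))
    for j in range(config.n_terms - 1):
        term_map[f"TERM{j:03d}"] = set(
            rng.choice(genes, size=config.term_size, replace=False))
    truth = {
        "planted_genes": planted_set,
        "enriched_term": "TERM_ENRICHED",
        "psg_sets": indicator,
        "log_means": logmean,
    }
    return records, indicator, term_map, truth
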