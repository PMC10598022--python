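import numpy as np
import pandas as pd
import pytest

from halcyon import (Phylogeny, SimConfig, enumerate_pairs,
                     simulate_tree_and_traits)
from halcyon.pairlmm import FIXED_EFFECTS


@pytest.fixture
def three_tip():
    """((a:1,b:1):1,c:2); — the smallest asymmetric ultrametric tree."""
    return Phylogeny.from_newick("((a:1,b:1):1,c:2);")


@pytest.fixture
def four_tip():
    return Phylogeny.from_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture(scope="session")
def sim_world():
    """One reference synthetic tree + traits shared across tests."""
    cfg = SimConfig(n_tips=16)
    tree, traits, truth = simulate_tree_and_traits(cfg, seed=20240101)
    return cfg, tree, traits, truth


def random_ultrametric(n_tips: int, rng) -> Phylogeny:
    """Random coalescent-style ultrametric tree for oracle comparisons."""
    nodes = [(f"t{i}", 0.0) for i in range(n_tips)]
    h = 0.0
    while len(nodes) > 1:
        h += rng.exponential(1.0) + 0.05
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = (f"({na}:{h - ha:.8f},{nb}:{h - hb:.8f})", h)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return Phylogeny.from_newick(nodes[0][0] + ";")


def make_pair_data(tree, traits, rng, beta=None, sg_a=0.3, sg_mrca=1.0,
                   sg_e=1.0):
    """Draw a pair table from the mixed model's own generative process.

    beta maps fixed-effect names to coefficients (default all zero);
    each lineage gets one idiosyncratic effect felt by every pair that
    contains it; the MRCA effect is multivariate normal with the
    diag-normalized phylogenetic covariance of the MRCA nodes.
    """
    beta = {**{k: 0.0 for k in FIXED_EFFECTS}, **(beta or {})}
    rows = []
    for a, b in enumerate_pairs(tree.tip_labels):
        rows.append(dict(
            tip_a=a, tip_b=b, mrca_id=tree.mrca(a, b),
            divergence_time=tree.divergence_time(a, b),
            C=0, D=int(rng.poisson(40)),
            plunge_focal=int(traits.plunge[a] == traits.plunge[b] == 1),
            island_focal=int(traits.island[a] == traits.island[b] == 1),
            n_genes=10, response=0.0))
    df = pd.DataFrame(rows)
    lineages = sorted(tree.tip_labels)
    u = {l: rng.normal(0, np.sqrt(sg_a)) for l in lineages}
    mlev = sorted(df["mrca_id"].unique())
    K = tree.phylo_covariance(mlev)
    K = K / np.mean(np.diag(K)) + 1e-8 * np.eye(len(K))
    um = dict(zip(mlev, np.linalg.cholesky(sg_mrca * K)
                  @ rng.standard_normal(len(mlev))))
    X = np.column_stack([
        np.ones(len(df)), df["D"], df["divergence_time"],
        df["plunge_focal"], df["island_focal"],
        df["D"] * df["divergence_time"]])
    bvec = np.array([beta[k] for k in FIXED_EFFECTS])
    df["response"] = (X @ bvec
                      + df["tip_a"].map(u).to_numpy()
                      + df["tip_b"].map(u).to_numpy()
                      + df["mrca_id"].map(um).to_numpy()
                      + rng.normal(0, np.sqrt(sg_e), len(df)))
    return df


def random_branch_tree(n_tips: int, rng) -> Phylogeny:
    """Random non-ultrametric tree (gene-tree style branch lengths)."""
    nodes = [f"t{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = (f"({a}:{rng.uniform(0.05, 1.0):.6f},"
                  f"{b}:{rng.uniform(0.05, 1.0):.6f})")
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return Phylogeny.from_newick(nodes[0] + ";")
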