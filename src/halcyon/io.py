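"""Readers and writers for every external representation the pipeline
touches: amino-acid FASTA alignments, Newick trees, PSMC plain-text output,
and the TSV tables for traits, gene-level test scores and Ne trajectories.

All tabular files are tab-delimited UTF-8 with a header row.  Readers
validate and reject malformed input rather than coercing it; every writer
produces files its paired reader accepts unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .tree import Phylogeny, TraitMap

__all__ = [
    "AMINO_ACIDS",
    "GeneTestResult",
    "NeTrajectory",
    "TEST_NAMES",
    "parse_psmc_output",
    "read_fasta",
    "read_gene_test_table",
    "read_newick",
    "read_trait_table",
    "read_trajectory_tsv",
    "write_results",
    "write_trajectory_tsv",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AMBIGUOUS = set("BJOUXZ*")
_GAPLIKE = set("-.?")

#: Registered gene-level tests.  ``branch_adaptive`` (per-branch adaptive
#: test, aBSREL-style) is the only per-branch one; the rest are per-gene.
TEST_NAMES = frozenset({
    "site",                  # site-model positive selection
    "branch_site",           # branch-site foreground test (BS2-style)
    "relax",                 # relaxed/intensified-selection confirmation
    "branch_adaptive",       # per-branch adaptive test (aBSREL-style)
    "residue_convergence",   # profile-change residue convergence posterior
    "rate_convergence",      # relative-rate convergence scan
})
PER_BRANCH_TESTS = frozenset({"branch_adaptive"})


class FormatError(ValueError):
    pass


# --------------------------------------------------------------------- FASTA
def read_fasta(path) -> dict:
    """Read an amino-acid alignment keyed by record label.

    Sequences are upper-cased; gap (``-``) and ambiguity (``X`` etc.)
    symbols are retained.  Ragged alignments and duplicate labels raise.
    """
    aln: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in aln:
            raise FormatError(f"duplicate sequence label {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set(AMINO_ACIDS) - _AMBIGUOUS - _GAPLIKE
        if bad:
            raise FormatError(
                f"sequence {rec.id!r} has non-amino-acid symbols {sorted(bad)}"
            )
        aln[rec.id] = seq
    if not aln:
        raise FormatError(f"no FASTA records in {path}")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        ref = len(next(iter(aln.values())))
        off = [k for k, s in aln.items() if len(s) != ref]
        raise FormatError(f"ragged alignment: {off[0]!r} differs in length")
    return aln


def write_fasta(aln: dict, path) -> None:
    with open(path, "w") as fh:
        for label, seq in aln.items():
            fh.write(f">{label}\n{seq}\n")


# -------------------------------------------------------------------- Newick
def read_newick(path) -> Phylogeny:
    """Read a rooted, branch-length-annotated Newick tree.

    Internal node ids are postorder indices of the canonical ladderized
    tree, so identical Newick strings always yield identical ids.
    """
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------- PSMC
@dataclass
class NeTrajectory:
    """Piecewise-constant effective-population-size history.

    ``ne_values[k]`` holds between ``times[k]`` (inclusive) and
    ``times[k+1]``; times are years before present, sizes are individuals.
    ``mu`` (per site per year) and ``gen_time`` (years) record the scaling
    used to convert from coalescent units.
    """

    species_label: str
    times: np.ndarray
    ne_values: np.ndarray
    mu: float = float("nan")
    gen_time: float = float("nan")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ne_values = np.asarray(self.ne_values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.ne_values.shape:
            raise FormatError("times and ne_values must be 1-D, same length")
        if len(self.times) < 1:
            raise FormatError("empty trajectory")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("times must be strictly increasing")
        if np.any(self.ne_values <= 0):
            raise FormatError("Ne values must be positive")

    def at(self, t) -> np.ndarray:
        """Right-continuous step evaluation at times ``t`` (years)."""
        t = np.asarray(t, dtype=float)
        k = np.searchsorted(self.times, t, side="right") - 1
        return self.ne_values[np.clip(k, 0, len(self.times) - 1)]


def parse_psmc_output(path, mu: float, gen_time: float,
                      bin_size: int = 100,
                      species_label: str | None = None) -> NeTrajectory:
    """Rescale a PSMC text output into years and individuals.

    Uses the final iteration block.  With θ0 the block's per-bin
    heterozygosity estimate and s the bin size,

        N0   = θ0 / (4 μ s)
        t_k  = 2 N0 · (scaled time) · g      (years)
        Ne_k = N0 · λ_k                      (individuals)
    """
    if mu <= 0 or gen_time <= 0 or bin_size <= 0:
        raise FormatError("mu, gen_time and bin_size must be positive")
    blocks = []
    current: dict | None = None
    with open(path) as fh:
        for line in fh:
            tag = line.split("\t", 1)[0].strip()
            if tag == "RD":
                current = {"theta0": None, "t": [], "lam": []}
                blocks.append(current)
            elif current is not None and tag == "TR":
                current["theta0"] = float(line.split()[1])
            elif current is not None and tag == "RS":
                parts = line.split()
                current["t"].append(float(parts[2]))
                current["lam"].append(float(parts[3]))
    blocks = [b for b in blocks if b["t"] and b["theta0"] is not None]
    if not blocks:
        raise FormatError(f"no complete PSMC iteration block in {path}")
    last = blocks[-1]
    theta0 = last["theta0"]
    if theta0 <= 0:
        raise FormatError(f"non-positive theta0 ({theta0}) in {path}")
    n0 = theta0 / (4.0 * mu * bin_size)
    times = 2.0 * n0 * np.asarray(last["t"]) * gen_time
    ne = n0 * np.asarray(last["lam"])
    label = species_label or re.sub(r"\.[^.]*$", "", str(path).split("/")[-1])
    return NeTrajectory(label, times, ne, mu=mu, gen_time=gen_time)


def read_trajectory_tsv(path, species_label: str | None = None) -> NeTrajectory:
    """Read a two-column (time_years, ne) TSV trajectory."""
    df = pd.read_csv(path, sep="\t")
    need = {"time_years", "ne"}
    if not need <= set(df.columns):
        raise FormatError(f"trajectory TSV needs columns {sorted(need)}")
    label = species_label or str(df["species"].iloc[0]) if "species" in df \
        else species_label or re.sub(r"\.[^.]*$", "", str(path).split("/")[-1])
    return NeTrajectory(label, df["time_years"].to_numpy(),
                        df["ne"].to_numpy())


def write_trajectory_tsv(traj: NeTrajectory, path) -> None:
    pd.DataFrame({
        "species": traj.species_label,
        "time_years": traj.times,
        "ne": traj.ne_values,
    }).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- traits
def read_trait_table(path, tree: Phylogeny | None = None) -> TraitMap:
    """Read the species trait TSV (species, plunge, island[, ln_mass]).

    Binary columns must be 0/1.  If a tree is given the species set must
    match its tips exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    need = {"species", "plunge", "island"}
    if not need <= set(df.columns):
        raise FormatError(f"trait table needs columns {sorted(need)}")
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].tolist()
        raise FormatError(f"duplicated species rows: {dup}")
    for col in ("plunge", "island"):
        vals = set(df[col].tolist())
        if not vals <= {0, 1}:
            raise FormatError(f"non-binary value in column {col!r}: "
                              f"{sorted(vals - {0, 1})}")
    plunge = dict(zip(df["species"], df["plunge"].astype(int)))
    island = dict(zip(df["species"], df["island"].astype(int)))
    ln_mass = {}
    if "ln_mass" in df.columns:
        ln_mass = {s: float(m) for s, m in zip(df["species"], df["ln_mass"])
                   if pd.notna(m)}
    traits = TraitMap(plunge=plunge, island=island, ln_mass=ln_mass)
    if tree is not None:
        traits.validate_against(tree)
    return traits


def write_trait_table(traits: TraitMap, path) -> None:
    species = sorted(traits.plunge)
    pd.DataFrame({
        "species": species,
        "plunge": [traits.plunge[s] for s in species],
        "island": [traits.island[s] for s in species],
        "ln_mass": [traits.ln_mass.get(s, float("nan")) for s in species],
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- gene tests
@dataclass(frozen=True)
class GeneTestResult:
    """One gene-level test outcome: a p-value or posterior in [0, 1]
    (disambiguated by ``test_name``), optionally branch-specific."""

    gene_id: str
    test_name: str
    score: float
    branch_id: str | None = None
    qvalue: float | None = None

    def __post_init__(self):
        if self.test_name not in TEST_NAMES:
            raise FormatError(f"unknown test name {self.test_name!r}")
        if not 0.0 <= self.score <= 1.0:
            raise FormatError(
                f"score {self.score} outside [0, 1] for {self.gene_id!r}"
            )
        if self.qvalue is not None and not 0.0 <= self.qvalue <= 1.0:
            raise FormatError(f"q-value outside [0, 1] for {self.gene_id!r}")
        per_branch = self.test_name in PER_BRANCH_TESTS
        if per_branch and not self.branch_id:
            raise FormatError(
                f"{self.test_name} is per-branch: branch_id required"
            )
        if not per_branch and self.branch_id:
            raise FormatError(f"{self.test_name} is not per-branch")


def read_gene_test_table(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "test_name": str})
    need = {"gene_id", "test_name", "score"}
    if not need <= set(df.columns):
        raise FormatError(f"gene test table needs columns {sorted(need)}")
    out = []
    for row in df.itertuples(index=False):
        branch = getattr(row, "branch_id", None)
        if isinstance(branch, float) and np.isnan(branch):
            branch = None
        q = getattr(row, "qvalue", None)
        if q is not None and isinstance(q, float) and np.isnan(q):
            q = None
        out.append(GeneTestResult(
            gene_id=row.gene_id, test_name=row.test_name,
            score=float(row.score), branch_id=branch,
            qvalue=None if q is None else float(q),
        ))
    return out


def write_results(records, path) -> None:
    pd.DataFrame([{
        "gene_id": r.gene_id,
        "test_name": r.test_name,
        "branch_id": r.branch_id,
        "score": r.score,
        "qvalue": r.qvalue,
    } for r in records]).to_csv(path, sep="\t", index=False)
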