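"""Synthetic sequence generation under nonlinear selection and phylogeny.

Sequences are binary spin strings sigma in {-1, +1}^L carrying an additive
scalar trait tau(sigma) = sum_i D_i sigma_i, where D is a vector of
per-site mutational effects.  Selection favours a trait value tau* through
the quadratic Hamiltonian

    H(sigma) = (kappa / 2) * (tau(sigma) - tau*)^2,

and sequences are sampled by single-spin-flip Metropolis Monte Carlo.
Phylogeny is introduced by evolving one equilibrium ancestor along a
perfect binary tree (a fixed number mu of *accepted* mutations per branch)
or along an arbitrary newick tree (Poisson-distributed accepted mutations
proportional to branch length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from . import _kernels

__all__ = [
    "EffectVector",
    "SelectionParams",
    "BinaryMSA",
    "PhylogenyRecord",
    "StallError",
    "make_effect_vector",
    "kappa_for_target",
    "hamiltonian",
    "trait",
    "metropolis_step",
    "sample_equilibrium_sequence",
    "sample_equilibrium_msa",
    "evolve_on_binary_tree",
    "evolve_on_newick_tree",
    "mean_pairwise_hamming",
]

DEFAULT_EQUILIBRATION = 3000  # accepted flips; enough for energy convergence
DEFAULT_STALL_CAP = 10**6  # consecutive rejections before aborting


class StallError(RuntimeError):
    """Raised when the Metropolis chain cannot accept further mutations."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectVector:
    """Ground-truth mutational-effect vector with designated sector sites.

    Attributes
    ----------
    D : (L,) float array
        Per-site effect of flipping the site's state on the additive trait.
    sector_indices : (L_S,) int array
        Indices of the sector sites (the sites with large |D_i|).
    """

    D: np.ndarray
    sector_indices: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        idx = np.asarray(self.sector_indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= D.size):
            raise ValueError("sector_indices out of range")
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "sector_indices", idx)

    @property
    def L(self) -> int:
        return self.D.size

    @property
    def L_S(self) -> int:
        return self.sector_indices.size

    @property
    def sector_mask(self) -> np.ndarray:
        mask = np.zeros(self.L, dtype=bool)
        mask[self.sector_indices] = True
        return mask


@dataclass(frozen=True)
class SelectionParams:
    """Selection strength kappa (>= 0) and favoured trait value tau*."""

    kappa: float
    tau_star: float

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class BinaryMSA:
    """An M x L alignment of spins in {-1, +1} (int8)."""

    sequences: np.ndarray

    def __post_init__(self):
        seqs = np.asarray(self.sequences, dtype=np.int8)
        if seqs.ndim != 2 or seqs.shape[0] < 1 or seqs.shape[1] < 1:
            raise ValueError("sequences must be a non-empty 2-D array")
        if not np.isin(seqs, (-1, 1)).all():
            raise ValueError("entries must be -1 or +1")
        object.__setattr__(self, "sequences", seqs)

    @property
    def M(self) -> int:
        return self.sequences.shape[0]

    @property
    def L(self) -> int:
        return self.sequences.shape[1]


@dataclass
class PhylogenyRecord:
    """A tracked simulation along a tree: topology, all node sequences,
    the leaf alignment, and the per-site earliest-mutation generation G.

    ``G[i]`` is the smallest tree level (1 = the root's children) at which
    site i differs from the root state in any lineage; sites that never
    deviate get the sentinel ``n_levels + 1``.
    """

    topology: str  # "perfect-binary" or "newick"
    n_levels: int
    node_sequences: np.ndarray  # (n_nodes, L) int8, row 0 = root
    node_depths: np.ndarray  # (n_nodes,) int
    leaf_indices: np.ndarray  # (M,) node indices of the leaves
    G: np.ndarray  # (L,) int
    mutation_log: list = field(default_factory=list)  # per node: flip sites
    newick: Optional[str] = None
    mean_mutations_per_lineage: Optional[float] = None

    @property
    def leaf_msa(self) -> BinaryMSA:
        return BinaryMSA(self.node_sequences[self.leaf_indices])

    @property
    def root(self) -> np.ndarray:
        return self.node_sequences[0]

    @property
    def g_sentinel(self) -> int:
        return self.n_levels + 1

    # -- serialization ------------------------------------------------------

    def to_dir(self, path) -> None:
        from . import io as psio

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "tree.nwk").write_text(self._as_newick())
        leaf_set = set(self.leaf_indices.tolist())
        internal = [k for k in range(self.node_sequences.shape[0]) if k not in leaf_set]
        psio.write_binary_fasta(
            self.node_sequences[self.leaf_indices],
            path / "leaves.fasta",
            ids=[f"node{k}" for k in self.leaf_indices],
        )
        psio.write_binary_fasta(
            self.node_sequences[internal],
            path / "internal_nodes.fasta",
            ids=[f"node{k}" for k in internal],
        )
        pd.DataFrame({"site": np.arange(self.G.size), "G": self.G}).to_csv(
            path / "G.csv", index=False
        )
        rows = []
        for node, flips in enumerate(self.mutation_log):
            for order, site in enumerate(np.asarray(flips).tolist()):
                rows.append((node, order, site))
        pd.DataFrame(rows, columns=["node", "order", "site"]).to_csv(
            path / "mutation_log.csv", index=False
        )

    def _as_newick(self) -> str:
        if self.newick is not None:
            return self.newick

        def rec(k: int) -> str:
            left, right = 2 * k + 1, 2 * k + 2
            if left >= self.node_sequences.shape[0]:
                return f"node{k}:1"
            return f"({rec(left)},{rec(right)})node{k}:1"

        return rec(0) + ";\n"


# ---------------------------------------------------------------------------
# Effect vectors and the Hamiltonian
# ---------------------------------------------------------------------------


def make_effect_vector(
    L: int = 200,
    L_S: int = 20,
    sector_mean: float = 5.0,
    sector_sd: float = 0.5,
    bg_mean: float = 0.5,
    bg_sd: float = 0.5,
    flip_fraction: float = 0.0,
    seed: Optional[int] = None,
) -> EffectVector:
    """Draw a mutational-effect vector with a planted sector.

    The first ``L_S`` sites form the sector, with effects drawn from
    N(sector_mean, sector_sd^2); the remaining sites are background,
    N(bg_mean, bg_sd^2).  ``flip_fraction`` of the sector components
    (the leading ones) are multiplied by -1, producing a mixed-sign
    sector.  Defaults give a 20-site sector of mean effect 5 (variance
    0.25) over a background of mean 0.5 in a length-200 sequence.
    """
    if not 0 <= L_S <= L:
        raise ValueError("need 0 <= L_S <= L")
    if sector_sd < 0 or bg_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    if not 0 <= flip_fraction <= 1:
        raise ValueError("flip_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    D = np.empty(L)
    D[:L_S] = rng.normal(sector_mean, sector_sd, size=L_S)
    D[L_S:] = rng.normal(bg_mean, bg_sd, size=L - L_S)
    n_flip = int(round(flip_fraction * L_S))
    D[:n_flip] *= -1.0
    return EffectVector(D=D, sector_indices=np.arange(L_S))


def kappa_for_target(D, target: float = 10.0) -> float:
    """Selection strength normalised so that kappa * sum(D_i^2) = target."""
    D = np.asarray(D, dtype=float)
    return target / float(np.sum(D**2))


def trait(seq, D) -> float:
    """Additive trait tau(sigma) = sum_i D_i sigma_i."""
    return float(np.dot(np.asarray(D, float), np.asarray(seq, float)))


def hamiltonian(seq, effects: EffectVector | np.ndarray, params: SelectionParams) -> float:
    """Quadratic selection Hamiltonian (kappa/2) (tau(sigma) - tau*)^2."""
    D = effects.D if isinstance(effects, EffectVector) else np.asarray(effects, float)
    seq = np.asarray(seq)
    if seq.shape[-1] != D.size:
        raise ValueError("sequence length does not match effect vector")
    return 0.5 * params.kappa * (trait(seq, D) - params.tau_star) ** 2


# ---------------------------------------------------------------------------
# Metropolis sampling
# ---------------------------------------------------------------------------


def metropolis_step(seq, effects, params: SelectionParams, rng: np.random.Generator):
    """One proposal: flip a uniformly chosen site, accept with
    p = min(1, exp(-dH)).  Returns (new_seq, accepted)."""
    D = effects.D if isinstance(effects, EffectVector) else np.asarray(effects, float)
    seq = np.asarray(seq, dtype=np.int8)
    i = int(rng.integers(seq.size))
    tau = trait(seq, D)
    dtau = -2.0 * D[i] * seq[i]
    dH = 0.5 * params.kappa * dtau * (dtau + 2.0 * (tau - params.tau_star))
    accepted = dH <= 0 or rng.random() < np.exp(-dH)
    out = seq.copy()
    if accepted:
        out[i] = -out[i]
    return out, bool(accepted)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _run_chain(seq, D, params, n_accept, rng, stall_cap) -> np.ndarray:
    """Advance ``seq`` in place by ``n_accept`` accepted flips; return the log."""
    log = np.empty(max(n_accept, 1), dtype=np.int32)
    if n_accept == 0:
        return log[:0]
    status = _kernels.metropolis_chain(
        seq,
        np.asarray(D, float),
        float(params.kappa),
        float(params.tau_star),
        int(n_accept),
        _kernel_seed(rng),
        int(stall_cap),
        log,
    )
    if status == _kernels.STALLED:
        raise StallError(
            f"no proposal accepted within {stall_cap} consecutive attempts "
            f"(kappa={params.kappa:.4g}, tau*={params.tau_star:.4g})"
        )
    return log[:n_accept]


def _check_reachable(effects, params) -> None:
    D = effects.D if isinstance(effects, EffectVector) else np.asarray(effects, float)
    if abs(params.tau_star) > np.sum(np.abs(D)):
        warnings.warn(
            "favoured trait value tau* exceeds the maximal attainable trait "
            "sum(|D_i|); the chain will hover at the boundary",
            stacklevel=3,
        )


def sample_equilibrium_sequence(
    effects,
    params: SelectionParams,
    n_accepted: int = DEFAULT_EQUILIBRATION,
    seed: Optional[int] = None,
    stall_cap: int = DEFAULT_STALL_CAP,
) -> np.ndarray:
    """Sample one sequence from P(sigma) ~ exp(-H(sigma)).

    Starts from a uniform-random sequence and performs ``n_accepted``
    accepted Metropolis flips (proposal = flip one uniformly chosen site).
    """
    D = effects.D if isinstance(effects, EffectVector) else np.asarray(effects, float)
    _check_reachable(D, params)
    rng = np.random.default_rng(seed)
    seq = rng.choice(np.array([-1, 1], dtype=np.int8), size=D.size)
    _run_chain(seq, D, params, n_accepted, rng, stall_cap)
    return seq


def sample_equilibrium_msa(
    M: int,
    effects,
    params: SelectionParams,
    n_accepted: int = DEFAULT_EQUILIBRATION,
    seed: Optional[int] = None,
    stall_cap: int = DEFAULT_STALL_CAP,
) -> BinaryMSA:
    """M independent equilibrium sequences (the "no phylogeny" condition).

    Each row gets its own RNG stream spawned from ``seed``, so row m is
    reproducible independently of M.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    D = effects.D if isinstance(effects, EffectVector) else np.asarray(effects, float)
    _check_reachable(D, params)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(M)
    out = np.empty((M, D.size), dtype=np.int8)
    for m, child in enumerate(children):
        rng = np.random.default_rng(child)
        seq = rng.choice(np.array([-1, 1], dtype=np.int8), size=D.size)
        _run_chain(seq, D, params, n_accepted, rng, stall_cap)
        out[m] = seq
    return BinaryMSA(out)


# ---------------------------------------------------------------------------
# Evolution along trees
# ---------------------------------------------------------------------------


def _neutral_params() -> SelectionParams:
    return SelectionParams(kappa=0.0, tau_star=0.0)


def evolve_on_binary_tree(
    ancestor: Optional[np.ndarray],
    mu: int,
    n: int,
    effects,
    params: SelectionParams,
    neutral: bool = False,
    seed: Optional[int] = None,
    n_accepted_ancestor: int = DEFAULT_EQUILIBRATION,
    stall_cap: int = DEFAULT_STALL_CAP,
) -> PhylogenyRecord:
    """Evolve an ancestor along a perfect binary tree with ``n`` levels.

    Exactly ``mu`` accepted mutations occur on every branch (under the
    Metropolis criterion; every proposal accepted when ``neutral``),
    yielding 2^n leaves.  If ``ancestor`` is None it is generated
    internally: an equilibrium sequence, or uniform random when neutral.
    All node sequences, per-branch flip logs and the earliest-mutation
    generation G are retained.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    D = effects.D if isinstance(effects, EffectVector) else np.asarray(effects, float)
    run_params = _neutral_params() if neutral else params
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    anc_ss, tree_ss = ss.spawn(2)
    if ancestor is None:
        rng = np.random.default_rng(anc_ss)
        ancestor = rng.choice(np.array([-1, 1], dtype=np.int8), size=D.size)
        if not neutral:
            _check_reachable(D, params)
            _run_chain(ancestor, D, params, n_accepted_ancestor, rng, stall_cap)
    ancestor = np.asarray(ancestor, dtype=np.int8).copy()
    L = ancestor.size
    n_nodes = 2 ** (n + 1) - 1
    nodes = np.empty((n_nodes, L), dtype=np.int8)
    nodes[0] = ancestor
    depths = np.zeros(n_nodes, dtype=int)
    logs: list = [np.empty(0, dtype=np.int32)]
    branch_ss = tree_ss.spawn(n_nodes - 1)
    for k in range(1, n_nodes):
        parent = (k - 1) // 2
        depths[k] = depths[parent] + 1
        seq = nodes[parent].copy()
        rng = np.random.default_rng(branch_ss[k - 1])
        logs.append(_run_chain(seq, D, run_params, mu, rng, stall_cap))
        nodes[k] = seq
    leaf_indices = np.arange(n_nodes - 2**n, n_nodes)
    G = _earliest_generation(nodes, depths, n)
    return PhylogenyRecord(
        topology="perfect-binary",
        n_levels=n,
        node_sequences=nodes,
        node_depths=depths,
        leaf_indices=leaf_indices,
        G=G,
        mutation_log=logs,
    )


def _earliest_generation(nodes: np.ndarray, depths: np.ndarray, n_levels: int) -> np.ndarray:
    """Per site, the smallest depth >= 1 at which any node differs from the
    root; sentinel n_levels + 1 for sites that never deviate."""
    L = nodes.shape[1]
    G = np.full(L, n_levels + 1, dtype=int)
    root = nodes[0]
    for k in range(1, nodes.shape[0]):
        diff = nodes[k] != root
        np.minimum(G, np.where(diff, depths[k], n_levels + 1), out=G)
    return G


def evolve_on_newick_tree(
    ancestor: Optional[np.ndarray],
    tree,
    rate_constant: float,
    effects,
    params: SelectionParams,
    neutral: bool = False,
    seed: Optional[int] = None,
    n_accepted_ancestor: int = DEFAULT_EQUILIBRATION,
    stall_cap: int = DEFAULT_STALL_CAP,
) -> PhylogenyRecord:
    """Evolve an ancestor along an arbitrary rooted tree.

    ``tree`` is a newick string, a path to a newick file, or a
    ``dendropy.Tree``.  The number of accepted mutations on each branch is
    Poisson(rate_constant * branch_length).  Branch lengths are required.
    """
    if rate_constant <= 0:
        raise ValueError("rate_constant must be > 0")
    if isinstance(tree, dendropy.Tree):
        dtree = tree
    else:
        text = str(tree)
        if "(" not in text and Path(text).exists():
            text = Path(text).read_text()
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # tolerate duplicate labels
        )
    D = effects.D if isinstance(effects, EffectVector) else np.asarray(effects, float)
    run_params = _neutral_params() if neutral else params
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    anc_ss, tree_ss = ss.spawn(2)
    if ancestor is None:
        rng = np.random.default_rng(anc_ss)
        ancestor = rng.choice(np.array([-1, 1], dtype=np.int8), size=D.size)
        if not neutral:
            _check_reachable(D, params)
            _run_chain(ancestor, D, params, n_accepted_ancestor, rng, stall_cap)
    ancestor = np.asarray(ancestor, dtype=np.int8).copy()
    L = ancestor.size

    order = list(dtree.preorder_node_iter())
    index = {id(node): k for k, node in enumerate(order)}
    n_nodes = len(order)
    nodes_arr = np.empty((n_nodes, L), dtype=np.int8)
    depths = np.zeros(n_nodes, dtype=int)
    logs: list = [np.empty(0, dtype=np.int32)] * n_nodes
    nodes_arr[0] = ancestor
    branch_ss = tree_ss.spawn(max(n_nodes - 1, 1))
    leaf_idx = []
    for node in order:
        k = index[id(node)]
        if node is dtree.seed_node:
            if node.is_leaf():
                leaf_idx.append(k)
            continue
        parent = index[id(node.parent_node)]
        depths[k] = depths[parent] + 1
        length = node.edge.length
        if length is None:
            raise ValueError("newick tree must carry branch lengths on every edge")
        rng = np.random.default_rng(branch_ss[k - 1])
        m = int(rng.poisson(rate_constant * float(length)))
        seq = nodes_arr[parent].copy()
        logs[k] = _run_chain(seq, D, run_params, m, rng, stall_cap)
        nodes_arr[k] = seq
        if node.is_leaf():
            leaf_idx.append(k)

    leaf_indices = np.array(leaf_idx, dtype=int)
    n_levels = int(depths.max()) if n_nodes > 1 else 1
    G = _earliest_generation(nodes_arr, depths, n_levels)
    per_lineage = []
    for k in leaf_idx:
        total, node = 0, order[k]
        while node is not dtree.seed_node:
            total += logs[index[id(node)]].size
            node = node.parent_node
        per_lineage.append(total)
    return PhylogenyRecord(
        topology="newick",
        n_levels=n_levels,
        node_sequences=nodes_arr,
        node_depths=depths,
        leaf_indices=leaf_indices,
        G=G,
        mutation_log=logs,
        newick=dtree.as_string(schema="newick"),
        mean_mutations_per_lineage=float(np.mean(per_lineage)) if per_lineage else 0.0,
    )


def mean_pairwise_hamming(msa) -> float:
    """Average over all unordered sequence pairs of the fraction of
    differing sites."""
    seqs = msa.sequences if isinstance(msa, BinaryMSA) else np.asarray(msa, dtype=np.int8)
    if seqs.shape[0] < 2:
        raise ValueError("need at least two sequences")
    return float(_kernels.pairwise_hamming_mean(np.ascontiguousarray(seqs)))
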