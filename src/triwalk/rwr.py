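"""Random walk with restart on the composite network.

The walker iterates

    p_{k+1} = (1 - alpha) * W p_k + alpha * p_0

where ``alpha`` is the restart probability, ``W`` the column-stochastic
transition matrix and ``p_0`` the seed-weighted initial distribution.
Iteration stops when the L1 change between successive iterates falls below
``tol``.  Column ``j`` of ``W`` holds the distribution of moves out of node
``j`` (entry (i, j) is the probability of stepping j -> i), so ``W`` left-
multiplies the probability vector.

Transition construction.  From a node in one layer the outgoing mass is
budgeted per destination block using the jumping probabilities: from a gene,
``x`` to phenotypes and ``y`` to metabolites (remainder within-layer); from a
phenotype, ``x`` to genes and ``z`` to metabolites; from a metabolite, ``y``
to genes and ``z`` to phenotypes.  Within each destination block the mass is
split proportionally to edge weight.  Two reallocation rules keep columns
stochastic when blocks are missing:

* R1 — mass budgeted for a cross block in which the node has no edges is
  reassigned to its within-layer block.
* R2 — if the within-layer block is also empty, the within-layer mass is
  split among the present cross blocks proportionally to their nominal
  budgets (equally if those budgets are all zero).

A node with no edges at all yields an all-zero (dangling) column; such nodes
retain only restart mass and are reported in the transition's dangling list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .composite import LAYERS, CompositeNetwork, ValidationError

#: Largest system size accepted by the direct solver.
_CLOSED_FORM_MAX_NODES = 20_000


@dataclass(frozen=True)
class RWRParams:
    """All model knobs in one place.

    alpha : restart probability in (0, 1].
    x, y, z : jumping probabilities gene<->phenotype, gene<->metabolite,
        phenotype<->metabolite; per-layer outgoing budgets must not exceed 1
        (x + y, x + z and y + z each <= 1).
    a, b : initial restart mass on the gene and phenotype seed layers; the
        metabolite layer receives 1 - a - b.
    tol : L1 convergence threshold; max_iter : iteration cap.
    """

    alpha: float = 0.7
    x: float = 1.0 / 3.0
    y: float = 1.0 / 3.0
    z: float = 1.0 / 3.0
    a: float = 1.0 / 3.0
    b: float = 1.0 / 3.0
    tol: float = 1e-10
    max_iter: int = 1_000_000

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError(f"alpha must lie in (0, 1], got {self.alpha}")
        for name in ("x", "y", "z", "a", "b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for pair, total in (("x + y", self.x + self.y),
                            ("x + z", self.x + self.z),
                            ("y + z", self.y + self.z)):
            if total > 1.0 + 1e-12:
                raise ValidationError(
                    f"jumping budgets violate {pair} <= 1 (got {total})")
        if self.a + self.b > 1.0 + 1e-12:
            raise ValidationError(f"a + b must not exceed 1 (got {self.a + self.b})")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be a positive integer")

    def replace(self, **kwargs) -> "RWRParams":
        from dataclasses import replace as _replace
        return _replace(self, **kwargs)


@dataclass(frozen=True)
class SeedSet:
    """The phenotype of interest plus its known genes and metabolites."""

    phenotype_seeds: frozenset[str] = frozenset()
    gene_seeds: frozenset[str] = frozenset()
    metabolite_seeds: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "phenotype_seeds", frozenset(self.phenotype_seeds))
        object.__setattr__(self, "gene_seeds", frozenset(self.gene_seeds))
        object.__setattr__(self, "metabolite_seeds", frozenset(self.metabolite_seeds))
        if not (self.phenotype_seeds or self.gene_seeds or self.metabolite_seeds):
            raise ValidationError("seed set is empty: at least one seed is required")

    def validate_in(self, net: CompositeNetwork) -> None:
        for layer, seeds, index in (
            ("phenotype", self.phenotype_seeds, net.phenotype_index),
            ("gene", self.gene_seeds, net.gene_index),
            ("metabolite", self.metabolite_seeds, net.metabolite_index),
        ):
            for s in seeds:
                if s not in index:
                    raise ValidationError(f"{layer} seed {s!r} not in network")

    def layer_counts(self) -> tuple[int, int, int]:
        return len(self.gene_seeds), len(self.phenotype_seeds), len(self.metabolite_seeds)


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix plus the dangling-node report."""

    matrix: sp.csr_array
    dangling: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


# Cross budgets: budget from source layer s to target layer t.  Layer order is
# (gene, phenotype, metabolite); the diagonal (within-layer remainder) is
# filled in build_transition.
def _budget_matrix(x: float, y: float, z: float) -> np.ndarray:
    return np.array([
        [1.0 - x - y, x, y],
        [x, 1.0 - x - z, z],
        [y, z, 1.0 - y - z],
    ])


def build_transition(net: CompositeNetwork, x: float, y: float, z: float) -> TransitionMatrix:
    """Build the column-stochastic transition matrix with jumping probabilities."""
    if net.n_nodes == 0:
        raise ValidationError("cannot build a transition matrix on an empty network")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    for pair, total in (("x + y", x + y), ("x + z", x + z), ("y + z", y + z)):
        if total > 1.0 + 1e-12:
            raise ValidationError(f"jumping budgets violate {pair} <= 1 (got {total})")

    n = net.n_nodes
    sizes = net.layer_sizes
    layer_of = np.repeat(np.arange(3), sizes)
    A = net.full_adjacency().tocoo()

    # Per-column mass into each target layer.
    blocksum = np.zeros((3, n))
    np.add.at(blocksum, (layer_of[A.row], A.col), A.data)
    present = blocksum > 0.0

    budget = _budget_matrix(x, y, z)
    mass = np.zeros((3, n))
    start = 0
    for s, size in enumerate(sizes):
        cols = slice(start, start + size)
        start += size
        if size == 0:
            continue
        t1, t2 = [t for t in range(3) if t != s]
        p_w = present[s, cols]
        p1 = present[t1, cols]
        p2 = present[t2, cols]
        m1 = np.where(p1, budget[s, t1], 0.0)
        m2 = np.where(p2, budget[s, t2], 0.0)
        # R1: absent cross-block budgets fall back to the within-layer block.
        mw = budget[s, s] + np.where(p1, 0.0, budget[s, t1]) + np.where(p2, 0.0, budget[s, t2])
        # R2: absent within-layer block redistributes to present cross blocks.
        need = ~p_w & (p1 | p2)
        denom = m1 + m2
        add1 = np.zeros(size)
        add2 = np.zeros(size)
        prop = need & (denom > 0.0)
        add1[prop] = mw[prop] * m1[prop] / denom[prop]
        add2[prop] = mw[prop] * m2[prop] / denom[prop]
        even = need & (denom == 0.0)
        if even.any():
            count = p1.astype(float) + p2.astype(float)
            add1[even] = mw[even] * p1[even] / count[even]
            add2[even] = mw[even] * p2[even] / count[even]
        mass[t1, cols] = m1 + add1
        mass[t2, cols] = m2 + add2
        mass[s, cols] = np.where(p_w, mw, 0.0)

    scale = np.zeros_like(A.data)
    tgt = layer_of[A.row]
    scale = mass[tgt, A.col] / blocksum[tgt, A.col]
    W = sp.csr_array(sp.coo_array((A.data * scale, (A.row, A.col)), shape=(n, n)))

    dangling_mask = ~present.any(axis=0)
    dangling: list[tuple[str, str]] = []
    if dangling_mask.any():
        all_ids = net.genes + net.phenotypes + net.metabolites
        layer_names = np.array(LAYERS)[layer_of]
        dangling = [(str(layer_names[i]), all_ids[i])
                    for i in np.flatnonzero(dangling_mask)]
    return TransitionMatrix(W, dangling)


def build_initial(net: CompositeNetwork, seeds: SeedSet, a: float, b: float) -> np.ndarray:
    """Seed-weighted initial distribution over all composite nodes.

    Gene seeds share mass ``a`` equally, phenotype seeds mass ``b``,
    metabolite seeds mass ``1 - a - b``.  Mass budgeted for a layer without
    seeds is redistributed proportionally to the layers that do have seeds,
    so the vector always sums to 1.
    """
    for name, v in (("a", a), ("b", b)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    if a + b > 1.0 + 1e-12:
        raise ValidationError(f"a + b must not exceed 1 (got {a + b})")
    seeds.validate_in(net)

    nominal = np.array([a, b, 1.0 - a - b])
    seed_lists = (sorted(seeds.gene_seeds), sorted(seeds.phenotype_seeds),
                  sorted(seeds.metabolite_seeds))
    seeded = np.array([bool(s) for s in seed_lists])
    active = nominal * seeded
    total = active.sum()
    if total > 0:
        layer_mass = active / total
    else:  # all seeded layers carry zero nominal weight: split equally
        layer_mass = seeded / seeded.sum()

    p0 = np.zeros(net.n_nodes)
    indexes = (net.gene_index, net.phenotype_index, net.metabolite_index)
    for layer, (ids, off, index) in enumerate(zip(seed_lists, net.offsets, indexes)):
        if not ids:
            continue
        share = layer_mass[layer] / len(ids)
        for node in ids:
            p0[off + index[node]] = share
    return p0


@dataclass
class PropagationResult:
    steady: np.ndarray
    n_iter: int
    converged: bool


def propagate(W: sp.csr_array, p0: np.ndarray, alpha: float,
              tol: float = 1e-10, max_iter: int = 1_000_000) -> PropagationResult:
    """Iterate the restart walk to its steady state (L1 stopping rule).

    Dangling (all-zero) columns are allowed: their nodes keep only the
    restart mass ``alpha * p0`` re-injected each step.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must lie in (0, 1], got {alpha}")
    p = np.asarray(p0, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"p0 must sum to 1, got {p.sum()!r}")
    restart = alpha * p
    for k in range(1, max_iter + 1):
        p_next = (1.0 - alpha) * (W @ p) + restart
        if np.abs(p_next - p).sum() < tol:
            return PropagationResult(p_next, k, True)
        p = p_next
    warnings.warn(
        f"propagation did not converge within {max_iter} iterations "
        f"(last L1 change above {tol})", stacklevel=2)
    return PropagationResult(p, max_iter, False)


def solve_closed_form(W: sp.csr_array, p0: np.ndarray, alpha: float) -> np.ndarray:
    """Direct solve of the fixed point p = (1 - alpha) W p + alpha p0.

    Independent oracle for :func:`propagate`; guarded to systems of at most
    20,000 nodes.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must lie in (0, 1], got {alpha}")
    n = W.shape[0]
    if n > _CLOSED_FORM_MAX_NODES:
        raise ValidationError(
            f"closed-form solve limited to {_CLOSED_FORM_MAX_NODES} nodes (got {n})")
    if alpha == 1.0:
        return np.asarray(p0, dtype=float).copy()
    system = sp.eye_array(n, format="csc") - (1.0 - alpha) * sp.csc_array(W)
    return spla.spsolve(system, alpha * np.asarray(p0, dtype=float))
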