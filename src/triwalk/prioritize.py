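"""Candidate metabolite ranking and permutation-based significance.

Candidates are ranked by their steady-state probability.  Empirical p-values
come from a degree-preserving permutation null: each sub-network is rewired by
double-edge swaps (degrees fixed, weights travelling with their edges), a
random seed set of the same per-layer sizes is drawn, and the walk is re-run;
a candidate's p-value is the add-one fraction of null scores at least as large
as its observed score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .composite import CompositeNetwork, ValidationError
from .rwr import (RWRParams, SeedSet, TransitionMatrix, build_initial,
                  build_transition, propagate)

logger = logging.getLogger("triwalk")

CANDIDATE_MODES = ("metabolome_wide", "explicit_list", "random_k")


@dataclass(frozen=True)
class CandidateSet:
    """Which metabolites compete in a ranking.

    ``metabolome_wide`` takes every metabolite node minus the metabolite
    seeds; ``explicit_list`` takes ``ids``; ``random_k`` draws ``k - 1``
    non-seed metabolites uniformly without replacement plus the designated
    ``include`` metabolite (or ``k`` if none is designated).
    """

    mode: str = "metabolome_wide"
    ids: tuple[str, ...] = ()
    k: int = 0
    rng_seed: int = 0
    include: str | None = None

    def __post_init__(self):
        if self.mode not in CANDIDATE_MODES:
            raise ValidationError(
                f"candidate mode must be one of {CANDIDATE_MODES}, got {self.mode!r}")
        if self.mode == "explicit_list" and not self.ids:
            raise ValidationError("explicit_list candidate set requires ids")
        if self.mode == "random_k" and self.k < 1:
            raise ValidationError("random_k candidate set requires k >= 1")

    def resolve(self, net: CompositeNetwork, seeds: SeedSet) -> list[str]:
        """Materialize the candidate id list for a given network and seed set."""
        excluded = seeds.metabolite_seeds
        if self.mode == "metabolome_wide":
            out = [m for m in net.metabolites if m not in excluded]
        elif self.mode == "explicit_list":
            for m in self.ids:
                if m not in net.metabolite_index:
                    raise ValidationError(f"candidate metabolite {m!r} not in network")
            out = [m for m in self.ids if m not in excluded]
        else:  # random_k
            pool = [m for m in net.metabolites
                    if m not in excluded and m != self.include]
            n_draw = self.k - (1 if self.include is not None else 0)
            if n_draw > len(pool):
                raise ValidationError(
                    f"random_k asks for {n_draw} metabolites but only "
                    f"{len(pool)} are available")
            rng = np.random.default_rng(self.rng_seed)
            drawn = list(rng.choice(np.array(pool, dtype=object), size=n_draw,
                                    replace=False))
            if self.include is not None:
                if self.include not in net.metabolite_index:
                    raise ValidationError(
                        f"designated metabolite {self.include!r} not in network")
                drawn.append(self.include)
            out = sorted(str(m) for m in drawn)
        if not out:
            raise ValidationError("candidate set is empty after seed exclusions")
        return out


@dataclass
class PrioritizationResult:
    """Ranked candidates with scores and, optionally, permutation p-values.

    ``table`` columns: metabolite_id, score, rank, tied [, p_value].  Ranks
    are 1..n by descending score; exact score ties are broken by lexicographic
    metabolite id and flagged in ``tied``.
    """

    table: pd.DataFrame
    steady: np.ndarray
    converged: bool
    n_iter: int
    dangling: list[tuple[str, str]] = field(default_factory=list)

    def scores(self) -> pd.Series:
        return self.table.set_index("metabolite_id")["score"]


def _rank_table(cand_ids: list[str], cand_scores: np.ndarray) -> pd.DataFrame:
    order = sorted(range(len(cand_ids)),
                   key=lambda i: (-cand_scores[i], cand_ids[i]))
    ids = [cand_ids[i] for i in order]
    scores = cand_scores[np.array(order)]
    tied = np.zeros(len(ids), dtype=bool)
    for i in range(1, len(ids)):
        if scores[i] == scores[i - 1]:
            tied[i] = tied[i - 1] = True
    return pd.DataFrame({
        "metabolite_id": ids,
        "score": scores,
        "rank": np.arange(1, len(ids) + 1),
        "tied": tied,
    })


def _steady_state(net: CompositeNetwork, seeds: SeedSet, params: RWRParams,
                  transition: TransitionMatrix | None = None):
    seeds.validate_in(net)
    trans = transition if transition is not None else build_transition(
        net, params.x, params.y, params.z)
    p0 = build_initial(net, seeds, params.a, params.b)
    prop = propagate(trans.matrix, p0, params.alpha, params.tol, params.max_iter)
    return trans, prop


def prioritize(net: CompositeNetwork, seeds: SeedSet, params: RWRParams,
               candidates: CandidateSet) -> PrioritizationResult:
    """Rank candidate metabolites by steady-state proximity to the seeds."""
    cand_ids = candidates.resolve(net, seeds)
    trans, prop = _steady_state(net, seeds, params)
    off = net.offsets[2]
    idx = np.array([off + net.metabolite_index[m] for m in cand_ids])
    table = _rank_table(cand_ids, prop.steady[idx])
    return PrioritizationResult(table, prop.steady, prop.converged,
                                prop.n_iter, trans.dangling)


# ---------------------------------------------------------------------------
# Degree-preserving rewiring
# ---------------------------------------------------------------------------

def _swap_within(rows, cols, data, n, rng, swaps_per_edge):
    """Double-edge swaps on an undirected simple graph; weights stay with edges."""
    edges = [[int(u), int(v)] for u, v in zip(rows, cols)]
    existing = {frozenset(e) for e in edges}
    n_edges = len(edges)
    target = swaps_per_edge * n_edges
    done = 0
    attempts = 0
    max_attempts = 40 * target
    while done < target and attempts < max_attempts:
        attempts += 1
        e, f = rng.integers(0, n_edges, size=2)
        if e == f:
            continue
        u, v = edges[e]
        x, y = edges[f]
        if rng.integers(0, 2):
            x, y = y, x
        # proposed: (u, x) and (v, y)
        if u == x or v == y:
            continue
        new1, new2 = frozenset((u, x)), frozenset((v, y))
        old1, old2 = frozenset((u, v)), frozenset((x, y))
        if new1 in existing or new2 in existing or new1 == new2:
            continue
        existing.discard(old1)
        existing.discard(old2)
        existing.add(new1)
        existing.add(new2)
        edges[e] = [u, x]
        edges[f] = [v, y]
        done += 1
    if done < target:
        logger.info("within-layer rewiring stopped after %d/%d swaps", done, target)
    r = np.array([e[0] for e in edges])
    c = np.array([e[1] for e in edges])
    return sp.csr_array(sp.coo_array(
        (np.concatenate([data, data]),
         (np.concatenate([r, c]), np.concatenate([c, r]))), shape=(n, n)))


def _swap_bipartite(rows, cols, data, shape, rng, swaps_per_edge):
    """Target-swapping double-edge swaps on a bipartite graph."""
    edges = [[int(s), int(t)] for s, t in zip(rows, cols)]
    existing = {(s, t) for s, t in edges}
    n_edges = len(edges)
    target = swaps_per_edge * n_edges
    done = 0
    attempts = 0
    max_attempts = 40 * target
    while done < target and attempts < max_attempts:
        attempts += 1
        e, f = rng.integers(0, n_edges, size=2)
        if e == f:
            continue
        s1, t1 = edges[e]
        s2, t2 = edges[f]
        if t1 == t2 or s1 == s2:
            continue
        new1, new2 = (s1, t2), (s2, t1)
        if new1 in existing or new2 in existing:
            continue
        existing.discard((s1, t1))
        existing.discard((s2, t2))
        existing.add(new1)
        existing.add(new2)
        edges[e] = [s1, t2]
        edges[f] = [s2, t1]
        done += 1
    if done < target:
        logger.info("bipartite rewiring stopped after %d/%d swaps", done, target)
    r = np.array([e[0] for e in edges])
    c = np.array([e[1] for e in edges])
    return sp.csr_array(sp.coo_array((data, (r, c)), shape=shape))


def rewire_preserving_degrees(net: CompositeNetwork, rng_seed: int,
                              swaps_per_edge: int = 10) -> CompositeNetwork:
    """Rewire each of the six sub-networks independently, preserving degrees.

    Within-layer swaps preserve within-layer degree sequences; bipartite swaps
    preserve the degree sequences of both sides.  Sub-networks with fewer than
    two edges are returned unchanged.
    """
    if swaps_per_edge < 1:
        raise ValidationError("swaps_per_edge must be >= 1")
    rng = np.random.default_rng(rng_seed)
    new = {}
    for name in ("gg", "pp", "mm"):
        mat = getattr(net, name)
        coo = sp.triu(mat, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        if len(order) < 2:
            if len(order):
                logger.info("sub-network %s has < 2 edges; left unchanged", name)
            new[name] = mat.copy()
            continue
        new[name] = _swap_within(coo.row[order], coo.col[order],
                                 coo.data[order], mat.shape[0], rng, swaps_per_edge)
    for name in ("gm", "pg", "pm"):
        mat = getattr(net, name)
        coo = mat.tocoo()
        order = np.lexsort((coo.col, coo.row))
        if len(order) < 2:
            if len(order):
                logger.info("sub-network %s has < 2 edges; left unchanged", name)
            new[name] = mat.copy()
            continue
        new[name] = _swap_bipartite(coo.row[order], coo.col[order],
                                    coo.data[order], mat.shape, rng, swaps_per_edge)
    return CompositeNetwork(net.genes, net.phenotypes, net.metabolites, **new)


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------

def _draw_null_seeds(net: CompositeNetwork, counts: tuple[int, int, int],
                     rng: np.random.Generator) -> SeedSet:
    n_genes, n_phen, n_met = counts
    def draw(pool, k):
        if k == 0:
            return frozenset()
        if k > len(pool):
            raise ValidationError(
                f"cannot draw {k} null seeds from a layer of {len(pool)} nodes")
        picked = rng.choice(len(pool), size=k, replace=False)
        return frozenset(pool[i] for i in picked)
    return SeedSet(
        phenotype_seeds=draw(net.phenotypes, n_phen),
        gene_seeds=draw(net.genes, n_genes),
        metabolite_seeds=draw(net.metabolites, n_met),
    )


def permutation_pvalues(net: CompositeNetwork, seeds: SeedSet, params: RWRParams,
                        candidates: CandidateSet, n_perm: int = 1000,
                        rng_seed: int = 0,
                        swaps_per_edge: int = 10) -> PrioritizationResult:
    """Attach degree-preserving permutation p-values to a prioritization.

    For each of ``n_perm`` permutations the six sub-networks are rewired
    degree-preservingly, a random seed set with the observed per-layer seed
    counts is drawn, and every candidate's null score is recorded.  The
    p-value is the add-one estimator

        p = (1 + #{null score >= observed score}) / (1 + n_perm)

    so p is never 0 and lies in [1/(n_perm + 1), 1].  Deterministic given
    ``rng_seed``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = prioritize(net, seeds, params, candidates)
    cand_ids = list(observed.table["metabolite_id"])
    obs_scores = observed.table["score"].to_numpy()
    counts = seeds.layer_counts()
    rng = np.random.default_rng(rng_seed)
    off = net.offsets[2]
    idx = np.array([off + net.metabolite_index[m] for m in cand_ids])
    exceed = np.zeros(len(cand_ids), dtype=np.int64)
    for _ in range(n_perm):
        rewire_seed = int(rng.integers(0, 2**31 - 1))
        null_net = rewire_preserving_degrees(net, rewire_seed, swaps_per_edge)
        null_seeds = _draw_null_seeds(null_net, counts, rng)
        _, prop = _steady_state(null_net, null_seeds, params)
        exceed += prop.steady[idx] >= obs_scores
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    table = observed.table.copy()
    table["p_value"] = pvals
    return PrioritizationResult(table, observed.steady, observed.converged,
                                observed.n_iter, observed.dangling)
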