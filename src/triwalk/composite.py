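"""Three-layer composite network: data model, TSV I/O, bundle archive, noise model.

The composite network has three node layers (genes, phenotypes, metabolites)
joined by six weighted sub-networks: three undirected within-layer association
networks (gene-gene, phenotype-phenotype, metabolite-metabolite) and three
bipartite cross-layer networks (gene-metabolite, phenotype-gene,
phenotype-metabolite).  Edge weights are non-negative confidence scores.  The
full block adjacency

    A = [[A_GG, A_PG^T, A_GM ],
         [A_PG, A_PP,   A_PM ],
         [A_GM^T, A_PM^T, A_MM]]

is symmetric by construction; node order is genes, then phenotypes, then
metabolites, each layer sorted lexicographically by id.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("triwalk")

#: Layer names, in block order.
LAYERS = ("gene", "phenotype", "metabolite")

#: Bundle archive format version (bumped on incompatible layout changes).
BUNDLE_FORMAT_VERSION = 1


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class EdgeListParseError(ValidationError):
    """Raised for malformed edge-list lines; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _check_layer(layer: str) -> str:
    if layer not in LAYERS:
        raise ValidationError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    return layer


# ---------------------------------------------------------------------------
# Weighted edge lists
# ---------------------------------------------------------------------------

@dataclass
class WeightedEdgeList:
    """Canonicalized list of weighted edges between two layers.

    Within-layer lists (``source_layer == target_layer``) are undirected:
    each pair is stored once with ``source_id < target_id`` and self-loops
    are rejected.  Zero-weight edges are dropped; duplicate pairs keep the
    maximum weight (confidence-score semantics).
    """

    source_layer: str
    target_layer: str
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        _check_layer(self.source_layer)
        _check_layer(self.target_layer)

    @property
    def within_layer(self) -> bool:
        return self.source_layer == self.target_layer

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def source_ids(self) -> set[str]:
        ids = {u for u, _, _ in self.edges}
        if self.within_layer:
            ids |= {v for _, v, _ in self.edges}
        return ids

    def target_ids(self) -> set[str]:
        ids = {v for _, v, _ in self.edges}
        if self.within_layer:
            ids |= {u for u, _, _ in self.edges}
        return ids


def _canonicalize_edges(
    raw: list[tuple[str, str, float]],
    within_layer: bool,
    origin: str = "<memory>",
) -> list[tuple[str, str, float]]:
    """Drop zero weights, fold undirected duplicates, keep max weight."""
    merged: dict[tuple[str, str], float] = {}
    n_zero = 0
    n_dup = 0
    for u, v, w in raw:
        if w == 0.0:
            n_zero += 1
            continue
        key = (min(u, v), max(u, v)) if within_layer else (u, v)
        if key in merged:
            n_dup += 1
            merged[key] = max(merged[key], w)
        else:
            merged[key] = w
    if n_zero or n_dup:
        logger.info(
            "%s: dropped %d zero-weight edges, merged %d duplicates (kept max weight)",
            origin, n_zero, n_dup,
        )
    return [(u, v, w) for (u, v), w in sorted(merged.items())]


def read_edge_list(path, source_layer: str, target_layer: str) -> WeightedEdgeList:
    """Read a 3-column TSV (source_id, target_id, weight) into an edge list.

    A header row is auto-detected (third field fails to parse as a number).
    Raises :class:`EdgeListParseError` for malformed lines, and
    :class:`ValidationError` for negative weights or within-layer self-loops.
    """
    _check_layer(source_layer)
    _check_layer(target_layer)
    within = source_layer == target_layer
    raw: list[tuple[str, str, float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise EdgeListParseError(
                    f"expected 3 tab-separated fields, got {len(fields)}", lineno
                )
            u, v, wtext = fields
            if not u or not v:
                raise EdgeListParseError("empty node id", lineno)
            try:
                w = float(wtext)
            except ValueError:
                if lineno == 1 and not raw:
                    continue  # header row
                raise EdgeListParseError(
                    f"weight {wtext!r} is not a number", lineno
                ) from None
            if not np.isfinite(w):
                raise EdgeListParseError(f"non-finite weight {wtext!r}", lineno)
            if w < 0:
                raise ValidationError(
                    f"{path}, line {lineno}: negative weight {w} for edge ({u}, {v})"
                )
            if within and u == v:
                raise ValidationError(
                    f"{path}, line {lineno}: self-loop on {u!r} in a within-layer list"
                )
            raw.append((u, v, w))
    edges = _canonicalize_edges(raw, within, origin=str(path))
    return WeightedEdgeList(source_layer, target_layer, edges)


def write_edge_list(edge_list: WeightedEdgeList, path) -> None:
    """Write a canonicalized edge list as headerless 3-column TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v, w in edge_list.edges:
            fh.write(f"{u}\t{v}\t{w!r}\n")


def edge_list_from_pairs(
    source_layer: str,
    target_layer: str,
    pairs: list[tuple[str, str, float]],
) -> WeightedEdgeList:
    """Build a canonicalized edge list from in-memory (u, v, w) triples."""
    within = source_layer == target_layer
    for u, v, w in pairs:
        if w < 0:
            raise ValidationError(f"negative weight {w} for edge ({u}, {v})")
        if within and u == v:
            raise ValidationError(f"self-loop on {u!r} in a within-layer list")
    return WeightedEdgeList(
        source_layer, target_layer, _canonicalize_edges(list(pairs), within)
    )


# ---------------------------------------------------------------------------
# Composite network
# ---------------------------------------------------------------------------

def _sym_from_edges(edges, index: dict[str, int], n: int) -> sp.csr_array:
    if not edges or n == 0:
        return sp.csr_array((n, n))
    rows, cols, data = [], [], []
    for u, v, w in edges:
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    return sp.csr_array(sp.coo_array((data, (rows, cols)), shape=(n, n)))


def _bip_from_edges(edges, row_index, col_index, shape) -> sp.csr_array:
    if not edges or 0 in shape:
        return sp.csr_array(shape)
    rows = [row_index[u] for u, _, _ in edges]
    cols = [col_index[v] for _, v, _ in edges]
    data = [w for _, _, w in edges]
    return sp.csr_array(sp.coo_array((data, (rows, cols)), shape=shape))


@dataclass
class CompositeNetwork:
    """The object the walker moves on: three node layers plus six sub-networks.

    Within-layer matrices (``gg``, ``pp``, ``mm``) are symmetric with zero
    diagonal; cross-layer matrices are oriented ``gm`` gene x metabolite,
    ``pg`` phenotype x gene, ``pm`` phenotype x metabolite.
    """

    genes: list[str]
    phenotypes: list[str]
    metabolites: list[str]
    gg: sp.csr_array
    pp: sp.csr_array
    mm: sp.csr_array
    gm: sp.csr_array
    pg: sp.csr_array
    pm: sp.csr_array

    def __post_init__(self):
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._phenotype_index = {p: i for i, p in enumerate(self.phenotypes)}
        self._metabolite_index = {m: i for i, m in enumerate(self.metabolites)}
        self.validate()

    # -- indexing ----------------------------------------------------------
    @property
    def gene_index(self) -> dict[str, int]:
        return self._gene_index

    @property
    def phenotype_index(self) -> dict[str, int]:
        return self._phenotype_index

    @property
    def metabolite_index(self) -> dict[str, int]:
        return self._metabolite_index

    def layer_nodes(self, layer: str) -> list[str]:
        return {"gene": self.genes, "phenotype": self.phenotypes,
                "metabolite": self.metabolites}[_check_layer(layer)]

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return len(self.genes), len(self.phenotypes), len(self.metabolites)

    @property
    def n_nodes(self) -> int:
        return sum(self.layer_sizes)

    @property
    def offsets(self) -> tuple[int, int, int]:
        """Global index offset of each layer in (gene, phenotype, metabolite) order."""
        ng, np_, _ = self.layer_sizes
        return 0, ng, ng + np_

    def global_index(self, layer: str, node_id: str) -> int:
        off = dict(zip(LAYERS, self.offsets))
        idx = {"gene": self._gene_index, "phenotype": self._phenotype_index,
               "metabolite": self._metabolite_index}[_check_layer(layer)]
        if node_id not in idx:
            raise ValidationError(f"{layer} node {node_id!r} not in network")
        return off[layer] + idx[node_id]

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        ng, np_, nm = self.layer_sizes
        for name, ids, n in (("genes", self.genes, ng),
                             ("phenotypes", self.phenotypes, np_),
                             ("metabolites", self.metabolites, nm)):
            if len(set(ids)) != n:
                raise ValidationError(f"duplicate node ids in layer {name}")
        shapes = {"gg": (ng, ng), "pp": (np_, np_), "mm": (nm, nm),
                  "gm": (ng, nm), "pg": (np_, ng), "pm": (np_, nm)}
        for name, shape in shapes.items():
            mat = getattr(self, name)
            if mat.shape != shape:
                raise ValidationError(
                    f"block {name} has shape {mat.shape}, expected {shape}"
                )
            if mat.nnz and mat.data.min() < 0:
                raise ValidationError(f"block {name} contains negative weights")
        for name in ("gg", "pp", "mm"):
            mat = getattr(self, name)
            if mat.shape[0]:
                if abs(mat - mat.T).sum() > 0:
                    raise ValidationError(f"within-layer block {name} is not symmetric")
                if mat.diagonal().any():
                    raise ValidationError(f"within-layer block {name} has a nonzero diagonal")

    # -- assembly ----------------------------------------------------------
    def full_adjacency(self) -> sp.csr_array:
        """Symmetric block adjacency over all nodes (gene, phenotype, metabolite order)."""
        blocks = [
            [self.gg, self.pg.T, self.gm],
            [self.pg, self.pp, self.pm],
            [self.gm.T, self.pm.T, self.mm],
        ]
        return sp.csr_array(sp.bmat(blocks, format="csr"))

    def to_edge_lists(self) -> dict[str, WeightedEdgeList]:
        """Export the six sub-networks as canonicalized edge lists."""
        out: dict[str, WeightedEdgeList] = {}
        for key, mat, rows, cols, within in (
            ("gg", self.gg, self.genes, self.genes, True),
            ("pp", self.pp, self.phenotypes, self.phenotypes, True),
            ("mm", self.mm, self.metabolites, self.metabolites, True),
            ("gm", self.gm, self.genes, self.metabolites, False),
            ("pg", self.pg, self.phenotypes, self.genes, False),
            ("pm", self.pm, self.phenotypes, self.metabolites, False),
        ):
            coo = mat.tocoo()
            pairs = []
            for i, j, w in zip(coo.row, coo.col, coo.data):
                if within and i >= j:
                    continue
                pairs.append((rows[i], cols[j], float(w)))
            src_layer = "gene" if key in ("gg", "gm") else ("metabolite" if key == "mm" else "phenotype")
            tgt_layer = {"gg": "gene", "pp": "phenotype", "mm": "metabolite",
                         "gm": "metabolite", "pg": "gene", "pm": "metabolite"}[key]
            out[key] = edge_list_from_pairs(src_layer, tgt_layer, pairs)
        return out

    def summary(self) -> dict:
        """Node and edge counts per sub-network (Table-1 style layout)."""
        def undirected_count(mat):
            return int(mat.nnz // 2)

        return {
            "n_genes": len(self.genes),
            "n_phenotypes": len(self.phenotypes),
            "n_metabolites": len(self.metabolites),
            "edges": {
                "gene-gene": undirected_count(self.gg),
                "phenotype-phenotype": undirected_count(self.pp),
                "metabolite-metabolite": undirected_count(self.mm),
                "gene-metabolite": int(self.gm.nnz),
                "phenotype-gene": int(self.pg.nnz),
                "phenotype-metabolite": int(self.pm.nnz),
            },
        }

    # -- derived networks --------------------------------------------------
    def without_pm_edges(self, phenotype: str, metabolites) -> "CompositeNetwork":
        """Clone with the given phenotype-metabolite links removed.

        Observationally equivalent to a fresh network; used to hold out
        annotation links during cross-validation.
        """
        if phenotype not in self._phenotype_index:
            raise ValidationError(f"phenotype {phenotype!r} not in network")
        pm = self.pm.tolil(copy=True)
        pi = self._phenotype_index[phenotype]
        for m in metabolites:
            if m not in self._metabolite_index:
                raise ValidationError(f"metabolite {m!r} not in network")
            pm[pi, self._metabolite_index[m]] = 0.0
        pm = sp.csr_array(pm)
        pm.eliminate_zeros()
        return CompositeNetwork(self.genes, self.phenotypes, self.metabolites,
                                self.gg, self.pp, self.mm, self.gm, self.pg, pm)

    def metabolite_only(self) -> "CompositeNetwork":
        """Restriction to the metabolite layer and its within-layer network."""
        nm = len(self.metabolites)
        return CompositeNetwork(
            [], [], list(self.metabolites),
            sp.csr_array((0, 0)), sp.csr_array((0, 0)), self.mm,
            sp.csr_array((0, nm)), sp.csr_array((0, 0)), sp.csr_array((0, nm)),
        )


def build_composite(gg, pp, mm, gm, pg, pm) -> CompositeNetwork:
    """Assemble a composite network from six canonicalized edge lists.

    Node indices are the union of all ids seen per layer, so a node referenced
    only by a cross-layer list is registered as an isolated-in-layer node.
    """
    expected = {
        "gg": ("gene", "gene"), "pp": ("phenotype", "phenotype"),
        "mm": ("metabolite", "metabolite"), "gm": ("gene", "metabolite"),
        "pg": ("phenotype", "gene"), "pm": ("phenotype", "metabolite"),
    }
    lists = {"gg": gg, "pp": pp, "mm": mm, "gm": gm, "pg": pg, "pm": pm}
    for name, el in lists.items():
        if (el.source_layer, el.target_layer) != expected[name]:
            raise ValidationError(
                f"argument {name} must have layers {expected[name]}, "
                f"got ({el.source_layer}, {el.target_layer})"
            )
    genes = sorted(gg.source_ids() | gm.source_ids() | pg.target_ids())
    phenotypes = sorted(pp.source_ids() | pg.source_ids() | pm.source_ids())
    metabolites = sorted(mm.source_ids() | gm.target_ids() | pm.target_ids())
    if not (genes or phenotypes or metabolites):
        warnings.warn("building an empty composite network", stacklevel=2)
    gi = {g: i for i, g in enumerate(genes)}
    pi = {p: i for i, p in enumerate(phenotypes)}
    mi = {m: i for i, m in enumerate(metabolites)}
    net = CompositeNetwork(
        genes, phenotypes, metabolites,
        gg=_sym_from_edges(gg.edges, gi, len(genes)),
        pp=_sym_from_edges(pp.edges, pi, len(phenotypes)),
        mm=_sym_from_edges(mm.edges, mi, len(metabolites)),
        gm=_bip_from_edges(gm.edges, gi, mi, (len(genes), len(metabolites))),
        pg=_bip_from_edges(pg.edges, pi, gi, (len(phenotypes), len(genes))),
        pm=_bip_from_edges(pm.edges, pi, mi, (len(phenotypes), len(metabolites))),
    )
    logger.info("built composite network: %s", net.summary())
    return net


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

def _sorted_triu(mat: sp.csr_array):
    """Upper-triangle (i<j) coordinates and weights in deterministic order."""
    coo = sp.triu(mat, k=1).tocoo()
    order = np.lexsort((coo.col, coo.row))
    return coo.row[order], coo.col[order], coo.data[order]


def _sorted_coo(mat: sp.csr_array):
    coo = mat.tocoo()
    order = np.lexsort((coo.col, coo.row))
    return coo.row[order], coo.col[order], coo.data[order]


def perturb_weights(net: CompositeNetwork, sigma: float, rng_seed: int) -> CompositeNetwork:
    """Mix every edge weight with uniform noise: w' = (1 - sigma) * w + sigma * r.

    ``r ~ U(0,1)`` independently per edge; ``sigma`` is the noise proportion in
    the combined score.  Topology is unchanged; each undirected within-layer
    edge is perturbed once (both triangle halves get the same value).
    Deterministic given ``rng_seed``.
    """
    if not 0.0 <= sigma <= 1.0:
        raise ValidationError(f"sigma must lie in [0, 1], got {sigma}")
    rng = np.random.default_rng(rng_seed)
    over_one = 0

    def mix(data):
        nonlocal over_one
        over_one += int((data > 1.0).sum())
        r = rng.uniform(0.0, 1.0, size=data.shape)
        return (1.0 - sigma) * data + sigma * r

    new = {}
    for name in ("gg", "pp", "mm"):
        mat = getattr(net, name)
        n = mat.shape[0]
        rows, cols, data = _sorted_triu(mat)
        w = mix(data)
        new[name] = sp.csr_array(sp.coo_array(
            (np.concatenate([w, w]),
             (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
            shape=(n, n)))
    for name in ("gm", "pg", "pm"):
        mat = getattr(net, name)
        rows, cols, data = _sorted_coo(mat)
        new[name] = sp.csr_array(sp.coo_array((mix(data), (rows, cols)),
                                              shape=mat.shape))
    if over_one:
        warnings.warn(
            f"{over_one} edge weights exceed 1; the uniform-noise mixture "
            "assumes weights on a [0, 1] confidence scale", stacklevel=2)
    return CompositeNetwork(net.genes, net.phenotypes, net.metabolites, **new)


# ---------------------------------------------------------------------------
# Bundle archive
# ---------------------------------------------------------------------------

def save_bundle(net: CompositeNetwork, path) -> None:
    """Save a network as a single .npz archive (versioned container)."""
    arrays: dict[str, np.ndarray] = {
        "genes": np.array(net.genes, dtype=object),
        "phenotypes": np.array(net.phenotypes, dtype=object),
        "metabolites": np.array(net.metabolites, dtype=object),
    }
    for name in ("gg", "pp", "mm", "gm", "pg", "pm"):
        coo = getattr(net, name).tocoo()
        arrays[f"{name}_row"] = coo.row.astype(np.int64)
        arrays[f"{name}_col"] = coo.col.astype(np.int64)
        arrays[f"{name}_data"] = coo.data.astype(np.float64)
    meta = {"format_version": BUNDLE_FORMAT_VERSION,
            "layer_sizes": list(net.layer_sizes)}
    arrays["meta"] = np.array(json.dumps(meta))
    with open(path, "wb") as fh:
        np.savez_compressed(fh, **arrays)


def load_bundle(path) -> CompositeNetwork:
    """Load a network saved by :func:`save_bundle`."""
    with np.load(path, allow_pickle=True) as npz:
        meta = json.loads(str(npz["meta"]))
        if meta.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise ValidationError(
                f"unsupported bundle format version {meta.get('format_version')}"
            )
        genes = [str(g) for g in npz["genes"]]
        phenotypes = [str(p) for p in npz["phenotypes"]]
        metabolites = [str(m) for m in npz["metabolites"]]
        ng, np_, nm = len(genes), len(phenotypes), len(metabolites)
        shapes = {"gg": (ng, ng), "pp": (np_, np_), "mm": (nm, nm),
                  "gm": (ng, nm), "pg": (np_, ng), "pm": (np_, nm)}
        blocks = {}
        for name, shape in shapes.items():
            blocks[name] = sp.csr_array(sp.coo_array(
                (npz[f"{name}_data"], (npz[f"{name}_row"], npz[f"{name}_col"])),
                shape=shape))
    return CompositeNetwork(genes, phenotypes, metabolites, **blocks)
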