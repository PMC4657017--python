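"""Synthetic composite networks with planted disease modules.

The generator emulates the statistical shape of the real inputs — three
weighted within-layer association networks, sparse cross-layer links, and
phenotypes whose true genes and metabolites form locally dense, up-weighted
neighborhoods — so the prioritization and validation machinery can be
exercised with known ground truth.

Background within-layer graphs are Erdos-Renyi at configurable densities with
Beta(2, 5)-distributed weights (skewed toward low confidence, as in
confidence-score networks).  Each planted disease gets one phenotype node
wired to its true genes and to its "known" metabolites; true genes are wired
among themselves and to the true metabolites, and true metabolites among
themselves, at the module densities, with weights multiplied by
``signal_strength`` and clipped to 1 so everything stays on the [0, 1]
confidence scale.  A configurable fraction of each disease's true metabolites
is emitted as known in the annotations; the rest are held-out discoveries
recorded only in the ground truth.  With ``signal_strength = 1`` and module
densities equal to the background densities the planted structure carries no
signal, which is the null scenario used for calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .composite import (CompositeNetwork, ValidationError, build_composite,
                        edge_list_from_pairs, write_edge_list)
from .evaluate import DiseaseAnnotation, write_annotations


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults define the standard planted-signal scenario."""

    n_genes: int = 300
    n_phenotypes: int = 30
    n_metabolites: int = 200
    # background within-layer densities
    gene_density: float = 0.015
    phenotype_density: float = 0.05
    metabolite_density: float = 0.04
    # background cross-layer link density (all three bipartite nets)
    background_attachment: float = 0.002
    # background weight distribution Beta(weight_alpha, weight_beta)
    weight_alpha: float = 2.0
    weight_beta: float = 5.0
    # planted diseases
    n_diseases: int = 10
    genes_per_disease: int = 5
    metabolites_per_disease: int = 8
    known_metabolite_fraction: float = 0.8
    gene_module_density: float = 0.4
    metabolite_module_density: float = 0.12
    cross_module_density: float = 0.3
    signal_strength: float = 5.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("gene_density", "phenotype_density", "metabolite_density",
                     "background_attachment", "gene_module_density",
                     "metabolite_module_density", "cross_module_density",
                     "known_metabolite_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.signal_strength < 1.0:
            raise ValidationError("signal_strength must be >= 1")
        if self.n_diseases > self.n_phenotypes:
            raise ValidationError("more diseases than phenotype nodes")
        if self.n_diseases * self.genes_per_disease > self.n_genes:
            raise ValidationError("disease gene modules exceed the gene layer")
        if self.n_diseases * self.metabolites_per_disease > self.n_metabolites:
            raise ValidationError("disease metabolite modules exceed the metabolite layer")


@dataclass(frozen=True)
class DiseaseTruth:
    phenotype: str
    true_genes: frozenset[str]
    true_metabolites: frozenset[str]
    known_metabolites: frozenset[str]


@dataclass
class GroundTruth:
    """Per-disease planted modules, including the held-out discoveries."""

    diseases: list[DiseaseTruth] = field(default_factory=list)

    def for_phenotype(self, phenotype: str) -> DiseaseTruth:
        for d in self.diseases:
            if d.phenotype == phenotype:
                return d
        raise KeyError(phenotype)


def _er_pairs(ids, density, rng, weight):
    """Erdos-Renyi undirected edges with i < j, weights from ``weight(size)``."""
    n = len(ids)
    if n < 2 or density == 0.0:
        return []
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < density
    ws = weight(int(keep.sum()))
    return [(ids[i], ids[j], float(w))
            for i, j, w in zip(iu[keep], ju[keep], ws)]


def _bip_pairs(rows, cols, density, rng, weight):
    if not rows or not cols or density == 0.0:
        return []
    mask = rng.random((len(rows), len(cols))) < density
    ri, ci = np.nonzero(mask)
    ws = weight(len(ri))
    return [(rows[i], cols[j], float(w)) for i, j, w in zip(ri, ci, ws)]


def generate_composite(config: SyntheticConfig):
    """Generate ``(network, annotations, ground_truth)`` from a config.

    Fully reproducible: the same config (including ``rng_seed``) yields
    byte-identical edge lists.
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    phenotypes = [f"p{i:03d}" for i in range(config.n_phenotypes)]
    metabolites = [f"m{i:04d}" for i in range(config.n_metabolites)]

    def bg_weight(size):
        return rng.beta(config.weight_alpha, config.weight_beta, size=size)

    def module_weight(size):
        return np.minimum(1.0, config.signal_strength * bg_weight(size))

    gg = _er_pairs(genes, config.gene_density, rng, bg_weight)
    pp = _er_pairs(phenotypes, config.phenotype_density, rng, bg_weight)
    mm = _er_pairs(metabolites, config.metabolite_density, rng, bg_weight)
    gm = _bip_pairs(genes, metabolites, config.background_attachment, rng, bg_weight)
    pg = _bip_pairs(phenotypes, genes, config.background_attachment, rng, bg_weight)
    pm = _bip_pairs(phenotypes, metabolites, config.background_attachment, rng, bg_weight)

    # plant disease modules on disjoint node sets
    disease_phens = [str(p) for p in rng.choice(
        np.array(phenotypes, dtype=object), size=config.n_diseases, replace=False)]
    gene_pool = [str(g) for g in rng.permutation(np.array(genes, dtype=object))]
    met_pool = [str(m) for m in rng.permutation(np.array(metabolites, dtype=object))]

    truth = GroundTruth()
    annotations = []
    for d, phen in enumerate(disease_phens):
        g0 = d * config.genes_per_disease
        m0 = d * config.metabolites_per_disease
        mod_genes = sorted(gene_pool[g0:g0 + config.genes_per_disease])
        mod_mets = sorted(met_pool[m0:m0 + config.metabolites_per_disease])
        n_known = max(1, int(round(config.known_metabolite_fraction * len(mod_mets))))
        known = sorted(str(m) for m in rng.choice(
            np.array(mod_mets, dtype=object), size=n_known, replace=False))

        gg += _er_pairs(mod_genes, config.gene_module_density, rng, module_weight)
        mm += _er_pairs(mod_mets, config.metabolite_module_density, rng, module_weight)
        gm += _bip_pairs(mod_genes, mod_mets, config.cross_module_density,
                         rng, module_weight)
        pg += [(phen, g, float(w)) for g, w in zip(mod_genes, module_weight(len(mod_genes)))]
        pm += [(phen, m, float(w)) for m, w in zip(known, module_weight(len(known)))]

        truth.diseases.append(DiseaseTruth(
            phenotype=phen, true_genes=frozenset(mod_genes),
            true_metabolites=frozenset(mod_mets), known_metabolites=frozenset(known)))
        annotations.append(DiseaseAnnotation(
            phenotype=phen, known_metabolites=frozenset(known),
            known_genes=frozenset(mod_genes)))

    lists = {
        "gg": edge_list_from_pairs("gene", "gene", gg),
        "pp": edge_list_from_pairs("phenotype", "phenotype", pp),
        "mm": edge_list_from_pairs("metabolite", "metabolite", mm),
        "gm": edge_list_from_pairs("gene", "metabolite", gm),
        "pg": edge_list_from_pairs("phenotype", "gene", pg),
        "pm": edge_list_from_pairs("phenotype", "metabolite", pm),
    }
    net = build_composite(**lists)
    net = _with_all_nodes(net, genes, phenotypes, metabolites)
    return net, annotations, truth


def _with_all_nodes(net: CompositeNetwork, genes, phenotypes, metabolites):
    """Extend the node index to the full configured layers (isolated nodes kept)."""
    import scipy.sparse as sp

    full = {"gene": sorted(genes), "phenotype": sorted(phenotypes),
            "metabolite": sorted(metabolites)}
    maps = {}
    for layer, old_ids in (("gene", net.genes), ("phenotype", net.phenotypes),
                           ("metabolite", net.metabolites)):
        missing = set(old_ids) - set(full[layer])
        if missing:
            raise ValidationError(f"unknown {layer} ids: {sorted(missing)[:5]}")
        maps[layer] = {v: i for i, v in enumerate(full[layer])}

    def remap(mat, row_ids, col_ids, row_layer, col_layer):
        coo = mat.tocoo()
        rows = np.array([maps[row_layer][row_ids[i]] for i in coo.row], dtype=int)
        cols = np.array([maps[col_layer][col_ids[j]] for j in coo.col], dtype=int)
        shape = (len(full[row_layer]), len(full[col_layer]))
        return sp.csr_array(sp.coo_array((coo.data, (rows, cols)), shape=shape))

    return CompositeNetwork(
        full["gene"], full["phenotype"], full["metabolite"],
        gg=remap(net.gg, net.genes, net.genes, "gene", "gene"),
        pp=remap(net.pp, net.phenotypes, net.phenotypes, "phenotype", "phenotype"),
        mm=remap(net.mm, net.metabolites, net.metabolites, "metabolite", "metabolite"),
        gm=remap(net.gm, net.genes, net.metabolites, "gene", "metabolite"),
        pg=remap(net.pg, net.phenotypes, net.genes, "phenotype", "gene"),
        pm=remap(net.pm, net.phenotypes, net.metabolites, "phenotype", "metabolite"),
    )


def write_dataset(net: CompositeNetwork, annotations, truth: GroundTruth,
                  out_dir) -> None:
    """Write the six edge-list TSVs, the annotation TSV and the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = {"gg": "gene_gene.tsv", "pp": "phenotype_phenotype.tsv",
             "mm": "metabolite_metabolite.tsv", "gm": "gene_metabolite.tsv",
             "pg": "phenotype_gene.tsv", "pm": "phenotype_metabolite.tsv"}
    for key, el in net.to_edge_lists().items():
        write_edge_list(el, out / names[key])
    write_annotations(annotations, out / "annotations.tsv")
    with open(out / "ground_truth.tsv", "wt", encoding="utf-8") as fh:
        for d in truth.diseases:
            fh.write("\t".join([
                d.phenotype,
                ";".join(sorted(d.true_genes)),
                ";".join(sorted(d.true_metabolites)),
                ";".join(sorted(d.known_metabolites)),
            ]) + "\n")
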