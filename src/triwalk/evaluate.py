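"""Leave-one-out cross-validation, ROC/AUC, robustness and parameter sweeps.

For every known phenotype-metabolite link, the link is removed from the
network, seeds are rebuilt from the remaining knowledge, and the held-out
metabolite is ranked among a candidate set.  Folds are pooled into one ROC by
per-fold normalized ranks (scores are not comparable across folds run on
different networks), and the AUC uses the rank-sum identity

    AUC = mean over folds of (n_candidates - rank) / (n_candidates - 1)

which is the Mann-Whitney probability that the held-out metabolite outranks a
random negative candidate.  Exact score ties enter with midranks.

Seed-ablation modes mirror the method-comparison protocol:

* ``full`` — seeds are the target phenotype, its known genes, and the other
  known metabolites (phenotype + genes only when there are no others).
* ``metabolite_seed_only_baseline`` — propagation restricted to the
  metabolite sub-network with metabolite seeds only (the single-network
  comparator); folds without remaining metabolite seeds are skipped.
* ``no_known_metabolites`` — all phenotype-metabolite links of the target
  phenotype are removed and seeds are phenotype + genes only.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composite import CompositeNetwork, ValidationError, perturb_weights
from .prioritize import CandidateSet, _steady_state
from .rwr import RWRParams, SeedSet

logger = logging.getLogger("triwalk")

ABLATION_MODES = ("full", "metabolite_seed_only_baseline", "no_known_metabolites")


@dataclass(frozen=True)
class DiseaseAnnotation:
    """A phenotype with its curated metabolites, genes and optional class."""

    phenotype: str
    known_metabolites: frozenset[str] = frozenset()
    known_genes: frozenset[str] = frozenset()
    class_label: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "known_metabolites", frozenset(self.known_metabolites))
        object.__setattr__(self, "known_genes", frozenset(self.known_genes))


def read_annotations(path) -> list[DiseaseAnnotation]:
    """Read an annotation TSV.

    Columns: phenotype_id, ';'-joined metabolite ids, ';'-joined gene ids,
    optional class label.  Empty id lists are allowed.
    """
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}, line {lineno}: expected at least 3 columns")
            phen, mets, genes = fields[0], fields[1], fields[2]
            label = fields[3] if len(fields) > 3 and fields[3] else None
            out.append(DiseaseAnnotation(
                phenotype=phen,
                known_metabolites=frozenset(m for m in mets.split(";") if m),
                known_genes=frozenset(g for g in genes.split(";") if g),
                class_label=label,
            ))
    return out


def write_annotations(annotations, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for ann in annotations:
            fh.write("\t".join([
                ann.phenotype,
                ";".join(sorted(ann.known_metabolites)),
                ";".join(sorted(ann.known_genes)),
                ann.class_label or "",
            ]) + "\n")


# ---------------------------------------------------------------------------
# AUC from pooled ranks
# ---------------------------------------------------------------------------

def auc_from_ranks(positive_ranks) -> float:
    """Rank-sum AUC from (rank, n_candidates) pairs, one per fold.

    ``rank`` may be a midrank (real-valued) when scores tie.  Folds with
    fewer than two candidates carry no ranking information and are skipped
    with a warning.
    """
    contributions = []
    for rank, n in positive_ranks:
        if n < 2:
            warnings.warn(
                f"fold with {n} candidate(s) skipped in AUC", stacklevel=2)
            continue
        if not 1 <= rank <= n:
            raise ValidationError(f"rank {rank} outside [1, {n}]")
        contributions.append((n - rank) / (n - 1))
    if not contributions:
        raise ValidationError("no usable folds for AUC")
    return float(np.mean(contributions))


def roc_points(positive_ranks) -> pd.DataFrame:
    """Pooled ROC from per-fold normalized ranks.

    Each fold's positive sits at normalized rank u = (rank - 1) / (n - 1)
    within its own candidate list; sweeping a common threshold over u gives
    FPR = u and TPR = the empirical CDF of the positives' u values.
    """
    u = np.sort([(rank - 1.0) / (n - 1.0) for rank, n in positive_ranks if n >= 2])
    m = len(u)
    fpr = np.concatenate([[0.0], u, [1.0]])
    tpr = np.concatenate([[0.0], np.arange(1, m + 1) / m, [1.0]])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def roc_from_scores(pos_scores, neg_scores) -> pd.DataFrame:
    """ROC from pooled raw scores (positives vs negatives across all folds).

    Alternative pooling for folds that share one network; with heterogeneous
    per-fold networks the rank-pooled :func:`roc_points` is preferred because
    raw scores are not comparable across folds.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("score-pooled ROC needs positives and negatives")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(labels[order])
    fp = np.cumsum(1.0 - labels[order])
    keep = np.r_[np.diff(scores[order]) != 0, True]  # one point per threshold
    fpr = np.concatenate([[0.0], fp[keep] / len(neg)])
    tpr = np.concatenate([[0.0], tp[keep] / len(pos)])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


@dataclass
class ValidationResult:
    """Per-fold ranks plus the pooled ROC/AUC, stratifiable by disease class.

    ``folds`` columns: phenotype, test_metabolite, rank (midrank), n_candidates,
    score, class_label.
    """

    folds: pd.DataFrame
    roc: pd.DataFrame
    auc: float
    per_class: dict | None = None

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def auc_standard_error(self) -> float:
        """SE of the AUC as the standard error of per-fold contributions."""
        contrib = (self.folds["n_candidates"] - self.folds["rank"]) / (
            self.folds["n_candidates"] - 1)
        return float(contrib.std(ddof=1) / np.sqrt(len(contrib)))


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def _midrank(scores: np.ndarray, target_idx: int) -> float:
    s = scores[target_idx]
    higher = int((scores > s).sum())
    ties = int((scores == s).sum())  # includes the target itself
    return higher + (ties + 1) / 2.0


def _fold_candidates(base: CandidateSet, test_metabolite: str,
                     fold_seed: int) -> CandidateSet:
    if base.mode == "random_k":
        return CandidateSet(mode="random_k", k=base.k, rng_seed=fold_seed,
                            include=test_metabolite)
    return base


def loocv(net: CompositeNetwork, annotations, params: RWRParams,
          candidates: CandidateSet | None = None, ablation: str = "full",
          rng_seed: int = 0, roc_pooling: str = "ranks") -> ValidationResult:
    """Leave-one-out cross-validation over every known phenotype-metabolite link.

    ``roc_pooling`` selects how the pooled ROC curve is built: ``"ranks"``
    (default, per-fold normalized ranks) or ``"scores"`` (pooled raw scores).
    The AUC is always the rank-sum identity.
    """
    if ablation not in ABLATION_MODES:
        raise ValidationError(
            f"ablation must be one of {ABLATION_MODES}, got {ablation!r}")
    if roc_pooling not in ("ranks", "scores"):
        raise ValidationError(
            f"roc_pooling must be 'ranks' or 'scores', got {roc_pooling!r}")
    if candidates is None:
        candidates = CandidateSet(mode="metabolome_wide")
    rng = np.random.default_rng(rng_seed)
    met_net = net.metabolite_only() if ablation == "metabolite_seed_only_baseline" else None

    rows = []
    pooled_neg: list[float] = []
    for ann in annotations:
        known = sorted(ann.known_metabolites)
        if not known:
            continue
        for test_met in known:
            others = frozenset(m for m in known if m != test_met)
            fold_seed = int(rng.integers(0, 2**31 - 1))
            if ablation == "full":
                fold_net = net.without_pm_edges(ann.phenotype, [test_met])
                seeds = SeedSet(phenotype_seeds={ann.phenotype},
                                gene_seeds=ann.known_genes,
                                metabolite_seeds=others)
            elif ablation == "no_known_metabolites":
                fold_net = net.without_pm_edges(ann.phenotype, known)
                seeds = SeedSet(phenotype_seeds={ann.phenotype},
                                gene_seeds=ann.known_genes)
            else:  # metabolite_seed_only_baseline
                if not others:
                    logger.info(
                        "baseline fold (%s, %s) skipped: no metabolite seeds left",
                        ann.phenotype, test_met)
                    continue
                fold_net = met_net
                seeds = SeedSet(metabolite_seeds=others)
            if ablation != "metabolite_seed_only_baseline":
                # the held-out link must be gone from the fold's network
                pi = fold_net.phenotype_index[ann.phenotype]
                mi = fold_net.metabolite_index[test_met]
                assert fold_net.pm[pi, mi] == 0.0, "held-out edge leaked"
            cand = _fold_candidates(candidates, test_met, fold_seed)
            cand_ids = cand.resolve(fold_net, seeds)
            if test_met not in cand_ids:
                raise ValidationError(
                    f"test metabolite {test_met!r} missing from the candidate "
                    f"set of fold ({ann.phenotype}, {test_met})")
            _, prop = _steady_state(fold_net, seeds, params)
            off = fold_net.offsets[2]
            idx = np.array([off + fold_net.metabolite_index[m] for m in cand_ids])
            scores = prop.steady[idx]
            t = cand_ids.index(test_met)
            if roc_pooling == "scores":
                pooled_neg.extend(np.delete(scores, t).tolist())
            rows.append({
                "phenotype": ann.phenotype,
                "test_metabolite": test_met,
                "rank": _midrank(scores, t),
                "n_candidates": len(cand_ids),
                "score": float(scores[t]),
                "class_label": ann.class_label,
            })
    if not rows:
        raise ValidationError("no usable folds: check annotations and ablation mode")
    folds = pd.DataFrame(rows)
    pairs = list(zip(folds["rank"], folds["n_candidates"]))
    if roc_pooling == "scores":
        roc = roc_from_scores(folds["score"], pooled_neg)
    else:
        roc = roc_points(pairs)
    return ValidationResult(folds=folds, roc=roc, auc=auc_from_ranks(pairs))


def classwise_auc(result: ValidationResult, class_map: dict | None = None):
    """Recompute the AUC per disease class from that class's folds.

    Returns ``(per_class, mean_auc, se_auc)`` where ``per_class`` maps class
    label to ``(auc, n_folds)`` and the mean/SE are taken across classes.
    Folds without a label are grouped under ``"unclassified"``.
    """
    folds = result.folds.copy()
    if class_map is not None:
        folds["class_label"] = folds["phenotype"].map(class_map)
    folds["class_label"] = folds["class_label"].fillna("unclassified")
    per_class = {}
    for label, grp in folds.groupby("class_label"):
        pairs = list(zip(grp["rank"], grp["n_candidates"]))
        per_class[str(label)] = (auc_from_ranks(pairs), len(grp))
    aucs = np.array([v[0] for v in per_class.values()])
    mean = float(aucs.mean())
    se = float(aucs.std(ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
    return per_class, mean, se


# ---------------------------------------------------------------------------
# Robustness and parameter sweeps
# ---------------------------------------------------------------------------

def noise_sweep(net: CompositeNetwork, annotations, params: RWRParams,
                sigmas, rng_seed: int = 0,
                candidates: CandidateSet | None = None,
                ablation: str = "full") -> pd.DataFrame:
    """LOOCV AUC after mixing each edge weight with uniform noise, per sigma.

    All sigma values within one call share the same noise stream (the same
    per-edge uniform draws, mixed linearly), so the AUC-versus-sigma curve
    reflects the noise proportion rather than stream-to-stream variation;
    sigma = 0 reproduces the clean AUC exactly.  Replicates are obtained by
    calling with different ``rng_seed`` values.
    """
    sigmas = list(sigmas)
    for s in sigmas:
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"sigma must lie in [0, 1], got {s}")
    rng = np.random.default_rng(rng_seed)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    loocv_seed = int(rng.integers(0, 2**31 - 1))
    rows = []
    for sigma in sigmas:
        pnet = perturb_weights(net, sigma, noise_seed)
        res = loocv(pnet, annotations, params, candidates, ablation, loocv_seed)
        rows.append({"sigma": sigma, "auc": res.auc, "n_folds": res.n_folds})
    return pd.DataFrame(rows)


def parameter_sweep(net: CompositeNetwork, annotations, grid: dict,
                    base_params: RWRParams | None = None,
                    candidates: CandidateSet | None = None,
                    ablation: str = "full", rng_seed: int = 0):
    """LOOCV AUC over a Cartesian grid of parameter values.

    ``grid`` maps parameter names (alpha, x, y, z, a, b) to value lists.
    Grid points violating the parameter invariants are rejected up front;
    returns ``(table, rejected)`` where ``rejected`` lists the invalid points
    with their error messages.
    """
    if not grid:
        raise ValidationError("parameter grid is empty")
    base = base_params or RWRParams()
    names = sorted(grid)
    points = [dict(zip(names, combo))
              for combo in itertools.product(*(grid[n] for n in names))]
    valid, rejected = [], []
    for point in points:
        try:
            valid.append((point, base.replace(**point)))
        except ValidationError as exc:
            rejected.append((point, str(exc)))
    if rejected:
        logger.info("parameter sweep rejected %d invalid grid points", len(rejected))
    if not valid:
        raise ValidationError("no valid grid points after invariant checks")
    rows = []
    for point, params in valid:
        res = loocv(net, annotations, params, candidates, ablation, rng_seed)
        rows.append({**point, "auc": res.auc, "n_folds": res.n_folds})
    return pd.DataFrame(rows), rejected


# ---------------------------------------------------------------------------
# Score matrix
# ---------------------------------------------------------------------------

def score_matrix(net: CompositeNetwork, annotations, params: RWRParams):
    """Phenotype x metabolite matrix of steady-state scores, full knowledge.

    Each row uses the phenotype's complete annotation as seeds (nothing held
    out); the row's seed metabolites are excluded as candidates and reported
    separately.  Returns ``(matrix, exclusions)`` where excluded cells are NaN.
    """
    index = []
    rows = []
    exclusions = {}
    for ann in annotations:
        seeds = SeedSet(phenotype_seeds={ann.phenotype},
                        gene_seeds=ann.known_genes,
                        metabolite_seeds=ann.known_metabolites)
        _, prop = _steady_state(net, seeds, params)
        off = net.offsets[2]
        scores = prop.steady[off:off + len(net.metabolites)].astype(float)
        row = pd.Series(scores, index=net.metabolites)
        excluded = sorted(ann.known_metabolites)
        row[excluded] = np.nan
        index.append(ann.phenotype)
        rows.append(row)
        exclusions[ann.phenotype] = excluded
    if not rows:
        raise ValidationError("no annotations given")
    return pd.DataFrame(rows, index=index), exclusions


def top_k_long(matrix: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Long-format top-k metabolites per phenotype from a score matrix."""
    rows = []
    for phen, row in matrix.iterrows():
        top = row.dropna().sort_values(ascending=False).head(k)
        for rank, (met, score) in enumerate(top.items(), start=1):
            rows.append({"phenotype": phen, "metabolite": met,
                         "score": float(score), "rank": rank})
    return pd.DataFrame(rows)
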