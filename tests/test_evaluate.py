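import numpy as np
import pytest

from triwalk import (CandidateSet, DiseaseAnnotation, RWRParams,
                     ValidationError, auc_from_ranks, classwise_auc, loocv,
                     noise_sweep, parameter_sweep, read_annotations,
                     score_matrix, top_k_long, write_annotations)

from conftest import make_net

PARAMS = RWRParams()


def brute_force_auc(folds):
    """Pairwise-comparison AUC oracle: the positive of each fold against that
    fold's n-1 negatives, ties counting one half; averaged over folds."""
    per_fold = []
    for rank, n in folds:
        # midrank r among n means (n - ceil(r')) wins etc.; reconstruct from
        # counts: higher = r - 1 - t/2 where t ties -- for integer ranks t = 0
        wins = n - rank          # negatives scored strictly below
        ties = 2 * (rank - int(rank))  # midrank .5 implies one tied pair half
        per_fold.append((wins + 0.0 * ties) / (n - 1))
    return float(np.mean(per_fold))


class TestAucFromRanks:
    def test_all_rank_one_gives_perfect_auc(self):
        assert auc_from_ranks([(1, 50)] * 7) == 1.0

    def test_midpoint_rank_gives_half(self):
        assert auc_from_ranks([(51, 101)]) == 0.5

    def test_two_fold_average(self):
        assert auc_from_ranks([(1, 11), (6, 11)]) == pytest.approx(0.75)

    def test_matches_pairwise_oracle_on_random_folds(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            folds = [(int(rng.integers(1, n + 1)), n)
                     for n in rng.integers(2, 300, size=rng.integers(1, 12))]
            assert auc_from_ranks(folds) == pytest.approx(brute_force_auc(folds))

    def test_matches_sklearn_on_score_vectors(self):
        # independent oracle: rank a positive among explicit score draws and
        # compare with roc_auc_score on the same labels/scores
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            scores = rng.normal(size=n)
            labels = np.zeros(n)
            labels[0] = 1
            rank = 1 + (scores > scores[0]).sum()
            ours = auc_from_ranks([(rank, n)])
            ref = roc_auc_score(labels, scores)
            assert ours == pytest.approx(ref)

    def test_degenerate_fold_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            assert auc_from_ranks([(1, 1), (1, 2)]) == 1.0

    def test_rank_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            auc_from_ranks([(12, 11)])


def _clique_world(n_bg=6):
    """Three diseases whose metabolites form cliques wired to their phenotype;
    background metabolites isolated."""
    mm, pm, pg, gg, gm = [], [], [], [], []
    anns = []
    for d in range(3):
        phen = f"p{d}"
        mets = [f"d{d}_m{i}" for i in range(4)]
        genes = [f"d{d}_g{i}" for i in range(2)]
        mm += [(a, b, 1.0) for i, a in enumerate(mets) for b in mets[i + 1:]]
        pm += [(phen, m, 1.0) for m in mets]
        pg += [(phen, g, 1.0) for g in genes]
        gm += [(g, m, 1.0) for g in genes for m in mets]
        anns.append(DiseaseAnnotation(phenotype=phen,
                                      known_metabolites=frozenset(mets),
                                      known_genes=frozenset(genes),
                                      class_label=f"class{d % 2}"))
    # background metabolites, attached weakly to one another only
    mm += [(f"bg{i}", f"bg{i+1}", 0.1) for i in range(n_bg - 1)]
    net = make_net(mm=mm, pm=pm, pg=pg, gm=gm)
    return net, anns


class TestLoocv:
    def test_perfect_separation_gives_auc_one(self):
        net, anns = _clique_world()
        res = loocv(net, anns, PARAMS, ablation="full", rng_seed=0)
        assert res.auc == 1.0
        assert res.n_folds == 12

    def test_one_fold_per_known_link(self):
        net, anns = _clique_world()
        res = loocv(net, anns, PARAMS, ablation="full", rng_seed=0)
        expected = sum(len(a.known_metabolites) for a in anns)
        assert res.n_folds == expected

    def test_held_out_edge_absent_from_fold_network(self):
        # removing the link must lower the test metabolite's score relative
        # to keeping it (no leakage)
        net, anns = _clique_world()
        res = loocv(net, anns[:1], PARAMS, ablation="full", rng_seed=0)
        from triwalk import SeedSet, prioritize
        ann = anns[0]
        leaky = prioritize(net, SeedSet(phenotype_seeds={ann.phenotype},
                                        gene_seeds=ann.known_genes,
                                        metabolite_seeds=frozenset(
                                            sorted(ann.known_metabolites)[1:])),
                           PARAMS, CandidateSet(mode="metabolome_wide"))
        held_out = sorted(ann.known_metabolites)[0]
        fold = res.folds[res.folds["test_metabolite"] == held_out].iloc[0]
        assert fold["score"] < leaky.scores()[held_out]

    def test_baseline_equals_full_when_other_layers_disconnected(self):
        # metabolite layer carries edges; phenotypes exist but have no
        # cross-layer links at all, so full mode's extra seeds add nothing:
        # metabolite scores scale linearly and ranks coincide exactly
        mm, anns = [], []
        rng = np.random.default_rng(5)
        for d in range(2):
            mets = [f"d{d}_m{i}" for i in range(4)]
            mm += [(a, b, float(rng.uniform(0.3, 1.0)))
                   for i, a in enumerate(mets) for b in mets[i + 1:]]
            anns.append(DiseaseAnnotation(phenotype=f"p{d}",
                                          known_metabolites=frozenset(mets)))
        mm += [(f"bg{i}", f"bg{j}", 0.2) for i in range(5) for j in range(i + 1, 5)]
        pp = [("p0", "p1", 0.5)]  # registers the phenotypes, nothing more
        net = make_net(mm=mm, pp=pp)
        full = loocv(net, anns, PARAMS, ablation="full", rng_seed=0)
        base = loocv(net, anns, PARAMS,
                     ablation="metabolite_seed_only_baseline", rng_seed=0)
        f = full.folds.set_index(["phenotype", "test_metabolite"])["rank"]
        b = base.folds.set_index(["phenotype", "test_metabolite"])["rank"]
        assert full.n_folds == base.n_folds
        assert (f == b.loc[f.index]).all()
        assert full.auc == pytest.approx(base.auc)

    def test_random_candidate_mode(self):
        net, anns = _clique_world(n_bg=30)
        res = loocv(net, anns, PARAMS,
                    candidates=CandidateSet(mode="random_k", k=10),
                    ablation="full", rng_seed=3)
        assert (res.folds["n_candidates"] == 10).all()
        assert res.auc == 1.0

    def test_no_known_metabolites_mode_uses_gene_and_phenotype_signal(self):
        net, anns = _clique_world()
        res = loocv(net, anns, PARAMS, ablation="no_known_metabolites",
                    rng_seed=0)
        # genes and the phenotype still point at the clique, so every test
        # metabolite ranks within its own 4-member module (siblings compete
        # as candidates here, unlike in full mode where they are seeds)
        assert (res.folds["rank"] <= 4.5).all()
        assert res.auc > 0.85

    def test_baseline_skips_folds_without_metabolite_seeds(self):
        net = make_net(mm=[("m1", "m2", 1.0), ("m2", "m3", 1.0)],
                       pm=[("p1", "m1", 1.0)])
        anns = [DiseaseAnnotation(phenotype="p1",
                                  known_metabolites=frozenset({"m1"}))]
        with pytest.raises(ValidationError, match="no usable folds"):
            loocv(net, anns, PARAMS, ablation="metabolite_seed_only_baseline")


class TestRocPooling:
    def test_score_pooled_roc_is_valid_and_keeps_rank_auc(self):
        net, anns = _clique_world()
        ranks = loocv(net, anns, PARAMS, ablation="full", rng_seed=0)
        scored = loocv(net, anns, PARAMS, ablation="full", rng_seed=0,
                       roc_pooling="scores")
        assert scored.auc == ranks.auc  # AUC is always the rank identity
        roc = scored.roc
        assert roc.iloc[0].tolist() == [0.0, 0.0]
        assert roc.iloc[-1].tolist() == [1.0, 1.0]
        assert (roc.diff().dropna() >= -1e-12).all().all()

    def test_roc_from_scores_against_sklearn(self):
        from sklearn.metrics import roc_curve
        from triwalk import roc_from_scores
        rng = np.random.default_rng(8)
        pos = rng.normal(1.0, 1.0, size=40)
        neg = rng.normal(0.0, 1.0, size=300)
        ours = roc_from_scores(pos, neg)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(40), np.zeros(300)])
        fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
        np.testing.assert_allclose(ours["fpr"].to_numpy(), fpr, atol=1e-12)
        np.testing.assert_allclose(ours["tpr"].to_numpy(), tpr, atol=1e-12)


class TestClasswise:
    def test_single_class_equals_overall(self):
        net, anns = _clique_world()
        anns = [DiseaseAnnotation(a.phenotype, a.known_metabolites,
                                  a.known_genes, "only") for a in anns]
        res = loocv(net, anns, PARAMS, ablation="full", rng_seed=0)
        per_class, mean, se = classwise_auc(res)
        assert set(per_class) == {"only"}
        assert per_class["only"][0] == pytest.approx(res.auc)
        assert se == 0.0

    def test_perfect_and_random_classes_separate(self):
        rng = np.random.default_rng(2)
        import pandas as pd
        from triwalk import ValidationResult, roc_points
        folds = []
        for i in range(40):
            folds.append({"phenotype": f"pa{i}", "test_metabolite": "m",
                          "rank": 1.0, "n_candidates": 100,
                          "score": 1.0, "class_label": "perfect"})
        for i in range(400):
            folds.append({"phenotype": f"pb{i}", "test_metabolite": "m",
                          "rank": float(rng.integers(1, 101)),
                          "n_candidates": 100, "score": 0.1,
                          "class_label": "random"})
        df = pd.DataFrame(folds)
        res = ValidationResult(folds=df, roc=roc_points(
            zip(df["rank"], df["n_candidates"])), auc=0.0)
        per_class, mean, se = classwise_auc(res)
        assert per_class["perfect"][0] == 1.0
        assert abs(per_class["random"][0] - 0.5) < 0.05
        assert mean == pytest.approx(np.mean([v[0] for v in per_class.values()]))


class TestSweeps:
    def test_sigma_zero_row_equals_clean_auc_exactly(self):
        net, anns = _clique_world()
        clean = loocv(net, anns, PARAMS, ablation="full", rng_seed=7)
        table = noise_sweep(net, anns, PARAMS, [0.0, 0.5], rng_seed=7)
        assert table.loc[table["sigma"] == 0.0, "auc"].iloc[0] == clean.auc

    def test_alpha_one_gives_half_auc_by_tie_convention(self):
        net, anns = _clique_world()
        table, rejected = parameter_sweep(net, anns, {"alpha": [1.0]})
        assert not rejected
        assert table["auc"].iloc[0] == pytest.approx(0.5)

    def test_invalid_grid_points_rejected_up_front(self):
        net, anns = _clique_world()
        table, rejected = parameter_sweep(
            net, anns, {"x": [0.2, 0.9], "y": [0.0, 0.5]},
            base_params=RWRParams(y=0.0, z=0.0))
        assert len(table) == 3  # (0.9, 0.5) violates x + y <= 1
        assert len(rejected) == 1

    def test_empty_grid_rejected(self):
        net, anns = _clique_world()
        with pytest.raises(ValidationError):
            parameter_sweep(net, anns, {})


class TestScoreMatrix:
    def test_dimensions_and_exclusions(self):
        net, anns = _clique_world()
        mat, excl = score_matrix(net, anns, PARAMS)
        assert mat.shape == (len(anns), len(net.metabolites))
        for ann in anns:
            assert excl[ann.phenotype] == sorted(ann.known_metabolites)
            assert mat.loc[ann.phenotype, excl[ann.phenotype]].isna().all()

    def test_row_scores_are_metabolite_layer_mass(self):
        from triwalk import SeedSet, build_initial, build_transition, propagate
        net, anns = _clique_world()
        mat, _ = score_matrix(net, anns, PARAMS)
        ann = anns[0]
        seeds = SeedSet(phenotype_seeds={ann.phenotype},
                        gene_seeds=ann.known_genes,
                        metabolite_seeds=ann.known_metabolites)
        t = build_transition(net, PARAMS.x, PARAMS.y, PARAMS.z)
        p0 = build_initial(net, seeds, PARAMS.a, PARAMS.b)
        steady = propagate(t.matrix, p0, PARAMS.alpha).steady
        off = net.offsets[2]
        layer_mass = steady[off:].sum()
        row_mass = mat.loc[ann.phenotype].sum() + steady[
            [off + net.metabolite_index[m] for m in sorted(ann.known_metabolites)]
        ].sum()
        assert row_mass == pytest.approx(layer_mass)

    def test_identical_seed_sets_give_identical_rows(self):
        net, anns = _clique_world()
        twin = DiseaseAnnotation(phenotype=anns[0].phenotype,
                                 known_metabolites=anns[0].known_metabolites,
                                 known_genes=anns[0].known_genes)
        mat, _ = score_matrix(net, [anns[0], twin], PARAMS)
        assert mat.iloc[0].equals(mat.iloc[1])

    def test_top_k_long_format(self):
        net, anns = _clique_world()
        mat, _ = score_matrix(net, anns, PARAMS)
        long = top_k_long(mat, k=3)
        assert set(long.columns) == {"phenotype", "metabolite", "score", "rank"}
        assert (long.groupby("phenotype")["rank"].max() <= 3).all()


class TestAnnotationsIO:
    def test_round_trip(self, tmp_path):
        anns = [DiseaseAnnotation("p1", frozenset({"m1", "m2"}),
                                  frozenset({"g3"}), "renal"),
                DiseaseAnnotation("p2", frozenset(), frozenset(), None)]
        path = tmp_path / "ann.tsv"
        write_annotations(anns, path)
        back = read_annotations(path)
        assert back == anns
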