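import numpy as np
import pytest

from tfinfluence.exceptions import ContractError, DomainError
from tfinfluence.influence import (
    InfluenceMatrix,
    InfluencerReport,
    intersect_significant,
    read_influencer_report,
    restrict_to_tfs,
    topk_influencers,
    write_influencer_report,
)
from tfinfluence.io import SignificanceLists, TFAnnotation


def _infl(scores, gene_ids=None, protein_ids=None):
    scores = np.asarray(scores, float)
    scores = scores / scores.sum(axis=0)
    return InfluenceMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(scores.shape[0])],
        protein_ids=protein_ids or [f"p{j}" for j in range(scores.shape[1])],
        scores=scores,
        method_tag="test",
    )


class TestInfluenceMatrixInvariants:
    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        infl = _infl(rng.random((8, 5)) + 0.01)
        np.testing.assert_allclose(infl.scores.sum(axis=0), 1.0, rtol=1e-9)

    def test_negative_scores_rejected(self):
        with pytest.raises(DomainError):
            InfluenceMatrix(["g0"], ["p0"], np.array([[-0.1]]), "test")


class TestRestrictToTfs:
    def test_all_genes_keeps_matrix_identical(self):
        infl = _infl(np.random.default_rng(1).random((6, 3)) + 0.01)
        out = restrict_to_tfs(infl, TFAnnotation(set(infl.gene_ids)))
        np.testing.assert_allclose(out.scores, infl.scores, rtol=1e-12)

    def test_single_tf_gives_unit_columns(self):
        infl = _infl(np.random.default_rng(2).random((6, 3)) + 0.01)
        out = restrict_to_tfs(infl, TFAnnotation({"g2"}))
        assert out.gene_ids == ["g2"]
        np.testing.assert_allclose(out.scores, 1.0)

    def test_hand_renormalization(self):
        scores = np.array([[0.5], [0.3], [0.2]])
        infl = _infl(scores)
        out = restrict_to_tfs(infl, TFAnnotation({"g0", "g2"}))
        np.testing.assert_allclose(out.scores[:, 0], [0.5 / 0.7, 0.2 / 0.7])

    def test_empty_intersection_rejected(self):
        infl = _infl(np.ones((3, 2)))
        with pytest.raises(DomainError):
            restrict_to_tfs(infl, TFAnnotation({"absent"}))


class TestTopK:
    def test_default_k_returns_25_when_enough_tfs(self):
        rng = np.random.default_rng(3)
        infl = _infl(rng.random((30, 4)) + 0.01)
        report = topk_influencers(infl)
        assert all(len(v) == 25 for v in report.per_protein.values())

    def test_k_larger_than_tf_set_returns_all_sorted(self):
        infl = _infl(np.random.default_rng(4).random((6, 2)) + 0.01)
        report = topk_influencers(infl, k=50)
        for entries in report.per_protein.values():
            assert len(entries) == 6
            scores = [s for _, s in entries]
            assert scores == sorted(scores, reverse=True)

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(5)
        infl = _infl(rng.random((8, 4)) + 0.01)
        report = topk_influencers(infl, k=3)
        for j, pid in enumerate(infl.protein_ids):
            col = infl.scores[:, j]
            expected = sorted(
                zip(infl.gene_ids, col), key=lambda t: (-t[1], t[0])
            )[:3]
            got = report.per_protein[pid]
            assert [g for g, _ in got] == [g for g, _ in expected]
            np.testing.assert_allclose([s for _, s in got], [s for _, s in expected])

    def test_ties_break_lexicographically(self):
        scores = np.array([[0.25], [0.25], [0.25], [0.25]])
        infl = _infl(scores, gene_ids=["gb", "ga", "gd", "gc"])
        report = topk_influencers(infl, k=4)
        assert [g for g, _ in report.per_protein["p0"]] == ["ga", "gb", "gc", "gd"]

    def test_k_below_one_rejected(self):
        with pytest.raises(DomainError):
            topk_influencers(_infl(np.ones((2, 1))), k=0)


class TestIntersectSignificant:
    def _report(self):
        return InfluencerReport(
            per_protein={"p1": [("a", 0.5), ("b", 0.3), ("c", 0.2)],
                         "p2": [("a", 0.9), ("c", 0.1)]},
            k=25, method_tag="test",
        )

    def test_toy_intersection(self):
        lists = SignificanceLists("cmp", sig_genes={"b"}, sig_proteins={"p1"})
        out = intersect_significant(self._report(), lists)
        assert out.per_protein == {"p1": [("b", 0.3)]}
        assert out.filter_label == "cmp"

    def test_universal_sets_leave_report_unchanged(self):
        lists = SignificanceLists("cmp", sig_genes={"a", "b", "c"},
                                  sig_proteins={"p1", "p2"})
        out = intersect_significant(self._report(), lists)
        assert out.per_protein == self._report().per_protein

    def test_empty_sig_proteins_warns_and_empties(self):
        lists = SignificanceLists("cmp", sig_genes={"a"}, sig_proteins=set())
        with pytest.warns(UserWarning):
            out = intersect_significant(self._report(), lists)
        assert out.per_protein == {}


class TestReportIO:
    def test_rank_and_order_columns(self, tmp_path):
        report = InfluencerReport(
            per_protein={"p1": [("a", 0.5), ("b", 0.3), ("c", 0.2)]},
            k=25, method_tag="test",
        )
        path = tmp_path / "report.tsv"
        write_influencer_report(report, path)
        lines = path.read_text().splitlines()
        assert lines[1].split("\t") == ["protein_id", "rank", "tf_id", "score"]
        assert lines[2].split("\t")[:3] == ["p1", "1", "a"]

    def test_round_trip(self, tmp_path):
        report = InfluencerReport(
            per_protein={"p1": [("a", 0.5), ("b", 0.3)], "p2": [("c", 1.0)]},
            k=7, method_tag="readout_attention", filter_label="cmp",
        )
        path = tmp_path / "report.tsv"
        write_influencer_report(report, path)
        back = read_influencer_report(path)
        assert back.k == 7
        assert back.method_tag == "readout_attention"
        assert back.filter_label == "cmp"
        for pid in report.per_protein:
            assert [g for g, _ in back.per_protein[pid]] == \
                [g for g, _ in report.per_protein[pid]]
            np.testing.assert_allclose(
                [s for _, s in back.per_protein[pid]],
                [s for _, s in report.per_protein[pid]],
            )

    def test_empty_report_writes_header_only(self, tmp_path):
        report = InfluencerReport(per_protein={}, k=25, method_tag="test")
        path = tmp_path / "report.tsv"
        write_influencer_report(report, path)
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        assert len(lines) == 2  # metadata comment + column header


@pytest.fixture(scope="module")
def trained():
    from tfinfluence.model import Dataset, ModelConfig, build_model, train
    from tfinfluence.preprocess import ModelInputTensor, ProteinLabelMatrix

    rng = np.random.default_rng(0)
    genes = [f"g{i:02d}" for i in range(10)]
    prots = ["pA", "pB", "pC"]
    flag = np.array([1.0] * 4 + [0.0] * 6)
    expr = rng.random((10, 8))
    tensor = ModelInputTensor(genes, [f"s{j}" for j in range(8)], expr, flag)
    vals = rng.random((3, 8))
    labels = ProteinLabelMatrix(prots, list(tensor.sample_ids),
                                (vals >= 0.6).astype(float), 0.6, vals)
    ds = Dataset(tensor, labels, ["estrus"] * 8)
    cfg = ModelConfig(d_model=4, ffn_hidden=6, max_epochs=6, n_aug=6,
                      early_stop_patience=3, n_restarts=1, seed=0)
    model = train(build_model(cfg, genes, prots, flag), ds)
    return model, tensor


class TestExtractInfluence:
    @pytest.mark.parametrize("method", ["saliency", "readout_attention",
                                        "attention_only", "attention_column"])
    def test_columns_sum_to_one_for_every_method(self, trained, method):
        from tfinfluence.influence import extract_influence

        model, tensor = trained
        infl = extract_influence(model, tensor, method=method)
        np.testing.assert_allclose(infl.scores.sum(axis=0), 1.0, rtol=1e-9)
        assert infl.method_tag == method

    def test_single_sample_dataset_equals_single_sample_extraction(self, trained):
        from tfinfluence.influence import extract_influence
        from tfinfluence.preprocess import ModelInputTensor

        model, tensor = trained
        one = ModelInputTensor(list(tensor.gene_ids), [tensor.sample_ids[0]],
                               tensor.expression[:, :1], tensor.tf_flag)
        a = extract_influence(model, one)
        b = extract_influence(model, one)  # deterministic
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_invariant_to_gene_input_order(self, trained):
        from tfinfluence.influence import extract_influence
        from tfinfluence.preprocess import ModelInputTensor

        model, tensor = trained
        perm = np.random.default_rng(1).permutation(len(tensor.gene_ids))
        shuffled = ModelInputTensor([tensor.gene_ids[i] for i in perm],
                                    list(tensor.sample_ids),
                                    tensor.expression[perm], tensor.tf_flag[perm])
        a = extract_influence(model, tensor)
        b = extract_influence(model, shuffled)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)
        assert a.gene_ids == b.gene_ids

    def test_untrained_model_rejected(self):
        from tfinfluence.influence import extract_influence
        from tfinfluence.model import ModelConfig, build_model
        from tfinfluence.preprocess import ModelInputTensor

        genes = ["a", "b"]
        model = build_model(ModelConfig(d_model=4), genes, ["p"], np.zeros(2))
        tensor = ModelInputTensor(genes, ["s0"], np.zeros((2, 1)), np.zeros(2))
        with pytest.raises(ContractError):
            extract_influence(model, tensor)
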