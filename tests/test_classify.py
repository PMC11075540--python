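"""Order prediction, expanded-gene masking, phylogenetic disambiguation,
and the curation decision cascade."""

import dendropy
import numpy as np
import pytest

from tecurate.classify import (
    ClassificationRecord,
    OrderPrediction,
    classify_consensus,
    curate_library,
    mask_expanded_genes,
    predict_order_kmer,
    resolve_ambiguous,
    train_order_model,
)
from tecurate.profiles import ProfileHit
from tecurate.seqio import SequenceRecord
from tecurate.simulate import (
    COARSE_COMPOSITION,
    mutate_protein,
    random_dna,
    random_protein,
)
from tecurate.tirs import TIRFeature


def _hit(qid, profile, score, order, superfamily="", span=200):
    return ProfileHit(qid, profile, score, 0, span, order, superfamily)


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(42)
    records, labels = [], []
    for coarse in ("nonLTR", "LTR", "DNA"):
        for i in range(20):
            records.append(
                SequenceRecord(
                    f"{coarse}_{i}",
                    random_dna(rng, 1_500, COARSE_COMPOSITION[coarse]),
                )
            )
            labels.append(coarse)
    return train_order_model(records, labels), records, labels


@pytest.fixture(scope="module")
def ambiguity_references():
    rng = np.random.default_rng(7)
    dirs_base = random_protein(rng, 150)
    crypton_base = random_protein(rng, 150)
    refs = []
    for i in range(3):
        refs.append((f"DIRS_{i}", "DIRS", mutate_protein(rng, dirs_base, 0.08)))
        refs.append(
            (f"Crypton_{i}", "Crypton", mutate_protein(rng, crypton_base, 0.08))
        )
    return refs, dirs_base


class TestOrderPredictor:

    def test_resubstitution_recovers_training_label(self, model):
        m, records, labels = model
        pred = predict_order_kmer(records[0], m)
        assert pred.label == labels[0]

    def test_held_out_accuracy(self, model):
        m, _, _ = model
        rng = np.random.default_rng(43)
        correct = total = 0
        for coarse in ("nonLTR", "LTR", "DNA"):
            for i in range(34):
                rec = SequenceRecord(
                    f"h{coarse}{i}", random_dna(rng, 1_500, COARSE_COMPOSITION[coarse])
                )
                correct += predict_order_kmer(rec, m).label == coarse
                total += 1
        assert correct / total >= 0.9

    def test_all_n_sequence_is_unknown(self, model):
        m, _, _ = model
        pred = predict_order_kmer(SequenceRecord("n", "N" * 500), m)
        assert pred.label == "unknown"
        assert pred.confidence <= 1 / 3 + 1e-9

    def test_untrained_model_errors(self):
        from tecurate.classify import KmerOrderModel

        with pytest.raises(ValueError, match="untrained"):
            predict_order_kmer(SequenceRecord("x", "ACGT" * 100), KmerOrderModel())


class TestExpandedGeneMask:
    def test_expanded_dominance_masks(self):
        te = []
        exp = [_hit("c1", "Sel1", 80.0, "expanded")]
        assert mask_expanded_genes(te, exp) == {"c1"}

    def test_te_dominance_not_masked(self):
        te = [_hit("c1", "RT-Gypsy", 120.0, "LTR", "Gypsy")]
        exp = [_hit("c1", "Sel1", 20.0, "expanded")]
        assert mask_expanded_genes(te, exp) == set()

    def test_no_hits_not_masked(self):
        assert mask_expanded_genes([], []) == set()


class TestResolveAmbiguous:
    CONFLICTS = [
        _hit("q", "YR-DIRS", 100.0, "DIRS"),
        _hit("q", "YR-Crypton", 95.0, "Crypton"),
    ]

    def test_mutated_dirs_query_assigned_dirs(self, ambiguity_references):
        refs, dirs_base = ambiguity_references
        rng = np.random.default_rng(8)
        query = mutate_protein(rng, dirs_base, 0.05)
        order, _, resolved = resolve_ambiguous("q", self.CONFLICTS, refs, query)
        assert order == "DIRS" and resolved

    def test_equidistant_query_falls_back_to_best_score(self):
        # two identical reference groups: the query is equidistant by
        # construction
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        refs = [("DIRS_0", "DIRS", seq), ("Crypton_0", "Crypton", seq)]
        order, _, resolved = resolve_ambiguous("q", self.CONFLICTS, refs, seq)
        assert order == "DIRS"  # best score
        assert not resolved

    def test_external_tree_overrides_nj(self, ambiguity_references):
        refs, dirs_base = ambiguity_references
        rng = np.random.default_rng(9)
        query = mutate_protein(rng, dirs_base, 0.05)  # NJ would say DIRS
        newick = (
            "((q:0.01, Crypton_0:0.01):0.1, (DIRS_0:0.01, DIRS_1:0.01,"
            " DIRS_2:0.01):0.1, (Crypton_1:0.02, Crypton_2:0.02):0.1);"
        )
        tree = dendropy.Tree.get(data=newick, schema="newick")
        order, _, resolved = resolve_ambiguous(
            "q", self.CONFLICTS, refs, query, external_tree=tree
        )
        assert order == "Crypton" and resolved


class TestClassifyConsensus:
    PRED_DNA = OrderPrediction("c", "DNA", 0.95)
    PRED_LTR = OrderPrediction("c", "LTR", 0.95)
    TIR = TIRFeature(0, 12, 2988, 3000, 12, 0)

    @staticmethod
    def _rec(n=3_000):
        return SequenceRecord("c", "ACGT" * (n // 4))

    def test_dna_tir_all_four_criteria_curated(self):
        hit = _hit("c", "transposase-hAT", 110.0, "DNA/TIR", "hAT")
        res = classify_consensus(
            self._rec(), self.PRED_DNA, hit, [hit], self.TIR, set()
        )
        assert res.status == "curated"
        assert (res.te_class, res.te_order, res.te_superfamily) == (
            "II", "DNA/TIR", "hAT",
        )

    def test_removing_tir_breaks_curation(self):
        hit = _hit("c", "transposase-hAT", 110.0, "DNA/TIR", "hAT")
        res = classify_consensus(
            self._rec(), self.PRED_DNA, hit, [hit], None, set()
        )
        assert res.status == "unresolved"

    @pytest.mark.parametrize("n, ok", [(500, False), (3_000, True), (18_000, False)])
    def test_size_window_gates_dna_tir(self, n, ok):
        hit = _hit("c", "transposase-hAT", 110.0, "DNA/TIR", "hAT")
        tir = TIRFeature(0, 12, n - 12, n, 12, 0)
        res = classify_consensus(
            self._rec(n), self.PRED_DNA, hit, [hit], tir, set()
        )
        assert (res.status == "curated") is ok

    def test_no_hit_no_tir_is_relic(self):
        res = classify_consensus(
            self._rec(1_500), self.PRED_DNA, None, [], None, set()
        )
        assert res.status == "relic"
        assert not res.evidence["domain_hit"]

    def test_mite_curated_without_domain(self):
        rec = SequenceRecord("c", "ACGT" * 75)  # 300 bp
        tir = TIRFeature(0, 12, 288, 300, 12, 0)
        res = classify_consensus(rec, self.PRED_DNA, None, [], tir, set())
        assert res.status == "curated" and res.te_order == "MITE"

    def test_ltr_with_rt_hit_needs_no_tir(self):
        hit = _hit("c", "RT-Gypsy", 130.0, "LTR", "Gypsy")
        res = classify_consensus(
            self._rec(4_000), self.PRED_LTR, hit, [hit], None, set()
        )
        assert res.status == "curated"
        assert (res.te_class, res.te_order, res.te_superfamily) == (
            "I", "LTR", "Gypsy",
        )

    def test_prediction_disagreement_is_unresolved(self):
        hit = _hit("c", "RT-Gypsy", 130.0, "LTR", "Gypsy")
        res = classify_consensus(
            self._rec(4_000), self.PRED_DNA, hit, [hit], None, set()
        )
        assert res.status == "unresolved"

    def test_masked_id_is_expanded_gene(self):
        hit = _hit("c", "RT-Gypsy", 130.0, "LTR", "Gypsy")
        res = classify_consensus(
            self._rec(), self.PRED_LTR, hit, [hit], None, {"c"}
        )
        assert res.status == "expanded_gene"

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            ClassificationRecord(
                "c", "II", "DNA/TIR", "hAT", "fam", "curated",
                {"domain_hit": True, "tir": False, "size_ok": True},
            )


class TestCurateLibrary:
    def test_generator_truth_counts(self, sim_library, pipeline_result):
        truth = sim_library.truth.set_index("consensus_id")["true_status"]
        table = pipeline_result.table.set_index("consensus_id")
        expected = truth.value_counts().to_dict()
        got = pipeline_result.summary["by_status"]
        assert got == expected

    def test_statuses_partition_input(self, sim_library, pipeline_result):
        assert (
            sum(pipeline_result.summary["by_status"].values())
            == len(sim_library.records)
        )

    def test_empty_input(self, tmp_path):
        curated, table, summary = curate_library([], [], out_dir=tmp_path)
        assert curated == [] and summary["n_curated"] == 0
        assert (tmp_path / "curated.fasta").exists()

    def test_curated_headers_follow_library_convention(self, pipeline_result):
        for rec in pipeline_result.curated:
            assert "#" in rec.id
            family, taxo = rec.id.split("#", 1)
            assert family and taxo
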