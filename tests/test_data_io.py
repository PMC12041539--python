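"""CSV ingestion, fixture molecules, the synthetic task, metrics, checkpoints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specgin import (
    SpectralGraphAutoencoder,
    fixture_molecules,
    load_graphs,
    read_smiles_csv,
    roc_auc,
    save_graphs,
    smiles_to_graph,
    synthetic_classification_dataset,
)
from specgin.checkpoint import (
    load_classifier,
    load_pretrainer,
    read_checkpoint,
    save_pretrainer,
    write_checkpoint,
)
from specgin.spectral import ChebEncoder


class TestCsvReader:
    def test_bad_smiles_dropped_and_counted(self, tmp_path, caplog):
        p = tmp_path / "d.csv"
        p.write_text("smiles,task\nCCO,1\nnot_a_smiles,0\nc1ccccc1,\n")
        with caplog.at_level("WARNING"):
            table = read_smiles_csv(p)
        assert len(table) == 2 and table.n_dropped == 1
        assert "dropping row" in caplog.text

    def test_label_column_count(self, tmp_path):
        cols = ",".join(f"t{i}" for i in range(12))
        p = tmp_path / "d.csv"
        p.write_text(f"smiles,{cols}\nCCO,{','.join('1' * 12)}\n")
        assert read_smiles_csv(p).n_tasks == 12

    def test_empty_cell_is_missing_not_zero(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("smiles,a,b\nCCO,,1\n")
        table = read_smiles_csv(p)
        assert np.isnan(table.labels[0, 0]) and table.labels[0, 1] == 1.0

    def test_missing_smiles_column_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("mol,task\nCCO,1\n")
        with pytest.raises(ValueError, match="smiles"):
            read_smiles_csv(p)


class TestFixtures:
    def test_at_least_200_and_deterministic(self):
        fx = fixture_molecules()
        assert len(fx) >= 200
        assert fx == fixture_molecules()

    def test_every_fixture_parses(self, fixture_graphs):
        assert all(g.n_nodes >= 1 for g in fixture_graphs)

    def test_feature_coverage(self, fixture_graphs):
        has_aromatic = any(g.node_features[:, 26].any() for g in fixture_graphs)
        # a charged atom occupies a formal-charge slot other than index 3 (0)
        charge_cols = np.array([0, 1, 2, 4, 5, 6])
        has_charge = any(
            g.node_features[:, charge_cols].any() for g in fixture_graphs
        )
        # E or Z stereo flags live in bond-vector slots 7 and 8
        has_stereo = any(
            len(g.edge_features) and g.edge_features[:, 7:9].any()
            for g in fixture_graphs
        )
        assert has_aromatic and has_charge and has_stereo


class TestSyntheticTask:
    def test_labels_recomputable_from_graphs(self):
        ds = synthetic_classification_dataset(60, np.random.default_rng(0))
        for smi, label in zip(ds.smiles, ds.labels[:, 0]):
            g = smiles_to_graph(smi)
            assert float(g.node_features[:, 25].any()) == label

    def test_same_seed_identical(self):
        d1 = synthetic_classification_dataset(40, np.random.default_rng(9))
        d2 = synthetic_classification_dataset(40, np.random.default_rng(9))
        assert d1.smiles == d2.smiles
        np.testing.assert_array_equal(d1.labels, d2.labels)

    def test_class_balance_at_500(self):
        ds = synthetic_classification_dataset(500, np.random.default_rng(1))
        assert 0.4 <= ds.labels.mean() <= 0.6

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            synthetic_classification_dataset(5, np.random.default_rng(0))


def _pairwise_auc(y, s):
    """O(n^2) oracle: P(score_pos > score_neg), ties counting one half."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3]) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            y = (rng.random(20) < 0.5).astype(float)
            if y.min() == y.max():
                continue
            s = rng.choice([0.1, 0.4, 0.4, 0.7, 0.9], size=20)
            assert roc_auc(y, s) == pytest.approx(_pairwise_auc(y, s), abs=1e-12)

    @given(shift=st.floats(-3, 3), scale=st.floats(0.1, 5))
    @settings(max_examples=30, derandomize=True)
    def test_invariant_to_monotone_transform(self, shift, scale):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 10, dtype=float)
        s = rng.random(20)
        assert roc_auc(y, s) == pytest.approx(
            roc_auc(y, np.exp(scale * s) + shift)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_multilabel_macro_with_missing(self):
        y = np.array([[0, 1], [1, np.nan], [0, 0], [1, 1]])
        s = np.array([[0.1, 0.9], [0.8, 0.5], [0.2, 0.2], [0.9, 0.7]])
        expected = (roc_auc(y[:, 0], s[:, 0])
                    + roc_auc(np.array([1., 0, 1]), np.array([0.9, 0.2, 0.7]))) / 2
        assert roc_auc(y, s) == pytest.approx(expected)


class TestCheckpoint:
    def test_bit_exact_roundtrip(self, tmp_path):
        enc = ChebEncoder(np.random.default_rng(0))
        path = tmp_path / "enc.npz"
        write_checkpoint(enc, path, config={"note": "test"}, seed=7)
        ckpt = read_checkpoint(path)
        assert ckpt.seed == 7 and ckpt.version == 1
        for name, arr in enc.state_dict().items():
            np.testing.assert_array_equal(ckpt.weights[name], arr)

    def test_truncated_file_rejected(self, tmp_path):
        enc = ChebEncoder(np.random.default_rng(0))
        path = tmp_path / "enc.npz"
        write_checkpoint(enc, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="corrupt"):
            read_checkpoint(path)

    def test_pretrainer_roundtrip_preserves_embeddings(self, tmp_path):
        graphs = [smiles_to_graph(s) for s in ["CCO", "c1ccccc1", "CCCN"]]
        est = SpectralGraphAutoencoder(epochs=1, random_state=0).fit(graphs)
        path = tmp_path / "pre.npz"
        save_pretrainer(est, path)
        loaded = load_pretrainer(path)
        for a, b in zip(est.transform(graphs), loaded.transform(graphs)):
            np.testing.assert_array_equal(a, b)

    def test_classifier_roundtrip_preserves_predictions(self, tmp_path):
        from specgin import DualBranchGraphClassifier
        from specgin.checkpoint import save_classifier

        graphs = [smiles_to_graph(s) for s in
                  ["CCO", "c1ccccc1", "CCCN", "C1CCCCC1", "CCOC", "Cc1ccccc1",
                   "CCCC", "c1ccncc1", "CCN", "C1CCOC1"]]
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        est = DualBranchGraphClassifier(
            epochs=2, random_state=1, validation_fraction=0.0
        ).fit(graphs, y)
        path = tmp_path / "clf.npz"
        save_classifier(est, path)
        loaded = load_classifier(path)
        np.testing.assert_array_equal(
            est.predict_proba(graphs), loaded.predict_proba(graphs)
        )


class TestGraphContainer:
    def test_roundtrip(self, tmp_path):
        graphs = [smiles_to_graph("CCO", labels=[1.0]),
                  smiles_to_graph("c1ccccc1", labels=[0.0])]
        path = tmp_path / "g.npz"
        save_graphs(path, graphs)
        loaded = load_graphs(path)
        assert [g.smiles for g in loaded] == ["CCO", "c1ccccc1"]
        np.testing.assert_array_equal(loaded[0].node_features,
                                      graphs[0].node_features)
        np.testing.assert_array_equal(loaded[1].edge_index, graphs[1].edge_index)


class TestCli:
    def test_featurize_train_evaluate_pipeline(self, tmp_path):
        from click.testing import CliRunner

        from specgin.cli import main

        csv = tmp_path / "mols.csv"
        rows = ["CCO,0", "c1ccccc1,1", "CCCN,0", "C1CCCCC1,1", "CCOC,0",
                "Cc1ccccc1,1", "CCCC,0", "c1ccncc1,1", "CCN,0", "C1CCOC1,1"]
        csv.write_text("smiles,has_ring\n" + "\n".join(rows) + "\n")
        runner = CliRunner()
        graphs = tmp_path / "g.npz"
        r = runner.invoke(main, ["featurize", "--in", str(csv), "--out", str(graphs)])
        assert r.exit_code == 0, r.output
        model = tmp_path / "m.npz"
        r = runner.invoke(main, [
            "train", "--data", str(graphs), "--out", str(model),
            "--epochs", "2", "--seed", "0",
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["evaluate", "--model", str(model),
                                 "--data", str(graphs)])
        assert r.exit_code == 0, r.output
        assert "ROC-AUC" in r.output
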