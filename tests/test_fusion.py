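import math
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histofuse import fusion
from histofuse.fusion import (
    FusionConfig,
    bow_feature_name,
    bow_fit,
    bow_transform,
    build_documents,
    build_feature_matrix,
    discretize,
    document_tokens,
    fit_tfidf,
    likelihood_vocabulary,
    plh_features,
)


class TestDiscretize:
    @pytest.mark.parametrize("p,decimals,want", [
        (0.386, 2, "0.39"),
        (0.0, 1, "0"),
        (0.0, 2, "0"),
        (0.25, 1, "0.3"),       # half-up, not banker's
        (0.145, 2, "0.15"),
        (0.9, 2, "0.9"),        # trailing zeros stripped
        (1.0, 1, "1"),
        (0.04, 2, "0.04"),
        (0.05, 1, "0.1"),
    ])
    def test_values(self, p, decimals, want):
        assert discretize(p, decimals) == want

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            discretize(1.2, 1)
        with pytest.raises(ValueError):
            discretize(-0.1, 2)

    @given(st.floats(0, 1), st.sampled_from([1, 2]))
    @settings(max_examples=200, deadline=None)
    def test_decimal_arithmetic_oracle(self, p, decimals):
        got = discretize(p, decimals)
        want = Decimal(repr(p)).quantize(Decimal(1).scaleb(-decimals),
                                         rounding=ROUND_HALF_UP)
        assert Decimal(got) == want

    def test_vocabulary_sizes(self):
        assert len(likelihood_vocabulary(1)) == 11
        assert len(likelihood_vocabulary(2)) == 101
        assert likelihood_vocabulary(1)[:3] == ["0", "0.1", "0.2"]

    def test_feature_naming_convention(self):
        assert fusion.plh_feature_name("0.39") == "hist_-0.39"
        assert bow_feature_name("0.39") == "bow_039"
        assert bow_feature_name("0.9") == "bow_09"
        assert bow_feature_name("0.04") == "bow_004"
        assert bow_feature_name("1") == "bow_1"


class TestPlh:
    def test_point_mass(self):
        doc = pd.DataFrame({"p_A": [0.3] * 4, "p_B": [0.7] * 4,
                            "label": ["B"] * 4})
        f = plh_features(doc, FusionConfig(decimals=1, include_labels=False),
                         classes=["A", "B"])
        assert f["hist_-0.7"] == 1.0
        assert f.drop("hist_-0.7").sum() == 0.0

    def test_hand_counted_histogram(self, tiny_table):
        table, _ = tiny_table
        doc = table[table.case_id == "c1"]
        f = plh_features(doc, FusionConfig(decimals=1, include_labels=False),
                         classes=["A", "B"])
        # {0.14, 0.17, 0.86} -> 0.1, 0.2 (0.17 rounds up), 0.9
        assert f["hist_-0.1"] == pytest.approx(1 / 3)
        assert f["hist_-0.2"] == pytest.approx(1 / 3)
        assert f["hist_-0.9"] == pytest.approx(1 / 3)

    def test_normalization(self, binary_cohort):
        _, table, _ = binary_cohort
        doc = table[table.case_id == table.case_id.iloc[0]]
        cfg = FusionConfig(decimals=2, include_labels=True)
        f = plh_features(doc, cfg, classes=["A", "B"])
        lik = [fusion.plh_feature_name(t) for t in likelihood_vocabulary(2)]
        lab = [fusion.plh_feature_name(t) for t in ("A", "B")]
        assert f[lik].sum() == pytest.approx(1.0)
        assert f[lab].sum() == pytest.approx(1.0)

    def test_empty_document_names_it(self):
        with pytest.raises(ValueError, match="'caseX'"):
            plh_features(pd.DataFrame(columns=["p_A", "p_B", "label"]),
                         FusionConfig(), classes=["A", "B"],
                         document_id="caseX")


def tfidf_oracle(corpus: dict[str, list[str]], vocab: list[str],
                 doc: list[str]) -> dict[str, float]:
    """Brute-force smoothed TF-IDF with L2 normalization."""
    n = len(corpus)
    df = {t: sum(t in d for d in corpus.values()) for t in vocab}
    idf = {t: math.log((1 + n) / (1 + df[t])) + 1 for t in vocab}
    tf = {t: doc.count(t) / len(doc) for t in vocab}
    raw = {t: tf[t] * idf[t] for t in vocab}
    nrm = math.sqrt(sum(v * v for v in raw.values()))
    return {t: (v / nrm if nrm else 0.0) for t, v in raw.items()}


class TestBow:
    VOCAB = ["0.1", "0.5", "0.9"]

    def test_token_in_every_doc_idf_one(self):
        model = bow_fit({"a": ["0.1"], "b": ["0.1", "0.5"]}, self.VOCAB)
        assert model.idf["0.1"] == pytest.approx(1.0)

    def test_two_document_oracle(self):
        corpus = {"A": ["0.1", "0.1", "0.9"], "B": ["0.9"]}
        model = bow_fit(corpus, self.VOCAB)
        got = bow_transform(corpus["A"], model)
        want = tfidf_oracle(corpus, self.VOCAB, corpus["A"])
        for t in self.VOCAB:
            assert got[bow_feature_name(t)] == pytest.approx(want[t])

    def test_unseen_token_smoothed(self):
        model = bow_fit({"a": ["0.1"], "b": ["0.1"]}, self.VOCAB)
        out = bow_transform(["0.5"], model)
        # df=0 -> idf = ln(3/1)+1; single token -> unit after L2
        assert out[bow_feature_name("0.5")] == pytest.approx(1.0)

    def test_single_training_document_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            bow_fit({"only": ["0.1"]}, self.VOCAB)

    def test_unit_norm(self):
        model = bow_fit({"a": ["0.1", "0.5"], "b": ["0.9"]}, self.VOCAB)
        v = bow_transform(["0.1", "0.9", "0.9"], model).to_numpy()
        assert np.linalg.norm(v) == pytest.approx(1.0)

    @given(st.lists(st.sampled_from(["0.1", "0.5", "0.9"]), min_size=1,
                    max_size=10),
           st.integers(0, 10))
    @settings(max_examples=60, deadline=None)
    def test_oracle_property(self, doc, seed):
        rng = np.random.default_rng(seed)
        corpus = {f"d{i}": [self.VOCAB[j] for j in
                            rng.integers(0, 3, rng.integers(1, 6))]
                  for i in range(rng.integers(2, 6))}
        model = bow_fit(corpus, self.VOCAB)
        got = bow_transform(doc, model)
        want = tfidf_oracle(corpus, self.VOCAB, doc)
        for t in self.VOCAB:
            assert got[bow_feature_name(t)] == pytest.approx(want[t])

    def test_json_roundtrip(self, tmp_path):
        model = bow_fit({"a": ["0.1"], "b": ["0.9"]}, self.VOCAB)
        model.to_json(tmp_path / "m.json")
        back = fusion.TfidfModel.from_json(tmp_path / "m.json")
        assert back.idf == model.idf

    def test_matches_sklearn_convention(self):
        from sklearn.feature_extraction.text import TfidfVectorizer

        corpus = {"a": ["x", "x", "y"], "b": ["y", "z"], "c": ["z"]}
        vec = TfidfVectorizer(vocabulary=["x", "y", "z"],
                              analyzer=lambda d: d)
        ref = vec.fit_transform(list(corpus.values())).toarray()
        model = bow_fit(corpus, ["x", "y", "z"])
        for i, doc in enumerate(corpus.values()):
            mine = bow_transform(doc, model).to_numpy()
            assert np.allclose(mine, ref[i])


class TestDocuments:
    def make(self, sizes: dict[str, dict[str, int]]):
        rows = []
        for case, slides in sizes.items():
            for slide, n in slides.items():
                for i in range(n):
                    rows.append({"case_id": case, "slide_id": slide,
                                 "col": i, "row": 0, "p_A": 0.4, "p_B": 0.6,
                                 "label": "B"})
        table = pd.DataFrame(rows)
        cohort = pd.DataFrame({"case_id": list(sizes),
                               "class_label": "A", "recurrence": 0})
        return table, cohort

    def test_multi_slide_pooling(self):
        table, cohort = self.make({"c1": {"s1": 10, "s2": 20}})
        docs = build_documents(table, cohort, FusionConfig())
        assert len(docs["c1"]) == 30

    def test_single_slide_selection(self):
        table, cohort = self.make({"c1": {"s1": 10, "s2": 20}})
        docs = build_documents(table, cohort,
                               FusionConfig(document_unit="single_slide"))
        assert len(docs["c1"]) == 20
        assert set(docs["c1"].slide_id) == {"s2"}

    def test_single_slide_tie_lexicographic(self):
        table, cohort = self.make({"c1": {"sB": 5, "sA": 5}})
        docs = build_documents(table, cohort,
                               FusionConfig(document_unit="single_slide"))
        assert set(docs["c1"].slide_id) == {"sA"}

    def test_one_slide_case_identical_across_units(self):
        table, cohort = self.make({"c1": {"s1": 7}})
        multi = build_documents(table, cohort, FusionConfig())
        single = build_documents(table, cohort,
                                 FusionConfig(document_unit="single_slide"))
        pd.testing.assert_frame_equal(multi["c1"], single["c1"])

    def test_empty_case_excluded_with_warning(self):
        table, cohort = self.make({"c1": {"s1": 3}})
        cohort = pd.concat([cohort, pd.DataFrame([{
            "case_id": "c2", "class_label": "A", "recurrence": 0}])],
            ignore_index=True)
        with pytest.warns(UserWarning, match="c2"):
            docs = build_documents(table, cohort, FusionConfig())
        assert "c2" not in docs

    def test_unknown_case_rejected(self):
        table, cohort = self.make({"c1": {"s1": 3}})
        with pytest.raises(ValueError, match="unknown document ids"):
            build_documents(table, cohort.iloc[0:0], FusionConfig())


class TestFeatureMatrix:
    def test_prognostic_206_columns(self, binary_cohort):
        _, table, cohort = binary_cohort
        cfg = FusionConfig.prognostic()
        tfidf = fit_tfidf(table, cohort, cfg)
        mat = build_feature_matrix(table, cohort, cfg, tfidf)
        assert mat.shape[1] == 206
        assert "hist_-0.39" in mat.columns
        assert "bow_039" in mat.columns
        assert "hist_-A" in mat.columns and "bow_B" in mat.columns

    def test_diagnostic_25_columns_three_classes(self):
        rows = []
        for c, cls in (("c1", "A"), ("c2", "B"), ("c3", "C")):
            for i in range(5):
                rows.append({"case_id": c, "slide_id": f"{c}_s", "col": i,
                             "row": 0, "p_A": 0.2, "p_B": 0.3, "p_C": 0.5,
                             "label": cls})
        table = pd.DataFrame(rows)
        cohort = pd.DataFrame({"case_id": ["c1", "c2", "c3"],
                               "class_label": ["A", "B", "C"],
                               "recurrence": 0})
        cfg = FusionConfig.diagnostic()
        tfidf = fit_tfidf(table, cohort, cfg)
        mat = build_feature_matrix(table, cohort, cfg, tfidf)
        # (11 + 3) PLH + 11 BoW
        assert mat.shape[1] == 25
        assert not any(c in mat.columns for c in ("bow_A", "bow_B", "bow_C"))

    def test_empty_cohort_keeps_columns(self, binary_cohort):
        _, table, cohort = binary_cohort
        cfg = FusionConfig.prognostic()
        tfidf = fit_tfidf(table, cohort, cfg)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = build_feature_matrix(table.iloc[0:0], cohort.iloc[0:0],
                                       cfg, tfidf)
        assert mat.shape == (0, 206)

    def test_patch_order_invariance(self, binary_cohort):
        _, table, cohort = binary_cohort
        cfg = FusionConfig.prognostic()
        tfidf = fit_tfidf(table, cohort, cfg)
        mat1 = build_feature_matrix(table, cohort, cfg, tfidf)
        shuffled = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        mat2 = build_feature_matrix(shuffled, cohort, cfg, tfidf)
        pd.testing.assert_frame_equal(mat1.sort_index(), mat2.sort_index())

    def test_plh_sums_and_bow_norms(self, binary_cohort):
        _, table, cohort = binary_cohort
        cfg = FusionConfig.prognostic()
        tfidf = fit_tfidf(table, cohort, cfg)
        mat = build_feature_matrix(table, cohort, cfg, tfidf)
        lik = [fusion.plh_feature_name(t) for t in likelihood_vocabulary(2)]
        bow = [c for c in mat.columns if c.startswith("bow_")]
        assert np.allclose(mat[lik].sum(axis=1), 1.0)
        assert np.allclose(np.linalg.norm(mat[bow], axis=1), 1.0)
        assert (mat.to_numpy() >= 0).all()
        assert np.isfinite(mat.to_numpy()).all()

    def test_tfidf_fitted_on_train_split_only(self, binary_cohort):
        # mutating test-split rows must not change the fitted model
        _, table, cohort = binary_cohort
        from histofuse import signature

        coh = signature.assign_split(cohort, seed=0)
        cfg = FusionConfig.prognostic()
        m1 = fit_tfidf(table, coh, cfg)
        test_cases = set(coh.loc[coh.split == "test", "case_id"])
        mutated = table.copy()
        mask = mutated.case_id.isin(test_cases)
        mutated.loc[mask, "p_B"] = 0.123
        mutated.loc[mask, "p_A"] = 1 - 0.123
        m2 = fit_tfidf(mutated, coh, cfg)
        assert m1.df == m2.df and m1.n_documents == m2.n_documents

    def test_likelihood_class_designation(self, binary_cohort):
        _, table, cohort = binary_cohort
        cfg_a = FusionConfig.prognostic(likelihood_class="A")
        cfg_b = FusionConfig.prognostic(likelihood_class="B")
        docs = build_documents(table, cohort, cfg_a)
        doc = next(iter(docs.values()))
        ta = document_tokens(doc, cfg_a, ["A", "B"])
        tb = document_tokens(doc, cfg_b, ["A", "B"])
        assert ta != tb  # complementary likelihoods give different tokens
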