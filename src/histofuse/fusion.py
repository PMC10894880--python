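"""Multi-instance fusion of patch likelihoods into document-level features.

Two complementary pipelines, computed over a fixed token vocabulary:

* PLH (patch likelihood histogram): relative frequency of each discretized
  likelihood token (and optionally each predicted label) among a document's
  patches — features named ``hist_-<token>``.
* BoW (bag of words): smoothed TF-IDF weights over the same tokens, fitted
  on the training corpus only and L2-normalized per document — features
  named ``bow_<token without the decimal point>`` (0.39 -> ``bow_039``).

A "document" is either all slides of a case pooled together or one
designated slide per case (the slide with the most kept patches).

The binary prognostic configuration (two-decimal tokens, labels and
probabilities in both pipelines) yields (101 + 2) * 2 = 206 feature columns.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "FusionConfig",
    "TfidfModel",
    "discretize",
    "likelihood_vocabulary",
    "plh_feature_name",
    "bow_feature_name",
    "plh_features",
    "bow_fit",
    "bow_transform",
    "build_documents",
    "build_feature_matrix",
    "table_classes",
    "row_likelihoods",
]


def discretize(p: float, decimals: int) -> str:
    """Round a probability half-up to ``decimals`` places and render a token.

    Trailing zeros are stripped: 0.90 -> "0.9", 0.0 -> "0", 1.00 -> "1".
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability outside [0, 1]: {p}")
    q = Decimal(repr(float(p))).quantize(
        Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
    return str(q.normalize())


def likelihood_vocabulary(decimals: int) -> list[str]:
    """All decimal tokens in [0, 1] at the given precision (11 or 101)."""
    if decimals not in (1, 2):
        raise ValueError("decimals must be 1 or 2")
    step = 10 ** decimals
    return [str((Decimal(i) / step).normalize()) for i in range(step + 1)]


def plh_feature_name(token: str) -> str:
    return f"hist_-{token}"


def bow_feature_name(token: str) -> str:
    return f"bow_{token.replace('.', '')}"


@dataclass(frozen=True)
class FusionConfig:
    """Fusion configuration.

    label_scope: "both" puts predicted-label tokens in PLH and BoW
    (prognostic style); "plh_only" restricts them to the histogram
    (diagnostic style).  ``likelihood_class`` designates which class's
    probability is the per-patch likelihood; None means the positive
    (lexicographically last) class for binary tables and the row's predicted
    class for multiclass tables.
    """

    decimals: int = 2
    include_probabilities: bool = True
    include_labels: bool = True
    label_scope: str = "both"
    document_unit: str = "case_multi_slide"
    likelihood_class: str | None = None

    def __post_init__(self):
        if self.decimals not in (1, 2):
            raise ValueError("decimals must be 1 (diagnostic) or 2 (prognostic)")
        if self.label_scope not in ("both", "plh_only"):
            raise ValueError("label_scope must be 'both' or 'plh_only'")
        if self.document_unit not in ("case_multi_slide", "single_slide"):
            raise ValueError(
                "document_unit must be 'case_multi_slide' or 'single_slide'")

    @classmethod
    def diagnostic(cls, **kw) -> "FusionConfig":
        """One-decimal tokens; labels as histogram features only."""
        return cls(decimals=1, label_scope="plh_only", **kw)

    @classmethod
    def prognostic(cls, **kw) -> "FusionConfig":
        """Two-decimal tokens; labels and probabilities in both pipelines."""
        return cls(decimals=2, label_scope="both", **kw)

    def plh_tokens(self, classes: list[str]) -> list[str]:
        toks: list[str] = []
        if self.include_probabilities:
            toks += likelihood_vocabulary(self.decimals)
        if self.include_labels:
            toks += list(classes)
        return toks

    def bow_tokens(self, classes: list[str]) -> list[str]:
        toks: list[str] = []
        if self.include_probabilities:
            toks += likelihood_vocabulary(self.decimals)
        if self.include_labels and self.label_scope == "both":
            toks += list(classes)
        return toks

    def feature_names(self, classes: list[str]) -> list[str]:
        return ([plh_feature_name(t) for t in self.plh_tokens(classes)]
                + [bow_feature_name(t) for t in self.bow_tokens(classes)])


def table_classes(table: pd.DataFrame) -> list[str]:
    """Class labels implied by the ``p_<class>`` columns, sorted."""
    cls = sorted(c[2:] for c in table.columns if c.startswith("p_"))
    if not cls:
        raise ValueError("table has no p_<class> probability columns")
    return cls


def row_likelihoods(doc: pd.DataFrame, cfg: FusionConfig,
                    classes: list[str]) -> np.ndarray:
    """Per-patch scalar likelihood under the configured convention."""
    if cfg.likelihood_class is not None:
        col = f"p_{cfg.likelihood_class}"
        if col not in doc.columns:
            raise ValueError(f"no column {col} for designated likelihood class")
        return doc[col].to_numpy(dtype=float)
    probs = doc[[f"p_{c}" for c in classes]].to_numpy(dtype=float)
    if len(classes) == 2:
        return probs[:, -1]          # positive = lexicographically last class
    return probs.max(axis=1)         # predicted class's probability


def _doc_likelihood_tokens(doc: pd.DataFrame, cfg: FusionConfig,
                           classes: list[str]) -> list[str]:
    return [discretize(p, cfg.decimals)
            for p in row_likelihoods(doc, cfg, classes)]


def plh_features(doc: pd.DataFrame, cfg: FusionConfig,
                 classes: list[str] | None = None,
                 document_id: str = "?") -> pd.Series:
    """Histogram features of one document: per-token patch fractions.

    Likelihood-token features sum to 1 over the vocabulary, as do
    label-token features when enabled.
    """
    if len(doc) == 0:
        raise ValueError(f"document {document_id!r} has no kept patches")
    classes = classes or table_classes(doc)
    names = [plh_feature_name(t) for t in cfg.plh_tokens(classes)]
    out = pd.Series(0.0, index=names)
    n = len(doc)
    if cfg.include_probabilities:
        for tok, cnt in Counter(_doc_likelihood_tokens(doc, cfg, classes)).items():
            out[plh_feature_name(tok)] = cnt / n
    if cfg.include_labels:
        for tok, cnt in Counter(doc["label"]).items():
            out[plh_feature_name(str(tok))] = cnt / n
    return out


@dataclass
class TfidfModel:
    """Smoothed-idf TF-IDF weights fitted on the training corpus.

    idf(t) = ln((1 + N) / (1 + df(t))) + 1 over the N training documents;
    transform applies tf * idf and L2-normalizes, never refitting.
    """

    vocabulary: list[str]
    df: dict[str, int]
    n_documents: int

    @property
    def idf(self) -> dict[str, float]:
        n = self.n_documents
        return {t: np.log((1 + n) / (1 + self.df.get(t, 0))) + 1.0
                for t in self.vocabulary}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"vocabulary": self.vocabulary, "df": self.df,
                       "n_documents": self.n_documents, "idf": self.idf}, fh)

    @classmethod
    def from_json(cls, path) -> "TfidfModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(vocabulary=d["vocabulary"], df=d["df"],
                   n_documents=d["n_documents"])


def bow_fit(documents: dict[str, Counter | list[str]],
            vocabulary: list[str]) -> TfidfModel:
    """Fit document frequencies over the fixed vocabulary (training docs only)."""
    if len(documents) < 2:
        raise ValueError("need >= 2 training documents for a meaningful idf")
    df: dict[str, int] = {}
    for tokens in documents.values():
        for t in set(Counter(tokens)):
            df[t] = df.get(t, 0) + 1
    df = {t: df.get(t, 0) for t in vocabulary}
    return TfidfModel(vocabulary=list(vocabulary), df=df,
                      n_documents=len(documents))


def bow_transform(tokens: Counter | list[str], model: TfidfModel) -> pd.Series:
    """TF-IDF features of one document, L2-normalized (zero-safe)."""
    counts = Counter(tokens)
    total = sum(counts.values())
    idf = model.idf
    vals = np.array(
        [(counts.get(t, 0) / total if total else 0.0) * idf[t]
         for t in model.vocabulary])
    nrm = np.linalg.norm(vals)
    if nrm > 0:
        vals = vals / nrm
    return pd.Series(vals, index=[bow_feature_name(t) for t in model.vocabulary])


def build_documents(table: pd.DataFrame, cohort: pd.DataFrame,
                    cfg: FusionConfig) -> dict[str, pd.DataFrame]:
    """Group patch rows into one document per case.

    ``case_multi_slide`` pools every slide of the case; ``single_slide``
    keeps only the slide with most kept patches (ties: lexicographically
    smallest slide_id).  Cases without any kept patch are excluded with a
    warning.
    """
    known = set(cohort["case_id"])
    unknown = set(table["case_id"]) - known
    if unknown:
        raise ValueError(f"unknown document ids in table: {sorted(unknown)[:5]}")
    docs: dict[str, pd.DataFrame] = {}
    grouped = dict(tuple(table.groupby("case_id", sort=True)))
    for case_id in cohort["case_id"]:
        grp = grouped.get(case_id)
        if grp is None or len(grp) == 0:
            warnings.warn(f"case {case_id!r} has no kept patches; excluded",
                          stacklevel=2)
            continue
        if cfg.document_unit == "single_slide":
            sizes = grp.groupby("slide_id").size()
            best = sizes.index[np.lexsort((sizes.index, -sizes.values))][0]
            grp = grp[grp["slide_id"] == best]
        docs[case_id] = grp.reset_index(drop=True)
    return docs


def document_tokens(doc: pd.DataFrame, cfg: FusionConfig,
                    classes: list[str]) -> list[str]:
    """Token multiset of one document for the BoW pipeline."""
    toks: list[str] = []
    if cfg.include_probabilities:
        toks += _doc_likelihood_tokens(doc, cfg, classes)
    if cfg.include_labels and cfg.label_scope == "both":
        toks += [str(l) for l in doc["label"]]
    return toks


def fit_tfidf(table: pd.DataFrame, cohort: pd.DataFrame,
              cfg: FusionConfig) -> TfidfModel:
    """Fit the TF-IDF model on training documents (split=='train' when present)."""
    classes = table_classes(table)
    train = cohort
    if "split" in cohort.columns and (cohort["split"] == "train").any():
        train = cohort[cohort["split"] == "train"]
    sub = table[table["case_id"].isin(set(train["case_id"]))]
    docs = build_documents(sub, train, cfg)
    corpus = {d: document_tokens(g, cfg, classes) for d, g in docs.items()}
    return bow_fit(corpus, cfg.bow_tokens(classes))


def build_feature_matrix(table: pd.DataFrame, cohort: pd.DataFrame,
                         cfg: FusionConfig,
                         tfidf: TfidfModel) -> pd.DataFrame:
    """Documents x named-features matrix with the full fixed column set.

    Column count is determined by the vocabulary alone (206 for the binary
    prognostic configuration), regardless of token occupancy.
    """
    classes = table_classes(table)
    columns = cfg.feature_names(classes)
    docs = build_documents(table, cohort, cfg)
    rows = {}
    for doc_id, grp in docs.items():
        plh = plh_features(grp, cfg, classes, document_id=doc_id)
        bow = bow_transform(document_tokens(grp, cfg, classes), tfidf)
        rows[doc_id] = pd.concat([plh, bow])
    mat = pd.DataFrame.from_dict(rows, orient="index")
    if mat.empty:
        mat = pd.DataFrame(columns=columns, dtype=float)
    return mat.reindex(columns=columns, fill_value=0.0).astype(float)
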