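"""Trainable qualification: snippet → pooled embedding → dense layer.

The architecture mirrors the three-step contract of the rule-based
pipeline's learned counterpart: (1) embed each snippet token, (2) mean-pool
the embeddings of the *entity* tokens only (context enters through
neighbor features), (3) classify the pooled vector with a single
fully-connected layer.  Token embeddings here are hashed sparse lexical
features, so the module trains in seconds on CPU; the embedding backend is
a pluggable function, allowing a contextual language model to be
substituted without touching pooling or the classifier head.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin

from .types import Mention

KEEP, DISCARD = "keep", "discard"


@dataclass(frozen=True)
class LabeledSnippet:
    """A context window around one entity, with its keep/discard label.

    ``entity_range`` is (first, last) inclusive token indices within
    ``tokens``; ``label`` is ``"keep"`` or ``"discard"``.
    """

    tokens: tuple[str, ...]
    entity_range: tuple[int, int]
    label: Optional[str] = None

    def __post_init__(self) -> None:
        a, b = self.entity_range
        if not (0 <= a <= b < len(self.tokens)):
            raise ValueError(
                f"entity range {self.entity_range} outside snippet of "
                f"{len(self.tokens)} tokens"
            )
        if self.label not in (None, KEEP, DISCARD):
            raise ValueError(f"bad label {self.label!r}")


def _hash_index(feature: str, d: int) -> int:
    digest = hashlib.blake2b(feature.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") % d


def token_features(tokens: Sequence[str], i: int, entity: tuple[int, int]) -> list[str]:
    """Lexical feature strings for token ``i`` of a snippet."""
    a, b = entity
    if i < a:
        bucket = max(i - a, -3)
    elif i > b:
        bucket = min(i - b, 3)
    else:
        bucket = 0
    feats = [f"tok={tokens[i]}", f"pos={bucket}"]
    for off in (-2, -1, 1, 2):
        j = i + off
        neighbor = tokens[j] if 0 <= j < len(tokens) else "<pad>"
        feats.append(f"n{off:+d}={neighbor}")
    return feats


def featurize_snippet(snippet: LabeledSnippet, d: int) -> sparse.csr_matrix:
    """Mean of the hashed feature vectors of the entity-range tokens.

    Raises on an empty entity range (enforced at construction).
    """
    a, b = snippet.entity_range
    indices: dict[int, float] = {}
    for i in range(a, b + 1):
        for feat in token_features(snippet.tokens, i, (a, b)):
            idx = _hash_index(feat, d)
            indices[idx] = indices.get(idx, 0.0) + 1.0
    n_entity = b - a + 1
    cols = np.fromiter(indices.keys(), dtype=np.int64, count=len(indices))
    vals = np.fromiter(indices.values(), dtype=np.float64, count=len(indices)) / n_entity
    return sparse.csr_matrix((vals, (np.zeros_like(cols), cols)), shape=(1, d))


def featurize_snippets(snippets: Sequence[LabeledSnippet], d: int) -> sparse.csr_matrix:
    if not snippets:
        return sparse.csr_matrix((0, d))
    return sparse.vstack([featurize_snippet(s, d) for s in snippets], format="csr")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SnippetQualifier(BaseEstimator, ClassifierMixin):
    """Keep/discard classifier over pooled hashed snippet embeddings.

    Logistic head trained by full-batch gradient descent with backtracking
    line search, so the training loss is nonincreasing by construction and
    runs are bit-reproducible for a fixed ``random_state``.

    Parameters
    ----------
    n_features : hashing dimension d of the feature space.
    epochs : gradient-descent steps.
    lr : initial learning rate (adapted by backtracking).
    threshold : keep-probability below which a mention is discarded.
    random_state : retained for provenance; training is deterministic.
    """

    def __init__(
        self,
        n_features: int = 2**16,
        epochs: int = 200,
        lr: float = 10.0,
        threshold: float = 0.5,
        random_state: int = 0,
    ) -> None:
        self.n_features = n_features
        self.epochs = epochs
        self.lr = lr
        self.threshold = threshold
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        X: Union[Sequence[LabeledSnippet], sparse.spmatrix],
        y: Optional[Sequence] = None,
    ) -> "SnippetQualifier":
        if y is None:
            snippets = list(X)
            labels = [s.label for s in snippets]
            if any(lab is None for lab in labels):
                raise ValueError("unlabeled snippet passed to fit without y")
            y_arr = np.array([1.0 if lab == KEEP else 0.0 for lab in labels])
            X_mat = featurize_snippets(snippets, self.n_features)
        else:
            y_arr = np.asarray(y, dtype=np.float64)
            X_mat = (
                X
                if sparse.issparse(X)
                else featurize_snippets(list(X), self.n_features)
            )
        if len(np.unique(y_arr)) < 2:
            raise ValueError("training data contains a single class")
        n = X_mat.shape[0]
        w = np.zeros(self.n_features)
        b = 0.0
        lr = float(self.lr)
        losses = []

        def loss_of(w_, b_):
            z = X_mat @ w_ + b_
            # stable log(1+exp(-|z|)) formulation
            return float(
                np.mean(np.maximum(z, 0) - z * y_arr + np.log1p(np.exp(-np.abs(z))))
            )

        current = loss_of(w, b)
        losses.append(current)
        for _ in range(self.epochs):
            p = _sigmoid(X_mat @ w + b)
            resid = p - y_arr
            grad_w = X_mat.T @ resid / n
            grad_b = float(np.mean(resid))
            trial = lr
            while True:
                w_new = w - trial * grad_w
                b_new = b - trial * grad_b
                new_loss = loss_of(w_new, b_new)
                if new_loss <= current or trial < 1e-12:
                    break
                trial *= 0.5
            if new_loss <= current:
                w, b, current = w_new, b_new, new_loss
            # let the step size recover after cautious epochs
            lr = min(self.lr, trial * 2.0)
            losses.append(current)
        self.coef_ = w
        self.intercept_ = b
        self.loss_curve_ = np.array(losses)
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = self.n_features
        return self

    # -- inference ---------------------------------------------------------
    def _matrix(self, X) -> sparse.spmatrix:
        if sparse.issparse(X):
            return X
        return featurize_snippets(list(X), self.n_features)

    def decision_function(self, X) -> np.ndarray:
        return self._matrix(X) @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(float)

    # -- persistence -------------------------------------------------------
    MAGIC = "charlson-nlp/qualifier"
    VERSION = 1

    def save(self, path: Union[str, Path]) -> None:
        np.savez_compressed(
            path,
            magic=np.array(self.MAGIC),
            version=np.array(self.VERSION),
            d=np.array(self.n_features),
            weights=self.coef_,
            bias=np.array(self.intercept_),
            threshold=np.array(self.threshold),
            seed=np.array(self.random_state),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SnippetQualifier":
        with np.load(path, allow_pickle=False) as data:
            if str(data["magic"]) != cls.MAGIC:
                raise ValueError(f"{path}: not a qualifier model file")
            model = cls(
                n_features=int(data["d"]),
                threshold=float(data["threshold"]),
                random_state=int(data["seed"]),
            )
            model.coef_ = data["weights"]
            model.intercept_ = float(data["bias"])
            model.classes_ = np.array([0.0, 1.0])
            model.n_features_in_ = model.n_features
        return model


def train_qualifier(
    snippets: Sequence[LabeledSnippet],
    d: int = 2**16,
    seed: int = 0,
    epochs: int = 200,
) -> SnippetQualifier:
    """Functional wrapper fitting a :class:`SnippetQualifier`."""
    return SnippetQualifier(n_features=d, epochs=epochs, random_state=seed).fit(
        list(snippets)
    )


def qualify_learned(
    mentions: Sequence[Mention],
    snippets: Sequence[LabeledSnippet],
    model: SnippetQualifier,
) -> list[Mention]:
    """Score mentions with the learned qualifier; discard below threshold.

    ``snippets`` must align one-to-one with ``mentions``.
    """
    if len(mentions) != len(snippets):
        raise ValueError("mentions and snippets must align")
    if not mentions:
        return []
    scores = model.predict_proba(list(snippets))[:, 1]
    for m, score in zip(mentions, scores):
        m.score = float(score)
        m.discarded = bool(score < model.threshold)
    return list(mentions)
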