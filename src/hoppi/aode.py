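"""Averaged One-Dependence Estimator (AODE) and a Naive Bayes baseline.

The AODE weakens the Naive Bayes independence assumption by averaging, over
every feature i usable as a parent, one-dependence estimators in which each
other feature depends on the class and on feature i:

    P(+|f_1..f_n) = sum_i P(+, f_i) prod_{j != i} P(f_j | +, f_i)
                    -----------------------------------------------
                    sum_c sum_i P(c, f_i) prod_{j != i} P(f_j | c, f_i)

with Laplace-smoothed base estimates

    P(c, f_i)      = (F(c, f_i) + 1) / (m_i + k v_i)
    P(c, f_i, f_j) = (F(c, f_i, f_j) + 1) / (m_ij + k v_i v_j)
    P(f_j | c, f_i) = P(c, f_i, f_j) / P(c, f_i)

where F(.) are training counts, m_i (m_ij) the number of training vectors
with feature i (features i and j) known, k the number of classes and v_i
the number of discrete bins of feature i.  Unknown (MISSING) features are
skipped in both the sums and the products.  Products are accumulated in
log space; with the handful of features used here this matches the naive
product to ~1e-12.

No minimum parent-frequency cutoff is applied by default (every known
feature serves as a parent); a configurable cutoff exists for users who
want the textbook m >= 30 rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .vectorizer import MISSING, DiscretizationScheme

POS, NEG = 1, 0  # class indices; classes are {negative, positive}


@dataclass
class AODEModel:
    """Laplace-smoothed count tables defining a fitted AODE.

    ``F1[c, i, a]`` counts training vectors of class c with feature i in
    bin a; ``F2[c, i, a, j, b]`` the corresponding pairwise counts
    (symmetric in its two feature slots); ``m[i]`` / ``m2[i, j]`` count
    vectors with the feature(s) known, pooled over classes.
    """

    v: np.ndarray  # (d,) bins per feature
    m: np.ndarray  # (d,)
    m2: np.ndarray  # (d, d)
    F1: np.ndarray  # (k, d, vmax)
    F2: np.ndarray  # (k, d, vmax, d, vmax)
    n_class: np.ndarray  # (k,) training vectors per class
    k: int = 2
    parent_min_count: int = 0
    scheme: DiscretizationScheme | None = None

    @property
    def d(self) -> int:
        return len(self.v)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> dict:
        obj = {
            "format": "hoppi-aode-1",
            "k": self.k,
            "v": self.v.tolist(),
            "m": self.m.tolist(),
            "m2": self.m2.tolist(),
            "F1": self.F1.tolist(),
            "F2": self.F2.tolist(),
            "n_class": self.n_class.tolist(),
            "parent_min_count": self.parent_min_count,
        }
        if self.scheme is not None:
            obj["scheme"] = self.scheme.to_json()
        return obj

    @classmethod
    def from_json(cls, obj: dict) -> "AODEModel":
        if obj.get("format") != "hoppi-aode-1":
            raise ValueError("unrecognized model file format")
        scheme = (
            DiscretizationScheme.from_json(obj["scheme"]) if "scheme" in obj else None
        )
        return cls(
            v=np.asarray(obj["v"], dtype=np.int64),
            m=np.asarray(obj["m"], dtype=np.int64),
            m2=np.asarray(obj["m2"], dtype=np.int64),
            F1=np.asarray(obj["F1"], dtype=np.int64),
            F2=np.asarray(obj["F2"], dtype=np.int64),
            n_class=np.asarray(obj["n_class"], dtype=np.int64),
            k=int(obj["k"]),
            parent_min_count=int(obj["parent_min_count"]),
            scheme=scheme,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "AODEModel":
        return cls.from_json(json.loads(Path(path).read_text()))


def fit(
    vectors: np.ndarray,
    labels: Sequence[int],
    v: Sequence[int],
    parent_min_count: int = 0,
    scheme: DiscretizationScheme | None = None,
) -> AODEModel:
    """Fit count tables from discrete vectors (MISSING = -1 allowed).

    ``v`` gives the number of bins per feature (from the discretization
    scheme); a bin index >= v_i indicates a scheme mismatch and raises.
    """
    X = np.asarray(vectors, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("training set must be a non-empty 2-D array")
    if len(X) != len(y):
        raise ValueError("vectors and labels length mismatch")
    v = np.asarray(v, dtype=np.int64)
    d = X.shape[1]
    if len(v) != d:
        raise ValueError("bin-count vector length mismatch")
    if (X >= v[None, :]).any():
        raise ValueError("bin index out of range: scheme mismatch")
    if (X < MISSING).any():
        raise ValueError("bin indices must be >= -1")
    k = 2
    vmax = int(v.max())
    known = X != MISSING
    m = known.sum(axis=0)
    m2 = (known[:, :, None] & known[:, None, :]).sum(axis=0)
    F1 = np.zeros((k, d, vmax), dtype=np.int64)
    F2 = np.zeros((k, d, vmax, d, vmax), dtype=np.int64)
    for c in (NEG, POS):
        Xc = X[y == c]
        kn = Xc != MISSING
        for i in range(d):
            rows = Xc[kn[:, i]]
            np.add.at(F1[c, i], rows[:, i], 1)
            for j in range(i + 1, d):
                both = rows[rows[:, j] != MISSING]
                np.add.at(F2[c, i], (both[:, i], np.full(len(both), j), both[:, j]), 1)
        # mirror for symmetry
        for i in range(d):
            for j in range(i + 1, d):
                F2[c, j, :, i, :] = F2[c, i, :, j, :].T
    n_class = np.array([(y == NEG).sum(), (y == POS).sum()], dtype=np.int64)
    return AODEModel(
        v=v, m=m, m2=m2, F1=F1, F2=F2, n_class=n_class, k=k,
        parent_min_count=parent_min_count, scheme=scheme,
    )


def joint_prob(model: AODEModel, c: int, i: int, a: int) -> float:
    """Smoothed P(c, f_i = a) = (F + 1) / (m_i + k v_i)."""
    return (model.F1[c, i, a] + 1.0) / (model.m[i] + model.k * model.v[i])


def pair_prob(model: AODEModel, c: int, i: int, a: int, j: int, b: int) -> float:
    """Smoothed P(c, f_i = a, f_j = b) = (F + 1) / (m_ij + k v_i v_j)."""
    if i == j:
        raise ValueError("pair_prob requires two distinct features")
    return (model.F2[c, i, a, j, b] + 1.0) / (
        model.m2[i, j] + model.k * model.v[i] * model.v[j]
    )


def cond_prob(model: AODEModel, j: int, b: int, c: int, i: int, a: int) -> float:
    """P(f_j = b | c, f_i = a) as a quotient of the smoothed estimates.

    The quotient can exceed 1 because numerator and denominator carry
    different smoothing masses; it is always positive and finite.
    """
    return pair_prob(model, c, i, a, j, b) / joint_prob(model, c, i, a)


def _class_log_scores(model: AODEModel, x: np.ndarray) -> np.ndarray:
    known = np.flatnonzero(x != MISSING)
    parents = [i for i in known if model.m[i] >= model.parent_min_count]
    if len(known) == 0 or len(parents) == 0:
        raise ValueError("no known feature available as an AODE parent")
    scores = np.empty(model.k)
    for c in (NEG, POS):
        terms = []
        for i in parents:
            t = np.log(joint_prob(model, c, i, x[i]))
            for j in known:
                if j != i:
                    t += np.log(cond_prob(model, j, x[j], c, i, x[i]))
            terms.append(t)
        scores[c] = logsumexp(terms)
    return scores


def predict_proba(model: AODEModel, x: np.ndarray) -> float:
    """Posterior probability of the positive class for one discrete vector."""
    x = np.asarray(x, dtype=np.int64)
    s = _class_log_scores(model, x)
    return float(np.exp(s[POS] - logsumexp(s)))


def predict_proba_many(model: AODEModel, X: np.ndarray) -> np.ndarray:
    return np.array([predict_proba(model, x) for x in np.asarray(X, dtype=np.int64)])


def nbc_predict_proba(model: AODEModel, x: np.ndarray) -> float:
    """Naive Bayes posterior reusing the same smoothed joint estimates.

    score(c) = P(c)^(1-n) * prod_i P(c, f_i) over the n known features,
    with P(c) = (N_c + 1)/(N + k).  With a single feature this is exactly
    the AODE posterior.
    """
    x = np.asarray(x, dtype=np.int64)
    known = np.flatnonzero(x != MISSING)
    if len(known) == 0:
        raise ValueError("no known feature")
    n_total = int(model.n_class.sum())
    scores = np.empty(model.k)
    for c in (NEG, POS):
        prior = (model.n_class[c] + 1.0) / (n_total + model.k)
        t = (1 - len(known)) * np.log(prior)
        for i in known:
            t += np.log(joint_prob(model, c, i, x[i]))
        scores[c] = t
    return float(np.exp(scores[POS] - logsumexp(scores)))


def nbc_predict_proba_many(model: AODEModel, X: np.ndarray) -> np.ndarray:
    return np.array(
        [nbc_predict_proba(model, x) for x in np.asarray(X, dtype=np.int64)]
    )


def classify(p_pos: float, threshold: float) -> int:
    """Positive iff the posterior is greater than or equal to the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return POS if p_pos >= threshold else NEG
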