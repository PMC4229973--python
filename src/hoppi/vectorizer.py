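"""Order-invariant encoding of feature vectors: half-space selection and
supervised entropy/MDL discretization.

A protein pair has two order-dependent F_Seq encodings, (e_A, m_A, e_B, m_B)
and its swap.  To make the classifier blind to input order, the encoding
lying on a fixed side of the swap-symmetry hyperplane is selected: with a
fixed reference point X1 and its swap X2, the normal rn = X1 - midpoint(X1,
X2) is anti-symmetric under the coordinate swap, and an encoding P1 is kept
iff rn . P1 > 0 (the midpoint term cancels because rn is orthogonal to every
swap-symmetric vector).  When the inner product is exactly 0 the two
encodings are equivalent under the hyperplane and the input orientation is
kept.

Continuous features are then discretized with the recursive minimum
description length method: binary splits chosen to minimize class entropy,
accepted only when the information gain exceeds the MDL acceptance
threshold, applied recursively to each side.  Split candidates are
midpoints between adjacent distinct values that are class boundary points.
A boundary value equal to a split point falls in the right (upper) bin.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import FEATURE_NAMES, FeatureVector

#: bin value reserved for an unknown feature
MISSING = -1


@dataclass(frozen=True)
class ReferenceOrientation:
    """Fixed reference point X1 defining the selected half-space."""

    x1: tuple[float, float, float, float] = (0.0, 1.0, 100.0, 0.0)

    @property
    def rn(self) -> np.ndarray:
        """Normal from the midpoint of (X1, swap(X1)) to X1; anti-symmetric."""
        x1 = np.asarray(self.x1, dtype=float)
        x2 = x1[[2, 3, 0, 1]]
        return x1 - (x1 + x2) / 2.0


DEFAULT_REFERENCE = ReferenceOrientation()


def canonicalize(fv: FeatureVector, ref: ReferenceOrientation = DEFAULT_REFERENCE) -> FeatureVector:
    """Return the half-space representative of ``fv``.

    Keeps ``fv`` when rn . fseq >= 0 (ties keep the input orientation),
    otherwise swaps the two F_Seq halves.  F_Dom and F_Net are untouched.
    """
    if float(ref.rn @ fv.fseq.as_array()) < 0.0:
        return fv.swapped()
    return fv


# ---------------------------------------------------------------------------
# MDL-based entropy discretization
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _best_split(values: np.ndarray, labels: np.ndarray) -> tuple[float, int] | None:
    """Best accepted MDL cut on sorted ``values``; None when no cut passes.

    Returns (cut point, index of first element of the right partition).
    """
    n = len(values)
    classes = np.unique(labels)
    k = len(classes)
    if n < 2 or k < 2:
        return None
    onehot = labels[:, None] == classes[None, :]
    cum = np.cumsum(onehot, axis=0)  # class counts of the left partition
    total = cum[-1]

    # candidate boundaries: between adjacent distinct-value groups that are
    # not both pure with the same class (boundary-point restriction, which
    # provably contains the entropy-optimal cut)
    distinct = values[1:] != values[:-1]
    if not distinct.any():
        return None
    # group starts
    starts = np.flatnonzero(np.concatenate(([True], distinct)))
    ends = np.concatenate((starts[1:], [n]))
    ngroups = len(starts)
    # per-group class counts
    gcounts = cum[ends - 1] - np.vstack((np.zeros(k, dtype=cum.dtype), cum[starts[1:] - 1]))
    pure_cls = np.where(
        (gcounts > 0).sum(axis=1) == 1, np.argmax(gcounts > 0, axis=1), -1
    )
    cand_idx = []  # split index = start of right group
    for gi in range(ngroups - 1):
        l, r = pure_cls[gi], pure_cls[gi + 1]
        if l == -1 or r == -1 or l != r:
            cand_idx.append(starts[gi + 1])
    if not cand_idx:
        return None
    cand = np.asarray(cand_idx)

    left = cum[cand - 1]  # (ncand, k)
    right = total[None, :] - left
    nl = left.sum(axis=1).astype(float)
    nr = right.sum(axis=1).astype(float)

    def ent(mat: np.ndarray, tot: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = mat / tot[:, None]
            t = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return t.sum(axis=1)

    h = _entropy(total)
    hl = ent(left, nl)
    hr = ent(right, nr)
    gain = h - (nl / n) * hl - (nr / n) * hr
    best = int(np.argmax(gain))
    # tie-break: smallest cut index among equal gains (argmax returns first)
    k1 = (left[best] > 0).sum()
    k2 = (right[best] > 0).sum()
    delta = math.log2(3**k - 2) - (k * h - k1 * hl[best] - k2 * hr[best])
    threshold = (math.log2(n - 1) + delta) / n
    if gain[best] <= threshold:
        return None
    idx = int(cand[best])
    cut = (values[idx - 1] + values[idx]) / 2.0
    return cut, idx


def mdlp_splits(values: Sequence[float], labels: Sequence[int]) -> list[float]:
    """Accepted MDL split points for one feature, in increasing order."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(v, kind="stable")
    v, y = v[order], y[order]
    splits: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        res = _best_split(v[lo:hi], y[lo:hi])
        if res is None:
            return
        cut, idx = res
        splits.append(cut)
        recurse(lo, lo + idx)
        recurse(lo + idx, hi)

    recurse(0, len(v))
    return sorted(splits)


@dataclass
class DiscretizationScheme:
    """Per-feature ordered split points; v_i = len(splits_i) + 1 bins."""

    splits: list[list[float]]
    reference: ReferenceOrientation = field(default_factory=ReferenceOrientation)

    @property
    def n_bins(self) -> list[int]:
        return [len(s) + 1 for s in self.splits]

    def to_json(self) -> dict:
        return {
            "reference_x1": list(self.reference.x1),
            "splits": {
                name: list(s) for name, s in zip(FEATURE_NAMES, self.splits)
            },
        }

    @classmethod
    def from_json(cls, obj: dict) -> "DiscretizationScheme":
        ref = ReferenceOrientation(tuple(obj["reference_x1"]))
        return cls([list(obj["splits"][n]) for n in FEATURE_NAMES], ref)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DiscretizationScheme":
        return cls.from_json(json.loads(Path(path).read_text()))


def fit_discretizer(
    values: np.ndarray,
    labels: Sequence[int],
    reference: ReferenceOrientation = DEFAULT_REFERENCE,
) -> DiscretizationScheme:
    """Fit MDL split points per feature column of ``values`` (n x d).

    A feature admitting no accepted split gets a single bin.  ``values``
    are expected to be canonicalized training vectors.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    return DiscretizationScheme(
        [mdlp_splits(values[:, i], y) for i in range(values.shape[1])],
        reference,
    )


def apply_bins(value: float, splits: Sequence[float]) -> int:
    """Bin index of ``value``: a value equal to a split goes to the right bin."""
    return bisect_right(splits, value)


def vectorize(
    fv: FeatureVector,
    scheme: DiscretizationScheme,
) -> np.ndarray:
    """Canonicalize then discretize the 6 features into bin indices.

    Sentinel feature values (100, 0, -1) are binned like ordinary reals.
    """
    canon = canonicalize(fv, scheme.reference)
    arr = canon.as_array()
    return np.array(
        [apply_bins(arr[i], scheme.splits[i]) for i in range(len(arr))], dtype=np.int64
    )


def vectorize_many(
    fvs: Sequence[FeatureVector], scheme: DiscretizationScheme
) -> np.ndarray:
    return np.vstack([vectorize(fv, scheme) for fv in fvs]) if fvs else np.empty(
        (0, len(FEATURE_NAMES)), dtype=np.int64
    )
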