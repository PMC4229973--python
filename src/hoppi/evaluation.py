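"""Evaluation protocol: ROC/AUC/pAUC, MCC, F-measure, random negative
sampling, leakage-free stratified k-fold cross-validation, threshold
selection, SPW distribution analysis and an equal-variance t-test for
comparing per-fold AUCs.

Positive interaction data vastly outnumbered by unknown pairs is emulated
by sampling, for each positive set, a fixed multiple (400x by default) of
random non-interacting pairs over the same protein universe.  In
cross-validation the entire feature reference (template positives,
propensity table, PPI network, discretization scheme and classifier
counts) is rebuilt per fold from the training folds only, so a test pair's
own interaction can never inform its features.
"""

from __future__ import annotations

import itertools
import logging
import math
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import aode as aode_mod
from .features import (
    FeatureContext,
    FeatureVector,
    featurize_pair,
    fnet_score,
    has_zero_evalue_template,
)
from .io_model import NEGATIVE, POSITIVE, InteractionDataset, InteractionPair
from .vectorizer import (
    ReferenceOrientation,
    canonicalize,
    fit_discretizer,
    vectorize_many,
)

logger = logging.getLogger("hoppi")


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

def sample_negatives(
    positive_pairs: Sequence[InteractionPair],
    ratio: int = 400,
    seed: int | None = None,
    proteins: Sequence[str] | None = None,
) -> list[InteractionPair]:
    """Randomly pair proteins into ``ratio * n_pos`` unique negatives.

    The universe defaults to the proteins appearing in the positive pairs.
    Negatives are distinct unordered pairs of two different proteins, drawn
    uniformly and excluding every positive pair; reproducible given seed.
    """
    positives = {p.key for p in positive_pairs}
    if proteins is None:
        universe = sorted({pid for p in positive_pairs for pid in p.key})
    else:
        universe = sorted(set(proteins))
    n = len(universe)
    needed = ratio * len(positive_pairs)
    n_pos_distinct = sum(1 for a, b in positives if a != b)
    available = n * (n - 1) // 2 - n_pos_distinct
    if needed > available:
        raise ValueError(
            f"cannot sample {needed} negatives: only {available} non-positive "
            f"pairs exist over {n} proteins"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    if needed * 3 >= available:
        # dense regime: enumerate candidates and sample without replacement
        candidates = [
            (a, b)
            for a, b in itertools.combinations(universe, 2)
            if (a, b) not in positives
        ]
        idx = rng.choice(len(candidates), size=needed, replace=False)
        chosen = {candidates[i] for i in idx}
    else:
        while len(chosen) < needed:
            draw = rng.integers(0, n, size=2 * (needed - len(chosen)) + 16)
            for a_i, b_i in draw.reshape(-1, 2):
                if a_i == b_i:
                    continue
                key = (universe[min(a_i, b_i)], universe[max(a_i, b_i)])
                if key in positives or key in chosen:
                    continue
                chosen.add(key)
                if len(chosen) == needed:
                    break
    return [InteractionPair(a, b, NEGATIVE) for a, b in sorted(chosen)]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_counts(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= threshold
    return ConfusionCounts(
        TP=int((pred & (y == POSITIVE)).sum()),
        FP=int((pred & (y == NEGATIVE)).sum()),
        TN=int((~pred & (y == NEGATIVE)).sum()),
        FN=int((~pred & (y == POSITIVE)).sum()),
    )


def precision(c: ConfusionCounts) -> float:
    return c.TP / (c.TP + c.FP) if c.TP + c.FP else 0.0


def recall(c: ConfusionCounts) -> float:
    return c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0


def specificity(c: ConfusionCounts) -> float:
    return c.TN / (c.TN + c.FP) if c.TN + c.FP else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when TP = 0."""
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class ROCResult:
    """ROC curve points with trapezoidal AUC and normalized partial AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def pauc(self, max_fpr: float) -> float:
        """Partial area under the curve over FPR in [0, max_fpr], divided by
        max_fpr so that a perfect classifier scores 1.0 at every cutoff."""
        if not 0.0 < max_fpr <= 1.0:
            raise ValueError("max_fpr must lie in (0, 1]")
        fpr, tpr = self.fpr, self.tpr
        stop = np.searchsorted(fpr, max_fpr, side="right")
        x = fpr[:stop]
        y = tpr[:stop]
        if stop < len(fpr) and (len(x) == 0 or x[-1] < max_fpr):
            # interpolate the curve at the cutoff
            y_cut = np.interp(max_fpr, fpr, tpr)
            x = np.append(x, max_fpr)
            y = np.append(y, y_cut)
        return float(np.trapezoid(y, x)) / max_fpr


def roc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve with tied scores collapsed into single threshold steps."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float),
                                  drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def select_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Score value maximizing the F-measure; ties -> the smallest threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(s, kind="stable")
    s, y = s[order], y[order]
    n_pos = int((y == POSITIVE).sum())
    # predicting positive for score >= s[i]: cumulative counts from the right
    pos_ge = np.cumsum((y == POSITIVE)[::-1])[::-1]
    all_ge = np.arange(len(s), 0, -1)
    cand = np.flatnonzero(np.diff(s, prepend=-np.inf) > 0)  # first of each tie
    tp = pos_ge[cand].astype(float)
    fp = all_ge[cand] - tp
    fn = n_pos - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(tp > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
    best = np.flatnonzero(f == f.max())
    return float(s[cand[best[0]]])


def compare_auc_ttest(
    aucs_method1: Sequence[float], aucs_method2: Sequence[float]
) -> float:
    """Two-sample equal-variance t-test p-value on per-fold AUCs."""
    a = np.asarray(aucs_method1, dtype=float)
    b = np.asarray(aucs_method2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two folds per method")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        # degenerate: no spread in either sample
        return 1.0 if a[0] == b[0] else 0.0
    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if math.isnan(p):
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return p


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Knobs of the cross-validated pipeline (defaults follow the method)."""

    threshold: float = 0.5
    classifier: str = "aode"  # or "nbc"
    seq_evalue_cutoff: float = 1e2
    net_evalue_cutoff: float = 1e-3
    edge_weight: float = 1.0
    pseudocount: float = 1.0
    pauc_fpr: float = 0.005
    exclude_zero_evalue_templates: bool = False
    reference: ReferenceOrientation = field(default_factory=ReferenceOrientation)


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    roc: ROCResult
    auc: float
    pauc: float
    mcc: float
    f_measure: float
    precision: float
    recall: float
    specificity: float
    scores: np.ndarray
    labels: np.ndarray
    leaked_templates: int
    leaked_edges: int


@dataclass
class CVReport:
    folds: list[FoldResult]

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.folds])

    def mean(self, name: str) -> float:
        return float(self._values(name).mean())

    def std(self, name: str) -> float:
        return float(self._values(name).std(ddof=1)) if len(self.folds) > 1 else 0.0

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {"n_folds": len(self.folds)}
        for name in ("auc", "pauc", "mcc", "f_measure", "precision", "recall",
                     "specificity"):
            out[f"{name}_mean"] = self.mean(name)
            out[f"{name}_std"] = self.std(name)
        return out

    @property
    def pooled_scores(self) -> np.ndarray:
        return np.concatenate([f.scores for f in self.folds])

    @property
    def pooled_labels(self) -> np.ndarray:
        return np.concatenate([f.labels for f in self.folds])


def stratified_folds(
    pairs: Sequence[InteractionPair], k: int, seed: int | None
) -> list[list[int]]:
    """Seeded class-stratified partition of pair indices into k folds.

    Fold membership is a function of pair identity (not list position), so
    the partition — and every downstream metric — is invariant to the order
    in which pairs were listed in the input files.
    """
    if k > len(pairs):
        raise ValueError("more folds than pairs")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (POSITIVE, NEGATIVE):
        idx = [i for i, p in enumerate(pairs) if p.label == cls]
        idx.sort(key=lambda i: pairs[i].key)  # canonical order before shuffling
        idx = [idx[j] for j in rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return folds


def _fold_context(
    train_pairs: Sequence[InteractionPair],
    hits: Mapping,
    domains: Mapping,
    config: CVConfig,
) -> FeatureContext:
    return FeatureContext.build(
        train_pairs,
        hits,
        domains,
        pseudocount=config.pseudocount,
        edge_weight=config.edge_weight,
        seq_evalue_cutoff=config.seq_evalue_cutoff,
        net_evalue_cutoff=config.net_evalue_cutoff,
    )


def _featurize_all(
    pairs: Sequence[InteractionPair], ctx: FeatureContext
) -> list[FeatureVector]:
    return [featurize_pair(p.idA, p.idB, ctx) for p in pairs]


def kfold_cv(
    dataset: InteractionDataset,
    hits: Mapping,
    domains: Mapping,
    k: int = 10,
    seed: int | None = 0,
    config: CVConfig | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation with per-fold context rebuild.

    For each fold the template positive set, propensity table, PPI network,
    discretization scheme and classifier are all fitted on the training
    folds only; the held-out pairs are then featurized against that
    reference and scored.
    """
    config = config or CVConfig()
    pairs = dataset.pairs
    folds = stratified_folds(pairs, k, seed)
    results: list[FoldResult] = []
    predict = (
        aode_mod.predict_proba_many
        if config.classifier == "aode"
        else aode_mod.nbc_predict_proba_many
    )
    for fold_id, test_idx in enumerate(folds):
        t0 = time.perf_counter()
        test_set = set(test_idx)
        train_pairs = [p for i, p in enumerate(pairs) if i not in test_set]
        test_pairs = [pairs[i] for i in test_idx]
        ctx = _fold_context(train_pairs, hits, domains, config)

        # leakage audit: the held-out pairs must be absent from this fold's
        # template positives and network edges
        leaked_templates = sum(1 for p in test_pairs if p.key in ctx.positive_pairs)
        leaked_edges = sum(
            1 for p in test_pairs if ctx.network.has_edge(p.idA, p.idB)
        )

        train_fvs = [canonicalize(fv, config.reference)
                     for fv in _featurize_all(train_pairs, ctx)]
        train_X = np.vstack([fv.as_array() for fv in train_fvs])
        train_y = [p.label for p in train_pairs]
        scheme = fit_discretizer(train_X, train_y, config.reference)
        model = aode_mod.fit(
            vectorize_many(train_fvs, scheme), train_y, scheme.n_bins, scheme=scheme
        )

        if config.exclude_zero_evalue_templates:
            test_pairs = [
                p for p in test_pairs
                if not has_zero_evalue_template(p.idA, p.idB, ctx)
            ]
        test_fvs = _featurize_all(test_pairs, ctx)
        scores = predict(model, vectorize_many(test_fvs, scheme))
        labels = np.array([p.label for p in test_pairs])

        rr = roc(scores, labels)
        counts = confusion_counts(scores, labels, config.threshold)
        results.append(
            FoldResult(
                fold=fold_id,
                counts=counts,
                roc=rr,
                auc=rr.auc,
                pauc=rr.pauc(config.pauc_fpr),
                mcc=mcc(counts),
                f_measure=f_measure(counts),
                precision=precision(counts),
                recall=recall(counts),
                specificity=specificity(counts),
                scores=np.asarray(scores),
                labels=labels,
                leaked_templates=leaked_templates,
                leaked_edges=leaked_edges,
            )
        )
        logger.info(
            "fold %d: auc=%.3f pauc=%.3f (%.2fs)",
            fold_id, rr.auc, results[-1].pauc, time.perf_counter() - t0,
        )
    return CVReport(results)


# ---------------------------------------------------------------------------
# SPW distribution analysis
# ---------------------------------------------------------------------------

def spw_distribution(
    dataset: InteractionDataset,
    hits: Mapping,
    k: int = 10,
    seed: int | None = 0,
    cap: float = 5.0,
    evalue_cutoff: float = 1e-3,
    edge_weight: float = 1.0,
) -> pd.DataFrame:
    """Per-class percentage of pairs at each SPW value, averaged over folds.

    For each fold a PPI network is built from the training folds' positives
    and the lowest SPW between homolog hits is computed for every held-out
    pair.  Exact SPW values below ``cap`` are tallied individually, larger
    ones pooled into a ">=cap" row and pairs with no path into "NP".
    """
    from .features import build_network  # local to avoid cycle at import time

    pairs = dataset.pairs
    folds = stratified_folds(pairs, k, seed)
    tallies: dict[int, dict[object, float]] = {POSITIVE: {}, NEGATIVE: {}}
    for test_idx in folds:
        test_set = set(test_idx)
        train_pos = [
            p for i, p in enumerate(pairs)
            if i not in test_set and p.label == POSITIVE
        ]
        net = build_network(train_pos, edge_weight)
        for i in test_idx:
            p = pairs[i]
            val = fnet_score(
                hits.get(p.idA, ()), hits.get(p.idB, ()), net, evalue_cutoff
            )
            if val < 0:
                key: object = "NP"
            elif val >= cap:
                key = f">={cap:g}"
            else:
                key = float(val)
            cls = tallies[p.label]
            cls[key] = cls.get(key, 0.0) + 1.0

    def sort_key(k_: object):
        return (1, 0) if isinstance(k_, str) else (0, k_)

    keys = sorted(set(tallies[POSITIVE]) | set(tallies[NEGATIVE]), key=sort_key)
    rows = []
    for key in keys:
        row = {"spw": key}
        for cls, name in ((POSITIVE, "positive"), (NEGATIVE, "negative")):
            total = sum(tallies[cls].values())
            row[f"{name}_pct"] = (
                100.0 * tallies[cls].get(key, 0.0) / total if total else 0.0
            )
            # average count per fold
            row[f"{name}_mean_count"] = tallies[cls].get(key, 0.0) / k
        rows.append(row)
    return pd.DataFrame(rows)
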