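"""The three homology-derived features for a protein pair.

For a target pair (S_A, S_B) and a training reference built from known
interactions, three features are computed:

* **F_Seq** — sequence similarity to the best known interacting template
  pair: the pair (T_A, T_B) of similarity hits, one per side, that is a known
  positive and minimizes sqrt(e_A^2 + e_B^2); reported as
  (e-value_A, mincov_A, e-value_B, mincov_B).  mincov is the number of
  positive-scoring alignment positions divided by the length of the longer
  of the two aligned sequences.  Default when no interacting template pair
  exists: (100, 0, 100, 0), matching the e-value cutoff of 1e2 used for
  the search.
* **F_Dom** — the mean, over all unordered domain pairs formable between the
  two proteins' domain sets, of a log-odds interaction propensity estimated
  from training pairs; 0 when either protein has no domains.
* **F_Net** — the shortest-path weight (SPW): the minimum over hit pairs
  (p_A, p_B), at a stricter e-value cutoff of 1e-3, of the sum of edge
  weights on the shortest path between p_A and p_B in the training PPI
  network; -1 when no path exists for any combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .io_model import (
    POSITIVE,
    InteractionPair,
    SimilarityHit,
    canonical_pair,
)

#: sentinel feature values for "no evidence found"
NO_TEMPLATE_EVALUE = 100.0
NO_PATH_FNET = -1.0

#: default e-value cutoffs (permissive for template search, strict for SPW)
SEQ_EVALUE_CUTOFF = 1e2
NET_EVALUE_CUTOFF = 1e-3


@dataclass(frozen=True)
class SeqFeature:
    """F_Seq: e-value and minimum coverage for each side of the best template."""

    evalueA: float = NO_TEMPLATE_EVALUE
    mincovA: float = 0.0
    evalueB: float = NO_TEMPLATE_EVALUE
    mincovB: float = 0.0

    def swapped(self) -> "SeqFeature":
        return SeqFeature(self.evalueB, self.mincovB, self.evalueA, self.mincovA)

    def as_array(self) -> np.ndarray:
        return np.array([self.evalueA, self.mincovA, self.evalueB, self.mincovB])


@dataclass(frozen=True)
class FeatureVector:
    """The full feature vector {F_Seq, F_Dom, F_Net} for one protein pair."""

    fseq: SeqFeature
    fdom: float
    fnet: float

    def swapped(self) -> "FeatureVector":
        return FeatureVector(self.fseq.swapped(), self.fdom, self.fnet)

    def as_array(self) -> np.ndarray:
        """Feature order: (evalueA, mincovA, evalueB, mincovB, fdom, fnet)."""
        return np.concatenate([self.fseq.as_array(), [self.fdom, self.fnet]])


FEATURE_NAMES = ("evalueA", "mincovA", "evalueB", "mincovB", "fdom", "fnet")


def compute_mincov(hit: SimilarityHit) -> float:
    """positives / length of the longer sequence, clipped to [0, 1]."""
    cov = hit.positives / max(hit.query_len, hit.subject_len)
    return min(max(cov, 0.0), 1.0)


def fseq_feature(
    hitsA: Sequence[SimilarityHit],
    hitsB: Sequence[SimilarityHit],
    positive_pairs: set[tuple[str, str]],
    evalue_cutoff: float = SEQ_EVALUE_CUTOFF,
) -> SeqFeature:
    """Select the interacting template pair minimizing sqrt(e_A^2 + e_B^2).

    ``positive_pairs`` holds canonically ordered id pairs, so both
    assignments of an unordered template pair to the two slots are covered.
    Ties on the Euclidean norm break by smaller e_A, then larger
    mincov_A + mincov_B, then lexicographic template ids, for determinism.
    Returns the (100, 0, 100, 0) default when no combination is a known
    positive.
    """
    candA = [h for h in hitsA if h.evalue <= evalue_cutoff]
    candB = [h for h in hitsB if h.evalue <= evalue_cutoff]
    best: tuple | None = None
    best_feat: SeqFeature | None = None
    for ha in candA:
        for hb in candB:
            if canonical_pair(ha.subject_id, hb.subject_id) not in positive_pairs:
                continue
            ma, mb = compute_mincov(ha), compute_mincov(hb)
            key = (
                math.hypot(ha.evalue, hb.evalue),
                ha.evalue,
                -(ma + mb),
                ha.subject_id,
                hb.subject_id,
            )
            if best is None or key < best:
                best = key
                best_feat = SeqFeature(ha.evalue, ma, hb.evalue, mb)
    return best_feat if best_feat is not None else SeqFeature()


# ---------------------------------------------------------------------------
# F_Dom: domain-pair interaction propensities
# ---------------------------------------------------------------------------

@dataclass
class PropensityTable:
    """Log-odds interaction propensities for unordered domain pairs.

    propensity(d_x, d_y) = ln of the ratio between the class-relative
    frequencies of the pair among positive and negative training pairs,
    with an additive pseudocount applied to every stored pair's count in
    both classes (the raw ratio is undefined whenever a pair was never
    seen in negatives, which is common).
    """

    counts: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    pos_total: int = 0
    neg_total: int = 0
    pseudocount: float = 1.0

    def propensity(self, dx: str, dy: str) -> float:
        """ln frequency ratio for a stored pair; 0.0 for unseen pairs."""
        key = canonical_pair(dx, dy)
        if key not in self.counts:
            return 0.0
        fpos, fneg = self.counts[key]
        a = self.pseudocount
        n = len(self.counts)
        ppos = (fpos + a) / (self.pos_total + n * a)
        pneg = (fneg + a) / (self.neg_total + n * a)
        return math.log(ppos / pneg)


def _domain_pairs(
    domsA: frozenset[str] | set[str], domsB: frozenset[str] | set[str]
) -> set[tuple[str, str]]:
    """Distinct unordered domain pairs formable between two domain sets."""
    return {canonical_pair(dx, dy) for dx in domsA for dy in domsB}


def build_propensity_table(
    pairs: Iterable[InteractionPair],
    domains: Mapping[str, frozenset[str]],
    pseudocount: float = 1.0,
) -> PropensityTable:
    """Count domain-pair incidences per class over labeled training pairs.

    Each labeled protein pair contributes +1 to F(label, d_x, d_y) for every
    distinct unordered domain pair formable between its two domain sets.
    """
    counts: dict[tuple[str, str], list[int]] = {}
    totals = [0, 0]  # [negative, positive]
    for pair in pairs:
        domsA = domains.get(pair.idA, frozenset())
        domsB = domains.get(pair.idB, frozenset())
        for key in _domain_pairs(domsA, domsB):
            cell = counts.setdefault(key, [0, 0])
            cell[pair.label] += 1
            totals[pair.label] += 1
    return PropensityTable(
        counts={k: (v[POSITIVE], v[1 - POSITIVE]) for k, v in counts.items()},
        pos_total=totals[POSITIVE],
        neg_total=totals[1 - POSITIVE],
        pseudocount=pseudocount,
    )


def fdom_score(
    domainsA: frozenset[str] | set[str],
    domainsB: frozenset[str] | set[str],
    table: PropensityTable,
) -> float:
    """Mean propensity over all formable domain pairs; 0 without domains.

    Pairs never seen in training contribute 0 to the sum but still count in
    the denominator (absence of evidence is the neutral value).
    """
    if not domainsA or not domainsB:
        return 0.0
    pairs = _domain_pairs(domainsA, domainsB)
    return sum(table.propensity(*p) for p in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# F_Net: shortest-path weight between homologs in the PPI network
# ---------------------------------------------------------------------------

def build_network(
    positive_pairs: Iterable[InteractionPair | tuple[str, str]],
    default_weight: float = 1.0,
) -> nx.Graph:
    """Undirected weighted PPI graph from positive training pairs.

    One edge per unique unordered pair; self-pairs become self-loops.
    """
    if default_weight <= 0:
        raise ValueError("edge weight must be positive")
    g = nx.Graph()
    for p in positive_pairs:
        a, b = (p.idA, p.idB) if isinstance(p, InteractionPair) else p
        g.add_edge(a, b, weight=default_weight)
    return g


def spw(network: nx.Graph, src: str, dst: str) -> float | None:
    """Shortest-path weight between two nodes; None when no path exists.

    spw(x, x) is 0 for any node present in the network (the zero-length
    path; no self-loop edge is required).
    """
    if src not in network or dst not in network:
        return None
    try:
        return float(nx.dijkstra_path_length(network, src, dst, weight="weight"))
    except nx.NetworkXNoPath:
        return None


def fnet_score(
    hitsA: Sequence[SimilarityHit],
    hitsB: Sequence[SimilarityHit],
    network: nx.Graph,
    evalue_cutoff: float = NET_EVALUE_CUTOFF,
) -> float:
    """Lowest SPW over all hit combinations (p_A, p_B); -1 when undefined."""
    sources = {h.subject_id for h in hitsA if h.evalue <= evalue_cutoff}
    targets = {h.subject_id for h in hitsB if h.evalue <= evalue_cutoff}
    sources &= set(network.nodes)
    targets &= set(network.nodes)
    if not sources or not targets:
        return NO_PATH_FNET
    dist = nx.multi_source_dijkstra_path_length(network, sources, weight="weight")
    best = min((dist[t] for t in targets if t in dist), default=None)
    return float(best) if best is not None else NO_PATH_FNET


# ---------------------------------------------------------------------------
# feature context: everything a trained reference provides
# ---------------------------------------------------------------------------

@dataclass
class FeatureContext:
    """Training-fold reference against which target pairs are featurized.

    Holds the known positive template pairs, the domain propensity table,
    the training PPI network and the hit/domain lookups.  In
    cross-validation one context is rebuilt per fold from the training
    folds only, so no test pair's own interaction can leak into its
    features.
    """

    positive_pairs: set[tuple[str, str]]
    table: PropensityTable
    network: nx.Graph
    hits: Mapping[str, Sequence[SimilarityHit]]
    domains: Mapping[str, frozenset[str]]
    seq_evalue_cutoff: float = SEQ_EVALUE_CUTOFF
    net_evalue_cutoff: float = NET_EVALUE_CUTOFF

    @classmethod
    def build(
        cls,
        training_pairs: Iterable[InteractionPair],
        hits: Mapping[str, Sequence[SimilarityHit]],
        domains: Mapping[str, frozenset[str]],
        pseudocount: float = 1.0,
        edge_weight: float = 1.0,
        seq_evalue_cutoff: float = SEQ_EVALUE_CUTOFF,
        net_evalue_cutoff: float = NET_EVALUE_CUTOFF,
    ) -> "FeatureContext":
        training_pairs = list(training_pairs)
        positives = [p for p in training_pairs if p.label == POSITIVE]
        return cls(
            positive_pairs={p.key for p in positives},
            table=build_propensity_table(training_pairs, domains, pseudocount),
            network=build_network(positives, edge_weight),
            hits=hits,
            domains=domains,
            seq_evalue_cutoff=seq_evalue_cutoff,
            net_evalue_cutoff=net_evalue_cutoff,
        )

    def hits_for(self, pid: str) -> Sequence[SimilarityHit]:
        return self.hits.get(pid, ())


def featurize_pair(idA: str, idB: str, ctx: FeatureContext) -> FeatureVector:
    """Assemble the raw (un-canonicalized, continuous) feature vector.

    Swapping the input order swaps the two halves of F_Seq and leaves
    F_Dom/F_Net unchanged; order invariance proper is established later by
    half-space canonicalization.
    """
    hitsA, hitsB = ctx.hits_for(idA), ctx.hits_for(idB)
    fseq = fseq_feature(hitsA, hitsB, ctx.positive_pairs, ctx.seq_evalue_cutoff)
    fdom = fdom_score(
        ctx.domains.get(idA, frozenset()), ctx.domains.get(idB, frozenset()), ctx.table
    )
    fnet = fnet_score(hitsA, hitsB, ctx.network, ctx.net_evalue_cutoff)
    return FeatureVector(fseq, fdom, fnet)


def has_zero_evalue_template(idA: str, idB: str, ctx: FeatureContext) -> bool:
    """True when some interacting template pair has both e-values exactly 0.

    Used by the optional evaluation filter that drops target pairs whose
    interaction is trivially recoverable through identical sequences.
    """
    subjA = {h.subject_id for h in ctx.hits_for(idA) if h.evalue == 0.0}
    subjB = {h.subject_id for h in ctx.hits_for(idB) if h.evalue == 0.0}
    for a in subjA:
        for b in subjB:
            if canonical_pair(a, b) in ctx.positive_pairs:
                return True
    return False
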