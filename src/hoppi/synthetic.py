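"""Self-contained synthetic fixtures with a controllable planted signal.

The generator emulates the inputs the pipeline consumes — a protein set,
labeled interaction pairs, a similarity-hit table and domain assignments —
without any external database or alignment run.  Proteins are organized in
small homolog families anchored to hidden "template" proteins connected in
a base network:

1. a base network is built over ``n_proteins / family_size`` templates
   (Erdos-Renyi-style by default, preferential-attachment optionally);
2. each protein is a noisy homolog of its template: the hit table connects
   every protein to all members of its family, with a self-hit at e-value 0
   and cross-hits with e-values drawn log-uniformly from
   ``homolog_evalue_range`` and coverage-consistent positives counts;
3. with probability ``signal_strength`` a positive pair is drawn from a
   random base-network edge (one member from each endpoint family),
   otherwise uniformly at random, so at full signal the positives'
   templates are always network-adjacent;
4. each protein carries its template's characteristic domain with
   probability ``signal_strength`` (plus occasional random extras),
   otherwise random domains, so domain pairs across base-network edges are
   enriched in positives exactly when the signal is planted;
5. negatives are drawn by the evaluation module's uniform sampler at
   ``neg_ratio`` per positive.

At ``signal_strength = 0`` the labels are independent of every feature and
downstream cross-validation must sit at chance; at 1 the three features all
carry signal.  Sequences are random amino-acid strings generated only to
satisfy FASTA round-trips and length fields; hit e-values are simulated,
not computed from alignments, because the pipeline's contract is the hit
table itself.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .evaluation import sample_negatives
from .io_model import (
    POSITIVE,
    DomainAssignment,
    InteractionDataset,
    InteractionPair,
    ProteinRecord,
    SimilarityHit,
    write_domains,
    write_edges,
    write_fasta,
    write_hits,
    write_pairs,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults give a desk-scale planted-signal study."""

    n_proteins: int = 200
    n_positive: int = 300
    neg_ratio: int = 50
    network_model: str = "random"  # or "scale-free"
    homolog_evalue_range: tuple[float, float] = (1e-50, 1e-10)
    signal_strength: float = 1.0
    n_domains: int = 50
    family_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_positive <= 0 or self.n_domains <= 0:
            raise ValueError("counts must be positive")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")
        lo, hi = self.homolog_evalue_range
        if not 0 < lo <= hi:
            raise ValueError("homolog_evalue_range must satisfy 0 < lo <= hi")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.network_model not in ("random", "scale-free"):
            raise ValueError("network_model must be 'random' or 'scale-free'")


@dataclass
class SyntheticDataset:
    """A generated study: dataset, hit/domain tables and ground truth."""

    config: SyntheticConfig
    dataset: InteractionDataset
    hits: dict[str, list[SimilarityHit]]
    domains: dict[str, frozenset[str]]
    template_network: nx.Graph
    template_of: dict[str, int] = field(default_factory=dict)


def _template_network(n_templates: int, model: str, rng: np.random.Generator) -> nx.Graph:
    seed = int(rng.integers(2**31))
    if model == "scale-free":
        g = nx.barabasi_albert_graph(n_templates, 2, seed=seed)
    else:
        g = nx.gnm_random_graph(n_templates, 2 * n_templates, seed=seed)
    return g


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Deterministically generate a dataset from the config (incl. its seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    n_templates = max(2, n // config.family_size)
    net = _template_network(n_templates, config.network_model, rng)
    if net.number_of_edges() == 0:
        raise ValueError("base network has no edges; enlarge the configuration")

    width = len(str(n - 1))
    ids = [f"P{i:0{width}d}" for i in range(n)]
    template_of = {pid: i % n_templates for i, pid in enumerate(ids)}
    families: dict[int, list[str]] = {}
    for pid, t in template_of.items():
        families.setdefault(t, []).append(pid)

    lengths = rng.integers(80, 400, size=n)
    proteins = {
        pid: ProteinRecord(pid, "".join(rng.choice(AMINO_ACIDS, size=int(L))))
        for pid, L in zip(ids, lengths)
    }

    # hit table: each protein hits every member of its homolog family
    lo, hi = config.homolog_evalue_range
    hits: dict[str, list[SimilarityHit]] = {pid: [] for pid in ids}
    for members in families.values():
        for q in members:
            for s in members:
                ql, sl = proteins[q].length, proteins[s].length
                if q == s:
                    ev, cov = 0.0, 1.0
                else:
                    ev = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                    cov = float(rng.uniform(0.6, 0.95))
                positives = int(round(cov * max(ql, sl)))
                hits[q].append(SimilarityHit(q, s, ev, positives, ql, sl))

    # positive pairs: planted on base-network edges w.p. signal_strength
    edges = sorted(net.edges())
    pos: set[tuple[str, str]] = set()
    max_attempts = 200 * config.n_positive
    attempts = 0
    while len(pos) < config.n_positive:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("could not place the requested number of positives")
        if rng.random() < config.signal_strength:
            tx, ty = edges[rng.integers(len(edges))]
            a = families[tx][rng.integers(len(families[tx]))]
            b = families[ty][rng.integers(len(families[ty]))]
        else:
            ia, ib = rng.choice(n, size=2, replace=False)
            a, b = ids[ia], ids[ib]
        if a == b:
            continue
        pos.add((a, b) if a <= b else (b, a))
    positives = [InteractionPair(a, b, POSITIVE) for a, b in sorted(pos)]

    # domains: template-characteristic with probability signal_strength
    domain_pool = [f"D{j:04d}" for j in range(config.n_domains)]
    domains: dict[str, frozenset[str]] = {}
    for pid in ids:
        doms: set[str] = set()
        if rng.random() < config.signal_strength:
            doms.add(domain_pool[template_of[pid] % config.n_domains])
            if rng.random() < 0.3:
                doms.add(domain_pool[rng.integers(config.n_domains)])
        else:
            for _ in range(int(rng.integers(1, 3))):
                doms.add(domain_pool[rng.integers(config.n_domains)])
        domains[pid] = frozenset(doms)

    negatives = sample_negatives(
        positives,
        ratio=config.neg_ratio,
        seed=int(rng.integers(2**31)),
        proteins=ids,
    )
    dataset = InteractionDataset(proteins=proteins, pairs=positives + negatives)
    dataset.validate()
    return SyntheticDataset(
        config=config,
        dataset=dataset,
        hits=hits,
        domains=domains,
        template_network=net,
        template_of=template_of,
    )


def write_fixture(data: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the fixture in the package's text formats plus a manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": d / "proteins.fasta",
        "positives": d / "positives.tsv",
        "negatives": d / "negatives.tsv",
        "hits": d / "hits.tsv",
        "domains": d / "domains.tsv",
        "edges": d / "template_edges.tsv",
        "manifest": d / "manifest.json",
    }
    ds = data.dataset
    write_fasta((ds.proteins[k] for k in sorted(ds.proteins)), paths["fasta"])
    write_pairs(ds.positives, paths["positives"])
    write_pairs(ds.negatives, paths["negatives"])
    all_hits = [h for pid in sorted(data.hits) for h in data.hits[pid]]
    write_hits(all_hits, paths["hits"])
    write_domains(
        sorted(
            (DomainAssignment(pid, doms) for pid, doms in data.domains.items()),
            key=lambda a: a.protein_id,
        ),
        paths["domains"],
    )
    write_edges(
        [(f"T{a}", f"T{b}", 1.0) for a, b in sorted(data.template_network.edges())],
        paths["edges"],
    )
    manifest = asdict(data.config)
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths
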