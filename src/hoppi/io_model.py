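"""Domain types and plain-text readers/writers shared by the whole package.

All on-disk formats are deliberately simple text: FASTA for sequences and
tab-separated tables for interaction pairs, similarity hits, domain
assignments and weighted edge lists.  The hit table is a 6-column extension
of BLAST tabular output (query, subject, e-value, positives, query length,
subject length) because standard ``-outfmt 6`` lacks the positives count and
the sequence lengths the features need.  A BLAST invocation producing it is::

    blastp -query q.fa -db db -outfmt '6 qseqid sseqid evalue positive qlen slen'

The package only ever consumes such tables; it never runs BLAST itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

#: class labels for interaction pairs
POSITIVE = 1
NEGATIVE = 0

LABEL_NAMES = {POSITIVE: "+", NEGATIVE: "-"}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair ``{a, b}`` in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InteractionPair:
    """An unordered, canonically stored protein pair with a class label.

    ``idA <= idB`` lexicographically; self-pairs are permitted.
    """

    idA: str
    idB: str
    label: int

    def __post_init__(self) -> None:
        if self.idA > self.idB:
            a, b = self.idA, self.idB
            object.__setattr__(self, "idA", b)
            object.__setattr__(self, "idB", a)
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE} or {NEGATIVE}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.idA, self.idB)


@dataclass(frozen=True)
class SimilarityHit:
    """One query->subject alignment record from a similarity search.

    ``positives`` counts alignment positions with a positive substitution
    score; it may exceed ``min(query_len, subject_len)`` for gapped
    alignments, so only non-negativity is enforced.
    """

    query_id: str
    subject_id: str
    evalue: float
    positives: int
    query_len: int
    subject_len: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}->{self.subject_id}")
        if self.positives < 0:
            raise ValueError("positives count must be >= 0")
        if self.query_len <= 0 or self.subject_len <= 0:
            raise ValueError("sequence lengths must be positive")


@dataclass(frozen=True)
class DomainAssignment:
    """The set of domain accessions found in one protein (possibly empty)."""

    protein_id: str
    domains: frozenset[str]


@dataclass
class InteractionDataset:
    """Labeled unordered protein pairs plus the sequences they refer to."""

    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    pairs: list[InteractionPair] = field(default_factory=list)

    def validate(self) -> None:
        """Check referential integrity and pair uniqueness/disjointness."""
        seen: dict[tuple[str, str], int] = {}
        for p in self.pairs:
            for pid in (p.idA, p.idB):
                if pid not in self.proteins:
                    raise ValueError(f"pair references unknown protein {pid!r}")
            if p.key in seen:
                raise ValueError(f"duplicate or conflicting labels for pair {p.key}")
            seen[p.key] = p.label

    @property
    def positives(self) -> list[InteractionPair]:
        return [p for p in self.pairs if p.label == POSITIVE]

    @property
    def negatives(self) -> list[InteractionPair]:
        return [p for p in self.pairs if p.label == NEGATIVE]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records; ids must be unique."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: empty sequence for {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    return records


def _rows(path: str | Path, ncols: int) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != ncols:
                raise ParseError(
                    f"{path}:{lineno}: expected {ncols} tab-separated columns, "
                    f"got {len(cols)}"
                )
            yield lineno, cols


def read_pairs(path: str | Path, label: int) -> list[InteractionPair]:
    """Read a two-column id file as canonicalized pairs with a fixed label.

    Duplicates after canonicalization are collapsed with a warning.
    """
    out: list[InteractionPair] = []
    seen: set[tuple[str, str]] = set()
    dupes = 0
    for _, (a, b) in _rows(path, 2):
        pair = InteractionPair(a, b, label)
        if pair.key in seen:
            dupes += 1
            continue
        seen.add(pair.key)
        out.append(pair)
    if dupes:
        warnings.warn(
            f"{path}: collapsed {dupes} duplicate pair(s) after canonicalization",
            stacklevel=2,
        )
    return out


def read_hits(path: str | Path) -> list[SimilarityHit]:
    """Read a 6-column hit table, preserving file order."""
    hits: list[SimilarityHit] = []
    for lineno, cols in _rows(path, 6):
        q, s, ev, pos, ql, sl = cols
        try:
            hit = SimilarityHit(q, s, float(ev), int(pos), int(ql), int(sl))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad hit row: {exc}") from exc
        hits.append(hit)
    return hits


def read_domains(path: str | Path) -> list[DomainAssignment]:
    """Read (protein_id, domain_accession) rows grouped into per-protein sets."""
    grouped: dict[str, set[str]] = {}
    for _, (pid, acc) in _rows(path, 2):
        grouped.setdefault(pid, set()).add(acc)
    return [DomainAssignment(pid, frozenset(doms)) for pid, doms in grouped.items()]


def read_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a weighted edge list (idA, idB, weight)."""
    edges = []
    for lineno, (a, b, w) in _rows(path, 3):
        try:
            weight = float(w)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad weight {w!r}") from exc
        edges.append((a, b, weight))
    return edges


def domains_as_map(assignments: Iterable[DomainAssignment]) -> dict[str, frozenset[str]]:
    return {a.protein_id: a.domains for a in assignments}


def hits_by_query(hits: Iterable[SimilarityHit]) -> dict[str, list[SimilarityHit]]:
    grouped: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return grouped


# ---------------------------------------------------------------------------
# writers (exact round-trip partners of the readers above)
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_pairs(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.idA}\t{p.idB}\n")


def write_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.evalue!r}\t{h.positives}"
                f"\t{h.query_len}\t{h.subject_len}\n"
            )


def write_domains(assignments: Iterable[DomainAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in assignments:
            for acc in sorted(a.domains):
                fh.write(f"{a.protein_id}\t{acc}\n")


def write_edges(edges: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w!r}\n")
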