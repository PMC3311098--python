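"""Core domain types for multiple PPI-network alignment.

A problem instance consists of k undirected protein-protein interaction
(PPI) networks with disjoint vertex sets, together with a sparse
cross-network sequence-similarity matrix.  The output of the aligner is an
:class:`Alignment`: a collection of mutually disjoint *match-sets*, each a
group of proteins (possibly several per network) asserted to be functional
orthologs.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

logger = logging.getLogger("mnalign")


class MnalignError(Exception):
    """Base class for all package errors."""


class InputFormatError(MnalignError):
    """Malformed or inconsistent input data."""


class InvariantViolation(MnalignError):
    """An internal consistency requirement was violated."""


def _canon(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered protein pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Network:
    """One undirected, unweighted PPI network.

    Edges are stored as canonically ordered tuples; self-loops and
    duplicates must have been removed by the caller (the readers in
    :mod:`mnalign.io` do this).
    """

    network_id: str
    vertices: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise InvariantViolation(
                    f"self-loop {a!r} in network {self.network_id!r}"
                )
            if (a, b) != _canon(a, b):
                raise InvariantViolation(
                    f"edge ({a!r}, {b!r}) not canonically ordered"
                )
            if a not in self.vertices or b not in self.vertices:
                raise InvariantViolation(
                    f"edge ({a!r}, {b!r}) has an endpoint outside network "
                    f"{self.network_id!r}"
                )


class NetworkCollection:
    """The k input networks with a global (collision-free) protein namespace.

    If the same raw protein identifier occurs in more than one network, every
    vertex is renamed to ``"<network_id>::<raw_id>"`` on ingest so that
    distinct (network, raw-id) pairs always map to distinct global ids.  The
    raw ids are kept and can be recovered with :meth:`raw_id`.
    """

    def __init__(self, networks: Iterable[Network]):
        networks = list(networks)
        if not networks:
            raise InputFormatError("a NetworkCollection needs >= 1 network")
        ids = [g.network_id for g in networks]
        if len(set(ids)) != len(ids):
            raise InputFormatError(f"duplicate network ids in {ids}")

        collision = False
        seen: set[str] = set()
        for g in networks:
            if seen & g.vertices:
                collision = True
                break
            seen |= g.vertices

        self._raw: dict[str, str] = {}
        if collision:
            logger.warning(
                "raw protein ids collide across networks; "
                "namespacing all ids as '<network>::<protein>'"
            )
            renamed = []
            for g in networks:
                mapping = {v: f"{g.network_id}::{v}" for v in g.vertices}
                renamed.append(
                    Network(
                        g.network_id,
                        frozenset(mapping.values()),
                        frozenset(
                            _canon(mapping[a], mapping[b]) for a, b in g.edges
                        ),
                    )
                )
                self._raw.update({gv: rv for rv, gv in mapping.items()})
            networks = renamed

        self.networks: tuple[Network, ...] = tuple(networks)
        self._net_of: dict[str, str] = {}
        self._adj: dict[str, set[str]] = {}
        for g in self.networks:
            for v in g.vertices:
                self._net_of[v] = g.network_id
                self._adj[v] = set()
            for a, b in g.edges:
                self._adj[a].add(b)
                self._adj[b].add(a)

    # -- basic accessors -------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.networks)

    @property
    def n(self) -> int:
        return len(self._net_of)

    @property
    def vertices(self) -> Iterator[str]:
        return iter(self._net_of)

    def net_of(self, protein: str) -> str:
        try:
            return self._net_of[protein]
        except KeyError:
            raise KeyError(f"unknown protein {protein!r}") from None

    def __contains__(self, protein: str) -> bool:
        return protein in self._net_of

    def neighbors(self, protein: str) -> set[str]:
        return self._adj[protein]

    def raw_id(self, protein: str) -> str:
        """Original identifier of ``protein`` before any namespacing."""
        return self._raw.get(protein, protein)

    def edges(self) -> Iterator[tuple[str, str, str]]:
        """Yield (network_id, a, b) for every edge, each edge once."""
        for g in self.networks:
            for a, b in sorted(g.edges):
                yield g.network_id, a, b

    def edge_count(self) -> int:
        return sum(len(g.edges) for g in self.networks)


class SimilarityMatrix:
    """Sparse symmetric cross-network similarity ``sim(v_x, v_y)``.

    Only strictly positive scores are stored; an absent pair means 0.
    Within-network pairs are always 0 and are never stored — sequence
    similarity inside one species carries no signal for the alignment
    problem, so the matrix lives entirely on cross-network pairs.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._partners: dict[str, dict[str, float]] = {}
        if entries:
            for (a, b), s in entries.items():
                self._set(a, b, s)

    def _set(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise InvariantViolation(f"self-similarity entry for {a!r}")
        if score <= 0:
            raise InvariantViolation("only positive scores may be stored")
        self._partners.setdefault(a, {})[b] = score
        self._partners.setdefault(b, {})[a] = score

    @classmethod
    def from_entries(
        cls,
        rows: Iterable[tuple[str, str, float]],
        nets: NetworkCollection,
        *,
        strict: bool = False,
    ) -> "SimilarityMatrix":
        """Build a matrix from (idA, idB, score) rows.

        Within-network pairs and zero scores are dropped (counts logged);
        duplicate rows keep the maximum score; negative scores raise.
        Unknown proteins are dropped with a warning, or raise when
        ``strict`` is set.
        """
        sim = cls()
        n_within = n_zero = n_unknown = 0
        best: dict[tuple[str, str], float] = {}
        for a, b, s in rows:
            if s < 0:
                raise InputFormatError(
                    f"negative similarity score {s} for pair ({a!r}, {b!r})"
                )
            if a not in nets or b not in nets:
                if strict:
                    missing = a if a not in nets else b
                    raise InputFormatError(
                        f"similarity row references unknown protein {missing!r}"
                    )
                n_unknown += 1
                continue
            if nets.net_of(a) == nets.net_of(b):
                n_within += 1
                continue
            if s == 0:
                n_zero += 1
                continue
            key = _canon(a, b)
            if s > best.get(key, 0.0):
                best[key] = s
        for (a, b), s in best.items():
            sim._set(a, b, s)
        if n_within or n_zero or n_unknown:
            logger.info(
                "similarity ingest dropped %d within-network, %d zero-score, "
                "%d unknown-protein rows",
                n_within,
                n_zero,
                n_unknown,
            )
        return sim

    # -- queries ---------------------------------------------------------

    def get(self, a: str, b: str) -> float:
        return self._partners.get(a, {}).get(b, 0.0)

    def partners(self, protein: str) -> Mapping[str, float]:
        """All nonzero partners of ``protein`` with their scores."""
        return self._partners.get(protein, {})

    def proteins(self) -> set[str]:
        """Proteins with at least one nonzero similarity entry."""
        return set(self._partners)

    def items(self) -> Iterator[tuple[str, str, float]]:
        """Yield every stored pair once, canonically ordered."""
        for a, ps in self._partners.items():
            for b, s in ps.items():
                if a < b:
                    yield a, b, s

    def __len__(self) -> int:
        return sum(len(ps) for ps in self._partners.values()) // 2

    def support(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.items()}


@dataclass(frozen=True)
class MatchSet:
    """A group of proteins matched together (the unit of alignment output)."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise InvariantViolation("empty match-set")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __contains__(self, protein: str) -> bool:
        return protein in self.members

    def networks(self, nets: NetworkCollection) -> set[str]:
        """Net(S): the networks touched by this match-set."""
        return {nets.net_of(v) for v in self.members}


class Alignment:
    """A set of mutually disjoint match-sets.

    Final alignments require every match-set to have >= 2 members; proteins
    in no match-set are *uncovered* (unaligned).
    """

    def __init__(
        self,
        match_sets: Iterable[Iterable[str]],
        *,
        min_size: int = 2,
    ):
        sets = []
        for ms in match_sets:
            ms = ms if isinstance(ms, MatchSet) else MatchSet(frozenset(ms))
            if len(ms) < min_size:
                raise InvariantViolation(
                    f"match-set {sorted(ms.members)} smaller than {min_size}"
                )
            sets.append(ms)
        self.match_sets: tuple[MatchSet, ...] = tuple(
            sorted(sets, key=lambda m: sorted(m.members))
        )
        self._index: dict[str, int] = {}
        for i, ms in enumerate(self.match_sets):
            for v in ms:
                if v in self._index:
                    raise InvariantViolation(
                        f"protein {v!r} appears in two match-sets"
                    )
                self._index[v] = i

    def __len__(self) -> int:
        return len(self.match_sets)

    def __iter__(self) -> Iterator[MatchSet]:
        return iter(self.match_sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return set(self.as_sets()) == set(other.as_sets())

    def __hash__(self) -> int:  # pragma: no cover - rarely used
        return hash(frozenset(self.as_sets()))

    def as_sets(self) -> list[frozenset[str]]:
        return [ms.members for ms in self.match_sets]

    def index_of(self, protein: str) -> int | None:
        """Index of the match-set containing ``protein``, or None."""
        return self._index.get(protein)

    def set_of(self, protein: str) -> MatchSet | None:
        i = self._index.get(protein)
        return None if i is None else self.match_sets[i]

    def covered(self) -> set[str]:
        return set(self._index)

    @property
    def coverage(self) -> int:
        return len(self._index)


# Protein -> set of (opaque) GO-term identifiers.  Proteins absent from the
# map are simply unannotated.
AnnotationMap = dict[str, set[str]]


@dataclass
class AlignmentParams:
    """User-facing knobs of the aligner.

    tau
        Seed threshold: a within-cluster cross-network pair becomes a seed
        when its (decision) similarity score is >= tau.  Same units as the
        similarity scores.
    beta
        Fraction in (0, 1] of the maximal within-union score a cross-set
        pair must exceed to count as "similar" in the merge criterion.
    rho
        Fraction in (0, 1]; larger values demand more mutually similar
        cross-set pairs before two match-sets merge.  With rho > 0.5 and
        two networks the aligner degenerates to one-to-one pairwise mode.
    omega
        Size cap: a merged match-set may hold at most omega proteins per
        network it spans.  Suggested range [1.5, 2.5].
    criterion
        Clustering criterion function, "i1" (size-normalised within-cluster
        similarity) or "i2" (plain within-cluster similarity sum).
    cluster_count_override
        Force the number of clusters instead of the default n_sim / k.
    merge_zero_sim_singletons
        Allow two singleton match-sets to merge during seed expansion even
        when their similarity is 0 (the expansion stage trusts topology for
        singleton pairs; the remaining-protein stage never does).
    tie_break
        Identifier of the deterministic tie-break rule; "lex-lifo" pushes
        queue batches in lexicographic order and pops equal priorities
        last-in-first-out.
    """

    tau: float = 0.0
    beta: float = 0.1
    rho: float = 0.5
    omega: float = 2.5
    criterion: str = "i1"
    cluster_count_override: int | None = None
    merge_zero_sim_singletons: bool = True
    tie_break: str = "lex-lifo"
    random_seed: int = 0
    preprocess: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.beta <= 1:
            raise InputFormatError("beta must be in (0, 1]")
        if not 0 < self.rho <= 1:
            raise InputFormatError("rho must be in (0, 1]")
        if self.omega <= 0:
            raise InputFormatError("omega must be positive")
        if self.criterion not in ("i1", "i2"):
            raise InputFormatError("criterion must be 'i1' or 'i2'")
        if self.tie_break != "lex-lifo":
            raise InputFormatError(f"unknown tie-break {self.tie_break!r}")
        if (
            self.cluster_count_override is not None
            and self.cluster_count_override < 1
        ):
            raise InputFormatError("cluster_count_override must be >= 1")
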