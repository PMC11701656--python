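"""Shared in-memory containers for the network-inference pipeline.

Protein pairs are stored as 2-tuples of identifier strings.  Undirected
pairs are kept in canonical order (lexicographically smaller protein
first); directed pairs (regulator, target) keep their orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple

Pair = Tuple[str, str]

#: The ten evidence types integrated by the framework.
EVIDENCE_TYPES = frozenset(
    {"DOM", "GIN", "GRG", "MEX", "MIR", "PEX", "PHP", "PIN", "SCL", "TFB"}
)

#: Evidence types eligible for cross-species transfer.  DOM, PHP and SCL
#: already aggregate cross-species information and must not be transferred.
TRANSFERABLE_TYPES = frozenset({"GIN", "GRG", "MEX", "MIR", "PEX", "PIN", "TFB"})

#: The six gold-standard categories.
GOLD_STANDARD_NAMES = (
    "Complex",
    "Metabolic",
    "Signaling",
    "Operon",
    "PPI",
    "Regulatory",
)


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) in canonical (sorted) order.

    Self-pairs are rejected: a functional association always involves two
    distinct proteins.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a <= b else (b, a)


@dataclass
class EvidenceScoreTable:
    """Raw association scores for one (evidence type, dataset, species).

    ``scores`` maps protein pairs to finite floats.  For undirected
    evidence the keys are canonicalized on construction; GRG keys are
    (regulator, target) and keep their orientation.
    """

    evidence_type: str
    species: str
    dataset_id: str
    scores: Dict[Pair, float]
    directed: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.evidence_type not in EVIDENCE_TYPES:
            raise ValueError(f"unknown evidence type {self.evidence_type!r}")
        if self.directed is None:
            self.directed = self.evidence_type == "GRG"
        clean: Dict[Pair, float] = {}
        for (a, b), s in self.scores.items():
            if not math.isfinite(s):
                raise ValueError(f"non-finite score for pair ({a}, {b})")
            key = (a, b) if self.directed else canonical_pair(a, b)
            if key[0] == key[1]:
                raise ValueError(f"self-pair not allowed: {a!r}")
            clean[key] = float(s)
        self.scores = clean

    def undirected_scores(self) -> Dict[Pair, float]:
        """Scores keyed by canonical unordered pair.

        For directed tables, when both orientations are present the
        maximum score is kept (the stronger regulatory signal).
        """
        if not self.directed:
            return dict(self.scores)
        out: Dict[Pair, float] = {}
        for (a, b), s in self.scores.items():
            key = canonical_pair(a, b)
            if key not in out or s > out[key]:
                out[key] = s
        return out

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class GoldStandard:
    """A named set of (possibly directed) protein pairs used as positives."""

    name: str
    links: Set[Pair]
    directed: bool = False

    def __post_init__(self) -> None:
        clean: Set[Pair] = set()
        for a, b in self.links:
            if a == b:
                raise ValueError(f"self-link not allowed in gold standard: {a!r}")
            clean.add((a, b) if self.directed else canonical_pair(a, b))
        self.links = clean

    def undirected_links(self) -> FrozenSet[Pair]:
        """The link set projected onto the undirected pair universe.

        Directed (regulatory) links are treated as undirected pairs during
        training; direction stays a link attribute, not a separate pair.
        """
        return frozenset(canonical_pair(a, b) for a, b in self.links)

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.links

    def __len__(self) -> int:
        return len(self.links)


@dataclass
class OrthologMap:
    """InParanoid-style ortholog pairs between two species.

    ``pairs`` holds (protein in species A, protein in species B) tuples;
    ``groups`` maps a group identifier to its (A-side, B-side) co-ortholog
    sets.  Every grouped protein appears in at least one pair.
    """

    species_pair: Tuple[str, str]
    pairs: Set[Pair]
    groups: Dict[str, Tuple[FrozenSet[str], FrozenSet[str]]] = field(
        default_factory=dict
    )

    def a_to_b(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
        return out

    def b_to_a(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(b, set()).add(a)
        return out

    def proteins_a(self) -> Set[str]:
        return {a for a, _ in self.pairs}

    def proteins_b(self) -> Set[str]:
        return {b for _, b in self.pairs}

    def reversed(self) -> "OrthologMap":
        return OrthologMap(
            species_pair=(self.species_pair[1], self.species_pair[0]),
            pairs={(b, a) for a, b in self.pairs},
            groups={g: (bs, as_) for g, (as_, bs) in self.groups.items()},
        )

    def __len__(self) -> int:
        return len(self.pairs)


#: Direction flags on network links.
DIRECTIONS = ("none", "ab", "ba")


@dataclass(eq=False)
class Link:
    """One calibrated network link.

    ``a``/``b`` are in canonical order; ``direction`` is ``"ab"`` when the
    regulatory orientation is a->b, ``"ba"`` for b->a and ``"none"`` for
    undirected links.  ``ppv_source`` records whether the confidence comes
    from the evidence-based logistic calibration or from gold-standard
    membership (gsPPV).
    """

    a: str
    b: str
    ppv: float
    direction: str = "none"
    gold_standard: str = ""
    fbs: float = float("nan")
    ppv_source: str = "evidence"
    llrs: Dict[str, float] = field(default_factory=dict)
    grg_llr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-link not allowed")
        if self.a > self.b:
            # canonicalize and flip the direction flag accordingly
            self.a, self.b = self.b, self.a
            if self.direction == "ab":
                self.direction = "ba"
            elif self.direction == "ba":
                self.direction = "ab"
        if self.direction not in DIRECTIONS:
            raise ValueError(f"bad direction flag {self.direction!r}")
        if not 0.0 <= self.ppv <= 1.0:
            raise ValueError(f"PPV outside [0, 1]: {self.ppv}")

    @property
    def pair(self) -> Pair:
        return (self.a, self.b)

    def _key(self):
        fbs = None if math.isnan(self.fbs) else self.fbs
        return (
            self.a,
            self.b,
            self.ppv,
            self.direction,
            self.gold_standard,
            fbs,
            self.ppv_source,
            tuple(sorted(self.llrs.items())),
            self.grg_llr,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Link):
            return NotImplemented
        return self._key() == other._key()


class Network:
    """A set of calibrated links indexed by canonical protein pair."""

    def __init__(self, links: Iterable[Link] = ()) -> None:
        self.links: Dict[Pair, Link] = {}
        for link in links:
            self.add(link)

    def add(self, link: Link) -> None:
        if link.pair in self.links:
            raise ValueError(f"duplicate link {link.pair}")
        self.links[link.pair] = link

    def nodes(self) -> Set[str]:
        out: Set[str] = set()
        for a, b in self.links:
            out.add(a)
            out.add(b)
        return out

    def pairs(self) -> Set[Pair]:
        return set(self.links)

    def neighbors(self) -> Dict[str, Dict[str, Link]]:
        """Adjacency: node -> {neighbor -> link}."""
        adj: Dict[str, Dict[str, Link]] = {}
        for (a, b), link in self.links.items():
            adj.setdefault(a, {})[b] = link
            adj.setdefault(b, {})[a] = link
        return adj

    def __len__(self) -> int:
        return len(self.links)

    def __contains__(self, pair: Pair) -> bool:
        return tuple(sorted(pair)) in self.links

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.links == other.links
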