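"""Construction of the six gold-standard link sets.

Gold standards are curated proxies for true functional couplings, used as
the positive class when training evidence likelihoods: protein complexes,
metabolic and signaling pathways, shared operons, physical interactions
and (directed) transcription-factor regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, List, Sequence, Set, Tuple

from .containers import GoldStandard, Pair, canonical_pair


@dataclass
class ComplexRecord:
    """A protein complex: identifier and member set."""

    id: str
    members: Set[str]


@dataclass
class PathwayRecord:
    """A pathway: identifier and member set."""

    id: str
    members: Set[str]


@dataclass
class ExperimentRecord:
    """One interaction-detection experiment.

    ``interactions`` is a list of (pair, publication id) tuples.
    """

    id: str
    interactions: List[Tuple[Pair, str]] = field(default_factory=list)


def _clique(members: Iterable[str]) -> Set[Pair]:
    return {canonical_pair(a, b) for a, b in combinations(sorted(set(members)), 2)}


def build_complex_gs(
    records: Sequence[ComplexRecord], max_size: int = 100
) -> GoldStandard:
    """Clique-expand complexes into links; oversized complexes contribute
    nothing.

    Very large complexes are dominated by false co-membership, so any
    complex with more than ``max_size`` members is excluded outright.
    """
    links: Set[Pair] = set()
    for rec in records:
        if len(rec.members) <= max_size:
            links |= _clique(rec.members)
    return GoldStandard(name="Complex", links=links, directed=False)


def build_pathway_gs(records: Sequence[PathwayRecord], name: str) -> GoldStandard:
    """Fully connect the members of each pathway; union over pathways."""
    if name not in {"Metabolic", "Signaling"}:
        raise ValueError("pathway gold standard name must be Metabolic or Signaling")
    links: Set[Pair] = set()
    for rec in records:
        links |= _clique(rec.members)
    return GoldStandard(name=name, links=links, directed=False)


def build_ppi_gs(
    experiments: Sequence[ExperimentRecord],
    other_gs: Sequence[GoldStandard] = (),
    max_exp_size: int = 100,
    min_support: int = 2,
) -> GoldStandard:
    """Physical-interaction gold standard.

    Experiments reporting more than ``max_exp_size`` interactions are
    discarded (high-throughput screens are too error-prone to count as
    support).  A pair is kept iff it occurs in at least ``min_support``
    surviving experiments, or is present in any other gold standard.
    """
    rescue: Set[Pair] = set()
    for gs in other_gs:
        rescue |= gs.undirected_links()
    support: dict = {}
    for exp in experiments:
        if len(exp.interactions) > max_exp_size:
            continue
        seen_here: Set[Pair] = set()
        for (a, b), _pub in exp.interactions:
            if a == b:
                continue
            seen_here.add(canonical_pair(a, b))
        for pair in seen_here:
            support.setdefault(pair, set()).add(exp.id)
    links = {
        pair
        for pair, exps in support.items()
        if len(exps) >= min_support or pair in rescue
    }
    return GoldStandard(name="PPI", links=links, directed=False)


def build_regulatory_gs(sources: Sequence[Iterable[Pair]]) -> GoldStandard:
    """Directed union of TF->target pair sources.

    A pair present in both orientations yields two distinct directed links.
    """
    links: Set[Pair] = set()
    for source in sources:
        for tf, target in source:
            if tf == target:
                continue
            links.add((tf, target))
    return GoldStandard(name="Regulatory", links=links, directed=True)


def build_operon_gs(operons: Sequence[Iterable[str]]) -> GoldStandard:
    """Clique-expand shared-operon membership; union over operons."""
    links: Set[Pair] = set()
    for operon in operons:
        links |= _clique(operon)
    return GoldStandard(name="Operon", links=links, directed=False)
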