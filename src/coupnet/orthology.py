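"""Cross-species machinery: species trees, evidence and network transfer.

Species distances are defined as one minus the average fraction of
orthologous proteins in both directions; a tree over those distances (the
"orthophylogram") backs both the phylogenetic-profile score and the
closest-species selection used for whole-network transfer.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .containers import (
    TRANSFERABLE_TYPES,
    EvidenceScoreTable,
    Link,
    Network,
    OrthologMap,
    Pair,
    canonical_pair,
)


@dataclass
class SpeciesTree:
    """A species tree with branch lengths.

    ``tree`` is a scikit-bio TreeNode whose tips are the species labels.
    ``root_species`` is set when the tree was rooted at a species of
    interest (for phylogenetic-profile scoring); None for plain UPGMA
    trees.
    """

    tree: TreeNode
    species: Tuple[str, ...]
    root_species: Optional[str] = None

    @property
    def total_length(self) -> float:
        return float(
            sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))
        )

    def spanning_length(self, leaves: Iterable[str]) -> float:
        """Total branch length of the minimal subtree connecting ``leaves``.

        An edge belongs to the spanning (Steiner) subtree iff selected
        leaves lie on both of its sides; the result is independent of the
        rooting.  Fewer than two selected leaves span no edge.
        """
        selected = set(leaves)
        unknown = selected - set(self.species)
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        if len(selected) < 2:
            return 0.0
        total = 0.0
        counts: Dict[int, int] = {}
        for node in self.tree.postorder(include_self=True):
            if node.is_tip():
                c = 1 if node.name in selected else 0
            else:
                c = sum(counts[id(ch)] for ch in node.children)
            counts[id(node)] = c
            if node.parent is not None and 0 < c < len(selected):
                total += node.length or 0.0
        return total

    def to_newick(self) -> str:
        buf = _stdio.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def species_distance(ortho: OrthologMap, n_a: int, n_b: int) -> float:
    """1 - average fraction of orthologous proteins in both directions."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("proteome sizes must be positive")
    frac_a = len(ortho.proteins_a()) / n_a
    frac_b = len(ortho.proteins_b()) / n_b
    return 1.0 - (frac_a + frac_b) / 2.0


def _check_distance_matrix(distances: np.ndarray, species: Sequence[str]) -> np.ndarray:
    d = np.asarray(distances, dtype=float)
    if d.shape != (len(species), len(species)):
        raise ValueError("distance matrix shape does not match species list")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    return d


def _upgma_tree(d: np.ndarray, species: Sequence[str]) -> TreeNode:
    """Average-linkage clustering converted to an ultrametric tree."""
    z = linkage(squareform(d, checks=False), method="average")
    nodes: List[TreeNode] = [TreeNode(name=s) for s in species]
    heights = [0.0] * len(species)
    for row in z:
        i, j, h = int(row[0]), int(row[1]), float(row[2]) / 2.0
        left, right = nodes[i], nodes[j]
        left.length = h - heights[i]
        right.length = h - heights[j]
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
        heights.append(h)
    return nodes[-1]


def build_species_tree(
    distances,
    species: Sequence[str],
    method: str = "upgma",
    root_species: Optional[str] = None,
) -> SpeciesTree:
    """Build a species tree from a symmetric distance matrix.

    ``method="nj"`` runs canonical neighbour joining (negative branch
    lengths clamped to zero) and, when ``root_species`` is given, roots
    the tree at that species' attachment point.  ``method="upgma"``
    produces an ultrametric average-linkage tree.
    """
    d = _check_distance_matrix(distances, species)
    if len(species) < 2:
        raise ValueError("need at least two species")
    if len(species) == 2:
        half = d[0, 1] / 2.0
        tree = TreeNode(
            children=[
                TreeNode(name=species[0], length=half),
                TreeNode(name=species[1], length=half),
            ]
        )
        return SpeciesTree(tree=tree, species=tuple(species), root_species=root_species)
    if method == "nj":
        tree = nj(DistanceMatrix(d, ids=list(species)))
        for node in tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                node.length = 0.0
        if root_species is not None:
            tip = tree.find(root_species)
            if tip.parent is not None:
                tree = tree.root_at(tip.parent)
    elif method == "upgma":
        tree = _upgma_tree(d, species)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpeciesTree(tree=tree, species=tuple(species), root_species=root_species)


def transfer_evidence(
    source: EvidenceScoreTable, ortho: OrthologMap
) -> EvidenceScoreTable:
    """Map an evidence table into another species through orthologs.

    Each source pair maps to the cross-product of its endpoints'
    orthologs; when several source pairs land on the same target pair
    (many-to-one co-ortholog groups) their scores are averaged into a
    single entry.  DOM, PHP and SCL are refused: they already contain
    cross-species information.
    """
    if source.evidence_type not in TRANSFERABLE_TYPES:
        raise ValueError(
            f"{source.evidence_type} is not transferable: DOM, PHP and SCL "
            "already contain cross-species information"
        )
    if source.species == ortho.species_pair[0]:
        mapping = ortho.a_to_b()
        target_species = ortho.species_pair[1]
    elif source.species == ortho.species_pair[1]:
        mapping = ortho.b_to_a()
        target_species = ortho.species_pair[0]
    else:
        raise ValueError(
            f"ortholog map {ortho.species_pair} does not cover species "
            f"{source.species!r}"
        )
    collected: Dict[Pair, List[float]] = {}
    for (a, b), score in source.scores.items():
        for ta in mapping.get(a, ()):
            for tb in mapping.get(b, ()):
                if ta == tb:
                    continue
                key = (ta, tb) if source.directed else canonical_pair(ta, tb)
                collected.setdefault(key, []).append(score)
    scores = {pair: float(np.mean(vals)) for pair, vals in collected.items()}
    return EvidenceScoreTable(
        evidence_type=source.evidence_type,
        species=target_species,
        dataset_id=f"{source.dataset_id}@{source.species}",
        scores=scores,
        directed=source.directed,
    )


def _taxonomy_distance(
    lineage_a: Sequence[str], lineage_b: Sequence[str]
) -> int:
    """Path length between two species in the lineage tree, counting ranks."""
    k = 0
    for x, y in zip(lineage_a, lineage_b):
        if x != y:
            break
        k += 1
    return (len(lineage_a) - k) + (len(lineage_b) - k)


def closest_species(
    target: str,
    candidates: Sequence[str],
    taxonomy: Optional[Dict[str, Sequence[str]]],
    distances: Dict[Tuple[str, str], float],
) -> str:
    """Pick the candidate species nearest to ``target``.

    Primary criterion is path length in the taxonomy lineage tree; ties,
    or candidates/targets missing from the taxonomy, fall back to the
    smallest orthophylogram distance.  Remaining ties break
    lexicographically for determinism.
    """
    if not candidates:
        raise ValueError("need at least one candidate species")

    def ortho_dist(c: str) -> float:
        return distances.get(
            (target, c), distances.get((c, target), float("inf"))
        )

    if taxonomy is not None and target in taxonomy:
        scored = [
            (c, _taxonomy_distance(taxonomy[target], taxonomy[c]))
            for c in candidates
            if c in taxonomy
        ]
        if scored:
            best = min(t for _, t in scored)
            tied = sorted(c for c, t in scored if t == best)
            if len(tied) == 1:
                return tied[0]
            return min(tied, key=lambda c: (ortho_dist(c), c))
    return min(sorted(candidates), key=lambda c: (ortho_dist(c), c))


def transfer_network(source: Network, ortho: OrthologMap) -> Network:
    """Transfer whole-network links through orthologs.

    Every source link expands to all pairs of its endpoints' orthologs,
    keeping the original link confidence; duplicate target pairs keep the
    maximum PPV.
    """
    mapping = ortho.a_to_b()
    best: Dict[Pair, Link] = {}
    for (a, b), link in source.links.items():
        for ta in mapping.get(a, ()):
            for tb in mapping.get(b, ()):
                if ta == tb:
                    continue
                direction = "none"
                if link.direction == "ab":
                    direction = "ab" if ta <= tb else "ba"
                elif link.direction == "ba":
                    direction = "ba" if ta <= tb else "ab"
                new = Link(
                    a=ta,
                    b=tb,
                    ppv=link.ppv,
                    direction=direction,
                    gold_standard=link.gold_standard,
                    fbs=link.fbs,
                    ppv_source=link.ppv_source,
                    grg_llr=link.grg_llr,
                )
                old = best.get(new.pair)
                if old is None or new.ppv > old.ppv:
                    best[new.pair] = new
    return Network(best.values())


class NetworkSimilarity(NamedTuple):
    node_ji: float
    node_oc: float
    link_ji: float
    link_oc: float


def _ji_oc(set_a: Set, set_b: Set) -> Tuple[float, float]:
    if not set_a and not set_b:
        return 0.0, 0.0
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    smaller = min(len(set_a), len(set_b))
    ji = inter / union if union else 0.0
    oc = inter / smaller if smaller else 0.0
    return ji, oc


def network_similarity(net_a: Network, net_b: Network) -> NetworkSimilarity:
    """Jaccard and overlap-coefficient similarity of nodes and links."""
    node_ji, node_oc = _ji_oc(net_a.nodes(), net_b.nodes())
    link_ji, link_oc = _ji_oc(net_a.pairs(), net_b.pairs())
    return NetworkSimilarity(node_ji, node_oc, link_ji, link_oc)
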