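"""Raw association scores for the ten evidence types.

Every score quantifies, from one omics layer, how strongly two proteins
appear to act together: shared interacting domains (DOM), correlated
genetic-interaction profiles (GIN), ChIP-seq regulator-target support
(GRG), mRNA co-expression (MEX), shared microRNA regulators (MIR), protein
co-expression over tissues (PEX), co-occurrence across the species tree
(PHP), literature-supported physical interaction (PIN), co-localization
semantic similarity (SCL) and shared transcription-factor binding (TFB).

All logarithms are natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .containers import EvidenceScoreTable, Pair, canonical_pair
from .io import GeneInterval, NarrowPeakRecord
from .orthology import SpeciesTree

# ---------------------------------------------------------------------------
# DOM: domain-domain interaction
# ---------------------------------------------------------------------------


@dataclass
class DomainAnnotation:
    """Protein -> domain sets plus scored domain-pair interactions.

    ``pair_scores`` maps canonical domain pairs to interaction support in
    [0, 1]; ``degree`` counts the scored partner domains of each domain.
    """

    domains: Dict[str, Set[str]]
    pair_scores: Dict[Tuple[str, str], float]
    degree: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pair_scores = {
            tuple(sorted(k)): float(v) for k, v in self.pair_scores.items()
        }
        if not self.degree:
            deg: Dict[str, Set[str]] = {}
            for d1, d2 in self.pair_scores:
                deg.setdefault(d1, set()).add(d2)
                deg.setdefault(d2, set()).add(d1)
            self.degree = {d: len(ps) for d, ps in deg.items()}


def dom_score(a: str, b: str, ann: DomainAnnotation) -> Optional[float]:
    """Domain-interaction support between proteins ``a`` and ``b``.

    With N the product of the two proteins' domain counts and m the number
    of scored domain pairs between them, the score is (m/N) times the mean
    of the domain-pair supports, each weighted by 1/ln(d_a + d_b) where
    d_a, d_b are the scored degrees of the interacting domains.  Returns 0
    when no domain pair is scored, and None when either protein lacks
    domain annotation.
    """
    doms_a = ann.domains.get(a)
    doms_b = ann.domains.get(b)
    if not doms_a or not doms_b:
        return None
    n_total = len(doms_a) * len(doms_b)
    acc = 0.0
    m = 0
    for da in doms_a:
        for db in doms_b:
            key = tuple(sorted((da, db)))
            if key in ann.pair_scores:
                m += 1
                deg = ann.degree.get(da, 1) + ann.degree.get(db, 1)
                acc += ann.pair_scores[key] / math.log(deg)
    if m == 0:
        return 0.0
    return (m / n_total) * (acc / m)


# ---------------------------------------------------------------------------
# PIN: physical interaction from literature support
# ---------------------------------------------------------------------------


@dataclass
class PublicationSupport:
    """Publication support for physical interactions.

    ``publications`` maps canonical pairs to supporting publication ids;
    ``publication_size`` gives the number of interactions each publication
    reports; ``protein_degree`` the total interactions of each protein in
    the source database.
    """

    publications: Dict[Pair, List[str]]
    publication_size: Dict[str, int]
    protein_degree: Dict[str, int]

    def __post_init__(self) -> None:
        self.publications = {
            canonical_pair(*k): list(v) for k, v in self.publications.items()
        }


def pin_score(a: str, b: str, support: PublicationSupport) -> Optional[float]:
    """Literature-weighted physical-interaction score.

    The mean of 1/ln(1 + |PMID_i|) over the n supporting publications,
    times 1/ln(d_A + d_B).  Small dedicated studies therefore count more
    than high-throughput screens, and hub proteins are downweighted.
    Undefined (None) when the pair has no support or when the combined
    degree makes the log weight non-positive.
    """
    pubs = support.publications.get(canonical_pair(a, b))
    if not pubs:
        return None
    d_sum = support.protein_degree.get(a, 0) + support.protein_degree.get(b, 0)
    if d_sum <= 1:
        return None
    acc = sum(
        1.0 / math.log(1 + support.publication_size[p]) for p in pubs
    )
    return (acc / len(pubs)) * (1.0 / math.log(d_sum))


# ---------------------------------------------------------------------------
# GIN / MEX / PEX: profile correlations
# ---------------------------------------------------------------------------


def profile_correlation_score(
    profile_a: Sequence[float],
    profile_b: Sequence[float],
    min_valid: int,
) -> Optional[float]:
    """Spearman correlation over jointly valid (finite) positions.

    Returns None when fewer than ``min_valid`` positions are valid in both
    profiles or when either valid subvector has zero variance.  Ties get
    average ranks.
    """
    x = np.asarray(profile_a, dtype=float)
    y = np.asarray(profile_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must share the same axis")
    mask = np.isfinite(x) & np.isfinite(y)
    if int(mask.sum()) < min_valid:
        return None
    xv, yv = x[mask], y[mask]
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return None
    rho = stats.spearmanr(xv, yv).statistic
    if not np.isfinite(rho):
        return None
    return float(rho)


def mex_postprocess(
    correlations: Dict[Pair, float],
    homolog_pairs: Set[Pair],
    species: str = "spA",
    dataset_id: str = "mex0",
) -> EvidenceScoreTable:
    """Filter and rescale co-expression correlations.

    Homolog pairs are removed (their co-expression reflects shared
    ancestry, not coupling); pairs with absolute correlation at or below
    0.5 are dropped; the surviving absolute correlations are min-max
    scaled to [0, 1] within the dataset.  A single surviving pair maps to
    1.0 by convention.
    """
    homologs = {canonical_pair(*p) for p in homolog_pairs}
    retained = {
        canonical_pair(*p): abs(r)
        for p, r in correlations.items()
        if canonical_pair(*p) not in homologs and abs(r) > 0.5
    }
    if retained:
        vals = np.array(list(retained.values()))
        lo, hi = float(vals.min()), float(vals.max())
        if hi > lo:
            retained = {p: (v - lo) / (hi - lo) for p, v in retained.items()}
        else:
            retained = {p: 1.0 for p in retained}
    return EvidenceScoreTable(
        evidence_type="MEX",
        species=species,
        dataset_id=dataset_id,
        scores=retained,
        directed=False,
    )


# ---------------------------------------------------------------------------
# MIR / TFB / PEX: Jaccard scores
# ---------------------------------------------------------------------------


def jaccard_regulator_score(set_a: Set[str], set_b: Set[str]) -> Optional[float]:
    """Jaccard index of two regulator sets; None when zero or undefined."""
    union = set_a | set_b
    if not union:
        return None
    ji = len(set_a & set_b) / len(union)
    return ji if ji > 0 else None


def pex_top_tissue_score(
    expr_a: Sequence[float],
    expr_b: Sequence[float],
    top_fraction: float = 0.25,
) -> Optional[float]:
    """Jaccard index of the two proteins' top-expressed tissue sets.

    Each protein contributes its ceil(top_fraction * T) highest-expression
    tissues (T = length of the tissue axis, ties broken by tissue index);
    missing (non-finite) tissues are ignored.  None when the overlap is
    zero or a profile is entirely missing.
    """
    x = np.asarray(expr_a, dtype=float)
    y = np.asarray(expr_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression vectors must share the tissue axis")
    k = math.ceil(top_fraction * len(x))

    def top_set(v: np.ndarray) -> Optional[Set[int]]:
        valid = np.flatnonzero(np.isfinite(v))
        if valid.size == 0:
            return None
        order = sorted(valid, key=lambda i: (-v[i], i))
        return set(order[:k])

    ta, tb = top_set(x), top_set(y)
    if ta is None or tb is None:
        return None
    return jaccard_regulator_score({f"t{i}" for i in ta}, {f"t{i}" for i in tb})


# ---------------------------------------------------------------------------
# PHP: phylogenetic profile similarity
# ---------------------------------------------------------------------------


def php_score(
    profile_a: Sequence[int],
    profile_b: Sequence[int],
    tree: SpeciesTree,
    eps_fraction: float = 1e-6,
) -> float:
    """Tree-weighted phylogenetic-profile similarity.

    The positive score is the branch length of the minimal subtree
    spanning species where both proteins have orthologs, over the total
    tree length; the negative score the same for species where exactly one
    does.  The returned value is ln(positive/negative).  Deep shared
    conservation thus scores high, discordant presence low.  Zero
    numerator or denominator is floored at ``eps_fraction`` (of the
    normalized length), capping the score at +-ln(1/eps).
    """
    a = np.asarray(profile_a, dtype=bool)
    b = np.asarray(profile_b, dtype=bool)
    if a.shape != b.shape or len(a) != len(tree.species):
        raise ValueError("profiles must match the tree's species axis")
    both = [s for s, pa, pb in zip(tree.species, a, b) if pa and pb]
    one = [s for s, pa, pb in zip(tree.species, a, b) if pa != pb]
    total = tree.total_length
    if total <= 0:
        raise ValueError("tree has no branch length")
    pos = max(tree.spanning_length(both) / total, eps_fraction)
    neg = max(tree.spanning_length(one) / total, eps_fraction)
    return math.log(pos / neg)


# ---------------------------------------------------------------------------
# GRG: ChIP-seq regulator -> gene assignment
# ---------------------------------------------------------------------------


def grg_score(
    datasets: Sequence[Tuple[str, Sequence[NarrowPeakRecord]]],
    genes: Sequence[GeneInterval],
    assign_window: int = 10_000,
    species: str = "spA",
    dataset_id: str = "grg0",
) -> EvidenceScoreTable:
    """Directed TF->gene scores from ChIP-seq peak datasets.

    Per dataset, peak signal values are min-max normalized to [0, 1]
    (constant-signal datasets normalize to 1); each peak is assigned to
    genes whose interval, extended ``assign_window`` bp upstream of the
    annotated start (strand-aware; unstranded genes are treated as '+'),
    it overlaps.  Pairs supported by several peaks or datasets keep the
    maximum normalized enrichment.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if not genes:
        raise ValueError("gene annotation must be non-empty")
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        if g.strand == "-":
            lo, hi = g.start, g.end + assign_window
        else:
            lo, hi = g.start - assign_window, g.end
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
    best: Dict[Pair, float] = {}
    for tf, peaks in datasets:
        if not peaks:
            continue
        vals = np.array([p.signalValue for p in peaks], dtype=float)
        lo, hi = float(vals.min()), float(vals.max())
        for p, v in zip(peaks, vals):
            norm = 1.0 if hi == lo else (v - lo) / (hi - lo)
            tree = trees.get(p.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(p.start, p.end):
                gene = iv.data
                if gene == tf:
                    continue
                key = (tf, gene)
                if key not in best or norm > best[key]:
                    best[key] = norm
    return EvidenceScoreTable(
        evidence_type="GRG",
        species=species,
        dataset_id=dataset_id,
        scores=best,
        directed=True,
    )


# ---------------------------------------------------------------------------
# SCL: Wang graph-based semantic similarity
# ---------------------------------------------------------------------------

_DEFAULT_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class TermDAG:
    """An ontology DAG given as (child, parent, relation) edges.

    Edge weights follow the Wang semantic-similarity convention:
    0.8 for is_a, 0.6 for part_of by default.
    """

    def __init__(
        self,
        edges: Sequence[Tuple[str, str, str]],
        relation_weights: Optional[Dict[str, float]] = None,
    ) -> None:
        weights = dict(_DEFAULT_RELATION_WEIGHTS)
        if relation_weights:
            weights.update(relation_weights)
        self.parents: Dict[str, List[Tuple[str, float]]] = {}
        self.terms: Set[str] = set()
        for child, parent, relation in edges:
            if relation not in weights:
                raise ValueError(f"unknown relation {relation!r}")
            self.parents.setdefault(child, []).append((parent, weights[relation]))
            self.terms.add(child)
            self.terms.add(parent)
        self._svalue_cache: Dict[str, Dict[str, float]] = {}

    def svalues(self, term: str) -> Dict[str, float]:
        """S-values of ``term``'s ancestor DAG (downward-propagated
        products of edge weights, best path kept)."""
        if term not in self.terms:
            raise ValueError(f"unknown term {term!r}")
        cached = self._svalue_cache.get(term)
        if cached is not None:
            return cached
        s: Dict[str, float] = {term: 1.0}
        frontier = [term]
        while frontier:
            nxt: List[str] = []
            for t in frontier:
                for parent, w in self.parents.get(t, ()):
                    cand = w * s[t]
                    if cand > s.get(parent, 0.0):
                        s[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        self._svalue_cache[term] = s
        return s

    def term_similarity(self, t1: str, t2: str) -> float:
        s1 = self.svalues(t1)
        s2 = self.svalues(t2)
        common = set(s1) & set(s2)
        if not common:
            return 0.0
        num = sum(s1[t] + s2[t] for t in common)
        return num / (sum(s1.values()) + sum(s2.values()))


def wang_semantic_similarity(
    terms_a: Set[str], terms_b: Set[str], dag: TermDAG
) -> float:
    """Best-match-average Wang similarity between two term sets."""
    unknown = (terms_a | terms_b) - dag.terms
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    if not terms_a or not terms_b:
        return 0.0
    best_a = [max(dag.term_similarity(a, b) for b in terms_b) for a in terms_a]
    best_b = [max(dag.term_similarity(a, b) for a in terms_a) for b in terms_b]
    return (sum(best_a) + sum(best_b)) / (len(terms_a) + len(terms_b))
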