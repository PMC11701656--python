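"""Synthetic worlds with planted functional couplings.

Real gold standards are only noisy proxies for the unknown true
interactome.  For testing, this module inverts the problem: it plants a
known set of coupled protein pairs and derives evidence scores, gold
standards and ortholog maps from it, so every downstream stage of the
pipeline can be checked against ground truth.

Defaults: evidence scores for coupled pairs are drawn from N(1, 1) and for
uncoupled pairs from N(0, 1).  With these Gaussians the true
log-likelihood ratio has the closed form LLR(x) = x - 0.5, which serves as
an analytic oracle for the KDE/polynomial training stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import FrozenSet, Optional, Tuple

import numpy as np
from scipy import stats

from .containers import EvidenceScoreTable, GoldStandard, OrthologMap, Pair


@dataclass(frozen=True)
class PlantedWorld:
    """A single-species universe of proteins with known true couplings."""

    species: str
    proteins: Tuple[str, ...]
    true_couplings: FrozenSet[Pair]
    coupling_fraction: float
    seed: int

    def all_pairs(self) -> Tuple[Pair, ...]:
        return tuple(combinations(self.proteins, 2))

    @property
    def n_pairs(self) -> int:
        n = len(self.proteins)
        return n * (n - 1) // 2


def _derive_seed(base: int, tag: str) -> int:
    """Deterministic per-purpose seed below 2**31."""
    return (base * 1000003 + zlib.crc32(tag.encode())) % (2**31)


def generate_world(
    n_proteins: int,
    coupling_fraction: float,
    seed: int,
    species: str = "spA",
    prefix: str = "P",
) -> PlantedWorld:
    """Create a world of ``n_proteins`` with a planted coupled-pair set.

    Exactly ``round(coupling_fraction * C(n, 2))`` unordered pairs are
    planted as functionally coupled, chosen uniformly at random.
    """
    if n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    if not 0.0 < coupling_fraction < 1.0:
        raise ValueError("coupling_fraction must be in (0, 1)")
    proteins = tuple(f"{prefix}{i:05d}" for i in range(n_proteins))
    pairs = tuple(combinations(proteins, 2))
    k = int(round(coupling_fraction * len(pairs)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=k, replace=False)
    coupled = frozenset(pairs[i] for i in idx)
    return PlantedWorld(
        species=species,
        proteins=proteins,
        true_couplings=coupled,
        coupling_fraction=coupling_fraction,
        seed=seed,
    )


def generate_evidence(
    world: PlantedWorld,
    pos_model=None,
    neg_model=None,
    coverage: float = 1.0,
    dataset_id: str = "sim0",
    evidence_type: str = "PIN",
    seed: Optional[int] = None,
) -> EvidenceScoreTable:
    """Draw raw evidence scores from the planted world.

    Coupled pairs draw from ``pos_model`` and uncoupled pairs from
    ``neg_model`` (frozen scipy distributions; defaults N(1,1) / N(0,1)).
    Each pair independently receives a score with probability ``coverage``
    (seeded Bernoulli thinning, the simplest reproducible model of an
    incomplete assay).
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    if pos_model is None:
        pos_model = stats.norm(1.0, 1.0)
    if neg_model is None:
        neg_model = stats.norm(0.0, 1.0)
    if seed is None:
        seed = _derive_seed(world.seed, f"evidence:{dataset_id}")
    rng = np.random.default_rng(seed)
    pairs = world.all_pairs()
    if coverage < 1.0:
        mask = rng.random(len(pairs)) < coverage
    else:
        mask = np.ones(len(pairs), dtype=bool)
    is_pos = np.fromiter(
        (p in world.true_couplings for p in pairs), dtype=bool, count=len(pairs)
    )
    scores = np.where(
        is_pos,
        pos_model.rvs(size=len(pairs), random_state=rng),
        neg_model.rvs(size=len(pairs), random_state=rng),
    )
    table = {
        pair: float(scores[i]) for i, pair in enumerate(pairs) if mask[i]
    }
    return EvidenceScoreTable(
        evidence_type=evidence_type,
        species=world.species,
        dataset_id=dataset_id,
        scores=table,
        directed=False,
    )


def generate_gold_standard(
    world: PlantedWorld,
    recall: float,
    fpr: float,
    name: str = "Complex",
    seed: int = 0,
) -> GoldStandard:
    """A noisy gold standard derived from the planted truth.

    Each true coupling is included with probability ``recall``; each
    non-coupled pair with probability ``fpr``.
    """
    if not 0.0 <= recall <= 1.0:
        raise ValueError("recall must be in [0, 1]")
    if not 0.0 <= fpr <= 1.0:
        raise ValueError("fpr must be in [0, 1]")
    rng = np.random.default_rng(seed)
    links = set()
    for pair in world.all_pairs():
        p = recall if pair in world.true_couplings else fpr
        if p > 0 and rng.random() < p:
            links.add(pair)
    return GoldStandard(name=name, links=links, directed=False)


def generate_ortholog_map(
    world_a: PlantedWorld,
    world_b: PlantedWorld,
    one_to_many_rate: float = 0.0,
    seed: int = 0,
    group_size: int = 3,
) -> OrthologMap:
    """Build an ortholog map between two worlds.

    Targets in ``world_b`` are matched to source proteins in ``world_a``;
    with probability ``one_to_many_rate`` a target receives a co-ortholog
    group of ``group_size`` source proteins (exercising the many-to-one
    score-averaging rule), otherwise a single ortholog.
    """
    if not world_a.proteins or not world_b.proteins:
        raise ValueError("both worlds must be non-empty")
    if not 0.0 <= one_to_many_rate <= 1.0:
        raise ValueError("one_to_many_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sources = list(world_a.proteins)
    targets = list(world_b.proteins)
    rng.shuffle(sources)
    rng.shuffle(targets)
    pairs: set = set()
    groups = {}
    gi = 0
    si = 0
    for tgt in targets:
        if si >= len(sources):
            break
        if one_to_many_rate > 0 and rng.random() < one_to_many_rate:
            take = min(group_size, len(sources) - si)
        else:
            take = 1
        members = sources[si : si + take]
        si += take
        for src in members:
            pairs.add((src, tgt))
        groups[f"g{gi:05d}"] = (frozenset(members), frozenset({tgt}))
        gi += 1
    return OrthologMap(
        species_pair=(world_a.species, world_b.species),
        pairs=pairs,
        groups=groups,
    )
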