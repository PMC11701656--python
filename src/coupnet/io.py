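"""Readers and writers for the pipeline's file formats.

Genomic coordinates are handled 0-based half-open throughout.  Project
tables are plain TSV with a ``#key=value`` metadata preamble and a header
line; every writer has a matching reader with round-trip identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import yaml

from .containers import (
    EvidenceScoreTable,
    GoldStandard,
    Link,
    Network,
    OrthologMap,
    Pair,
)


class FormatError(ValueError):
    """A file does not conform to its expected dialect."""


class ValidationError(ValueError):
    """A parsed value violates a semantic constraint."""


# ---------------------------------------------------------------------------
# narrowPeak (ENCODE BED6+4)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NarrowPeakRecord:
    """One ENCODE narrowPeak row (BED6+4), 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    signalValue: float
    pValue: float
    qValue: float
    peak: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"start must be < end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.signalValue < 0:
            raise ValidationError("signalValue must be >= 0")


def read_narrowpeak(path) -> List[NarrowPeakRecord]:
    """Parse a 10-column narrowPeak file; malformed rows name their line."""
    records: List[NarrowPeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}: line {lineno}: expected 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                records.append(
                    NarrowPeakRecord(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3],
                        score=int(fields[4]),
                        strand=fields[5],
                        signalValue=float(fields[6]),
                        pValue=float(fields[7]),
                        qValue=float(fields[8]),
                        peak=int(fields[9]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


@dataclass(frozen=True)
class GeneInterval:
    """A BED-like gene annotation interval (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."


def read_gene_bed(path) -> List[GeneInterval]:
    """Read gene intervals from a BED-like TSV: chrom start end gene [strand]."""
    genes: List[GeneInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 4 columns"
                )
            strand = fields[4] if len(fields) > 4 else "."
            genes.append(
                GeneInterval(
                    gene_id=fields[3],
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=strand,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# metadata-preamble TSV helpers
# ---------------------------------------------------------------------------


def _write_table(path, meta: Dict[str, str], header: List[str], rows) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _read_table(path) -> Tuple[Dict[str, str], List[str], List[List[str]]]:
    meta: Dict[str, str] = {}
    header: Optional[List[str]] = None
    rows: List[List[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k] = v
                continue
            if header is None:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    return meta, header or [], rows


# ---------------------------------------------------------------------------
# evidence tables
# ---------------------------------------------------------------------------


def write_evidence_table(table: EvidenceScoreTable, path) -> None:
    meta = {
        "evidence_type": table.evidence_type,
        "species": table.species,
        "dataset_id": table.dataset_id,
        "directed": str(bool(table.directed)).lower(),
    }
    rows = (
        (a, b, repr(s)) for (a, b), s in sorted(table.scores.items())
    )
    _write_table(path, meta, ["protein_a", "protein_b", "score"], rows)


def read_evidence_table(path) -> EvidenceScoreTable:
    meta, header, rows = _read_table(path)
    for key in ("evidence_type", "species", "dataset_id"):
        if key not in meta:
            raise FormatError(f"{path}: missing #{key}= metadata line")
    if header[:3] != ["protein_a", "protein_b", "score"]:
        raise FormatError(f"{path}: unexpected header {header}")
    scores = {}
    for row in rows:
        if len(row) < 3:
            raise FormatError(f"{path}: short row {row}")
        scores[(row[0], row[1])] = float(row[2])
    return EvidenceScoreTable(
        evidence_type=meta["evidence_type"],
        species=meta["species"],
        dataset_id=meta["dataset_id"],
        scores=scores,
        directed=meta.get("directed", "false") == "true",
    )


# ---------------------------------------------------------------------------
# gold standards
# ---------------------------------------------------------------------------


def write_gold_standard(gs: GoldStandard, path) -> None:
    meta = {"name": gs.name, "directed": str(bool(gs.directed)).lower()}
    rows = ((a, b) for a, b in sorted(gs.links))
    _write_table(path, meta, ["protein_a", "protein_b"], rows)


def read_gold_standard(path) -> GoldStandard:
    meta, header, rows = _read_table(path)
    if "name" not in meta:
        raise FormatError(f"{path}: missing #name= metadata line")
    links = set()
    for row in rows:
        if len(row) < 2:
            raise FormatError(f"{path}: short row {row}")
        links.add((row[0], row[1]))
    return GoldStandard(
        name=meta["name"],
        links=links,
        directed=meta.get("directed", "false") == "true",
    )


# ---------------------------------------------------------------------------
# ortholog tables
# ---------------------------------------------------------------------------


def write_ortholog_table(ortho: OrthologMap, path) -> None:
    meta = {
        "species_a": ortho.species_pair[0],
        "species_b": ortho.species_pair[1],
    }
    group_of: Dict[Pair, str] = {}
    for gid, (as_, bs) in ortho.groups.items():
        for a in as_:
            for b in bs:
                if (a, b) in ortho.pairs:
                    group_of[(a, b)] = gid
    rows = (
        (a, b, group_of.get((a, b), f"g-{a}-{b}"))
        for a, b in sorted(ortho.pairs)
    )
    _write_table(path, meta, ["protein_a", "protein_b", "group_id"], rows)


def read_ortholog_table(path) -> OrthologMap:
    meta, header, rows = _read_table(path)
    if len(header) < 3:
        raise FormatError(
            f"{path}: expected 3 columns (protein_a, protein_b, group_id), "
            f"got {len(header)}"
        )
    pairs: Set[Pair] = set()
    members: Dict[str, Tuple[Set[str], Set[str]]] = {}
    for row in rows:
        if len(row) < 3:
            raise FormatError(f"{path}: short row {row}")
        a, b, gid = row[0], row[1], row[2]
        pairs.add((a, b))  # duplicate rows deduplicated by the set
        side_a, side_b = members.setdefault(gid, (set(), set()))
        side_a.add(a)
        side_b.add(b)
    groups = {
        gid: (frozenset(sa), frozenset(sb)) for gid, (sa, sb) in members.items()
    }
    return OrthologMap(
        species_pair=(meta.get("species_a", "A"), meta.get("species_b", "B")),
        pairs=pairs,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

_NET_HEADER = [
    "protein_a",
    "protein_b",
    "ppv",
    "direction",
    "gold_standard",
    "fbs",
    "ppv_source",
    "grg_llr",
    "llrs",
]


def _fmt_llrs(llrs: Dict[str, float]) -> str:
    return ";".join(f"{k}:{v!r}" for k, v in sorted(llrs.items()))


def _parse_llrs(text: str) -> Dict[str, float]:
    if not text:
        return {}
    out = {}
    for item in text.split(";"):
        k, v = item.split(":", 1)
        out[k] = float(v)
    return out


def write_network(net: Network, path) -> None:
    rows = []
    for (a, b), link in sorted(net.links.items()):
        rows.append(
            (
                a,
                b,
                repr(link.ppv),
                link.direction,
                link.gold_standard,
                repr(link.fbs),
                link.ppv_source,
                "" if link.grg_llr is None else repr(link.grg_llr),
                _fmt_llrs(link.llrs),
            )
        )
    _write_table(path, {}, _NET_HEADER, rows)


def read_network(path) -> Network:
    meta, header, rows = _read_table(path)
    if header != _NET_HEADER:
        raise FormatError(f"{path}: unexpected network header {header}")
    net = Network()
    for row in rows:
        if len(row) != len(_NET_HEADER):
            # trailing empty fields may be stripped; pad
            row = row + [""] * (len(_NET_HEADER) - len(row))
        ppv = float(row[2])
        if not 0.0 <= ppv <= 1.0:
            raise ValidationError(f"{path}: PPV outside [0, 1]: {ppv}")
        fbs = float(row[5]) if row[5] else float("nan")
        grg = float(row[7]) if row[7] else None
        net.add(
            Link(
                a=row[0],
                b=row[1],
                ppv=ppv,
                direction=row[3],
                gold_standard=row[4],
                fbs=fbs,
                ppv_source=row[6],
                grg_llr=grg,
                llrs=_parse_llrs(row[8]),
            )
        )
    return net


# ---------------------------------------------------------------------------
# membership / experiment / regulatory inputs for gold-standard construction
# ---------------------------------------------------------------------------


def read_membership_table(path) -> List[Tuple[str, Set[str]]]:
    """Read (group id, protein) rows into ordered (id, member-set) records."""
    meta, header, rows = _read_table(path)
    order: List[str] = []
    members: Dict[str, Set[str]] = {}
    for row in rows:
        if len(row) < 2:
            raise FormatError(f"{path}: short row {row}")
        gid, prot = row[0], row[1]
        if gid not in members:
            members[gid] = set()
            order.append(gid)
        members[gid].add(prot)
    return [(gid, members[gid]) for gid in order]


def read_experiment_table(path) -> List[Tuple[str, str, Pair]]:
    """Read (experiment id, publication id, protein_a, protein_b) rows."""
    meta, header, rows = _read_table(path)
    out = []
    for row in rows:
        if len(row) < 4:
            raise FormatError(f"{path}: short row {row}")
        out.append((row[0], row[1], (row[2], row[3])))
    return out


def read_regulatory_pairs(path) -> List[Pair]:
    """Read directed (tf, target) rows."""
    meta, header, rows = _read_table(path)
    out = []
    for row in rows:
        if len(row) < 2:
            raise FormatError(f"{path}: short row {row}")
        out.append((row[0], row[1]))
    return out


def load_config(path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
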