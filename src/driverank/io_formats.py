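"""Readers and writers for the external file formats.

All readers normalize vocabularies and identifiers so downstream modules
see clean, deterministically ordered tables:

* mutation tables: MAF-dialect TSV with one row per somatic mutation;
* PPI networks: two-column edge lists ("#" comments allowed);
* gold standards: one gene symbol per line, or gene<TAB>disease pairs;
* rankings: ``rank<TAB>gene<TAB>score``.

Gene identifiers are treated as case-sensitive strings; no alias
resolution is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of mutation categories.
CATEGORIES = ("missense", "nonsense", "frameshift", "splice_site", "silent", "other")

#: Mapping from MAF ``Variant_Classification`` strings to the closed
#: category vocabulary.  Anything not listed maps to ``other``.
MAF_CLASSIFICATION_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "Splice_Site": "splice_site",
    "Silent": "silent",
}

DIALECTS = {"maf": MAF_CLASSIFICATION_MAP}

MANDATORY_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic mutation observed in one sample."""

    gene: str
    sample: str
    disease: str  # empty string in pan-cancer data
    category: str
    protein_position: Optional[int] = None
    polyphen2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.protein_position is not None and self.protein_position < 1:
            raise ValueError("protein_position must be >= 1")
        if self.polyphen2 is not None and not (0.0 <= self.polyphen2 <= 1.0):
            raise ValueError("polyphen2 must lie in [0, 1]")


@dataclass
class MutationTable:
    """Long-format mutation records plus the ordered gene universe.

    ``gene_universe`` is a lexicographically sorted superset of the genes
    appearing in ``records``; callers may extend it (e.g. with network
    genes) via :meth:`with_universe`.
    """

    records: list[MutationRecord]
    gene_universe: tuple[str, ...] = field(default=())
    warnings: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = {r.gene for r in self.records}
        universe = set(self.gene_universe) | seen
        self.gene_universe = tuple(sorted(universe))

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted({r.disease for r in self.records if r.disease}))

    def has_disease_labels(self) -> bool:
        return all(r.disease for r in self.records)

    def restrict_to_disease(self, disease: str) -> "MutationTable":
        known = self.diseases
        if disease not in known:
            raise ValueError(
                f"unknown disease {disease!r}; known labels: {', '.join(known) or '(none)'}"
            )
        recs = [r for r in self.records if r.disease == disease]
        return MutationTable(records=recs, gene_universe=self.gene_universe)

    def with_universe(self, extra: Iterable[str]) -> "MutationTable":
        return MutationTable(
            records=self.records,
            gene_universe=tuple(sorted(set(self.gene_universe) | set(extra))),
            warnings=dict(self.warnings),
        )


@dataclass
class PPINetwork:
    """Undirected PPI graph: ordered nodes, unordered edge set, degrees."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    warnings: dict[str, int] = field(default_factory=dict)

    @property
    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            for n in e:
                deg[n] += 1
        return deg

    def with_nodes(self, extra: Iterable[str]) -> "PPINetwork":
        """Return a copy extended with additional (isolated) nodes."""
        return PPINetwork(
            nodes=tuple(sorted(set(self.nodes) | set(extra))),
            edges=self.edges,
            warnings=dict(self.warnings),
        )

    def relabel(self, mapping: dict[str, str]) -> "PPINetwork":
        """Apply a node permutation; identity for nodes not in ``mapping``."""
        edges = frozenset(
            frozenset(mapping.get(u, u) for u in e) for e in self.edges
        )
        nodes = tuple(sorted(mapping.get(n, n) for n in self.nodes))
        return PPINetwork(nodes=nodes, edges=edges)


def _parse_position(raw: object, line_no: int) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text in ("", ".", "NA", "nan", "-"):
        return None
    try:
        pos = int(float(text))
    except ValueError as exc:
        raise FormatError(f"line {line_no}: unparseable protein position {text!r}") from exc
    if pos < 1:
        raise FormatError(f"line {line_no}: protein position {pos} < 1")
    return pos


def _parse_score(raw: object, line_no: int) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text in ("", ".", "NA", "nan", "-"):
        return None
    try:
        val = float(text)
    except ValueError as exc:
        raise FormatError(f"line {line_no}: unparseable PolyPhen2 score {text!r}") from exc
    if not (0.0 <= val <= 1.0):
        raise FormatError(f"line {line_no}: PolyPhen2 score {val} outside [0, 1]")
    return val


def read_mutation_table(path: str | Path, dialect: str = "maf") -> MutationTable:
    """Read a MAF-dialect mutation TSV into a :class:`MutationTable`.

    Raw variant-classification strings are mapped into the closed category
    vocabulary; unmapped strings become ``other`` and are tallied in
    ``table.warnings['unmapped_classification']``.  Row order is preserved
    in ``records``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    mapping = DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    has_disease = "Disease" in df.columns
    has_pos = "Protein_position" in df.columns
    has_pp2 = "PolyPhen2" in df.columns

    records: list[MutationRecord] = []
    unmapped = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        raw_class = getattr(row, "Variant_Classification")
        category = mapping.get(raw_class)
        if category is None:
            category = "other"
            unmapped += 1
        records.append(
            MutationRecord(
                gene=getattr(row, "Hugo_Symbol"),
                sample=getattr(row, "Tumor_Sample_Barcode"),
                disease=getattr(row, "Disease") if has_disease else "",
                category=category,
                protein_position=_parse_position(getattr(row, "Protein_position"), idx)
                if has_pos
                else None,
                polyphen2=_parse_score(getattr(row, "PolyPhen2"), idx) if has_pp2 else None,
            )
        )
    warnings = {}
    if unmapped:
        warnings["unmapped_classification"] = unmapped
        logger.warning("%s: %d rows with unmapped variant classification -> 'other'", path, unmapped)
    table = MutationTable(records=records)
    table.warnings = warnings
    return table


def write_mutation_table(path: str | Path, table: MutationTable) -> None:
    """Write a mutation table back to the MAF-dialect TSV (inverse of reading)."""
    inverse = {
        "missense": "Missense_Mutation",
        "nonsense": "Nonsense_Mutation",
        "frameshift": "Frame_Shift_Del",
        "splice_site": "Splice_Site",
        "silent": "Silent",
        "other": "Other",
    }
    rows = [
        {
            "Hugo_Symbol": r.gene,
            "Tumor_Sample_Barcode": r.sample,
            "Disease": r.disease,
            "Variant_Classification": inverse[r.category],
            "Protein_position": "" if r.protein_position is None else r.protein_position,
            "PolyPhen2": "" if r.polyphen2 is None else repr(r.polyphen2),
        }
        for r in table.records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Disease",
            "Variant_Classification",
            "Protein_position",
            "PolyPhen2",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_ppi_edgelist(path: str | Path) -> PPINetwork:
    """Read an undirected two-column edge list.

    Duplicate edges are collapsed; self-loops are dropped and counted in
    ``warnings['self_loops']``.  Node order is lexicographic.
    """
    edges: set[frozenset[str]] = set()
    nodes: set[str] = set()
    self_loops = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 2:
                raise FormatError(
                    f"{path}: line {line_no}: expected 2 tokens, got {len(tokens)}"
                )
            u, v = tokens
            if u == v:
                self_loops += 1
                nodes.add(u)
                continue
            nodes.update((u, v))
            edges.add(frozenset((u, v)))
    warnings = {}
    if self_loops:
        warnings["self_loops"] = self_loops
        logger.warning("%s: dropped %d self-loop(s)", path, self_loops)
    return PPINetwork(nodes=tuple(sorted(nodes)), edges=frozenset(edges), warnings=warnings)


def write_ppi_edgelist(path: str | Path, net: PPINetwork) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{u}\t{v}\n")


def read_gene_list(path: str | Path) -> tuple[str, ...]:
    """Read one gene symbol per line; duplicates collapsed with a warning."""
    genes: list[str] = []
    seen: set[str] = set()
    duplicates = 0
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if not g or g.startswith("#"):
                continue
            if g in seen:
                duplicates += 1
                continue
            seen.add(g)
            genes.append(g)
    if duplicates:
        logger.warning("%s: collapsed %d duplicate gene(s)", path, duplicates)
    return tuple(genes)


def write_gene_list(path: str | Path, genes: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


def read_pair_list(path: str | Path) -> list[tuple[str, str]]:
    """Read gene<TAB>disease pairs; the same gene may appear under several diseases."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split("\t")
            if len(tokens) != 2:
                raise FormatError(
                    f"{path}: line {line_no}: expected gene<TAB>disease, got {len(tokens)} fields"
                )
            pairs.append((tokens[0], tokens[1]))
    return pairs


def write_pair_list(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for g, d in pairs:
            fh.write(f"{g}\t{d}\n")


def write_ranking(path: str | Path, ranking) -> None:
    """Write ``rank<TAB>gene<TAB>score`` with a header; 12 significant digits."""
    with open(path, "w") as fh:
        fh.write("rank\tgene\tscore\n")
        for rank, item, s in zip(ranking.rank, ranking.items, ranking.scores):
            fh.write(f"{rank}\t{item}\t{s:.12g}\n")


def read_ranking(path: str | Path):
    """Read a ranking TSV written by :func:`write_ranking`."""
    from driverank.ocsvm import RankedGeneList

    df = pd.read_csv(path, sep="\t", dtype={"rank": int, "gene": str, "score": float})
    for col in ("rank", "gene", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return RankedGeneList.from_scores(dict(zip(df["gene"], df["score"])))
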