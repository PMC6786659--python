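"""Per-gene 3-dimensional feature vectors from somatic mutation tables.

Two modes:

* ``OG``  — (number of damaging missense mutations, total missense
  mutations, positional entropy of the missense mutations);
* ``TSG`` — (number of frameshift mutations, number of loss-of-function
  mutations = nonsense + frameshift, number of splice-site mutations).

"Damaging" missense means a PolyPhen2 score strictly greater than 0.447;
a missing score counts as non-damaging.  Positional entropy is the
Shannon entropy (natural log) of the empirical distribution of missense
mutations over distinct protein positions; mutations with missing
position are excluded from the entropy but still counted.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from driverank.io_formats import MutationTable

DAMAGING_THRESHOLD = 0.447

OG_FEATURE_NAMES = ("n_damaging_missense", "n_missense", "missense_position_entropy")
TSG_FEATURE_NAMES = ("n_frameshift", "n_LOF", "n_splice_site")


@dataclass
class GeneFeatureTable:
    """Per-gene feature matrix Phi for one driver-class mode."""

    mode: str  # "OG" or "TSG"
    genes: tuple[str, ...]
    phi: np.ndarray  # shape (n_genes, 3)
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("OG", "TSG"):
            raise ValueError(f"mode must be 'OG' or 'TSG', got {self.mode!r}")
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.genes), 3):
            raise ValueError("phi must have shape (n_genes, 3)")

    @property
    def feature_names(self) -> tuple[str, str, str]:
        return OG_FEATURE_NAMES if self.mode == "OG" else TSG_FEATURE_NAMES

    def row(self, gene: str) -> np.ndarray:
        return self.phi[self.genes.index(gene)]

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.phi, index=list(self.genes), columns=list(self.feature_names)).to_csv(
            path, sep="\t", index_label="gene"
        )


def positional_entropy(positions: Iterable[Optional[int]]) -> float:
    """Shannon entropy (natural log) of the empirical position distribution.

    Missing positions (``None``) are dropped; an empty or single-support
    multiset has entropy 0.
    """
    counts = Counter(p for p in positions if p is not None)
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def _maybe_restrict(table: MutationTable, disease: Optional[str]) -> MutationTable:
    if disease is None:
        return table
    return table.restrict_to_disease(disease)


def og_features(table: MutationTable, restrict_to_disease: Optional[str] = None) -> GeneFeatureTable:
    """Oncogene-mode features for every gene in the table's universe."""
    sub = _maybe_restrict(table, restrict_to_disease)
    damaging: Counter[str] = Counter()
    missense: Counter[str] = Counter()
    positions: dict[str, list[Optional[int]]] = {}
    for r in sub.records:
        if r.category != "missense":
            continue
        missense[r.gene] += 1
        if r.polyphen2 is not None and r.polyphen2 > DAMAGING_THRESHOLD:
            damaging[r.gene] += 1
        positions.setdefault(r.gene, []).append(r.protein_position)
    genes = sub.gene_universe
    phi = np.zeros((len(genes), 3))
    for i, g in enumerate(genes):
        phi[i] = (
            damaging.get(g, 0),
            missense.get(g, 0),
            positional_entropy(positions.get(g, ())),
        )
    return GeneFeatureTable(mode="OG", genes=genes, phi=phi)


def tsg_features(table: MutationTable, restrict_to_disease: Optional[str] = None) -> GeneFeatureTable:
    """Tumor-suppressor-mode features for every gene in the table's universe."""
    sub = _maybe_restrict(table, restrict_to_disease)
    counts: dict[str, Counter[str]] = {}
    for r in sub.records:
        counts.setdefault(r.gene, Counter())[r.category] += 1
    genes = sub.gene_universe
    phi = np.zeros((len(genes), 3))
    for i, g in enumerate(genes):
        c = counts.get(g, Counter())
        n_frameshift = c["frameshift"]
        n_lof = c["nonsense"] + c["frameshift"]
        phi[i] = (n_frameshift, n_lof, c["splice_site"])
    return GeneFeatureTable(mode="TSG", genes=genes, phi=phi)
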