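"""Disease descriptors, disease kernels, and the gene-disease pair kernel.

Cancer types are described by 43-dimensional binary vectors: 12 bits for
tumor-type characteristics and 31 bits for anatomical localizations.
Four disease kernels are available — uniform, Dirac, their average
(the standard multitask kernel), and a descriptor-based kernel — and
combine with any gene kernel through the product pair kernel
``K_pair((g,d),(g',d')) = K_gene(g,g') * K_disease(d,d')``.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from driverank.kernels import KernelMatrix

TYPE_VOCABULARY = (
    "adenocarcinoma",
    "adenoma",
    "blastoma",
    "carcinoma",
    "glioma",
    "leukemia",
    "lymphoma",
    "medulloblastoma",
    "melanoma",
    "myeloma",
    "rhabdomyosarcoma",
    "sarcoma",
)

LOCALIZATION_VOCABULARY = (
    "adrenal glands",
    "astrocytes",
    "B-cell",
    "bladder",
    "bone",
    "breast",
    "cervix",
    "central nervous system",
    "colon",
    "ducts",
    "endometrium",
    "eye",
    "head and neck",
    "heart",
    "kidney",
    "liver",
    "lung",
    "lymphocytes",
    "mucosa",
    "muscle",
    "nerve",
    "oesophagus",
    "ovary",
    "pancreas",
    "prostate",
    "salivary glands",
    "skin",
    "soft tissue",
    "stomach",
    "T-cell",
    "thyroid",
)

DESCRIPTOR_LENGTH = len(TYPE_VOCABULARY) + len(LOCALIZATION_VOCABULARY)

DiseaseKernel = Callable[[str, str], float]


@dataclass(frozen=True)
class DiseaseDescriptor:
    """Binary descriptor Psi(d) of one cancer type."""

    disease: str
    psi: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.psi) != DESCRIPTOR_LENGTH:
            raise ValueError(f"descriptor must have length {DESCRIPTOR_LENGTH}, got {len(self.psi)}")
        if any(b not in (0, 1) for b in self.psi):
            raise ValueError("descriptor entries must be 0 or 1")
        if sum(self.psi) == 0:
            raise ValueError("descriptor must have at least one nonzero entry")

    def as_array(self) -> np.ndarray:
        return np.array(self.psi, dtype=float)


@dataclass(frozen=True)
class GeneDiseasePair:
    gene: str
    disease: str


def _resolve(name: str, vocabulary: Sequence[str], block: str) -> int:
    lowered = {v.lower(): i for i, v in enumerate(vocabulary)}
    key = name.strip().lower()
    if key not in lowered:
        close = difflib.get_close_matches(key, lowered, n=3)
        hint = f"; closest: {', '.join(close)}" if close else ""
        raise ValueError(f"unknown {block} characteristic {name!r}{hint}")
    return lowered[key]


def build_descriptor(
    disease: str, types: Iterable[str], localizations: Iterable[str]
) -> DiseaseDescriptor:
    """Build Psi(d) with bits set exactly for the named characteristics.

    Names are matched case-insensitively against the fixed vocabularies;
    an unknown name raises with the closest vocabulary entries.
    """
    psi = [0] * DESCRIPTOR_LENGTH
    for t in types:
        psi[_resolve(t, TYPE_VOCABULARY, "tumor-type")] = 1
    offset = len(TYPE_VOCABULARY)
    for loc in localizations:
        psi[offset + _resolve(loc, LOCALIZATION_VOCABULARY, "localization")] = 1
    return DiseaseDescriptor(disease=disease, psi=tuple(psi))


def uniform_kernel(d: str, d2: str) -> float:
    return 1.0


def dirac_kernel(d: str, d2: str) -> float:
    return 1.0 if d == d2 else 0.0


def multitask_kernel(d: str, d2: str) -> float:
    """(K_uniform + K_Dirac) / 2: 1 on the diagonal, 1/2 off it."""
    return (uniform_kernel(d, d2) + dirac_kernel(d, d2)) / 2.0


def cancer_kernel(descriptors: Mapping[str, DiseaseDescriptor]) -> DiseaseKernel:
    """Descriptor kernel (Psi(d)^T Psi(d') + K_uniform + K_Dirac) / 3."""

    def k(d: str, d2: str) -> float:
        for name in (d, d2):
            if name not in descriptors:
                raise ValueError(f"no descriptor for disease {name!r}")
        dot = float(descriptors[d].as_array() @ descriptors[d2].as_array())
        return (dot + uniform_kernel(d, d2) + dirac_kernel(d, d2)) / 3.0

    return k


def disease_kernel_matrix(k: DiseaseKernel, diseases: Sequence[str]) -> KernelMatrix:
    """Materialize a disease-kernel function over a finite disease set."""
    n = len(diseases)
    M = np.empty((n, n))
    for i, a in enumerate(diseases):
        for j, b in enumerate(diseases):
            M[i, j] = k(a, b)
    return KernelMatrix(tuple(diseases), (M + M.T) / 2.0)


def _pair_label(p: GeneDiseasePair) -> str:
    return f"{p.gene}|{p.disease}"


def pair_kernel(
    K_gene: KernelMatrix,
    K_disease: DiseaseKernel,
    pairs_row: Sequence[GeneDiseasePair],
    pairs_col: Sequence[GeneDiseasePair] | None = None,
) -> KernelMatrix | np.ndarray:
    """Product kernel over (gene, disease) pairs.

    With ``pairs_col`` omitted, returns the square :class:`KernelMatrix`
    over ``pairs_row`` (items labeled ``gene|disease``); otherwise
    returns the rectangular cross block as an array.
    """
    square = pairs_col is None
    cols = pairs_row if square else pairs_col
    for p in list(pairs_row) + list(cols):
        if p.gene not in K_gene._index:
            raise ValueError(f"gene {p.gene!r} not in the gene kernel")
    G = K_gene.rows([p.gene for p in pairs_row], [p.gene for p in cols])
    diseases = sorted({p.disease for p in pairs_row} | {p.disease for p in cols})
    idx = {d: i for i, d in enumerate(diseases)}
    Kd = np.array([[K_disease(a, b) for b in diseases] for a in diseases])
    ri = np.array([idx[p.disease] for p in pairs_row])
    ci = np.array([idx[p.disease] for p in cols])
    M = G * Kd[np.ix_(ri, ci)]
    if square:
        labels = tuple(_pair_label(p) for p in pairs_row)
        if len(set(labels)) != len(labels):  # duplicated training pairs are legal
            labels = tuple(f"{lab}#{i}" for i, lab in enumerate(labels))
        return KernelMatrix(labels, (M + M.T) / 2.0)
    return M


def read_descriptor_csv(path: str | Path) -> dict[str, DiseaseDescriptor]:
    """Read a descriptor table: column ``disease`` then the 43 binary columns.

    Column names must match the fixed vocabulary (case-insensitive); the
    12 type columns come first, then the 31 localization columns.
    """
    df = pd.read_csv(path)
    if "disease" not in df.columns:
        raise ValueError(f"{path}: missing 'disease' column")
    expected = [v.lower() for v in TYPE_VOCABULARY + LOCALIZATION_VOCABULARY]
    got = [c.lower() for c in df.columns if c != "disease"]
    if got != expected:
        missing = set(expected) - set(got)
        surplus = set(got) - set(expected)
        raise ValueError(
            f"{path}: descriptor columns do not match the fixed vocabulary"
            f" (missing: {sorted(missing)}; unexpected: {sorted(surplus)})"
        )
    out: dict[str, DiseaseDescriptor] = {}
    value_cols = [c for c in df.columns if c != "disease"]
    for _, row in df.iterrows():
        bits = tuple(int(row[c]) for c in value_cols)
        out[str(row["disease"])] = DiseaseDescriptor(disease=str(row["disease"]), psi=bits)
    return out


def write_descriptor_csv(path: str | Path, descriptors: Mapping[str, DiseaseDescriptor]) -> None:
    cols = list(TYPE_VOCABULARY + LOCALIZATION_VOCABULARY)
    rows = [
        {"disease": d, **dict(zip(cols, desc.psi))} for d, desc in sorted(descriptors.items())
    ]
    pd.DataFrame(rows, columns=["disease"] + cols).to_csv(path, index=False)
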