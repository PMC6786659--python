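"""Seeded generator of synthetic mutation tables, PPI networks, and
multi-disease driver structure.

Planted TSG drivers carry elevated frameshift/nonsense/splice-site
rates; planted OG drivers carry elevated, damaging, positionally
concentrated missense rates.  The network is a preferential-attachment
graph with extra edges among drivers of each class, so that both the
mutation kernel and the diffusion kernel carry a recoverable signal
whose strength is controlled by ``driver_effect`` and ``module_boost``.

For multi-disease configurations, diseases sit on a ring: every disease
carries a block of globally shared drivers plus its own specific ones,
each disease's drivers form their own network module, ring-adjacent
diseases' modules are cross-linked, and disease descriptors encode
overlapping localization windows — so descriptor similarity mirrors the
network relatedness of diseases, the structure the descriptor-based
multitask variant exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from driverank.io_formats import MutationRecord, MutationTable, PPINetwork
from driverank.multitask import (
    DiseaseDescriptor,
    LOCALIZATION_VOCABULARY,
    TYPE_VOCABULARY,
    build_descriptor,
)
from driverank.ocsvm import RankedGeneList

CATEGORY_WEIGHTS = {
    "missense": 0.60,
    "silent": 0.20,
    "nonsense": 0.06,
    "frameshift": 0.06,
    "splice_site": 0.04,
    "other": 0.04,
}

TSG_CATEGORIES = ("frameshift", "nonsense", "splice_site")

GENE_LENGTH = 500  # protein positions available per gene
ADJACENT_MODULE_FACTOR = 0.75  # edge rate between adjacent diseases' modules,
# relative to module_boost
NEIGHBOR_SHARE_PROB = 0.3  # chance a specific driver is also planted in the
# next disease on the ring


@dataclass
class SyntheticConfig:
    n_genes: int = 200
    n_samples: int = 60
    n_drivers: int = 15  # per driver class (OG and TSG)
    driver_effect: float = 8.0
    background_rate: float = 0.025  # expected mutations per gene per sample
    gene_length_dispersion: float = 0.5
    ppi_attachment: int = 2  # preferential-attachment edges per new node
    module_boost: float = 0.35  # extra edge probability among same-class module drivers
    module_fraction: float = 0.6  # fraction of drivers that join the network module
    n_diseases: int = 1
    shared_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 4:
            raise ValueError("n_genes must be at least 4")
        if not (0 < self.n_drivers and 2 * self.n_drivers < self.n_genes):
            raise ValueError("need 2 * n_drivers < n_genes")
        if self.driver_effect < 1:
            raise ValueError("driver_effect must be >= 1")
        if not (0 < self.background_rate < 10):
            raise ValueError("background_rate out of range")
        if not (0 <= self.module_boost <= 1):
            raise ValueError("module_boost must be in [0, 1]")
        if not (0 <= self.module_fraction <= 1):
            raise ValueError("module_fraction must be in [0, 1]")
        if not (0 <= self.shared_fraction <= 1):
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.n_diseases < 1:
            raise ValueError("n_diseases must be >= 1")
        if self.ppi_attachment < 1 or self.ppi_attachment >= self.n_genes:
            raise ValueError("ppi_attachment out of range")


@dataclass
class SyntheticTruth:
    """Planted driver sets, per class and per disease."""

    og: dict[str, tuple[str, ...]]  # disease -> OG drivers
    tsg: dict[str, tuple[str, ...]]
    diseases: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.diseases:
            self.diseases = tuple(sorted(self.og))

    def all_og(self) -> tuple[str, ...]:
        return tuple(sorted({g for genes in self.og.values() for g in genes}))

    def all_tsg(self) -> tuple[str, ...]:
        return tuple(sorted({g for genes in self.tsg.values() for g in genes}))


def _assign_drivers(
    drivers: Sequence[str],
    diseases: Sequence[str],
    shared_fraction: float,
    rng: np.random.Generator,
) -> dict[str, tuple[str, ...]]:
    """Split drivers into a block shared by all diseases plus round-robin
    disease-specific blocks; a specific driver may also be planted in the
    ring-adjacent disease, so adjacent diseases overlap more."""
    n_shared = int(round(shared_fraction * len(drivers)))
    shared = list(drivers[:n_shared])
    specific = list(drivers[n_shared:])
    assignment: dict[str, list[str]] = {d: list(shared) for d in diseases}
    for i, g in enumerate(specific):
        home = i % len(diseases)
        assignment[diseases[home]].append(g)
        if len(diseases) > 1 and rng.random() < NEIGHBOR_SHARE_PROB:
            assignment[diseases[(home + 1) % len(diseases)]].append(g)
    return {d: tuple(sorted(set(genes))) for d, genes in assignment.items()}


def _make_descriptors(diseases: Sequence[str]) -> dict[str, DiseaseDescriptor]:
    """Overlapping localization windows: adjacent diseases share two bits.

    Diseases sit on a ring; windows of four localization bits advance by
    two per disease (modulo the ring circumference), so descriptor inner
    products are 2 for ring-adjacent diseases and 0 for distant ones —
    mirroring which diseases share planted drivers.
    """
    out: dict[str, DiseaseDescriptor] = {}
    n_loc = len(LOCALIZATION_VOCABULARY)
    ring = min(n_loc, 2 * len(diseases))
    for j, d in enumerate(diseases):
        dtype = TYPE_VOCABULARY[j % len(TYPE_VOCABULARY)]
        locs = {LOCALIZATION_VOCABULARY[(2 * j + k) % ring] for k in range(4)}
        out[d] = build_descriptor(d, types=[dtype], localizations=locs)
    return out


def disease_benchmark_config(seed: int = 7) -> SyntheticConfig:
    """Canonical 6-disease benchmark: 3 drivers shared by all diseases plus
    3 specific ones per disease and class, with per-disease network modules."""
    return SyntheticConfig(
        n_diseases=6,
        n_drivers=21,
        shared_fraction=1 / 7,
        n_samples=120,
        background_rate=0.02,
        module_boost=0.4,
        module_fraction=0.7,
        seed=seed,
    )


def generate(
    cfg: SyntheticConfig,
) -> tuple[MutationTable, PPINetwork, SyntheticTruth, dict[str, DiseaseDescriptor]]:
    """Generate one synthetic dataset; fully determined by ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_genes))
    genes = tuple(f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1))
    diseases = tuple(f"D{j + 1}" for j in range(cfg.n_diseases))

    # planted drivers: disjoint OG and TSG sets
    perm = rng.permutation(cfg.n_genes)
    og_drivers = tuple(genes[i] for i in perm[: cfg.n_drivers])
    tsg_drivers = tuple(genes[i] for i in perm[cfg.n_drivers : 2 * cfg.n_drivers])
    truth = SyntheticTruth(
        og=_assign_drivers(og_drivers, diseases, cfg.shared_fraction, rng),
        tsg=_assign_drivers(tsg_drivers, diseases, cfg.shared_fraction, rng),
        diseases=diseases,
    )
    og_by_disease = {d: set(v) for d, v in truth.og.items()}
    tsg_by_disease = {d: set(v) for d, v in truth.tsg.items()}

    # per-gene rate multipliers (gene length / mutability heterogeneity)
    multiplier = rng.lognormal(mean=0.0, sigma=cfg.gene_length_dispersion, size=cfg.n_genes)
    hotspots = {g: rng.choice(GENE_LENGTH, size=2, replace=False) + 1 for g in og_drivers}

    # samples round-robin across diseases
    sample_disease = [diseases[s % cfg.n_diseases] for s in range(cfg.n_samples)]
    records: list[MutationRecord] = []
    categories = tuple(CATEGORY_WEIGHTS)
    weights = np.array([CATEGORY_WEIGHTS[c] for c in categories])
    for s in range(cfg.n_samples):
        d = sample_disease[s]
        sample_id = f"S{s + 1:04d}"
        for gi, g in enumerate(genes):
            base = cfg.background_rate * multiplier[gi]
            rates = base * weights
            is_og = g in og_by_disease[d]
            is_tsg = g in tsg_by_disease[d]
            for ci, c in enumerate(categories):
                rate = rates[ci]
                if is_tsg and c in TSG_CATEGORIES:
                    rate *= cfg.driver_effect
                elif is_og and c == "missense":
                    rate *= cfg.driver_effect
                count = rng.poisson(rate)
                for _ in range(count):
                    pos = None
                    pp2 = None
                    if c == "missense":
                        if is_og:
                            pos = int(rng.choice(hotspots[g]))
                            pp2 = float(rng.beta(8.0, 2.0))
                        else:
                            pos = int(rng.integers(1, GENE_LENGTH + 1))
                            pp2 = float(rng.uniform(0.0, 1.0))
                    records.append(
                        MutationRecord(
                            gene=g,
                            sample=sample_id,
                            disease=d,
                            category=c,
                            protein_position=pos,
                            polyphen2=pp2,
                        )
                    )
    table = MutationTable(records=records, gene_universe=genes)

    # preferential-attachment network over all genes, with driver modules
    ba = nx.barabasi_albert_graph(cfg.n_genes, cfg.ppi_attachment, seed=int(rng.integers(2**31)))
    node_to_gene = {i: genes[j] for i, j in enumerate(rng.permutation(cfg.n_genes))}
    edges = {frozenset((node_to_gene[u], node_to_gene[v])) for u, v in ba.edges()}
    # one module per driver class and disease: drivers of the same disease
    # are preferentially interconnected, shared drivers bridge modules, and
    # ring-adjacent diseases' modules are linked at a reduced rate so that
    # network similarity mirrors disease similarity
    for assignment in (truth.og, truth.tsg):
        participants = {g for cluster in assignment.values() for g in cluster}
        n_module = int(round(cfg.module_fraction * len(participants)))
        ordered = sorted(participants)
        module_members = {ordered[i] for i in rng.permutation(len(ordered))[:n_module]}
        members_of = {
            d: [g for g in assignment[d] if g in module_members] for d in diseases
        }
        for d in diseases:
            members = members_of[d]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if rng.random() < cfg.module_boost:
                        edges.add(frozenset((members[i], members[j])))
        if len(diseases) > 1:
            cross_rate = cfg.module_boost * ADJACENT_MODULE_FACTOR
            for jd, d in enumerate(diseases):
                nxt = diseases[(jd + 1) % len(diseases)]
                for u in members_of[d]:
                    for v in members_of[nxt]:
                        if u != v and rng.random() < cross_rate:
                            edges.add(frozenset((u, v)))
    net = PPINetwork(nodes=genes, edges=frozenset(edges))

    descriptors = _make_descriptors(diseases)
    return table, net, truth, descriptors


def truth_report(
    truth_genes: Iterable[str], ranking: RankedGeneList, top_k: int
) -> dict[str, float]:
    """Count planted drivers among the top-k ranked genes."""
    planted = set(truth_genes)
    top = set(ranking.top(top_k))
    recovered = len(planted & top)
    return {
        "top_k": top_k,
        "n_planted": len(planted),
        "recovered": recovered,
        "fraction": recovered / len(planted) if planted else float("nan"),
    }
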