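"""Gene-set interaction enrichment against an undirected network.

Quantifies how interconnected a candidate risk-gene set is within a genetic
interaction network (an exported edge list), relative to random gene sets of
the same size drawn from a gene universe.  The statistic is *links per gene*:
by default the mean within-set degree, ``2 * E_internal / |set|``, where
``E_internal`` counts edges with both endpoints inside the set; an
edges-per-gene mode (``E_internal / |set|``) is provided for sensitivity.

Significance is assessed the way small permutation baselines are used in
practice: the mean and SD of the statistic over k random lists give
normal-theory upper confidence bounds (one-sided, z = 1.960 for p < 0.05 and
z = 2.576 for p < 0.01); the observed set is flagged significant when it
exceeds the bound.  With the default k = 4 lists this is an approximation —
see the calibration notes in the docs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeneSet",
    "BaselineStats",
    "EnrichmentResult",
    "Z_95",
    "Z_99",
    "normalize_edges",
    "links_per_gene",
    "sample_random_sets",
    "baseline_and_test",
    "enrichment_analysis",
]

Z_95 = 1.960
Z_99 = 2.576


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of unique gene symbols."""

    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class BaselineStats:
    """Links-per-gene of k random lists with normal-theory upper CI bounds."""

    values: tuple[float, ...]
    mean: float
    sd: float
    ci95_upper: float
    ci99_upper: float

    @property
    def n_lists(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float
    baseline: BaselineStats
    significant_05: bool
    significant_01: bool


def normalize_edges(pairs) -> frozenset[tuple[str, str]]:
    """Canonicalize an undirected edge list.

    Orders each pair lexicographically, collapses duplicates (A-B and B-A are
    one edge) and drops self-loops.
    """
    edges = set()
    for a, b in pairs:
        if a == b:
            continue
        edges.add((a, b) if a <= b else (b, a))
    return frozenset(edges)


def links_per_gene(gene_set: GeneSet, edges, mode: str = "degree") -> float:
    """Within-set connectivity of `gene_set` in the network `edges`.

    ``mode="degree"`` (default) returns the mean within-set degree
    ``2 * E_internal / |set|``; ``mode="edges"`` returns
    ``E_internal / |set|``.
    """
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    if mode not in ("degree", "edges"):
        raise ValueError(f"mode must be 'degree' or 'edges', got {mode!r}")
    members = gene_set.genes
    internal = sum(1 for a, b in edges if a in members and b in members)
    factor = 2.0 if mode == "degree" else 1.0
    return factor * internal / len(gene_set)


def sample_random_sets(
    universe: GeneSet,
    size: int,
    k: int,
    seed,
    disjoint: bool = True,
) -> list[GeneSet]:
    """Draw k random gene sets of `size` from `universe`, disjoint by default.

    Mutually disjoint sampling mirrors drawing non-overlapping random lists;
    ``disjoint=False`` draws each list independently (without replacement
    within a list).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(universe.genes))
    if size < 1 or k < 1:
        raise ValueError("size and k must be >= 1")
    if disjoint:
        if k * size > len(genes):
            raise ValueError(
                f"universe of {len(genes)} cannot supply {k} disjoint sets of {size}"
            )
        perm = rng.permutation(genes)
        return [
            GeneSet(label=f"random_{i + 1}",
                    genes=frozenset(perm[i * size:(i + 1) * size]))
            for i in range(k)
        ]
    if size > len(genes):
        raise ValueError(f"universe of {len(genes)} cannot supply a set of {size}")
    return [
        GeneSet(label=f"random_{i + 1}",
                genes=frozenset(rng.choice(genes, size=size, replace=False)))
        for i in range(k)
    ]


def baseline_and_test(observed: float, random_values) -> EnrichmentResult:
    """Compare an observed links-per-gene value against random-list values.

    Upper bounds are ``mean + z * sd`` with the one-sided z for p < 0.05 and
    p < 0.01; a significance flag is set when the observed value strictly
    exceeds the bound.
    """
    values = tuple(float(v) for v in random_values)
    if len(values) < 2:
        raise ValueError("need at least 2 random-list values for a baseline")
    arr = np.asarray(values)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    baseline = BaselineStats(
        values=values, mean=mean, sd=sd,
        ci95_upper=mean + Z_95 * sd, ci99_upper=mean + Z_99 * sd,
    )
    return EnrichmentResult(
        observed=float(observed),
        baseline=baseline,
        significant_05=observed > baseline.ci95_upper,
        significant_01=observed > baseline.ci99_upper,
    )


def enrichment_analysis(
    gene_set: GeneSet,
    edges,
    universe: GeneSet,
    k: int = 4,
    seed=0,
    mode: str = "degree",
    disjoint: bool = True,
) -> EnrichmentResult:
    """End-to-end enrichment test of `gene_set` against `k` random lists."""
    missing = gene_set.genes - universe.genes
    if missing:
        raise ValueError(
            f"{len(missing)} genes of {gene_set.label!r} absent from the universe "
            f"(e.g. {sorted(missing)[:3]})"
        )
    observed = links_per_gene(gene_set, edges, mode=mode)
    randoms = sample_random_sets(universe, size=len(gene_set), k=k, seed=seed,
                                 disjoint=disjoint)
    values = [links_per_gene(s, edges, mode=mode) for s in randoms]
    return baseline_and_test(observed, values)
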