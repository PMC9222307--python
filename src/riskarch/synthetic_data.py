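"""Synthetic inputs: GWAS-like variant tables, interaction networks, populations.

Three generators, all bit-reproducible for a fixed seed:

* :func:`gen_variant_table` emulates the structure of a published
  schizophrenia GWAS hit list — 128 variants of which 14 are indels, risk
  allele frequencies with mean 0.44 and SD 0.26, log odds ratios centred on
  zero with a balanced case/control direction split, and optionally planted
  RAF-OR correlations within the extreme effect-size quartiles.
* :func:`gen_interaction_network` builds an Erdős–Rényi genetic-interaction
  network with an optionally densified (planted) module, for calibrating and
  power-testing the links-per-gene enrichment test.
* :func:`simulate_population` draws individual genomes locus by locus and
  multiplies their functional outputs — an independent Monte-Carlo oracle for
  the closed-form combined probability.

None of these simulate linkage disequilibrium, genomic coordinates or
realistic GWAS noise; they reproduce stated moments and counts only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .allele_stats import quartile_partition
from .core_model import ArchitectureSpec
from .interaction_enrichment import GeneSet, normalize_edges

__all__ = [
    "VariantTableParams",
    "PopulationSimParams",
    "beta_shapes",
    "gen_variant_table",
    "gen_interaction_network",
    "simulate_population",
    "analytic_mean",
]

#: ln(OR) dispersion giving a mean adjusted OR of ~1.086 under
#: ln(OR) ~ N(0, sigma): solves 2*exp(s^2/2)*Phi(s) = 1.086.
DEFAULT_OR_LOG_SD = 0.10103

#: Default RAF moments: mean 0.44, SD 0.26.
DEFAULT_RAF_MEAN = 0.44
DEFAULT_RAF_SD = 0.26


def beta_shapes(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) shape parameters matching a target mean and SD."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean!r}")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(f"sd {sd!r} too large for a Beta with mean {mean!r}")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class VariantTableParams:
    """Parameters of the GWAS-like variant-table generator."""

    n_variants: int = 128
    indel_fraction: float = 14 / 128
    raf_mean: float = DEFAULT_RAF_MEAN
    raf_sd: float = DEFAULT_RAF_SD
    or_log_sd: float = DEFAULT_OR_LOG_SD
    direction_balance: float = 0.5
    #: Optional (r_lowest, r_highest): Pearson correlation between RAF and
    #: adjusted OR planted inside the lowest/highest adjusted-OR quartiles.
    quartile_correlations: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 4:
            raise ValueError("n_variants must be >= 4")
        for name in ("indel_fraction", "direction_balance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.or_log_sd < 0:
            raise ValueError("or_log_sd must be >= 0")
        if self.quartile_correlations is not None:
            for r in self.quartile_correlations:
                if not -1.0 <= r <= 1.0:
                    raise ValueError("planted correlations must be in [-1, 1]")


def _plant_correlation(rng, or_adj: np.ndarray, r: float, a: float, b: float) -> np.ndarray:
    """RAF draws correlated with or_adj at Pearson r via a Gaussian copula."""
    m = len(or_adj)
    ranks = stats.rankdata(or_adj, method="ordinal")
    z_or = stats.norm.ppf((ranks - 0.5) / m)
    z = r * z_or + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(m)
    return stats.beta.ppf(stats.norm.cdf(z), a, b)


def gen_variant_table(params: VariantTableParams = VariantTableParams()) -> pd.DataFrame:
    """Generate a variant table with the configured composition and moments.

    Indel count is ``round(n * indel_fraction)`` exactly; the case-enriched
    count is ``round(n * direction_balance)`` exactly (rows with or_raw == 1,
    possible only at or_log_sd = 0, carry no direction).  Realized mean RAF
    approaches ``raf_mean`` as n grows; planted quartile correlations are
    realized in sign.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_variants
    ids = np.array([f"rs{i:06d}" for i in range(1, n + 1)])

    types = np.full(n, "SNP", dtype=object)
    n_indel = int(round(n * p.indel_fraction))
    types[rng.choice(n, size=n_indel, replace=False)] = "indel"

    log_or_mag = np.abs(rng.standard_normal(n)) * p.or_log_sd
    # balance directions within SNPs and indels separately, so the
    # post-indel-filter split is exact (114 SNPs at 0.5 -> 57/57)
    signs = np.full(n, -1.0)
    for vtype in ("SNP", "indel"):
        idx = np.flatnonzero(types == vtype)
        n_case = int(round(len(idx) * p.direction_balance))
        signs[rng.permutation(idx)[:n_case]] = 1.0
    or_raw = np.exp(signs * log_or_mag)
    or_adj = np.exp(log_or_mag)

    a, b = beta_shapes(p.raf_mean, p.raf_sd)
    raf = stats.beta.rvs(a, b, size=n, random_state=rng)
    table = pd.DataFrame(
        {"id": ids, "variant_type": types, "raf": raf, "or_raw": or_raw}
    )

    if p.quartile_correlations is not None:
        quart = quartile_partition(table.assign(or_adjusted=or_adj), key="or_adjusted")
        for q, r in ((1, p.quartile_correlations[0]), (4, p.quartile_correlations[1])):
            mask = (quart == q).to_numpy()
            table.loc[mask, "raf"] = _plant_correlation(rng, or_adj[mask], r, a, b)
    return table


def gen_interaction_network(
    n_genes: int,
    edge_prob: float,
    planted_set_size: int = 0,
    enrichment_factor: float = 1.0,
    seed: int = 0,
) -> tuple[GeneSet, frozenset, GeneSet]:
    """Erdős–Rényi gene network with an optionally densified planted module.

    Background pairs carry an edge with probability ``edge_prob``; pairs with
    both genes in the planted set carry one with probability
    ``edge_prob * enrichment_factor`` (extra edges are added on top of the
    background so the marginal is exact).  Returns (universe, edges, planted).
    """
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError(f"edge_prob must be in [0, 1], got {edge_prob!r}")
    p_in = edge_prob * enrichment_factor
    if p_in > 1.0:
        raise ValueError(
            f"edge_prob * enrichment_factor = {p_in!r} exceeds 1"
        )
    if planted_set_size > n_genes:
        raise ValueError("planted_set_size cannot exceed n_genes")

    names = np.array([f"G{i:05d}" for i in range(n_genes)])
    ss = np.random.SeedSequence(seed)
    seed_bg, seed_extra, seed_pick = (int(s) for s in ss.generate_state(3) >> 1)

    graph = nx.fast_gnp_random_graph(n_genes, edge_prob, seed=seed_bg)
    planted_idx = np.sort(
        np.random.default_rng(seed_pick).choice(n_genes, size=planted_set_size,
                                                replace=False)
    )
    if planted_set_size >= 2 and p_in > edge_prob:
        # union probability: 1 - (1-p)(1-p_extra) = p_in
        p_extra = (p_in - edge_prob) / (1.0 - edge_prob)
        extra = nx.fast_gnp_random_graph(planted_set_size, p_extra, seed=seed_extra)
        graph.add_edges_from(
            (int(planted_idx[u]), int(planted_idx[v])) for u, v in extra.edges
        )

    edges = normalize_edges((names[u], names[v]) for u, v in graph.edges)
    universe = GeneSet(label="universe", genes=frozenset(names))
    planted = GeneSet(label="planted", genes=frozenset(names[planted_idx]))
    return universe, edges, planted


@dataclass(frozen=True)
class PopulationSimParams:
    """Inputs of the individual-level Monte-Carlo oracle."""

    spec: ArchitectureSpec
    n_total: float
    n_individuals: int = 100_000
    seed: int = 0


def _integer_counts(spec: ArchitectureSpec, n_total: float) -> list[int]:
    return [int(round(c.fraction * n_total)) for c in spec.classes]


def analytic_mean(spec: ArchitectureSpec, n_total: float) -> float:
    """Exact expectation of :func:`simulate_population`'s per-individual product.

    Per locus of class c the draw contributes ``vao ** (1 + partners)`` with
    probability RAF, else 1, so the per-locus mean is
    ``RAF * vao**(1+partners) + (1 - RAF)``.  For non-interacting classes this
    equals the class FLO and the whole expression equals the closed-form
    combined probability; for interacting classes it differs slightly from
    ``FLO ** (1 + partners)``, which amplifies the locus *average* rather
    than the allele output (see the methods notes).
    """
    log_p = 0.0
    for c, y in zip(spec.classes, _integer_counts(spec, n_total)):
        if c.vao is None or c.raf is None:
            raise ValueError(
                f"class {c.label!r} lacks (vao, raf); analytic_mean mirrors "
                "the allele-level sampling model"
            )
        per_locus = c.raf * c.vao ** (1 + c.partners) + (1.0 - c.raf)
        log_p += y * math.log(per_locus)
    return math.exp(log_p + spec.cnv_log_output)


def simulate_population(params: PopulationSimParams) -> tuple[float, float]:
    """Monte-Carlo mean per-individual functional output and its standard error.

    Each individual draws, at every locus of class c, the variant allele with
    probability RAF_c (contributing ``vao ** (1 + partners)``) or the
    reference allele (contributing 1); the individual's output is the product
    over all loci times the CNV multipliers.  Per class the log-product
    reduces to ``Binomial(y_c, RAF_c) * (1 + partners) * ln(vao)``, sampled
    exactly.  Classes must carry explicit (vao, raf); a bare FLO override
    does not define the allele-level sampling.
    """
    spec = params.spec
    for c in spec.classes:
        if c.flo_override is not None and (c.vao is None or c.raf is None):
            raise ValueError(
                f"class {c.label!r} has flo_override without (vao, raf); "
                "individual-level simulation needs the allele decomposition"
            )
    rng = np.random.default_rng(params.seed)
    log_products = np.zeros(params.n_individuals)
    for c, y in zip(spec.classes, _integer_counts(spec, params.n_total)):
        if y == 0 or c.vao == 1.0:
            continue
        hits = rng.binomial(y, c.raf, size=params.n_individuals)
        log_products += hits * (1 + c.partners) * math.log(c.vao)
    products = np.exp(log_products + spec.cnv_log_output)
    mean = float(products.mean())
    se = float(products.std(ddof=1) / math.sqrt(params.n_individuals))
    return mean, se
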