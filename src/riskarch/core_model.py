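"""Multiplicative threshold model of polygenic risk architecture.

The model treats each risk locus as emitting a functional output relative to
1 for the reference state.  A variant allele with output ``x`` (the variant
allele output, VAO) present at population frequency ``RAF`` gives the locus an
average functional locus output (FLO)::

    FLO = RAF * x + (1 - RAF)

Risk variants have x < 1 (FLO < 1), protective variants x > 1 (FLO > 1).
Independent loci combine multiplicatively: the probability of expressing a
threshold combination of risk variants in the population is::

    Pt = prod_c FLO_c ** y_c  *  prod_j CNV_FLO_j

where ``y_c`` is the number of loci in class ``c``.  Gene-gene interactions
amplify a locus: a risk gene interacting with ``n`` additional partners
contributes ``FLO ** (1 + n)`` per locus.  Large CNVs enter as fixed
multipliers (0.5 by default).  Solving ``Pt <= threshold`` (0.01, the assumed
schizophrenia prevalence) for the total locus count quantifies how many risk
genes a genome must carry to reach disease threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LocusClass",
    "ArchitectureSpec",
    "SolveResult",
    "ThresholdUnreachableError",
    "compute_flo",
    "effective_flo",
    "combined_probability",
    "solve_threshold",
    "cnv_equivalent_count",
    "round_count",
    "scenario",
    "best_guess_spec",
    "SCENARIO_NAMES",
    "ROUNDING_POLICIES",
]

ROUNDING_POLICIES = ("none", "nearest_hundred", "nearest_five", "floor")

#: Default prevalence threshold: lifetime prevalence of schizophrenia.
DEFAULT_THRESHOLD = 0.01

#: Default multiplicative output of a large deletion/duplication CNV.
DEFAULT_CNV_FLO = 0.5

_FRACTION_TOL = 1e-9


class ThresholdUnreachableError(ValueError):
    """Raised when the composition cannot drive Pt down to the threshold."""


def compute_flo(vao: float, raf: float) -> float:
    """Average functional locus output for a variant of output `vao` at frequency `raf`.

    Parameters
    ----------
    vao
        Variant allele output x > 0: the relative activity of the allele
        carrying the polymorphism (1 = reference, < 1 risk, > 1 protective).
    raf
        Risk allele frequency in [0, 1].

    Returns
    -------
    float
        ``raf * vao + (1 - raf)``, unrounded.
    """
    if not vao > 0:
        raise ValueError(f"vao must be > 0, got {vao!r}")
    if not 0.0 <= raf <= 1.0:
        raise ValueError(f"raf must be in [0, 1], got {raf!r}")
    return raf * vao + (1.0 - raf)


def effective_flo(flo: float, partners: int) -> float:
    """Per-locus output of a gene interacting with `partners` additional risk genes.

    An interacting pair assorts non-randomly, so each member contributes its
    FLO squared; each further partner raises the exponent by one:
    ``flo ** (1 + partners)``.
    """
    if not flo > 0:
        raise ValueError(f"flo must be > 0, got {flo!r}")
    if partners < 0 or int(partners) != partners:
        raise ValueError(f"partners must be a non-negative integer, got {partners!r}")
    return flo ** (1 + int(partners))


@dataclass(frozen=True)
class LocusClass:
    """A category of loci sharing one (VAO, RAF) or a fixed FLO.

    Parameters
    ----------
    label
        Free-text name for reporting.
    vao, raf
        Variant allele output and risk allele frequency; the class FLO is
        computed from them unless ``flo_override`` is given.
    partners
        Number of additional interacting risk genes; the per-locus
        contribution is FLO ** (1 + partners).
    fraction
        Share of the total (non-CNV) locus count in this class.
    flo_override
        Fixed FLO replacing the (vao, raf) computation — used to enter
        rounded published values such as 0.985 exactly.
    """

    label: str
    vao: float | None = None
    raf: float | None = None
    partners: int = 0
    fraction: float = 1.0
    flo_override: float | None = None

    def __post_init__(self) -> None:
        if self.flo_override is None:
            if self.vao is None or self.raf is None:
                raise ValueError(
                    f"class {self.label!r}: give (vao, raf) or flo_override"
                )
            compute_flo(self.vao, self.raf)  # validates ranges
        elif not self.flo_override > 0:
            raise ValueError(
                f"class {self.label!r}: flo_override must be > 0, got {self.flo_override!r}"
            )
        if self.partners < 0 or int(self.partners) != self.partners:
            raise ValueError(
                f"class {self.label!r}: partners must be a non-negative integer"
            )
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(
                f"class {self.label!r}: fraction must be in [0, 1], got {self.fraction!r}"
            )

    @property
    def flo(self) -> float:
        """Per-locus FLO before the interaction exponent."""
        if self.flo_override is not None:
            return self.flo_override
        return compute_flo(self.vao, self.raf)

    @property
    def effective(self) -> float:
        """Per-locus output including the interaction exponent."""
        return effective_flo(self.flo, self.partners)


@dataclass(frozen=True)
class ArchitectureSpec:
    """A full model scenario: locus classes, CNVs, threshold and reporting policy."""

    classes: tuple[LocusClass, ...]
    cnv_flos: tuple[float, ...] = ()
    threshold: float = DEFAULT_THRESHOLD
    rounding: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "cnv_flos", tuple(self.cnv_flos))
        if not self.classes:
            raise ValueError("spec needs at least one locus class")
        total = sum(c.fraction for c in self.classes)
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"class fractions must sum to 1, got {total!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold!r}")
        for f in self.cnv_flos:
            if not 0.0 < f <= 1.0:
                raise ValueError(f"cnv_flo must be in (0, 1], got {f!r}")
        if self.rounding not in ROUNDING_POLICIES:
            raise ValueError(
                f"rounding must be one of {ROUNDING_POLICIES}, got {self.rounding!r}"
            )

    @property
    def weighted_log_output(self) -> float:
        """Fraction-weighted mean of ln(effective FLO) — the per-locus log drop."""
        return sum(c.fraction * math.log(c.effective) for c in self.classes)

    @property
    def cnv_log_output(self) -> float:
        return sum(math.log(f) for f in self.cnv_flos)


@dataclass(frozen=True)
class SolveResult:
    """Solution of Pt(N) <= threshold for a scenario."""

    n_continuous: float
    n_integer: int
    n_reported: int
    per_class_counts: tuple[float, ...]
    achieved_pt: float
    cnv_equivalents: tuple[float, ...]


def combined_probability(spec: ArchitectureSpec, n_total: float) -> float:
    """Pt for `n_total` loci split among the spec's classes by their fractions.

    Real-valued ``n_total`` is permitted (class counts ``fraction * n_total``
    enter as real exponents); CNV multipliers always apply in full.
    """
    if n_total < 0:
        raise ValueError(f"n_total must be >= 0, got {n_total!r}")
    return math.exp(spec.weighted_log_output * n_total + spec.cnv_log_output)


def round_count(value: float, policy: str):
    """Apply a reporting rounding policy to a gene count; ``none`` is identity."""
    if policy == "none":
        return value
    if policy == "nearest_hundred":
        return int(round(value / 100.0)) * 100
    if policy == "nearest_five":
        return int(round(value / 5.0)) * 5
    if policy == "floor":
        return math.floor(value)
    raise ValueError(f"unknown rounding policy {policy!r}")


def cnv_equivalent_count(cnv_flo: float, locus_log_output: float) -> float:
    """Number of single-locus contributions one CNV substitutes.

    ``ln(cnv_flo) / locus_log_output`` — e.g. a 0.5-FLO CNV on a background of
    0.985-FLO loci replaces ln 0.5 / ln 0.985 ~ 45.9 loci.
    """
    if not 0.0 < cnv_flo < 1.0:
        raise ValueError(f"cnv_flo must be in (0, 1), got {cnv_flo!r}")
    if not locus_log_output < 0.0:
        raise ValueError(
            "locus_log_output must be negative (net-risk background), "
            f"got {locus_log_output!r}"
        )
    return math.log(cnv_flo) / locus_log_output


def solve_threshold(spec: ArchitectureSpec) -> SolveResult:
    """Solve for the number of loci at which Pt reaches the prevalence threshold.

    Returns the continuous closed-form root of ``Pt(N) = threshold``, the
    smallest integer N with ``Pt(N) <= threshold`` (genes are discrete), the
    integer count after the spec's reporting rounding, per-class real counts,
    the achieved Pt, and per-CNV locus-equivalent counts.

    Raises
    ------
    ThresholdUnreachableError
        If the fraction-weighted log output is >= 0 (net-neutral or
        net-protective composition) while the CNV product alone stays above
        the threshold.
    """
    w = spec.weighted_log_output
    cnv_log = spec.cnv_log_output
    log_target = math.log(spec.threshold)

    if cnv_log <= log_target:
        # CNV product alone (or an all-permissive threshold) already suffices.
        n_cont = 0.0
    elif w >= 0.0:
        raise ThresholdUnreachableError(
            "threshold unreachable: fraction-weighted log locus output is "
            f"{w:.6g} >= 0 (net-protective or neutral composition)"
        )
    else:
        n_cont = (log_target - cnv_log) / w

    # smallest integer N with Pt(N) <= threshold; guard the ceil against
    # representation error at exact integer roots
    n_int = max(0, math.ceil(n_cont - 1e-9))
    while combined_probability(spec, n_int) > spec.threshold:
        n_int += 1
    while n_int > 0 and combined_probability(spec, n_int - 1) <= spec.threshold:
        n_int -= 1

    equivalents = tuple(
        cnv_equivalent_count(f, w) if 0.0 < f < 1.0 and w < 0.0 else float("nan")
        for f in spec.cnv_flos
    )
    return SolveResult(
        n_continuous=n_cont,
        n_integer=n_int,
        n_reported=round_count(n_int, spec.rounding),
        per_class_counts=tuple(c.fraction * n_cont for c in spec.classes),
        achieved_pt=combined_probability(spec, n_int),
        cnv_equivalents=equivalents,
    )


# ---------------------------------------------------------------------------
# Published scenario presets
# ---------------------------------------------------------------------------

def _single(label: str, **kw) -> ArchitectureSpec:
    rounding = kw.pop("rounding", "none")
    cnv = kw.pop("cnv_flos", ())
    return ArchitectureSpec(
        classes=(LocusClass(label=label, fraction=1.0, **kw),),
        cnv_flos=cnv,
        rounding=rounding,
    )


def best_guess_spec(interacting_over: str = "total") -> ArchitectureSpec:
    """Composite best-guess architecture: plain, interacting and protective loci.

    45% plain risk loci (FLO 0.9978, from VAO 0.995 at RAF 0.44), 30%
    interacting with one partner (effective 0.9978 squared) and 25% protective
    (FLO 1.0022).  ``interacting_over="non_protective"`` instead reads the 30%
    interacting share against the non-protective subset only (52.5/22.5/25 of
    the total).
    """
    if interacting_over == "total":
        f_plain, f_int = 0.45, 0.30
    elif interacting_over == "non_protective":
        f_plain, f_int = 0.75 * 0.70, 0.75 * 0.30
    else:
        raise ValueError(
            "interacting_over must be 'total' or 'non_protective', "
            f"got {interacting_over!r}"
        )
    return ArchitectureSpec(
        classes=(
            LocusClass("plain_risk", flo_override=0.9978, fraction=f_plain),
            LocusClass("interacting_risk", flo_override=0.9978, partners=1, fraction=f_int),
            LocusClass("protective", flo_override=1.0022, fraction=0.25),
        ),
        rounding="nearest_hundred",
    )


def _fig3c(protective_fraction: float) -> ArchitectureSpec:
    return ArchitectureSpec(
        classes=(
            LocusClass("risk", flo_override=0.985, fraction=1.0 - protective_fraction),
            LocusClass("protective", flo_override=1.015, fraction=protective_fraction),
        ),
    )


def _fig5a(partners: int) -> ArchitectureSpec:
    if partners == 0:
        return _single("risk", flo_override=0.985, rounding="nearest_hundred")
    return ArchitectureSpec(
        classes=(
            LocusClass("risk", flo_override=0.985, fraction=0.70),
            LocusClass("interacting_risk", flo_override=0.985, partners=partners, fraction=0.30),
        ),
        rounding="nearest_hundred",
    )


_SCENARIOS = {
    # single risk class, VAO 0.8 at the empirical mean RAF 0.44
    "fig3a": lambda: _single("risk", vao=0.8, raf=0.44),
    # weak variants (VAO 0.95) at low frequency
    "fig3b": lambda: _single("risk", vao=0.95, raf=0.1, rounding="nearest_hundred"),
    # protective variants as 20% / 30% of loci
    "fig3c_p20": lambda: _fig3c(0.20),
    "fig3c_p30": lambda: _fig3c(0.30),
    # interaction scenarios on the 0.985 background
    "fig5a_noint": lambda: _fig5a(0),
    "fig5a_1plus1": lambda: _fig5a(1),
    "fig5a_1plus2": lambda: _fig5a(2),
    # CNV scenarios: deletion/duplication FLO 0.5 on the 0.985 background
    "fig5b_cnv1": lambda: _single(
        "risk", flo_override=0.985, cnv_flos=(DEFAULT_CNV_FLO,)
    ),
    "fig5b_cnv2": lambda: _single(
        "risk", flo_override=0.985, cnv_flos=(DEFAULT_CNV_FLO, DEFAULT_CNV_FLO)
    ),
    "bestguess": best_guess_spec,
}

SCENARIO_NAMES = tuple(sorted(_SCENARIOS))


def scenario(name: str) -> ArchitectureSpec:
    """Return a preset architecture by name (see ``SCENARIO_NAMES``)."""
    try:
        return _SCENARIOS[name]()
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIO_NAMES)}"
        ) from None
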