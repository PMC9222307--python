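"""Locus-output arithmetic and threshold solvers."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from riskarch import (
    ArchitectureSpec,
    LocusClass,
    ThresholdUnreachableError,
    cnv_equivalent_count,
    combined_probability,
    compute_flo,
    effective_flo,
    round_count,
    scenario,
    solve_threshold,
    best_guess_spec,
    SCENARIO_NAMES,
)
from conftest import iterative_solve


def single(flo=None, vao=None, raf=None, partners=0, cnv=(), threshold=0.01,
           rounding="none"):
    return ArchitectureSpec(
        classes=(LocusClass("c", vao=vao, raf=raf, partners=partners,
                            flo_override=flo),),
        cnv_flos=cnv, threshold=threshold, rounding=rounding,
    )


class TestComputeFlo:
    @pytest.mark.parametrize(
        "vao, raf, expected",
        [
            (0.995, 0.44, 0.9978),   # weak risk variant at the mean RAF
            (1.035, 0.44, 1.0154),   # protective variant, prints as 1.015
            (1.0, 0.73, 1.0),        # reference-identical allele
            (0.8, 0.0, 1.0),         # absent allele contributes nothing
            (0.8, 1.0, 0.8),         # fixed allele: locus output is the VAO
        ],
    )
    def test_examples(self, vao, raf, expected):
        assert compute_flo(vao, raf) == pytest.approx(expected, abs=1e-12)

    def test_reported_three_decimals(self):
        assert round(compute_flo(1.035, 0.44), 3) == 1.015

    @pytest.mark.parametrize("vao, raf", [(0.0, 0.5), (-1.0, 0.5), (0.8, -0.1), (0.8, 1.1)])
    def test_domain_errors_name_the_field(self, vao, raf):
        with pytest.raises(ValueError, match="vao|raf"):
            compute_flo(vao, raf)

    @given(st.floats(0.0, 1.0))
    def test_identity_vao_one(self, raf):
        assert compute_flo(1.0, raf) == 1.0

    @given(st.floats(0.01, 5.0))
    def test_boundary_rafs(self, vao):
        assert compute_flo(vao, 0.0) == 1.0
        assert compute_flo(vao, 1.0) == pytest.approx(vao)

    @given(st.floats(0.01, 0.999), st.floats(1e-9, 1.0))
    def test_risk_class_sign(self, vao, raf):
        flo = compute_flo(vao, raf)
        assert flo < 1.0


class TestEffectiveFlo:
    @pytest.mark.parametrize(
        "flo, partners, expected",
        [(0.985, 1, 0.970225), (0.985, 2, 0.955672), (0.985, 0, 0.985)],
    )
    def test_interaction_exponent(self, flo, partners, expected):
        assert effective_flo(flo, partners) == pytest.approx(expected, abs=1e-6)

    def test_printed_three_decimals(self):
        assert round(effective_flo(0.985, 1), 2) == 0.97
        assert round(effective_flo(0.985, 2), 3) == 0.956

    def test_negative_partners_rejected(self):
        with pytest.raises(ValueError, match="partners"):
            effective_flo(0.985, -1)


class TestCombinedProbability:
    def test_single_class_exponentiation(self):
        # independent oracle: direct exp(50 * ln 0.912)
        assert combined_probability(single(flo=0.912), 50) == pytest.approx(
            math.exp(50 * math.log(0.912)), abs=1e-12)
        assert combined_probability(single(flo=0.912), 50) == pytest.approx(
            0.00999, abs=1e-5)

    def test_neutral_composition_is_unity(self):
        spec = single(vao=1.0, raf=0.5)
        for n in (0, 10, 1000):
            assert combined_probability(spec, n) == 1.0

    def test_cnv_product_only_at_zero_loci(self):
        assert combined_probability(single(flo=0.985, cnv=(0.5,)), 0) == pytest.approx(0.5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="n_total"):
            combined_probability(single(flo=0.985), -1)


class TestSolveThreshold:
    def test_strong_variants_reach_threshold_at_50_genes(self):
        res = solve_threshold(scenario("fig3a"))
        assert res.n_integer == 50
        assert res.n_integer == iterative_solve(scenario("fig3a"))

    def test_weak_rare_variants_need_about_900(self):
        res = solve_threshold(scenario("fig3b"))
        assert res.n_integer == 919
        assert res.n_reported == 900

    def test_average_interaction_background_about_300(self):
        res = solve_threshold(scenario("fig5a_noint"))
        assert res.n_continuous == pytest.approx(math.log(0.01) / math.log(0.985))
        assert res.n_integer == 305
        assert res.n_reported == 300

    def test_one_cnv_leaves_250_to_260(self):
        res = solve_threshold(scenario("fig5b_cnv1"))
        assert res.n_integer == 259
        assert 250 <= res.n_integer <= 260

    def test_permissive_threshold_needs_no_genes(self):
        res = solve_threshold(single(flo=0.912, threshold=1.0))
        assert res.n_integer == 0

    def test_cnv_alone_sufficient(self):
        res = solve_threshold(single(flo=0.985, cnv=(0.25,), threshold=0.5))
        assert res.n_integer == 0
        assert res.achieved_pt <= 0.5

    def test_net_protective_unreachable(self):
        spec = single(flo=1.002)
        with pytest.raises(ThresholdUnreachableError):
            solve_threshold(spec)

    def test_bracket_property_on_presets(self):
        for name in SCENARIO_NAMES:
            spec = scenario(name)
            res = solve_threshold(spec)
            assert combined_probability(spec, res.n_integer) <= spec.threshold
            if res.n_integer > 0:
                assert combined_probability(spec, res.n_integer - 1) > spec.threshold

    def test_continuous_brackets_integer_single_class(self):
        for flo in (0.9, 0.95, 0.985, 0.999):
            res = solve_threshold(single(flo=flo))
            assert res.n_continuous <= res.n_integer < res.n_continuous + 1

    def test_per_class_counts_split_by_fraction(self):
        res = solve_threshold(best_guess_spec())
        assert sum(res.per_class_counts) == pytest.approx(res.n_continuous)
        assert res.per_class_counts[0] == pytest.approx(0.45 * res.n_continuous)


class TestOracleEquivalence:
    def test_closed_form_matches_iterative_on_random_specs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_classes = rng.integers(1, 4)
            fracs = rng.dirichlet(np.ones(n_classes))
            classes = tuple(
                LocusClass(f"c{i}", vao=float(rng.uniform(0.7, 0.99)),
                           raf=float(rng.uniform(0.05, 0.95)),
                           partners=int(rng.integers(0, 3)),
                           fraction=float(f))
                for i, f in enumerate(fracs)
            )
            cnv = (0.5,) if rng.random() < 0.3 else ()
            spec = ArchitectureSpec(classes=classes, cnv_flos=cnv)
            res = solve_threshold(spec)
            assert res.n_integer == iterative_solve(spec)
            assert abs(res.n_continuous - res.n_integer) <= 1.0


class TestMonotonicity:
    def test_count_nonincreasing_in_raf_and_effect_size(self):
        rafs = np.linspace(0.1, 0.9, 9)
        vaos = [0.95, 0.9, 0.85, 0.8]
        prev_by_vao = None
        for vao in vaos:
            ns = [solve_threshold(single(vao=vao, raf=r)).n_integer for r in rafs]
            assert all(a >= b for a, b in zip(ns, ns[1:]))  # raf direction
            if prev_by_vao is not None:
                assert all(a >= b for a, b in zip(prev_by_vao, ns))  # stronger effect
            prev_by_vao = ns

    def test_protective_fraction_raises_requirement(self):
        def with_protective(p):
            return ArchitectureSpec(classes=(
                LocusClass("risk", flo_override=0.985, fraction=1 - p),
                LocusClass("prot", flo_override=1.015, fraction=p),
            ))

        ns = [solve_threshold(with_protective(p)).n_integer
              for p in (0.0, 0.1, 0.2, 0.3)]
        assert all(a < b for a, b in zip(ns, ns[1:]))

    def test_interaction_partners_lower_requirement(self):
        ns = [solve_threshold(scenario(n)).n_integer
              for n in ("fig5a_noint", "fig5a_1plus1", "fig5a_1plus2")]
        assert ns[0] > ns[1] > ns[2]

    def test_each_cnv_lowers_requirement(self):
        ns = [solve_threshold(scenario(n)).n_integer
              for n in ("fig5a_noint", "fig5b_cnv1", "fig5b_cnv2")]
        assert ns[0] > ns[1] > ns[2]


class TestCnvEquivalents:
    @pytest.mark.parametrize(
        "cnv_flo, log_out, expected",
        [
            (0.5, math.log(0.985), 45.862),
            (0.985, math.log(0.985), 1.0),
            (0.25, math.log(0.5), 2.0),
        ],
    )
    def test_examples(self, cnv_flo, log_out, expected):
        assert cnv_equivalent_count(cnv_flo, log_out) == pytest.approx(expected, abs=1e-3)

    def test_protective_background_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cnv_equivalent_count(0.5, math.log(1.015))

    def test_solver_attaches_equivalents(self):
        res = solve_threshold(scenario("fig5b_cnv2"))
        assert len(res.cnv_equivalents) == 2
        assert res.cnv_equivalents[0] == pytest.approx(45.862, abs=1e-3)


class TestSpecValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ArchitectureSpec(classes=(
                LocusClass("a", flo_override=0.99, fraction=0.6),
                LocusClass("b", flo_override=0.99, fraction=0.5),
            ))

    def test_threshold_bounds(self):
        with pytest.raises(ValueError, match="threshold"):
            single(flo=0.99, threshold=0.0)

    def test_cnv_flo_bounds(self):
        with pytest.raises(ValueError, match="cnv_flo"):
            single(flo=0.99, cnv=(1.5,))

    def test_class_needs_flo_or_alleles(self):
        with pytest.raises(ValueError, match="flo_override"):
            LocusClass("bad")

    def test_unknown_rounding_policy(self):
        with pytest.raises(ValueError, match="rounding"):
            single(flo=0.99, rounding="nearest_ten")


class TestScenariosAndRounding:
    def test_unknown_scenario_lists_presets(self):
        with pytest.raises(ValueError, match="fig3a"):
            scenario("fig9z")

    def test_best_guess_composition(self):
        spec = best_guess_spec()
        fracs = {c.label: c.fraction for c in spec.classes}
        assert fracs == {"plain_risk": 0.45, "interacting_risk": 0.30,
                         "protective": 0.25}
        assert solve_threshold(spec).n_reported >= 2500

    def test_best_guess_alternative_basis_needs_more_genes(self):
        n_total = solve_threshold(best_guess_spec("total")).n_integer
        n_alt = solve_threshold(best_guess_spec("non_protective")).n_integer
        assert n_alt > n_total
        with pytest.raises(ValueError, match="interacting_over"):
            best_guess_spec("half")

    @pytest.mark.parametrize(
        "value, policy, expected",
        [(259, "none", 259), (919, "nearest_hundred", 900),
         (305, "nearest_hundred", 300), (45.86, "floor", 45),
         (258, "nearest_five", 260), (212, "nearest_five", 210)],
    )
    def test_round_count(self, value, policy, expected):
        assert round_count(value, policy) == expected
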