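"""Flux-cone operations: decomposition, coefficient bounds, extreme rays."""

from fractions import Fraction

import pytest

from basicpathways import (
    DomainError,
    RationalMatrix,
    TCA_CYCLE_PATHWAY,
    augment_with_dilution,
    build_fundamental_null_basis,
    coefficient_lower_bounds,
    compute_basic_pathways,
    decompose_pathway,
    enumerate_extreme_rays_bruteforce,
    is_admissible,
    is_extreme_ray,
    r_min_surface,
    random_model,
)
from basicpathways.model import model_from_dict
from basicpathways.transform import BasicPathwayBasis


@pytest.fixture(scope="module")
def toy_deficient_basis():
    """W = [[1,2],[2,1],[0,1]]: column 1 lacks a singleton entry.

    Constructed over the 1-metabolite model S0 = [[2, -1]], Lambda = 3, for
    which S = (2, -1, -3) annihilates both columns.
    """
    doc = {
        "metabolites": [{"id": "A", "dilution_rate": "3"}],
        "reactions": [
            {"id": "R1", "stoichiometry": {"A": "2"}},
            {"id": "R2", "stoichiometry": {"A": "-1"}},
        ],
    }
    model = model_from_dict(doc)
    G = build_fundamental_null_basis(model)
    W = RationalMatrix([[1, 2], [2, 1], [0, 1]])
    assert (augment_with_dilution(model).S @ W).is_zero()
    return BasicPathwayBasis(W=W, op_log=(), source=G)


class TestIsAdmissible:
    def test_zero_vector(self, case_S):
        assert is_admissible(case_S, [0] * 25)

    def test_tca_cycle_pathway(self, case_S):
        assert is_admissible(case_S, TCA_CYCLE_PATHWAY)

    def test_negated_entry_rejected(self, case_S, case_basis):
        v = case_basis.column(0)
        v[0] = -v[0]
        assert not is_admissible(case_S, v)

    def test_length_mismatch(self, case_S):
        with pytest.raises(DomainError):
            is_admissible(case_S, [0] * 7)


class TestDecomposePathway:
    def test_basis_column_gives_unit_vector(self, case_basis):
        for k in (0, 5, 11):
            dec = decompose_pathway(case_basis, case_basis.column(k))
            expected = [Fraction(0)] * case_basis.r
            expected[k] = Fraction(1)
            assert list(dec.coefficients) == expected
            assert dec.residual == 0

    def test_combination_recovered_exactly(self, case_basis):
        coeffs = [Fraction(0)] * 12
        coeffs[0], coeffs[4] = Fraction(2), Fraction(3)
        v = case_basis.W.matvec(coeffs)
        dec = decompose_pathway(case_basis, v)
        assert list(dec.coefficients) == coeffs

    def test_deficient_basis_negative_coefficient(self, case_basis):
        """A composite column (cycle + citrate route) makes its partner
        deficient; decomposing the bare cycle pathway then needs a negative
        coefficient, which is legitimate for a deficient basis."""
        W = case_basis.W.copy()
        for i in range(W.nrows):
            W[i, 11] = W[i, 11] + W[i, 6]
        dense = BasicPathwayBasis(W=W, op_log=(), source=case_basis.source)
        v = [Fraction(x) for x in TCA_CYCLE_PATHWAY]
        dec = decompose_pathway(dense, v)
        assert dec.coefficients[11] == 1
        assert dec.coefficients[6] == -1
        assert dense.W.matvec(list(dec.coefficients)) == v

    def test_split_sizes(self, case_basis):
        dec = decompose_pathway(case_basis, case_basis.column(3))
        assert len(dec.independent_components) == 12
        assert len(dec.dependent_components) == 13

    def test_non_null_vector_rejected(self, case_basis):
        v = [Fraction(1)] + [Fraction(0)] * 24
        with pytest.raises(DomainError):
            decompose_pathway(case_basis, v)

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_random(self, seed):
        import random

        rng = random.Random(seed)
        model = random_model(m=2 + seed % 5, r=2 + seed % 6, seed=seed)
        basis = compute_basic_pathways(model)
        coeffs = [Fraction(rng.randint(0, 4)) for _ in range(basis.r)]
        v = basis.W.matvec(coeffs)
        dec = decompose_pathway(basis, v)
        if basis.profile.complete:
            assert list(dec.coefficients) == coeffs
        assert basis.W.matvec(list(dec.coefficients)) == v


class TestCoefficientBounds:
    def test_toy_bound_matches_grid_oracle(self, toy_deficient_basis):
        b = coefficient_lower_bounds(toy_deficient_basis, {1: Fraction(1)})
        assert b.deficient_columns == (0,)
        assert b.lower_bound_d1 == Fraction(-1, 2)
        # brute-force oracle: r1 on a rational grid around the bound
        for num in range(-20, 10):
            r1 = Fraction(num, 10)
            v = toy_deficient_basis.W.matvec([r1, Fraction(1)])
            feasible = all(x >= 0 for x in v)
            assert feasible == (r1 >= Fraction(-1, 2))
            assert b.is_feasible([r1, Fraction(1)]) == feasible

    def test_boundary_point_has_zero_component(self, toy_deficient_basis):
        v = toy_deficient_basis.W.matvec([Fraction(-1, 2), Fraction(1)])
        assert any(x == 0 for x in v)
        assert all(x >= 0 for x in v)

    def test_complete_basis_rejected(self):
        model = random_model(m=2, r=2, seed=1)
        basis = compute_basic_pathways(model)
        if basis.profile.complete:
            with pytest.raises(DomainError):
                coefficient_lower_bounds(basis, {})

    def test_case_basis_bound(self, case_basis):
        prof = case_basis.profile
        assert prof.deficiency_index == 1
        fixed = {
            j: Fraction(1)
            for j in range(case_basis.r)
            if j not in prof.deficient_columns()
        }
        b = coefficient_lower_bounds(case_basis, fixed)
        lb = b.lower_bound_d1
        assert lb is not None and lb < 0
        jd = prof.deficient_columns()[0]

        def vec(r1):
            coeffs = [fixed.get(j, Fraction(0)) for j in range(case_basis.r)]
            coeffs[jd] = r1
            return case_basis.W.matvec(coeffs)

        eps = Fraction(1, 100)
        assert all(x >= 0 for x in vec(lb))
        assert all(x >= 0 for x in vec(lb + eps))
        assert any(x < 0 for x in vec(lb - eps))


class TestRMinSurface:
    def test_d1_direction_matches_scalar_bound(self, toy_deficient_basis):
        b = coefficient_lower_bounds(toy_deficient_basis, {1: Fraction(1)})
        rmin = r_min_surface(toy_deficient_basis, {1: Fraction(1)}, [Fraction(1)])
        assert rmin == -b.lower_bound_d1 == Fraction(1, 2)

    def test_boundary_tightness(self, toy_deficient_basis):
        rmin = r_min_surface(toy_deficient_basis, {1: Fraction(1)}, [Fraction(1)])
        v = toy_deficient_basis.W.matvec([-rmin, Fraction(1)])
        assert any(x == 0 for x in v)
        assert all(x >= 0 for x in v)

    def test_invalid_directions(self, toy_deficient_basis):
        with pytest.raises(DomainError):
            r_min_surface(toy_deficient_basis, {1: Fraction(1)}, [Fraction(-1)])
        with pytest.raises(DomainError):
            r_min_surface(toy_deficient_basis, {1: Fraction(1)}, [Fraction(0)])


class TestExtremeRays:
    def test_single_equation_cone(self):
        S = RationalMatrix([[1, -1]])
        assert is_extreme_ray(S, [1, 1])
        assert enumerate_extreme_rays_bruteforce(S) == [
            (Fraction(1), Fraction(1))
        ]

    def test_chain_cone(self):
        S = RationalMatrix([[1, -1, 0], [0, 1, -1]])
        assert enumerate_extreme_rays_bruteforce(S) == [
            (Fraction(1), Fraction(1), Fraction(1))
        ]

    def test_zero_and_inadmissible_rejected(self, case_S):
        with pytest.raises(DomainError):
            is_extreme_ray(case_S, [0] * 25)
        with pytest.raises(DomainError):
            is_extreme_ray(case_S, [1] + [0] * 24)

    def test_case_basis_columns_all_extreme(self, case_S, case_basis):
        for j in range(case_basis.r):
            assert is_extreme_ray(case_S, case_basis.column(j))

    def test_composite_column_is_not_extreme(self, case_S, case_basis):
        composite = [
            a + b
            for a, b in zip(case_basis.column(11), case_basis.column(6))
        ]
        assert is_admissible(case_S, composite)
        assert not is_extreme_ray(case_S, composite)

    def test_size_guard(self, case_S):
        with pytest.raises(DomainError):
            enumerate_extreme_rays_bruteforce(case_S)

    @pytest.mark.parametrize("seed", [2, 5, 8, 11])
    def test_cross_validation_with_rank_test(self, seed):
        model = random_model(m=3, r=4, seed=seed)
        S = augment_with_dilution(model).S
        rays = enumerate_extreme_rays_bruteforce(S, force=True)
        for v in rays:
            assert is_extreme_ray(S, list(v))
        basis = compute_basic_pathways(model)
        for j in range(basis.r):
            col = basis.column(j)
            if is_extreme_ray(S, col):
                from basicpathways.ratmat import primitive_column

                assert tuple(primitive_column(col)) in set(rays)
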