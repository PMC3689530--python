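"""Direct-summation structure factors: exactness, symmetry, precision, FFT."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braggkit.crystal_model import (
    FORM_FACTORS,
    CrystalStructure,
    Scatterer,
    UnitCell,
    d_star,
    expand_to_p1,
    random_p1_structure,
)
from braggkit.direct_summation import (
    AmplitudeComparison,
    CrystalliteExtent,
    ReflectionSet,
    compare_amplitudes,
    enumerate_hkl,
    fft_reference_sf,
    laue_interference,
    sf_batch,
    sf_finite_crystal,
    sf_single_cell,
)
from braggkit.errors import (
    EmptyComparisonError,
    InputError,
    ResourceLimitError,
    UsageError,
)

from conftest import random_structure_in


# -------------------------------------------------------------- single cell

class TestSingleCell:
    def test_atom_at_origin_is_real_form_factor(self, one_carbon_p1, cubic_cell):
        for hkl in [(1, 0, 0), (2, 3, 1), (0.4, 1.3, -0.7)]:
            f = sf_single_cell(one_carbon_p1, hkl)
            expected = FORM_FACTORS["C"].value(d_star(cubic_cell, hkl))
            assert f.imag == pytest.approx(0.0, abs=1e-12)
            assert f.real == pytest.approx(expected, rel=1e-12)

    def test_half_cell_shift_negates(self, cubic_cell):
        st_ = CrystalStructure.p1(cubic_cell, [Scatterer("C", "C", [0.5, 0, 0])])
        f = sf_single_cell(st_, (1, 0, 0))
        expected = -FORM_FACTORS["C"].value(d_star(cubic_cell, (1, 0, 0)))
        assert f.real == pytest.approx(expected, rel=1e-12)
        assert f.imag == pytest.approx(0.0, abs=1e-12)

    def test_p21_systematic_absence_0k0_odd(self, p21_one_atom):
        # the operator pair (x,y,z) / (-x,y+1/2,-z) forces F(0,k,0) = 0 for odd k
        for k in (1, 3, 5):
            assert abs(sf_single_cell(p21_one_atom, (0, k, 0))) < 1e-12
        assert abs(sf_single_cell(p21_one_atom, (0, 2, 0))) > 0.1

    def test_matches_reference_library(self):
        """Direct summation agrees with gemmi's independent calculator."""
        gemmi = pytest.importorskip("gemmi")
        st_ = random_p1_structure(n_atoms=20, seed=3)
        g = gemmi.Structure()
        cell = st_.cell
        g.cell = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
        g.spacegroup_hm = "P 1"
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        res = gemmi.Residue()
        res.name = "UNK"
        for sc in st_.scatterers:
            at = gemmi.Atom()
            at.name = sc.element
            at.element = gemmi.Element(sc.element)
            at.pos = g.cell.orthogonalize(gemmi.Fractional(*sc.position))
            at.occ = sc.occupancy
            at.b_iso = 8 * math.pi**2 * sc.u_iso
            res.add_atom(at)
        chain.add_residue(res)
        model.add_chain(chain)
        g.add_model(model)
        calc = gemmi.StructureFactorCalculatorX(g.cell)
        for hkl in [(1, 2, 3), (4, 0, 2), (-3, 5, -1), (0, 0, 6)]:
            f_ref = calc.calculate_sf_from_model(g[0], hkl)
            f = sf_single_cell(st_, hkl)
            # gemmi carries single-precision form-factor tables internally
            assert abs(f - f_ref) / abs(f) < 2e-6


# -------------------------------------------------------------- Laue factor

class TestLaueInterference:
    def test_single_cell_unity(self):
        assert laue_interference(CrystalliteExtent(1, 1, 1), (0.3, 0.7, -1.2)) == pytest.approx(1.0)

    def test_two_cell_null_at_half_integer(self):
        val = laue_interference(CrystalliteExtent(2, 1, 1), (0.5, 0, 0))
        assert abs(val) < 1e-12

    def test_integer_index_gives_cell_count(self):
        ext = CrystalliteExtent(10, 12, 14)
        val = laue_interference(ext, (2.0, -3.0, 5.0))
        assert val.real == pytest.approx(1680.0, rel=1e-10)
        assert val.imag == pytest.approx(0.0, abs=1e-6)

    @given(
        st.integers(1, 6), st.integers(1, 6), st.integers(1, 6),
        st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3),
    )
    @settings(max_examples=50, derandomize=True)
    def test_bounded_by_cell_count(self, n1, n2, n3, h, k, l):
        ext = CrystalliteExtent(n1, n2, n3)
        assert abs(laue_interference(ext, (h, k, l))) <= ext.n_cells * (1 + 1e-9)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(1, 9))
            h = float(rng.uniform(-2, 2))
            brute = sum(np.exp(2j * np.pi * h * u) for u in range(n))
            assert laue_interference(CrystalliteExtent(n, 1, 1), (h, 0, 0)) == pytest.approx(
                brute, abs=1e-9
            )

    def test_zeros_per_unit_interval(self):
        # an axis of N cells has exactly N-1 interference zeros per unit interval
        for n in (3, 5, 8):
            h = np.linspace(0.001, 0.999, 4001)
            mag = np.abs(laue_interference(CrystalliteExtent(n, 1, 1), np.stack(
                [h, np.zeros_like(h), np.zeros_like(h)], axis=-1)))
            for m in range(1, n):
                exact = laue_interference(CrystalliteExtent(n, 1, 1), (m / n, 0, 0))
                assert abs(exact) < 1e-9 * n
            # no other near-zeros: count deep minima
            deep = (mag[1:-1] < mag[:-2]) & (mag[1:-1] < mag[2:]) & (mag[1:-1] < 0.02 * n)
            assert deep.sum() == n - 1


# -------------------------------------------------------------- finite crystal

class TestFiniteCrystal:
    def test_single_extent_is_exact_continuum_limit(self, p63_five_atoms):
        ext = CrystalliteExtent(1, 1, 1)
        for hkl in [(1, 0, 0), (0.3, 1.7, -0.2)]:
            assert sf_finite_crystal(p63_five_atoms, ext, hkl) == sf_single_cell(
                p63_five_atoms, hkl
            )

    def test_integer_h_multiplies_by_cell_count(self, two_atom_p1):
        ext = CrystalliteExtent(2, 3, 4)
        f = sf_finite_crystal(two_atom_p1, ext, (1, 2, 1))
        f1 = sf_single_cell(two_atom_p1, (1, 2, 1))
        assert f == pytest.approx(24 * f1, rel=1e-10)

    def test_explicit_equals_factorized(self, two_atom_p1):
        rng = np.random.default_rng(7)
        for _ in range(100):
            ext = CrystalliteExtent(*rng.integers(1, 5, 3))
            hkl = tuple(rng.uniform(-2, 2, 3))
            fe = sf_finite_crystal(two_atom_p1, ext, hkl, "explicit")
            ff = sf_finite_crystal(two_atom_p1, ext, hkl, "factorized")
            assert abs(fe - ff) <= 1e-8 * max(abs(fe), 1e-30)

    def test_intensity_law_at_integer_h(self, p63_five_atoms):
        ext = CrystalliteExtent(10, 12, 14)
        i_fin = abs(sf_finite_crystal(p63_five_atoms, ext, (1, 0, 0))) ** 2
        i_cell = abs(sf_single_cell(p63_five_atoms, (1, 0, 0))) ** 2
        assert i_fin == pytest.approx(1680**2 * i_cell, rel=1e-10)

    def test_explicit_cap(self, one_carbon_p1):
        with pytest.raises(ResourceLimitError, match="factorized"):
            sf_finite_crystal(
                one_carbon_p1, CrystalliteExtent(101, 101, 101), (0.5, 0, 0), "explicit"
            )

    def test_bad_method(self, one_carbon_p1):
        with pytest.raises(UsageError):
            sf_finite_crystal(one_carbon_p1, CrystalliteExtent(1, 1, 1), (1, 0, 0), "fast")


# -------------------------------------------------------------- batches

class TestBatch:
    def test_singleton_matches_single_cell(self, p63_five_atoms):
        rs = sf_batch(p63_five_atoms, [(1, 2, 3)])
        assert rs.f_values[0] == pytest.approx(sf_single_cell(p63_five_atoms, (1, 2, 3)))

    def test_empty_list_gives_empty_set(self, one_carbon_p1):
        rs = sf_batch(one_carbon_p1, np.empty((0, 3)))
        assert len(rs) == 0

    def test_invalid_precision(self, one_carbon_p1):
        with pytest.raises(UsageError):
            sf_batch(one_carbon_p1, [(1, 0, 0)], precision="half")

    @pytest.mark.parametrize("precision,rtol", [("double", 1e-12), ("single", 1e-6)])
    def test_chunk_invariance(self, precision, rtol):
        st_ = random_p1_structure(n_atoms=150, seed=9)
        hkl = enumerate_hkl(st_.cell, 8.0)
        a = sf_batch(st_, hkl, precision=precision, chunk_size=1).amplitudes
        b = sf_batch(st_, hkl, precision=precision, chunk_size=64).amplitudes
        np.testing.assert_allclose(a, b, rtol=rtol)

    def test_friedel_symmetry(self):
        st_ = random_p1_structure(n_atoms=30, seed=11)
        rng = np.random.default_rng(2)
        hkl = rng.uniform(-4, 4, (25, 3))
        fa = sf_batch(st_, hkl).amplitudes
        fb = sf_batch(st_, -hkl).amplitudes
        np.testing.assert_allclose(fa, fb, rtol=1e-10)

    def test_occupancy_linearity_exact(self):
        st_ = random_p1_structure(n_atoms=20, seed=13)
        scaled = CrystalStructure.p1(
            st_.cell,
            [
                Scatterer(s.label, s.element, s.position, s.u_iso, 0.5 * s.occupancy)
                for s in st_.scatterers
            ],
        )
        hkl = enumerate_hkl(st_.cell, 10.0)
        np.testing.assert_allclose(
            sf_batch(scaled, hkl).amplitudes, 0.5 * sf_batch(st_, hkl).amplitudes, rtol=1e-14
        )

    @pytest.mark.parametrize("space_group", ["P 1", "P 21", "C 2", "P 21 21 21", "P 63"])
    def test_symmetry_expansion_oracle(self, space_group):
        st_ = random_structure_in(space_group, seed=17)
        p1 = expand_to_p1(st_)
        rng = np.random.default_rng(23)
        hkl = np.round(rng.uniform(-6, 6, (50, 3)))
        fa = sf_batch(st_, hkl).f_values
        fb = sf_batch(p1, hkl).f_values
        scale = np.abs(fa).max()
        np.testing.assert_allclose(fa / scale, fb / scale, atol=1e-10)

    def test_single_vs_double_discrepancy_small(self):
        # scaled-down version of the precision comparison (full size in acceptance)
        st_ = random_p1_structure(n_atoms=100, seed=20130618)
        hkl = enumerate_hkl(st_.cell, 4.0)
        cmp_ = compare_amplitudes(
            sf_batch(st_, hkl, precision="double"), sf_batch(st_, hkl, precision="single")
        )
        assert cmp_.mean_rel_err < 0.008


# -------------------------------------------------------------- enumeration

def test_enumerate_hkl_complete_and_bounded(cubic_cell):
    hkl = enumerate_hkl(cubic_cell, 2.5)
    ds = d_star(cubic_cell, hkl)
    assert np.all(ds <= 1 / 2.5 + 1e-12)
    assert np.all(ds > 0)
    # brute-force count over a generous cube
    h = np.arange(-5, 6)
    full = np.stack(np.meshgrid(h, h, h, indexing="ij"), axis=-1).reshape(-1, 3)
    dsf = d_star(cubic_cell, full.astype(float))
    assert len(hkl) == int(((dsf > 0) & (dsf <= 0.4)).sum())
    uniq = enumerate_hkl(cubic_cell, 2.5, friedel_unique=True)
    assert 2 * len(uniq) == len(hkl)


# -------------------------------------------------------------- FFT reference

class TestFftReference:
    def test_empty_structure_all_zero(self, cubic_cell):
        st_ = CrystalStructure.p1(cubic_cell, [])
        rs = fft_reference_sf(st_, 3.0)
        assert np.all(rs.amplitudes == 0)

    def test_point_atom_matches_form_factor(self, one_carbon_p1, cubic_cell):
        rs = fft_reference_sf(one_carbon_p1, 3.0)
        expected = FORM_FACTORS["C"].value(d_star(cubic_cell, rs.indices))
        np.testing.assert_allclose(rs.amplitudes, expected, rtol=0.02)

    def test_correlation_with_direct_summation(self):
        st_ = random_p1_structure(n_atoms=100, seed=31)
        rs_fft = fft_reference_sf(st_, 3.0)
        rs_dir = sf_batch(st_, rs_fft.indices)
        cmp_ = compare_amplitudes(rs_dir, rs_fft)
        assert cmp_.correlation > 0.99

    def test_error_decreases_with_grid_factor(self):
        st_ = random_p1_structure(n_atoms=60, seed=37)
        errs = []
        for gf in (2, 3, 4):
            rs_fft = fft_reference_sf(st_, 3.0, grid_factor=gf)
            errs.append(compare_amplitudes(sf_batch(st_, rs_fft.indices), rs_fft).mean_rel_err)
        assert errs[0] > errs[1] > errs[2]

    def test_requires_p1(self, p21_one_atom):
        with pytest.raises(InputError):
            fft_reference_sf(p21_one_atom, 3.0)


# -------------------------------------------------------------- comparison

class TestCompareAmplitudes:
    def test_identity(self):
        rs = ReflectionSet(np.array([[1, 0, 0], [2, 1, 0]]), np.array([3 + 0j, 1 + 1j]))
        cmp_ = compare_amplitudes(rs, rs)
        assert cmp_.mean_rel_err == 0.0
        assert cmp_.correlation == pytest.approx(1.0)
        assert cmp_.n_common == 2

    def test_doubling_gives_unit_error(self):
        idx = np.array([[1, 0, 0], [0, 2, 0], [1, 1, 1]])
        fv = np.array([2 + 1j, 0.5 - 2j, 3 + 0j])
        cmp_ = compare_amplitudes(ReflectionSet(idx, fv), ReflectionSet(idx, 2 * fv))
        assert cmp_.mean_rel_err == pytest.approx(1.0)
        assert cmp_.max_rel_err == pytest.approx(1.0)

    def test_no_common_indices(self):
        a = ReflectionSet(np.array([[1, 0, 0]]), np.array([1 + 0j]))
        b = ReflectionSet(np.array([[0, 1, 0]]), np.array([1 + 0j]))
        with pytest.raises(EmptyComparisonError):
            compare_amplitudes(a, b)


def test_reflection_set_tsv_round_trip(tmp_path, p63_five_atoms):
    rs = sf_batch(p63_five_atoms, [(1, 0, 0), (0.5, 1.2, -0.3), (2, 2, 2)])
    path = tmp_path / "refl.tsv"
    rs.write_tsv(path)
    back = ReflectionSet.read_tsv(path)
    np.testing.assert_allclose(back.indices, rs.indices, atol=1e-6)
    np.testing.assert_allclose(back.amplitudes, rs.amplitudes, rtol=1e-6)
    np.testing.assert_allclose(np.angle(back.f_values), np.angle(rs.f_values), atol=1e-6)
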