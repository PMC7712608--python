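"""Dipolar math: Dmax, back-calculation, tensor fitting, fitness score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdcfold.constants import GAMMA, MU0, PLANCK_H, VECTOR_TYPES, dmax
from rdcfold.errors import ValidationError
from rdcfold.geometry import Structure, internuclear_vector
from rdcfold.simulate import SimulationSpec, add_noise, simulate_rdcs
from rdcfold.tensor import (RdcRecord, SaupeTensor, back_calc, fit_tensor,
                            fitness, pooled_rmsd, quad_row)

from conftest import random_rotation

NH = VECTOR_TYPES[("N", "H", 0)]
CAHA = VECTOR_TYPES[("CA", "HA", 0)]


def random_saupe(rng, scale=5e-4) -> SaupeTensor:
    m = rng.normal(scale=scale, size=(3, 3))
    m = (m + m.T) / 2
    m -= np.eye(3) * np.trace(m) / 3
    return SaupeTensor.from_matrix(m)


def random_unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestDmax:
    def test_zero_gamma_and_cubic_law(self):
        assert dmax(0.0, GAMMA["H"], 1.02) == 0.0
        assert dmax(GAMMA["N"], GAMMA["H"], 2.04) == pytest.approx(
            dmax(GAMMA["N"], GAMMA["H"], 1.02) / 8.0, rel=1e-12)
        with pytest.raises(ValidationError):
            dmax(GAMMA["N"], GAMMA["H"], 0.0)

    def test_nh_caha_ratio_matches_hand_calculation(self):
        """Independent evaluation of the dipolar prefactor from the raw
        constants (own arithmetic, not the library formula)."""
        def hand(g1, g2, r_ang):
            r = r_ang * 1e-10
            return -MU0 * g1 * g2 * PLANCK_H / (8.0 * math.pi**3 * r**3)

        want = hand(GAMMA["N"], GAMMA["H"], 1.02) \
            / hand(GAMMA["C"], GAMMA["H"], 1.09)
        assert NH.dmax / CAHA.dmax == pytest.approx(want, rel=1e-9)
        # sign: 15N is negative-gamma, so N-H and CA-HA prefactors differ
        assert NH.dmax > 0 > CAHA.dmax

    def test_registry_consistency(self):
        for spec in VECTOR_TYPES.values():
            assert spec.dmax == pytest.approx(
                dmax(spec.gamma_1, spec.gamma_2, spec.r), rel=1e-9)


class TestBackCalc:
    def test_axis_evaluation_and_trace_identity(self):
        s = SaupeTensor(3e-4, -1e-4, 0.0, 0.0, 0.0)
        assert back_calc(np.array([0.0, 0.0, 1.0]), s, NH) == pytest.approx(
            NH.dmax * (-3e-4 + 1e-4), rel=1e-12)
        total = sum(back_calc(np.eye(3)[i], s, NH) for i in range(3))
        assert total == pytest.approx(0.0, abs=1e-12 * abs(NH.dmax))

    def test_matches_explicit_matrix_product(self, rng):
        for _ in range(10):
            s = random_saupe(rng)
            v = random_unit(rng)[0]
            want = NH.dmax * float(v @ s.matrix @ v)
            assert back_calc(v, s, NH) == pytest.approx(want, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = random_saupe(rng)
        v = random_unit(rng)[0]
        assert back_calc(v, s, NH) == back_calc(-v, s, NH)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValidationError):
            back_calc(np.array([0.0, 0.0, 2.0]),
                      SaupeTensor(0, 0, 0, 0, 0), NH)


class TestFitTensor:
    def test_generate_then_recover(self, rng):
        truth = random_saupe(rng)
        v = random_unit(rng, 20)
        specs = [NH] * 20
        d = [back_calc(v[i], truth, NH) for i in range(20)]
        got = fit_tensor(v, d, specs)
        assert np.allclose(got.matrix, truth.matrix, atol=1e-9)

    def test_zero_rdcs_give_zero_tensor(self, rng):
        v = random_unit(rng, 8)
        got = fit_tensor(v, np.zeros(8), [NH] * 8)
        assert np.allclose(got.matrix, 0.0, atol=1e-15)

    def test_five_independent_rows_equal_direct_solve(self, rng):
        truth = random_saupe(rng)
        while True:
            v = random_unit(rng, 5)
            a = NH.dmax * quad_row(v)
            if np.linalg.matrix_rank(a) == 5:
                break
        d = a @ truth.components
        want = np.linalg.solve(a, d)
        got = fit_tensor(v, d, [NH] * 5)
        assert np.allclose(got.components, want, atol=1e-12)

    def test_scale_equivariance(self, rng):
        v = random_unit(rng, 12)
        d = rng.normal(scale=10.0, size=12)
        s1 = fit_tensor(v, d, [NH] * 12)
        s3 = fit_tensor(v, 3.0 * d, [NH] * 12)
        assert np.allclose(s3.matrix, 3.0 * s1.matrix, rtol=1e-9)

    def test_underdetermined_minimum_norm(self, rng):
        v = random_unit(rng, 2)
        d = np.array([1.0, -2.0])
        got = fit_tensor(v, d, [NH] * 2).components
        a = NH.dmax * quad_row(v)
        # residual orthogonal to the column space, solution in the row space
        assert np.allclose(a.T @ (a @ got - d), 0.0, atol=1e-9)
        null = got - a.T @ np.linalg.lstsq(a.T, got, rcond=None)[0]
        assert np.linalg.norm(null) < 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            fit_tensor([], [], [])


class TestFitness:
    def test_self_consistency_zero(self, helix15):
        score = fitness(helix15.structure, helix15.datasets[0.0])
        assert score.value < 1e-9
        assert score.n_media == 2
        assert score.n_rdcs_used == len(helix15.datasets[0.0])

    def test_pooled_rms_arithmetic(self):
        # one medium, two couplings deviating by 3 and 4 Hz
        assert pooled_rmsd([3.0, 4.0], n_media=1, n_per_medium=2) \
            == pytest.approx(math.sqrt(25.0 / 2.0), rel=1e-12)

    def test_forced_deviations_survive_the_refit(self, rng, helix15):
        """Perturbations orthogonal to the design column space are
        untouched by the least-squares tensor refit: duplicating a
        coupling's vector with +delta/-delta values leaves residuals of
        exactly (delta, delta), so Eq.-style pooling is testable without
        fixing the tensor."""
        s = helix15.structure
        base = [r for r in helix15.datasets[0.0] if r.medium == 1][:5]
        dup = []
        for rec, delta in zip(base[:2], (3.0, 4.0)):
            for sign in (+1.0, -1.0):
                dup.append(RdcRecord(rec.residue_1, rec.atom_1,
                                     rec.residue_2, rec.atom_2, 1,
                                     rec.value + sign * delta, 0.0))
        data = base + dup
        got = fitness(s, data)
        want = math.sqrt((2 * 9.0 + 2 * 16.0) / 9.0)
        assert got.value == pytest.approx(want, rel=1e-9)

    def test_rigid_motion_invariance(self, helix15, rng):
        s = helix15.structure
        data = helix15.datasets[2.0]
        ref = fitness(s, data).value
        for _ in range(5):
            moved = Structure(s.sequence,
                              s.coords @ random_rotation(rng).T
                              + rng.normal(scale=10.0, size=3))
            assert fitness(moved, data).value == pytest.approx(ref, abs=1e-9)

    def test_noise_floor_bound(self, helix15):
        """The fitted RMS cannot exceed the raw noise residual; over many
        seeds it stays below E/sqrt(3) plus sampling slack."""
        clean = helix15.datasets[0.0]
        for e in (1.0, 2.0):
            for seed in range(20):
                noisy = add_noise(clean, e, seed)
                got = fitness(helix15.structure, noisy).value
                assert got <= e / math.sqrt(3.0) + 0.2

    def test_records_beyond_partial_fragment_skipped(self, helix15):
        s = helix15.structure
        partial = Structure(s.sequence[:6], s.coords[:6].copy())
        score = fitness(partial, helix15.datasets[0.0])
        assert score.n_skipped > 0
        assert score.n_rdcs_used + score.n_skipped \
            == len(helix15.datasets[0.0])
        assert score.value < 1e-9

    def test_weighted_variant_downweights_noisy_medium(self, helix15):
        clean = helix15.datasets[0.0]
        noisy = []
        for rec in clean:
            e = 0.01 if rec.medium == 1 else 4.0
            noisy.append(RdcRecord(rec.residue_1, rec.atom_1, rec.residue_2,
                                   rec.atom_2, rec.medium, rec.value, e))
        noisy = add_noise(noisy, 0.0, 0)
        perturbed = [
            RdcRecord(r.residue_1, r.atom_1, r.residue_2, r.atom_2, r.medium,
                      r.value + (0.0 if r.medium == 1 else 2.0),
                      r.uncertainty)
            for r in noisy]
        unweighted = fitness(helix15.structure, perturbed, weighted=False)
        weighted = fitness(helix15.structure, perturbed, weighted=True)
        assert weighted.value < unweighted.value


class TestSaupeTensor:
    def test_traceless_symmetric_by_construction(self, rng):
        s = random_saupe(rng)
        assert np.trace(s.matrix) == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(s.matrix, s.matrix.T)

    def test_from_matrix_validation(self):
        with pytest.raises(ValidationError):
            SaupeTensor.from_matrix(np.eye(3))  # not traceless
        with pytest.raises(ValidationError):
            SaupeTensor.from_matrix(np.arange(9.0).reshape(3, 3))
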