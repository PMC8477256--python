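"""Forward model: directivity, sparse blocks, adjoint, data simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import patlv as P
from patlv.forward import DENSE_ENTRY_BUDGET

from conftest import dense_oracle


class TestDirectivity:
    def test_datasheet_anchor_values(self):
        prof = P.DirectivityProfile()
        assert P.directivity(prof, 0.0) == pytest.approx(1.0)
        assert P.directivity(prof, 0.24) == pytest.approx(0.95)
        assert P.directivity(prof, 0.72) == pytest.approx(0.40)

    def test_symmetric_in_angle_sign(self):
        prof = P.DirectivityProfile()
        assert P.directivity(prof, -0.24) == pytest.approx(0.95)

    def test_zero_beyond_cutoff(self):
        prof = P.DirectivityProfile()
        assert P.directivity(prof, 1.2) == 0.0
        assert P.directivity(prof, 2.5) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.0, 1.19), st.floats(0.0, 1.19))
    def test_monotone_non_increasing(self, a, b):
        prof = P.DirectivityProfile()
        lo, hi = sorted((a, b))
        assert P.directivity(prof, hi) <= P.directivity(prof, lo) + 1e-12

    def test_alternative_modes(self):
        assert P.directivity(P.DirectivityProfile(mode="none"), 0.7) == 1.0
        cos = P.directivity(P.DirectivityProfile(mode="cosine"), 0.5)
        assert cos == pytest.approx(np.cos(0.5))


class TestSubmatrix:
    def test_integer_arrival_single_row(self, grid8, tiny_acoustics):
        # place one element so that some pixel lands exactly on a sample:
        # element at the position of pixel (0,0) minus 10*cdt along depth
        g = grid8
        cdt = tiny_acoustics.sample_distance_mm
        Y, X = g.pixel_centers()
        target = np.array([Y[0, 0], X[0, 0]])
        elem = target - np.array([10 * cdt, 0.0])
        arr = P.TransducerArray(positions=elem[None, :], normals=np.array([[1.0, 0.0]]),
                                pitch=1.0)
        geom = P.DetectionGeometry(arrays=(arr,), label="single")
        prof = P.DirectivityProfile(mode="none")
        A = P.build_submatrix(0, geom, g, tiny_acoustics, prof)
        col = A[:, 0].toarray().ravel()
        expected = 1.0 / (2 * np.pi * 10.0)  # r = 10 sample-lengths
        assert col[10] == pytest.approx(expected, rel=1e-12)
        assert np.count_nonzero(col) == 1

    def test_fractional_arrival_partition_of_unity(self, grid8, tiny_acoustics):
        g = grid8
        cdt = tiny_acoustics.sample_distance_mm
        Y, X = g.pixel_centers()
        target = np.array([Y[0, 0], X[0, 0]])
        elem = target - np.array([10.3 * cdt, 0.0])
        arr = P.TransducerArray(positions=elem[None, :], normals=np.array([[1.0, 0.0]]),
                                pitch=1.0)
        geom = P.DetectionGeometry(arrays=(arr,), label="single")
        prof = P.DirectivityProfile(mode="none")
        A = P.build_submatrix(0, geom, g, tiny_acoustics, prof)
        col = A[:, 0].toarray().ravel()
        amp = 1.0 / (2 * np.pi * 10.3)
        assert col[10] == pytest.approx(0.7 * amp, rel=1e-9)
        assert col[11] == pytest.approx(0.3 * amp, rel=1e-9)
        assert col[10] + col[11] == pytest.approx(amp, rel=1e-12)

    def test_paper_scale_block_entry_count(self):
        # bookkeeping only: dense size of one block at the study scale
        g = P.make_grid(128, 38.0)
        geom = P.make_single(g, Q=128, pitch_mm=0.3)
        ac = P.AcousticConfig(1500.0, 40e6, 1000)
        A = P.build_projection(geom, g, ac)
        assert A.block_dense_size == 1000 * 128 * 128
        assert A.dense_size == 128 * 1000 * 128 * 128

    def test_nnz_bounded_by_two_per_pixel(self, tiny_operator, grid8):
        for b in tiny_operator.blocks:
            assert b.nnz <= 2 * grid8.n**2

    def test_out_of_range_element_rejected(self, tiny_square, grid8, tiny_acoustics):
        with pytest.raises(IndexError):
            P.build_submatrix(99, tiny_square, grid8, tiny_acoustics)


class TestProjectionOperator:
    def test_matches_dense_oracle(self, tiny_square, grid8, tiny_acoustics):
        """Sparse blocks agree with a brute-force entry-by-entry build."""
        op = P.build_projection(tiny_square, grid8, tiny_acoustics)
        oracle = dense_oracle(tiny_square, grid8, tiny_acoustics)
        for sparse, dense in zip(op.blocks, oracle):
            assert np.allclose(sparse.toarray(), dense, rtol=1e-12, atol=1e-15)

    def test_forward_of_zero_image_is_zero(self, tiny_operator, grid8):
        assert np.all(tiny_operator.forward(np.zeros((grid8.n, grid8.n))) == 0)

    def test_adjoint_identity(self, tiny_operator):
        rng = np.random.default_rng(42)
        x = rng.normal(size=tiny_operator.shape[1])
        y = rng.normal(size=(tiny_operator.Q, tiny_operator.acoustics.T))
        lhs = float(np.sum(tiny_operator.forward(x) * y))
        rhs = float(np.sum(x * tiny_operator.adjoint(y).ravel()))
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_dense_materialisation_guard(self):
        g = P.make_grid(128, 38.0)
        geom = P.make_single(g, Q=128, pitch_mm=0.3)
        ac = P.AcousticConfig(1500.0, 40e6, 1000)
        op = P.build_projection(geom, g, ac)
        assert op.dense_size > DENSE_ENTRY_BUDGET
        with pytest.raises(MemoryError):
            op.to_dense()

    def test_linearity(self, tiny_operator, grid8):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(grid8.n, grid8.n))
        b = rng.normal(size=(grid8.n, grid8.n))
        lhs = tiny_operator.forward(2.0 * a - 3.0 * b)
        rhs = 2.0 * tiny_operator.forward(a) - 3.0 * tiny_operator.forward(b)
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestPressurePotential:
    def test_zero_pressure_zero_potential(self, tiny_acoustics):
        s = P.Sinogram(np.zeros((2, tiny_acoustics.T)), tiny_acoustics)
        assert np.all(P.pressure_to_potential(s).data == 0)

    def test_constant_pressure_gives_ramp(self, tiny_acoustics):
        s = P.Sinogram(np.ones((1, tiny_acoustics.T)), tiny_acoustics)
        g = P.pressure_to_potential(s).data[0]
        j = np.arange(tiny_acoustics.T)
        assert np.allclose(g, j * tiny_acoustics.dt_us, rtol=1e-12)

    def test_matches_quadrature_oracle(self, tiny_acoustics):
        from scipy.integrate import trapezoid

        rng = np.random.default_rng(11)
        p = rng.normal(size=(1, tiny_acoustics.T))
        g = P.pressure_to_potential(P.Sinogram(p, tiny_acoustics)).data[0]
        for j in (1, 7, 31, tiny_acoustics.T - 1):
            ref = trapezoid(p[0, : j + 1], dx=tiny_acoustics.dt_us)
            assert g[j] == pytest.approx(ref, rel=1e-12, abs=1e-15)

    def test_potential_starts_at_zero(self, tiny_acoustics):
        rng = np.random.default_rng(2)
        p = rng.normal(size=(3, tiny_acoustics.T))
        g = P.pressure_to_potential(P.Sinogram(p, tiny_acoustics))
        assert np.all(g.data[:, 0] == 0.0)


class TestSimulateData:
    def test_zero_phantom_rejected_but_tiny_source_ok(self, grid8, tiny_acoustics):
        with pytest.raises(ValueError):
            P.Phantom(np.zeros((8, 8)), grid8, "empty")

    def test_refine1_equals_operator_forward(self, grid64, tiny_acoustics):
        ac = P.AcousticConfig(1500.0, 2e6, 96)
        ph = P.disc_phantom(grid64, [(2.0, -3.0)], 6.0)
        geom = P.make_single(grid64, Q=16, pitch_mm=2.0)
        _, pot = P.simulate_data(ph, geom, ac, refine=1)
        op = P.build_projection(geom, grid64, ac)
        assert np.allclose(pot.data, op.forward(ph.image), rtol=1e-12, atol=1e-15)

    def test_single_pixel_arrival_time(self, tiny_acoustics):
        g = P.make_grid(16, 38.0)
        img = np.zeros((16, 16))
        img[4, 9] = 1.0
        ph = P.Phantom(img, g, "point")
        geom = P.make_single(g, Q=4, pitch_mm=4.0)
        _, pot = P.simulate_data(ph, geom, tiny_acoustics, refine=1)
        Y, X = g.pixel_centers()
        src = np.array([Y[4, 9], X[4, 9]])
        for i, p in enumerate(geom.all_positions()):
            r = np.linalg.norm(src - p)
            expected = r / tiny_acoustics.sample_distance_mm
            nz = np.nonzero(pot.data[i])[0]
            assert abs(nz[0] - round(expected)) <= 1

    def test_amplitude_decay_with_distance(self):
        # two equal point sources at r and 2r from the element: the
        # 1/(2 pi r) decay makes the near peak twice the far peak
        g = P.make_grid(64, 38.0)
        ac = P.AcousticConfig(1500.0, 4e6, 160)
        cdt = ac.sample_distance_mm
        Y, X = g.pixel_centers()
        img = np.zeros((64, 64))
        elem_pos = np.array([-g.extent_mm / 2.0, 0.0])
        # choose pixels nearest to depth offsets r and 2r on the axis
        r = 12.0
        for d in (r, 2 * r):
            idx = np.argmin((Y - (elem_pos[0] + d)) ** 2 + X**2)
            img.ravel()[idx] = 1.0
        ph = P.Phantom(img, g, "two-points")
        arr = P.TransducerArray(elem_pos[None, :], np.array([[1.0, 0.0]]), pitch=1.0)
        geom = P.DetectionGeometry((arr,), label="single")
        _, pot = P.simulate_data(ph, geom, ac, refine=1, antialias=False,
                                 profile=P.DirectivityProfile(mode="none"))
        trace = pot.data[0]
        # arrival samples are near r/cdt = 32 and 64; the summed bump weight
        # is exactly D/(2 pi r), so bump sums follow the 1/r decay law
        near = trace[:48].sum()
        far = trace[48:120].sum()
        Y, X = g.pixel_centers()
        pix = np.column_stack([Y.ravel(), X.ravel()])[img.ravel() > 0]
        r_near, r_far = sorted(np.linalg.norm(pix - elem_pos, axis=1))
        assert near / far == pytest.approx(r_far / r_near, rel=1e-9)

    def test_noise_is_seeded_and_reproducible(self, grid64):
        ac = P.AcousticConfig(1500.0, 2e6, 96)
        ph = P.disc_phantom(grid64, [(0.0, 0.0)], 6.0)
        geom = P.make_single(grid64, Q=8, pitch_mm=4.0)
        s1, g1 = P.simulate_data(ph, geom, ac, refine=1, noise_sd=0.05, seed=9)
        s2, g2 = P.simulate_data(ph, geom, ac, refine=1, noise_sd=0.05, seed=9)
        s3, _ = P.simulate_data(ph, geom, ac, refine=1, noise_sd=0.05, seed=10)
        assert np.array_equal(s1.data, s2.data)
        assert not np.array_equal(s1.data, s3.data)
        assert g1.provenance == "integrated-from-pressure"

    def test_default_record_length_covers_farthest_pixel(self, grid64):
        geom = P.make_square(grid64, Q=8, pitch_mm=4.0)
        ac = P.AcousticConfig(1500.0, 40e6, 1)
        T = P.default_num_samples(geom, grid64, ac)
        Y, X = grid64.pixel_centers()
        pix = np.column_stack([Y.ravel(), X.ravel()])
        dmax = max(
            np.linalg.norm(pix - p, axis=1).max() for p in geom.all_positions()
        )
        assert T >= dmax / ac.sample_distance_mm
        assert T <= dmax / ac.sample_distance_mm + 20
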