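"""Monte Carlo transport: sampling laws, ballistic limits, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibreloc as fl
from fibreloc.transport import PS_PER_CM

# ---------------------------------------------------------------------------
# pure-Python mirror of the transport kernel (independent scalar oracle)
# ---------------------------------------------------------------------------

_M64 = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15
_STREAM = 0xD1B54A32D192ED03


def _mix64(z):
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return z ^ (z >> 31)


class _Stream:
    def __init__(self, seed, i):
        self.s = _mix64((((seed + 1) * _GOLDEN) & _M64) ^ (((i + 1) * _STREAM) & _M64))

    def u(self):
        self.s = (self.s + _GOLDEN) & _M64
        z = _mix64(self.s)
        return ((z >> 11) + 1) * 2.0 ** -53


def _rotate(ux, uy, uz, cost, cosp, sinp):
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    if abs(uz) > 0.99999:
        nx, ny = sint * cosp, sint * sinp
        nz = cost if uz > 0.0 else -cost
    else:
        tmp = math.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / tmp + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / tmp + uy * cost
        nz = -sint * cosp * tmp + uz * cost
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


def _hg(g, u):
    if g == 0.0:
        return 2.0 * u - 1.0
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return min(1.0, max(-1.0, (1.0 + g * g - s * s) / (2.0 * g)))


def _oracle_photon(medium, source, seed, i):
    """Scalar re-implementation of launch + propagate for one photon.

    Consumes the identical (seed, i) substream as the production kernel and
    returns (exited_imaged, path_cm, n_scatter, weight) or None if absorbed
    or exited elsewhere.
    """
    st = _Stream(seed, i)
    mua, mus, gg = medium.mua, medium.mus, medium.g
    voxel = medium.voxel_cm
    nx_, ny_, nz_ = mua.shape
    cos_half = math.cos(source.cone_half_angle_rad(medium.n))
    u1, u2 = st.u(), st.u()
    cost = 1.0 - u1 * (1.0 - cos_half)
    phi = 2.0 * math.pi * u2
    ax, ay, az = source.axis
    dx, dy, dz = _rotate(ax, ay, az, cost, math.cos(phi), math.sin(phi))
    sigma = source.pulse_fwhm_ps / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    if sigma > 0.0:
        st.u(), st.u()
    x, y, z = source.tip_cm
    ix, iy, iz = int(x / voxel), int(y / voxel), int(z / voxel)
    path, w, nsc = 0.0, 1.0, 0
    face = medium.face_code
    while True:
        tau = -math.log(st.u())
        while True:
            musl, mual = mus[ix, iy, iz], mua[ix, iy, iz]
            tx = ((ix + 1) * voxel - x) / dx if dx > 0 else ((ix * voxel - x) / dx if dx < 0 else 1e30)
            ty = ((iy + 1) * voxel - y) / dy if dy > 0 else ((iy * voxel - y) / dy if dy < 0 else 1e30)
            tz = ((iz + 1) * voxel - z) / dz if dz > 0 else ((iz * voxel - z) / dz if dz < 0 else 1e30)
            tb = max(min(tx, ty, tz), 0.0)
            if musl > 0.0 and musl * tb >= tau:
                step = tau / musl
                x, y, z = x + dx * step, y + dy * step, z + dz * step
                path += step
                w *= math.exp(-mual * step)
                break
            x, y, z = x + dx * tb, y + dy * tb, z + dz * tb
            path += tb
            w *= math.exp(-mual * tb)
            tau -= musl * tb
            if w < 1e-4:
                if w <= 0.0:
                    return None
                if st.u() < 0.1:
                    w /= 0.1
                else:
                    return None
            if tx <= ty and tx <= tz:
                if dx > 0:
                    ix += 1
                    x = ix * voxel
                    if ix >= nx_:
                        return (face == 1, path, nsc, w)
                else:
                    x = ix * voxel
                    ix -= 1
                    if ix < 0:
                        return (face == 0, path, nsc, w)
            elif ty <= tz:
                if dy > 0:
                    iy += 1
                    y = iy * voxel
                    if iy >= ny_:
                        return (face == 3, path, nsc, w)
                else:
                    y = iy * voxel
                    iy -= 1
                    if iy < 0:
                        return (face == 2, path, nsc, w)
            else:
                if dz > 0:
                    iz += 1
                    z = iz * voxel
                    if iz >= nz_:
                        return (face == 5, path, nsc, w)
                else:
                    z = iz * voxel
                    iz -= 1
                    if iz < 0:
                        return (face == 4, path, nsc, w)
        if w < 1e-4:
            if st.u() < 0.1:
                w /= 0.1
            else:
                return None
        cost = _hg(gg[ix, iy, iz], st.u())
        phi = 2.0 * math.pi * st.u()
        dx, dy, dz = _rotate(dx, dy, dz, cost, math.cos(phi), math.sin(phi))
        nsc += 1


# ---------------------------------------------------------------------------
# elementary sampling operations
# ---------------------------------------------------------------------------

class TestFreePath:
    def test_worked_examples(self):
        assert fl.sample_free_path(10.0, 0.5) == pytest.approx(-math.log(0.5) / 10, rel=1e-12)
        assert fl.sample_free_path(10.0, 1.0) == 0.0

    def test_rejects_nonpositive_attenuation(self):
        with pytest.raises(fl.InvalidMediumError):
            fl.sample_free_path(0.0, 0.5)

    def test_sample_mean_matches_analytic(self):
        # exponential mean 1/mu_t within 3 sigma / sqrt(N)
        rng = np.random.default_rng(42)
        n = 10 ** 6
        for mu in (5.0, 10.0):
            draws = fl.sample_free_path(mu, 1.0 - rng.random(n))
            assert abs(draws.mean() - 1 / mu) < 3 * (1 / mu) / math.sqrt(n)


class TestHenyeyGreenstein:
    def test_isotropic_reduces_to_uniform_cosine(self):
        assert fl.sample_hg_cosine(0.0, 0.75) == pytest.approx(0.5)

    def test_forward_peaked_limit(self):
        assert fl.sample_hg_cosine(0.99, 1.0 - 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_rejects_invalid_anisotropy(self):
        with pytest.raises(fl.InvalidMediumError):
            fl.sample_hg_cosine(1.0, 0.5)

    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_sample_mean_equals_g(self, g):
        # E[cos theta] = g for the HG phase function
        rng = np.random.default_rng(7)
        n = 10 ** 6
        c = fl.sample_hg_cosine(g, 1.0 - rng.random(n))
        assert abs(c.mean() - g) < 3 * c.std() / math.sqrt(n)

    def test_cosines_bounded(self):
        rng = np.random.default_rng(3)
        c = fl.sample_hg_cosine(-0.8, rng.random(10000))
        assert np.all((c >= -1) & (c <= 1))

    @settings(deadline=None, derandomize=True)
    @given(g=st.floats(-0.999, 0.999),
           u=st.floats(1e-12, 1.0, exclude_min=False))
    def test_inverse_cdf_properties(self, g, u):
        # bounded everywhere; free path positive and finite for the same u
        c = fl.sample_hg_cosine(g, u)
        assert -1.0 <= c <= 1.0
        d = fl.sample_free_path(7.5, u)
        assert 0.0 <= d < math.inf


class TestLaunch:
    def _source(self, na=0.22, fwhm=0.0):
        return fl.FibreSource(tip_cm=(1, 1, 1), axis=(0, 0, 1), na=na,
                              pulse_fwhm_ps=fwhm)

    def test_cone_half_angle(self):
        assert math.degrees(self._source().cone_half_angle_rad(1.0)) == \
            pytest.approx(12.709, abs=1e-3)

    def test_directions_confined_to_na_cone(self):
        src = self._source()
        half = src.cone_half_angle_rad(1.33)
        for i in range(500):
            _, d, _ = fl.launch_photon(src, 1.33, seed=5, index=i)
            assert d @ np.array([0, 0, 1.0]) >= math.cos(half) - 1e-12

    def test_degenerate_cone_follows_axis(self):
        src = fl.FibreSource(tip_cm=(1, 1, 1), axis=(0, 0, 1), na=1e-9,
                             pulse_fwhm_ps=0.0)
        _, d, _ = fl.launch_photon(src, 1.0, seed=1, index=3)
        assert np.allclose(d, [0, 0, 1], atol=1e-8)

    def test_delta_pulse_has_zero_offsets(self):
        src = self._source(fwhm=0.0)
        offs = [fl.launch_photon(src, 1.0, seed=2, index=i)[2] for i in range(50)]
        assert offs == [0.0] * 50

    def test_gaussian_pulse_width(self):
        src = self._source(fwhm=100.0)
        offs = np.array([fl.launch_photon(src, 1.0, seed=2, index=i)[2]
                         for i in range(20000)])
        assert abs(offs.std() - 100 / 2.3548200450309493) < 1.5


# ---------------------------------------------------------------------------
# propagation physics
# ---------------------------------------------------------------------------

def _clear_slab(thickness=10.0, n=1.33, mua=0.0):
    nz = max(int(thickness / 0.5), 1)
    return fl.OpticalMedium.homogeneous((8, 8, nz), 0.5, mua, 0.0, 0.0, n=n)


class TestPropagation:
    def test_ballistic_time_of_flight(self):
        # without scattering every transit time is exactly d * n / c
        medium = _clear_slab()
        src = fl.FibreSource(tip_cm=(2, 2, 1e-9 + 0.0), axis=(0, 0, 1),
                             na=1e-9, pulse_fwhm_ps=0.0)
        src.tip_cm[2] = 0.25  # launch from inside the first voxel layer
        rec = fl.run_transport(medium, src, 200, seed=9)
        d = 10.0 - 0.25
        expected = d * 1.33 * PS_PER_CM
        assert len(rec) == 200
        assert np.allclose(rec.t_transit_ps, expected, rtol=1e-9)
        assert np.all(rec.n_scatter == 0)
        assert np.all(rec.label == fl.BALLISTIC)

    def test_beer_lambert_weight(self):
        # pure absorber: exit weight is exactly exp(-mua * d)
        medium = _clear_slab(mua=0.1)
        src = fl.FibreSource(tip_cm=(2, 2, 0.25), axis=(0, 0, 1), na=1e-9,
                             pulse_fwhm_ps=0.0)
        rec = fl.run_transport(medium, src, 50, seed=4)
        assert np.allclose(rec.weight, math.exp(-0.1 * 9.75), rtol=1e-9)

    def test_transit_path_consistency(self, lung_run):
        _, rec, _ = lung_run
        n = rec.meta["n_medium"]
        assert np.allclose(rec.t_transit_ps, rec.path_cm * n * PS_PER_CM,
                           rtol=1e-9)
        assert np.all(rec.weight > 0) and np.all(rec.weight <= 1)
        assert np.all(rec.n_scatter >= 0)

    def test_matches_scalar_oracle(self):
        # kernel agrees with an independent step-by-step re-implementation
        # consuming the identical random substreams
        medium = fl.OpticalMedium.homogeneous((16, 16, 4), 0.25, 0.05, 10.0,
                                              0.9, n=1.4)
        src = fl.FibreSource(tip_cm=(2, 2, 0.5), axis=(0, 0, 1),
                             pulse_fwhm_ps=0.0)
        seed, n = 17, 1000
        rec = fl.run_transport(medium, src, n, seed=seed)
        oracle = [_oracle_photon(medium, src, seed, i) for i in range(n)]
        hits = [(p, ns, w) for r in oracle if r is not None
                for ok, p, ns, w in [r] if ok]
        assert len(hits) == len(rec)
        opath = np.array([h[0] for h in hits])
        onsc = np.array([h[1] for h in hits])
        ow = np.array([h[2] for h in hits])
        assert np.allclose(rec.path_cm, opath, rtol=1e-9)
        assert np.array_equal(rec.n_scatter, onsc)
        assert np.allclose(rec.weight, ow, rtol=1e-9)
        assert rec.n_scatter.mean() == pytest.approx(onsc.mean(), rel=1e-12)

    def test_exit_fraction_consistent_across_budgets(self):
        # small and large runs estimate the same imaged-face exit probability
        medium = fl.OpticalMedium.homogeneous((32, 32, 4), 0.5, 0.05, 10.0,
                                              0.9, n=1.4)
        src = fl.FibreSource(tip_cm=(8, 8, 1.0), axis=(0, 0, 1),
                             pulse_fwhm_ps=0.0)
        big = fl.run_transport(medium, src, 100_000, seed=2)
        small = fl.run_transport(medium, src, 10_000, seed=3)
        p = len(big) / 100_000
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(len(small) / 10_000 - p) < 3 * se

    def test_same_seed_bit_identical(self):
        medium = fl.OpticalMedium.homogeneous((16, 16, 4), 0.5, 0.05, 10.0,
                                              0.9)
        src = fl.FibreSource(tip_cm=(4, 4, 1.0), axis=(1, 0, 0))
        a = fl.run_transport(medium, src, 5000, seed=21)
        b = fl.run_transport(medium, src, 5000, seed=21)
        for attr in ("exit_cm", "direction", "path_cm", "t_transit_ps",
                     "t_emit_ps", "n_scatter", "weight", "label"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))

    def test_tip_outside_medium_rejected(self):
        medium = _clear_slab()
        src = fl.FibreSource(tip_cm=(2, 2, 20.0), axis=(0, 0, 1))
        with pytest.raises(ValueError, match="inside"):
            fl.run_transport(medium, src, 10, seed=0)

    def test_zero_exit_returns_empty_with_warning(self, caplog):
        # opaque absorber: nothing reaches the imaged face
        medium = fl.OpticalMedium.homogeneous((8, 8, 8), 0.5, 1000.0, 0.0, 0.0)
        src = fl.FibreSource(tip_cm=(2, 2, 2), axis=(0, 0, 1), na=1e-9,
                             pulse_fwhm_ps=0.0)
        with caplog.at_level("WARNING"):
            rec = fl.run_transport(medium, src, 20, seed=1)
        assert len(rec) == 0
        assert any("no photons exited" in m for m in caplog.messages)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassification:
    def test_threshold_cases(self):
        src = fl.FibreSource(tip_cm=(0.0, 0.0, 0.0), axis=(0, 0, 1))
        # excess 40 ps -> snake at threshold 100 ps; 1500 ps -> diffuse
        straight = 2.0
        n = 1.0
        base = straight * n * PS_PER_CM
        rec = fl.PhotonRecords(
            exit_cm=np.array([[0, 0, 2.0]] * 3),
            direction=np.array([[0, 0, 1.0]] * 3),
            path_cm=np.zeros(3),
            t_transit_ps=np.array([base, base + 40.0, base + 1500.0]),
            t_emit_ps=np.zeros(3),
            n_scatter=np.array([0, 1, 9], np.int32),
            weight=np.ones(3),
            label=np.full(3, -1, np.int8),
            meta={"n_medium": n, "face_code": 5},
        )
        labels = fl.classify_photon(rec, src)
        assert list(labels) == [fl.BALLISTIC, fl.SNAKE, fl.DIFFUSE]

    def test_labels_partition_all_records(self, lung_run):
        _, rec, _ = lung_run
        assert np.isin(rec.label, [fl.BALLISTIC, fl.SNAKE, fl.DIFFUSE]).all()

    def test_mean_arrival_ordered_by_class(self, milk_run):
        # ballistic <= snake <= diffuse mean arrival times
        _, rec, _ = milk_run
        means = [rec.t_transit_ps[rec.label == lab].mean()
                 for lab in (fl.SNAKE, fl.DIFFUSE)]
        assert means[0] <= means[1]
        if (rec.label == fl.BALLISTIC).any():
            assert rec.t_transit_ps[rec.label == fl.BALLISTIC].mean() <= means[0]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            fl.ClassificationParams(snake_ps=500.0, diffuse_ps=100.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_ballistic_count_nonincreasing_with_thickness(self, seed):
        counts = []
        for thick in (0.5, 1.0, 2.0):
            nz = int(thick / 0.25)
            medium = fl.OpticalMedium.homogeneous((32, 32, nz), 0.25, 0.0,
                                                  10.0, 0.9, n=1.4)
            src = fl.FibreSource(tip_cm=(4.0, 4.0, 0.01), axis=(0, 0, 1),
                                 pulse_fwhm_ps=0.0)
            rec = fl.run_transport(medium, src, 30_000, seed=seed)
            counts.append(int((rec.label == fl.BALLISTIC).sum()))
        assert counts[0] >= counts[1] >= counts[2]


# ---------------------------------------------------------------------------
# type invariants
# ---------------------------------------------------------------------------

class TestTypeValidation:
    def test_medium_invariants(self):
        with pytest.raises(fl.InvalidMediumError):
            fl.OpticalMedium.homogeneous((4, 4, 4), 0.5, -0.1, 10, 0.9)
        with pytest.raises(fl.InvalidMediumError):
            fl.OpticalMedium.homogeneous((4, 4, 4), 0.5, 0.1, -1, 0.9)
        with pytest.raises(fl.InvalidMediumError):
            fl.OpticalMedium.homogeneous((4, 4, 4), 0.5, 0.1, 10, 1.0)
        with pytest.raises(fl.InvalidMediumError):
            fl.OpticalMedium.homogeneous((4, 4, 4), 0.5, 0.1, 10, 0.9, n=0.5)

    def test_source_invariants(self):
        with pytest.raises(ValueError):
            fl.FibreSource(tip_cm=(0, 0, 0), axis=(0, 0, 2.0))
        with pytest.raises(ValueError):
            fl.FibreSource(tip_cm=(0, 0, 0), axis=(0, 0, 1), na=1.5)
        with pytest.raises(ValueError):
            fl.FibreSource(tip_cm=(0, 0, 0), axis=(0, 0, 1), rep_period_ps=0)
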