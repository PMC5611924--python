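"""Monte Carlo photon migration from an embedded fibre tip to an imaged surface.

Photons are launched from the tip of a pulsed fibre source within the
numerical-aperture cone, transported through a voxelized absorbing/scattering
medium (Henyey-Greenstein phase function, continuous absorption weighting,
Russian roulette), and recorded when they exit the imaged face of the medium.
Exiting photons are classified as *ballistic*, *snake* or *diffuse* from their
excess transit time over the straight tip-to-exit flight.

Units used throughout the package: lengths in cm, coefficients in cm^-1,
times in ps.  The vacuum speed of light is ``C_CM_PER_NS``.

Each photon consumes an independent, counter-based random substream derived
from ``(seed, photon_index)`` (splitmix64), so results are bit-reproducible
and independent of batching.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

# speed of light in vacuum, cm / ns
C_CM_PER_NS = 29.9792458

#: transit time (ps) of 1 cm of path at refractive index 1
PS_PER_CM = 1000.0 / C_CM_PER_NS

# photon class labels
BALLISTIC, SNAKE, DIFFUSE = 0, 1, 2
LABEL_NAMES = ("ballistic", "snake", "diffuse")

# transport controls (weight-based variance reduction)
ROULETTE_WEIGHT = 1e-4
ROULETTE_SURVIVAL = 0.1
MAX_SCATTER = 4_000_000  # safety cap; practically unreachable with roulette

_FACE_CODES = {"-x": 0, "+x": 1, "-y": 2, "+y": 3, "-z": 4, "+z": 5}
# outward normals per face code
_FACE_NORMALS = {
    0: (-1.0, 0.0, 0.0),
    1: (1.0, 0.0, 0.0),
    2: (0.0, -1.0, 0.0),
    3: (0.0, 1.0, 0.0),
    4: (0.0, 0.0, -1.0),
    5: (0.0, 0.0, 1.0),
}
# indices of the two in-face coordinate axes (u, v) per face code
_FACE_UV = {0: (1, 2), 1: (1, 2), 2: (0, 2), 3: (0, 2), 4: (0, 1), 5: (0, 1)}


class InvalidMediumError(ValueError):
    """Raised for non-physical optical properties."""


class TransportFaultError(RuntimeError):
    """Raised when a photon state becomes non-finite during transport."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class OpticalMedium:
    """Voxelized slab phantom.

    The medium occupies ``[0, nx*voxel] x [0, ny*voxel] x [0, nz*voxel]`` cm.
    ``mua``/``mus``/``g`` are per-voxel arrays of shape ``(nx, ny, nz)``;
    the refractive index ``n`` is uniform.  ``imaged_face`` names the face
    observed by the camera (one of ``+x -x +y -y +z -z``).
    """

    mua: np.ndarray
    mus: np.ndarray
    g: np.ndarray
    voxel_cm: float
    n: float = 1.4
    imaged_face: str = "+z"

    def __post_init__(self):
        self.mua = np.ascontiguousarray(self.mua, dtype=np.float64)
        self.mus = np.ascontiguousarray(self.mus, dtype=np.float64)
        self.g = np.ascontiguousarray(self.g, dtype=np.float64)
        if self.mua.ndim != 3 or self.mua.shape != self.mus.shape or self.mua.shape != self.g.shape:
            raise InvalidMediumError("mua, mus, g must be 3-D arrays of identical shape")
        if min(self.mua.shape) < 1:
            raise InvalidMediumError("grid dimensions must be >= 1")
        if np.any(self.mua < 0):
            raise InvalidMediumError("absorption coefficient mua must be >= 0 everywhere")
        if np.any(self.mus < 0):
            raise InvalidMediumError("scattering coefficient mus must be >= 0 everywhere")
        if np.any(np.abs(self.g) >= 1):
            raise InvalidMediumError("anisotropy g must satisfy -1 < g < 1")
        if not self.voxel_cm > 0:
            raise InvalidMediumError("voxel edge length must be > 0")
        if self.n < 1:
            raise InvalidMediumError("refractive index must be >= 1")
        if self.imaged_face not in _FACE_CODES:
            raise InvalidMediumError(f"unknown imaged face {self.imaged_face!r}")

    @classmethod
    def homogeneous(cls, shape, voxel_cm, mua, mus, g, n=1.4, imaged_face="+z"):
        """Uniform medium of grid ``shape = (nx, ny, nz)``."""
        shape = tuple(int(s) for s in shape)
        return cls(
            mua=np.full(shape, float(mua)),
            mus=np.full(shape, float(mus)),
            g=np.full(shape, float(g)),
            voxel_cm=float(voxel_cm),
            n=float(n),
            imaged_face=imaged_face,
        )

    @property
    def shape(self):
        return self.mua.shape

    @property
    def extent_cm(self):
        """Physical size (Lx, Ly, Lz) in cm."""
        return tuple(s * self.voxel_cm for s in self.shape)

    @property
    def face_code(self) -> int:
        return _FACE_CODES[self.imaged_face]

    @property
    def face_normal(self):
        return np.array(_FACE_NORMALS[self.face_code])

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        lo = np.zeros(3)
        hi = np.array(self.extent_cm)
        return bool(np.all(p > lo) and np.all(p < hi))


@dataclass
class FibreSource:
    """Pulsed point-like emitter at the fibre tip.

    Emission directions are uniform within the cone of half-angle
    ``arcsin(min(NA/n, 1))`` about ``axis`` (the in-medium acceptance cone);
    emission times are Gaussian with the configured FWHM, centred at t=0.
    """

    tip_cm: np.ndarray
    axis: np.ndarray
    na: float = 0.22
    wavelength_nm: float = 785.0
    rep_period_ps: float = 12_500.0
    pulse_fwhm_ps: float = 50.0
    n_photons: int = 1_000_000

    def __post_init__(self):
        self.tip_cm = np.asarray(self.tip_cm, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        norm = float(np.linalg.norm(self.axis))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("emission axis must have unit norm (within 1e-9)")
        self.axis = self.axis / norm
        if not 0 < self.na < 1:
            raise ValueError("numerical aperture must lie in (0, 1)")
        if not self.rep_period_ps > 0:
            raise ValueError("pulse repetition period must be > 0")
        if self.pulse_fwhm_ps < 0:
            raise ValueError("pulse FWHM must be >= 0")
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")

    def cone_half_angle_rad(self, n_medium: float) -> float:
        """In-medium emission-cone half-angle, clamped to pi/2."""
        return math.asin(min(self.na / n_medium, 1.0))


@dataclass
class ClassificationParams:
    """Excess-time thresholds separating snake from ballistic and diffuse.

    ``snake_ps`` (~2 TDC bins by default) bounds the weakly scattered class;
    ``diffuse_ps`` reflects the ~1 ns delays of heavily scattered light.
    """

    snake_ps: float = 100.0
    diffuse_ps: float = 1000.0
    ballistic_eps_ps: float = 1e-6

    def __post_init__(self):
        if not 0 < self.snake_ps < self.diffuse_ps:
            raise ValueError("thresholds must satisfy 0 < snake_ps < diffuse_ps")


@dataclass
class PhotonRecords:
    """Column-oriented collection of exit records from one transport run.

    ``t_transit_ps`` is the in-medium flight time (= path * n / c, exactly);
    the camera sees ``arrival_ps = t_emit_ps + t_transit_ps``.
    """

    exit_cm: np.ndarray        # (n, 3) exit positions on the imaged face
    direction: np.ndarray      # (n, 3) unit exit directions
    path_cm: np.ndarray        # (n,) total optical path length
    t_transit_ps: np.ndarray   # (n,)
    t_emit_ps: np.ndarray      # (n,) emission offset within the pulse
    n_scatter: np.ndarray      # (n,) int32
    weight: np.ndarray         # (n,) in (0, 1]
    label: np.ndarray          # (n,) int8; -1 = unclassified
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return self.exit_cm.shape[0]

    @property
    def arrival_ps(self) -> np.ndarray:
        return self.t_emit_ps + self.t_transit_ps

    @property
    def uv_cm(self) -> np.ndarray:
        """Exit positions in the imaged-face (u, v) surface coordinates."""
        iu, iv = _FACE_UV[self.meta.get("face_code", 5)]
        return self.exit_cm[:, (iu, iv)]

    @classmethod
    def empty(cls, meta: Optional[dict] = None) -> "PhotonRecords":
        return cls(
            exit_cm=np.empty((0, 3)), direction=np.empty((0, 3)),
            path_cm=np.empty(0), t_transit_ps=np.empty(0), t_emit_ps=np.empty(0),
            n_scatter=np.empty(0, np.int32), weight=np.empty(0),
            label=np.full(0, -1, np.int8), meta=dict(meta or {}),
        )


# --------------------------------------------------------------------------
# counter-based RNG (splitmix64) — one substream per photon
# --------------------------------------------------------------------------

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_STREAM = np.uint64(0xD1B54A32D192ED03)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _stream_init(seed, i):
    return _mix64((seed + np.uint64(1)) * _GOLDEN ^ (i + np.uint64(1)) * _STREAM)


@njit(cache=True, inline="always")
def _next_uniform(st):
    """Uniform variate in (0, 1]; advances the stream in place."""
    st[0] = st[0] + _GOLDEN
    z = _mix64(st[0])
    return ((z >> np.uint64(11)) + np.uint64(1)) * _INV53


# --------------------------------------------------------------------------
# elementary sampling kernels
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _free_path(mu_t, u):
    return -math.log(u) / mu_t


@njit(cache=True, inline="always")
def _hg_cosine(g, u):
    if g == 0.0:
        return 2.0 * u - 1.0
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - s * s) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, cosp, sinp):
    """Deflect unit vector (ux,uy,uz) by polar angle acos(cost), azimuth phi."""
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost if uz > 0.0 else -cost
    else:
        tmp = math.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / tmp + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / tmp + uy * cost
        nz = -sint * cosp * tmp + uz * cost
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _launch(tipx, tipy, tipz, ax, ay, az, cos_half, sigma_ps, st):
    """Draw emission direction within the NA cone and a Gaussian time offset."""
    u1 = _next_uniform(st)
    u2 = _next_uniform(st)
    cost = 1.0 - u1 * (1.0 - cos_half)
    phi = 2.0 * math.pi * u2
    dx, dy, dz = _rotate(ax, ay, az, cost, math.cos(phi), math.sin(phi))
    t0 = 0.0
    if sigma_ps > 0.0:
        ua = _next_uniform(st)
        ub = _next_uniform(st)
        t0 = sigma_ps * math.sqrt(-2.0 * math.log(ua)) * math.cos(2.0 * math.pi * ub)
    return tipx, tipy, tipz, dx, dy, dz, t0


@njit(cache=True)
def _propagate(mua, mus, gg, voxel, face, x, y, z, dx, dy, dz, st):
    """Trace one photon until it exits the medium or is terminated.

    Returns (status, x, y, z, dx, dy, dz, path_cm, n_scatter, weight) with
    status 1 = exited the imaged face, 2 = exited another face,
    0 = terminated (roulette), 3 = numerical fault.

    Scattering flight lengths are sampled against the voxel-local mus;
    absorption reduces the statistical weight continuously along the path
    (implicit capture), with Russian roulette below ROULETTE_WEIGHT.
    """
    nx_, ny_, nz_ = mua.shape
    big = 1e30
    path = 0.0
    w = 1.0
    nsc = 0
    ix = int(x / voxel)
    iy = int(y / voxel)
    iz = int(z / voxel)
    if ix < 0 or ix >= nx_ or iy < 0 or iy >= ny_ or iz < 0 or iz >= nz_:
        return 3, x, y, z, dx, dy, dz, path, nsc, w
    while True:
        tau = -math.log(_next_uniform(st))  # scattering optical depth
        while True:
            musl = mus[ix, iy, iz]
            mual = mua[ix, iy, iz]
            # distance to the nearest voxel boundary along the flight
            if dx > 0.0:
                tx = ((ix + 1) * voxel - x) / dx
            elif dx < 0.0:
                tx = (ix * voxel - x) / dx
            else:
                tx = big
            if dy > 0.0:
                ty = ((iy + 1) * voxel - y) / dy
            elif dy < 0.0:
                ty = (iy * voxel - y) / dy
            else:
                ty = big
            if dz > 0.0:
                tz = ((iz + 1) * voxel - z) / dz
            elif dz < 0.0:
                tz = (iz * voxel - z) / dz
            else:
                tz = big
            tb = min(tx, ty, tz)
            if tb < 0.0:
                tb = 0.0
            if musl > 0.0 and musl * tb >= tau:
                # scattering site inside this voxel
                step = tau / musl
                x += dx * step
                y += dy * step
                z += dz * step
                path += step
                w *= math.exp(-mual * step)
                break
            # traverse to the voxel boundary
            x += dx * tb
            y += dy * tb
            z += dz * tb
            path += tb
            w *= math.exp(-mual * tb)
            tau -= musl * tb
            # roulette also during flights, so pure absorbers terminate
            if w < ROULETTE_WEIGHT:
                if w <= 0.0:
                    return 0, x, y, z, dx, dy, dz, path, nsc, w
                if _next_uniform(st) < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL
                else:
                    return 0, x, y, z, dx, dy, dz, path, nsc, w
            if tx <= ty and tx <= tz:
                if dx > 0.0:
                    ix += 1
                    x = ix * voxel
                    if ix >= nx_:
                        return (1 if face == 1 else 2), x, y, z, dx, dy, dz, path, nsc, w
                else:
                    x = ix * voxel
                    ix -= 1
                    if ix < 0:
                        return (1 if face == 0 else 2), x, y, z, dx, dy, dz, path, nsc, w
            elif ty <= tz:
                if dy > 0.0:
                    iy += 1
                    y = iy * voxel
                    if iy >= ny_:
                        return (1 if face == 3 else 2), x, y, z, dx, dy, dz, path, nsc, w
                else:
                    y = iy * voxel
                    iy -= 1
                    if iy < 0:
                        return (1 if face == 2 else 2), x, y, z, dx, dy, dz, path, nsc, w
            else:
                if dz > 0.0:
                    iz += 1
                    z = iz * voxel
                    if iz >= nz_:
                        return (1 if face == 5 else 2), x, y, z, dx, dy, dz, path, nsc, w
                else:
                    z = iz * voxel
                    iz -= 1
                    if iz < 0:
                        return (1 if face == 4 else 2), x, y, z, dx, dy, dz, path, nsc, w
        # Russian roulette on low-weight photons
        if w < ROULETTE_WEIGHT:
            if _next_uniform(st) < ROULETTE_SURVIVAL:
                w /= ROULETTE_SURVIVAL
            else:
                return 0, x, y, z, dx, dy, dz, path, nsc, w
        # Henyey-Greenstein deflection
        gl = gg[ix, iy, iz]
        cost = _hg_cosine(gl, _next_uniform(st))
        phi = 2.0 * math.pi * _next_uniform(st)
        dx, dy, dz = _rotate(dx, dy, dz, cost, math.cos(phi), math.sin(phi))
        nsc += 1
        if nsc >= MAX_SCATTER:
            return 0, x, y, z, dx, dy, dz, path, nsc, w
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)
                and math.isfinite(dx) and math.isfinite(dy) and math.isfinite(dz)):
            return 3, x, y, z, dx, dy, dz, path, nsc, w


@njit(cache=True)
def _run_kernel(mua, mus, gg, voxel, face,
                tipx, tipy, tipz, ax, ay, az, cos_half, sigma_ps,
                n_photons, seed, out):
    """Transport n_photons; fill `out` rows for imaged-face exits.

    Returns the number of exit records, or -(i+1) on a numerical fault in
    photon i.
    """
    st = np.empty(1, np.uint64)
    cnt = 0
    for i in range(n_photons):
        st[0] = _stream_init(np.uint64(seed), np.uint64(i))
        x, y, z, dx, dy, dz, t0 = _launch(tipx, tipy, tipz, ax, ay, az,
                                          cos_half, sigma_ps, st)
        status, ex, ey, ez, fdx, fdy, fdz, path, nsc, w = _propagate(
            mua, mus, gg, voxel, face, x, y, z, dx, dy, dz, st)
        if status == 1:
            out[cnt, 0] = ex
            out[cnt, 1] = ey
            out[cnt, 2] = ez
            out[cnt, 3] = fdx
            out[cnt, 4] = fdy
            out[cnt, 5] = fdz
            out[cnt, 6] = path
            out[cnt, 7] = nsc
            out[cnt, 8] = w
            out[cnt, 9] = t0
            cnt += 1
        elif status == 3:
            return -(i + 1)
    return cnt


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def sample_free_path(mu_t, u):
    """Exponential free-path length ``-ln(u)/mu_t`` (cm).

    ``u`` is a uniform variate in (0, 1]; accepts arrays.
    """
    mu_t = np.asarray(mu_t, dtype=float)
    if np.any(mu_t <= 0):
        raise InvalidMediumError("total attenuation mu_t must be > 0")
    u = np.asarray(u, dtype=float)
    out = -np.log(u) / mu_t
    return float(out) if out.ndim == 0 else out


def sample_hg_cosine(g, u):
    """Henyey-Greenstein deflection cosine by inverse-CDF sampling.

    For g = 0 this reduces to the isotropic ``2u - 1``; results are clamped
    to [-1, 1].  Accepts arrays in ``u``.
    """
    g = float(g)
    if abs(g) >= 1:
        raise InvalidMediumError("anisotropy g must satisfy -1 < g < 1")
    u = np.asarray(u, dtype=float)
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = np.clip((1.0 + g * g - s * s) / (2.0 * g), -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def launch_photon(source: FibreSource, n_medium: float, seed: int, index: int = 0):
    """Initial state of photon ``index`` of a run: (position, direction, t_emit_ps)."""
    st = np.empty(1, np.uint64)
    st[0] = _stream_init(np.uint64(seed), np.uint64(index))
    cos_half = math.cos(source.cone_half_angle_rad(n_medium))
    sigma = source.pulse_fwhm_ps / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    x, y, z, dx, dy, dz, t0 = _launch(
        source.tip_cm[0], source.tip_cm[1], source.tip_cm[2],
        source.axis[0], source.axis[1], source.axis[2], cos_half, sigma, st)
    return np.array([x, y, z]), np.array([dx, dy, dz]), t0


def propagate_photon(medium: OpticalMedium, position, direction,
                     seed: int = 0, index: int = 0, t_emit_ps: float = 0.0):
    """Trace a single photon from ``position`` along ``direction``.

    Returns a one-row :class:`PhotonRecords` if the photon exits the imaged
    face, ``None`` if it is absorbed or leaves through another face.
    """
    position = np.asarray(position, dtype=float)
    if not medium.contains(position):
        raise ValueError("initial position must lie strictly inside the medium")
    st = np.empty(1, np.uint64)
    st[0] = _stream_init(np.uint64(seed), np.uint64(index))
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    status, ex, ey, ez, dx, dy, dz, path, nsc, w = _propagate(
        medium.mua, medium.mus, medium.g, medium.voxel_cm, medium.face_code,
        position[0], position[1], position[2], d[0], d[1], d[2], st)
    if status == 3:
        raise TransportFaultError(f"non-finite photon state (photon index {index})")
    if status != 1:
        return None
    meta = {"n_medium": medium.n, "face_code": medium.face_code,
            "normal": medium.face_normal, "n_launched": 1, "seed": seed}
    return PhotonRecords(
        exit_cm=np.array([[ex, ey, ez]]),
        direction=np.array([[dx, dy, dz]]),
        path_cm=np.array([path]),
        t_transit_ps=np.array([path * medium.n * PS_PER_CM]),
        t_emit_ps=np.array([t_emit_ps]),
        n_scatter=np.array([nsc], np.int32),
        weight=np.array([w]),
        label=np.full(1, -1, np.int8),
        meta=meta,
    )


def classify_photon(records: PhotonRecords, source: FibreSource,
                    params: Optional[ClassificationParams] = None) -> np.ndarray:
    """Label records ballistic / snake / diffuse by excess transit time.

    The excess is the transit time minus the straight-line tip-to-exit
    flight time at the medium index; the three labels partition all records.
    """
    params = params or ClassificationParams()
    n_medium = records.meta["n_medium"]
    straight = np.linalg.norm(records.exit_cm - source.tip_cm, axis=1)
    excess = records.t_transit_ps - straight * n_medium * PS_PER_CM
    labels = np.full(len(records), DIFFUSE, np.int8)
    labels[excess <= params.snake_ps] = SNAKE
    labels[excess <= params.ballistic_eps_ps] = BALLISTIC
    return labels


def run_transport(medium: OpticalMedium, source: FibreSource,
                  n_photons: Optional[int] = None, seed: int = 0,
                  params: Optional[ClassificationParams] = None) -> PhotonRecords:
    """Transport ``n_photons`` from the fibre tip; return labelled exit records.

    Reproducible bit-for-bit for a fixed seed.  A run in which no photon
    reaches the imaged face returns an empty collection (with a warning).
    """
    if n_photons is None:
        n_photons = source.n_photons
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if not medium.contains(source.tip_cm):
        raise ValueError("fibre tip must lie strictly inside the medium")
    cos_half = math.cos(source.cone_half_angle_rad(medium.n))
    sigma = source.pulse_fwhm_ps / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    out = np.empty((n_photons, 10))
    cnt = _run_kernel(
        medium.mua, medium.mus, medium.g, medium.voxel_cm, medium.face_code,
        source.tip_cm[0], source.tip_cm[1], source.tip_cm[2],
        source.axis[0], source.axis[1], source.axis[2],
        cos_half, sigma, n_photons, seed, out)
    if cnt < 0:
        raise TransportFaultError(f"non-finite photon state (photon index {-cnt - 1})")
    out = out[:cnt]
    meta = {
        "seed": int(seed),
        "n_launched": int(n_photons),
        "n_medium": float(medium.n),
        "face_code": medium.face_code,
        "normal": medium.face_normal,
        "rep_period_ps": float(source.rep_period_ps),
        "tip_cm": source.tip_cm.tolist(),
        "axis": source.axis.tolist(),
        "na": float(source.na),
        "pulse_fwhm_ps": float(source.pulse_fwhm_ps),
    }
    records = PhotonRecords(
        exit_cm=out[:, 0:3].copy(),
        direction=out[:, 3:6].copy(),
        path_cm=out[:, 6].copy(),
        t_transit_ps=out[:, 6] * medium.n * PS_PER_CM,
        t_emit_ps=out[:, 9].copy(),
        n_scatter=out[:, 7].astype(np.int32),
        weight=out[:, 8].copy(),
        label=np.full(cnt, -1, np.int8),
        meta=meta,
    )
    if cnt == 0:
        logger.warning("run_transport: no photons exited the imaged face "
                       "(n_photons=%d, seed=%d)", n_photons, seed)
    records.label = classify_photon(records, source, params)
    return records
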