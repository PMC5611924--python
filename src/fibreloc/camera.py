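"""SPAD-array TCSPC camera model: projection, detection, IRF, binning, noise.

Converts exit records from the transport stage into a time-correlated
single-photon-counting (TCSPC) data cube: a ``(nx, ny, nt)`` histogram of
photon arrival times over many repetitions of the laser pulse.  The model
covers the orthographic lens projection with an angular acceptance gate,
photon detection efficiency and pixel fill factor, Gaussian (or tabulated)
instrument-response-function jitter, TDC binning, dark counts,
unsynchronised ambient background (a flat addition to every histogram), and
an optional first-photon-per-frame pileup mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .transport import PhotonRecords

logger = logging.getLogger(__name__)

#: Gaussian FWHM / sigma
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: default IRF: 200 ps FWHM detector jitter
DEFAULT_IRF_SIGMA_PS = 200.0 / _FWHM


def window_from_rep_rate_hz(rate_hz: float) -> float:
    """Histogram window (ps) for a laser repetition rate; 80 MHz -> 12 500 ps."""
    if not rate_hz > 0:
        raise ValueError("repetition rate must be > 0")
    return 1e12 / rate_hz


@dataclass
class CameraModel:
    """Detector-array and acquisition description.

    Defaults follow a 32 x 32 SPAD array timing arrivals in 50 ps TDC bins
    with 200 ps jitter over a 12.5 ns window, a ~1% fill factor, and an
    object-plane pixel pitch of 1 cm.
    """

    nx: int = 32
    ny: int = 32
    pitch_cm: float = 1.0
    accept_half_deg: float = 15.0
    pde: float = 0.2
    fill_factor: float = 0.01
    irf_sigma_ps: float = DEFAULT_IRF_SIGMA_PS
    irf_kernel: Optional[np.ndarray] = None   # tabulated over TDC bins
    irf_origin_bin: int = 0                   # kernel index corresponding to zero delay
    tdc_bin_ps: float = 50.0
    window_ps: float = 12_500.0
    trigger_delay_ps: float = 500.0
    dark_hz: float = 40.0
    background_hz: float = 0.0
    wrap_late: bool = False
    fov_origin_cm: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("pixel grid dimensions must be >= 1")
        if not self.pitch_cm > 0:
            raise ValueError("pixel pitch must be > 0")
        if not 0 <= self.pde <= 1:
            raise ValueError("photon detection efficiency must lie in [0, 1]")
        if not 0 <= self.fill_factor <= 1:
            raise ValueError("fill factor must lie in [0, 1]")
        if not self.tdc_bin_ps > 0 or not self.window_ps > 0:
            raise ValueError("TDC bin width and window must be > 0")
        ratio = self.window_ps / self.tdc_bin_ps
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("histogram window must be an integer multiple of the bin width")
        if self.irf_kernel is not None:
            self.irf_kernel = np.asarray(self.irf_kernel, dtype=float)
            if abs(self.irf_kernel.sum() - 1.0) > 1e-9:
                raise ValueError("tabulated IRF kernel must sum to 1 (within 1e-9)")
            if np.any(self.irf_kernel < 0):
                raise ValueError("IRF kernel entries must be >= 0")
        if self.dark_hz < 0 or self.background_hz < 0:
            raise ValueError("dark and background rates must be >= 0")

    @property
    def nt(self) -> int:
        return int(round(self.window_ps / self.tdc_bin_ps))

    @property
    def cos_accept(self) -> float:
        return math.cos(math.radians(self.accept_half_deg))


@dataclass
class TCSPCCube:
    """Per-pixel arrival-time histograms: counts of shape ``(nx, ny, nt)``.

    ``counts`` is integer for raw acquisitions; baseline-subtracted cubes
    carry non-negative floats.  ``meta`` records provenance (seed, scenario,
    noise totals, field-of-view origin...).
    """

    counts: np.ndarray
    bin_ps: float
    window_ps: float
    exposure_s: float
    pulse_count: int
    pitch_cm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (nx, ny, nt)")
        if self.counts.shape[2] != int(round(self.window_ps / self.bin_ps)):
            raise ValueError("nt must equal window / bin width")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def nt(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self):
        return self.counts.shape

    def bin_centres_ps(self) -> np.ndarray:
        return (np.arange(self.nt) + 0.5) * self.bin_ps

    def copy(self, counts: Optional[np.ndarray] = None) -> "TCSPCCube":
        return TCSPCCube(
            counts=self.counts.copy() if counts is None else counts,
            bin_ps=self.bin_ps, window_ps=self.window_ps,
            exposure_s=self.exposure_s, pulse_count=self.pulse_count,
            pitch_cm=self.pitch_cm, meta=dict(self.meta),
        )


# --------------------------------------------------------------------------
# projection and detection
# --------------------------------------------------------------------------

def project_exit(records: PhotonRecords, camera: CameraModel):
    """Map exit records to pixel indices.

    A record is accepted iff its exit direction lies within the camera's
    acceptance half-angle of the optical axis (the imaged-face outward
    normal) and its exit position falls inside the field of view.  Pixels
    use half-open binning: ``pixel = floor((uv - fov_origin) / pitch)``,
    0-based, x rightward and y upward.

    Returns ``(px, py, accepted)`` arrays.
    """
    normal = np.asarray(records.meta.get("normal", (0.0, 0.0, 1.0)), dtype=float)
    uv = records.uv_cm
    along = records.direction @ normal
    ok = along >= camera.cos_accept
    rel = (uv - np.asarray(camera.fov_origin_cm)) / camera.pitch_cm
    px = np.floor(rel[:, 0]).astype(np.int64)
    py = np.floor(rel[:, 1]).astype(np.int64)
    ok &= (px >= 0) & (px < camera.nx) & (py >= 0) & (py < camera.ny)
    return px, py, ok


def detect_photon(records: PhotonRecords, camera: CameraModel,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-record Bernoulli detection with p = PDE x fill factor x weight."""
    p = camera.pde * camera.fill_factor * records.weight
    return rng.random(len(records)) < p


def _sample_irf_offsets(camera: CameraModel, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    if camera.irf_kernel is not None:
        j = rng.choice(len(camera.irf_kernel), size=size, p=camera.irf_kernel)
        return (j - camera.irf_origin_bin) * camera.tdc_bin_ps
    if camera.irf_sigma_ps > 0:
        return rng.normal(0.0, camera.irf_sigma_ps, size)
    return np.zeros(size)


def smear_and_bin(t_ps, camera: CameraModel, rng: np.random.Generator):
    """Apply IRF jitter and TDC quantization to arrival times.

    Returns ``(bins, kept)``: the TDC bin index per time and a boolean mask.
    Times landing outside the window are wrapped modulo the window when the
    camera's ``wrap_late`` flag is set, otherwise discarded (``kept=False``).
    """
    t = np.atleast_1d(np.asarray(t_ps, dtype=float))
    if not np.all(np.isfinite(t)):
        raise ValueError("arrival times must be finite")
    t = t + _sample_irf_offsets(camera, t.size, rng)
    if camera.wrap_late:
        t = np.mod(t, camera.window_ps)
        kept = np.ones(t.size, bool)
    else:
        kept = (t >= 0) & (t < camera.window_ps)
    bins = np.floor(t / camera.tdc_bin_ps).astype(np.int64)
    bins = np.clip(bins, 0, camera.nt - 1)  # guard exact window edge after wrap
    return bins, kept


# --------------------------------------------------------------------------
# cube accumulation
# --------------------------------------------------------------------------

def _noise_expectation(camera: CameraModel, exposure_s: float) -> float:
    """Expected dark + unsynchronised-background counts per pixel per bin."""
    return (camera.dark_hz + camera.background_hz) * exposure_s / camera.nt


def accumulate_cube(records: PhotonRecords, camera: CameraModel,
                    exposure_s: float, pulses_per_frame: int = 160,
                    mode: str = "poisson", seed: int = 0,
                    rep_period_ps: Optional[float] = None) -> TCSPCCube:
    """Histogram detections from ``records`` over a full exposure.

    The record set is treated as an unbiased sample of the per-pulse exit
    flux: each record contributes an expected
    ``(pulse_count / n_launched) * PDE * fill * weight`` detections over the
    exposure.  Dark counts and unsynchronised background enter as Poisson
    draws, uniform across bins.  ``mode="poisson"`` (default) draws
    independent counts per bin; ``mode="first-photon"`` emulates pileup by
    keeping at most one (the earliest) timestamp per pixel per frame of
    ``pulses_per_frame`` laser pulses.
    """
    if not exposure_s > 0:
        raise ValueError("exposure must be > 0")
    if pulses_per_frame < 1:
        raise ValueError("pulses per frame must be >= 1")
    if mode not in ("poisson", "first-photon"):
        raise ValueError(f"unknown pileup mode {mode!r}")
    rep = rep_period_ps or records.meta.get("rep_period_ps")
    if rep is None:
        raise ValueError("repetition period not given and absent from record metadata")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5CAD]))
    pulses = int(round(exposure_s * 1e12 / rep))
    n_launched = int(records.meta.get("n_launched", max(len(records), 1)))
    nt = camera.nt

    px, py, ok = project_exit(records, camera)
    px, py = px[ok], py[ok]
    # electronic trigger delay places the signal away from the window edge
    t_arr = records.arrival_ps[ok] + camera.trigger_delay_ps
    lam = (pulses / n_launched) * camera.pde * camera.fill_factor * records.weight[ok]

    counts = np.zeros((camera.nx, camera.ny, nt), np.int64)
    meta = {
        "seed": int(seed),
        "mode": mode,
        "pulses_per_frame": int(pulses_per_frame),
        "fov_origin_cm": tuple(camera.fov_origin_cm),
        "rep_period_ps": float(rep),
        "n_records_accepted": int(px.size),
    }
    for key in ("scenario", "tip_cm", "true_pixel", "n_launched"):
        if key in records.meta:
            meta[key] = records.meta[key]

    if mode == "poisson":
        k = rng.poisson(lam)
        rep_idx = np.repeat(np.arange(px.size), k)
        times = np.repeat(t_arr, k)
        bins, kept = smear_and_bin(times, camera, rng) if times.size else (
            np.empty(0, np.int64), np.empty(0, bool))
        fx, fy, fb = px[rep_idx][kept], py[rep_idx][kept], bins[kept]
        np.add.at(counts, (fx, fy, fb), 1)
        signal_binned = int(kept.sum())
        signal_discarded = int((~kept).sum())
        noise_mu = _noise_expectation(camera, exposure_s)
        dark_bg = rng.poisson(noise_mu, size=counts.shape) if noise_mu > 0 else np.zeros_like(counts)
        counts += dark_bg
        meta.update(signal_binned=signal_binned, signal_discarded=signal_discarded,
                    noise_total=int(dark_bg.sum()))
    else:
        counts, extra = _accumulate_first_photon(
            camera, exposure_s, pulses, pulses_per_frame, px, py, t_arr, lam, rng)
        meta.update(extra)

    return TCSPCCube(
        counts=counts.astype(np.uint32),
        bin_ps=camera.tdc_bin_ps, window_ps=camera.window_ps,
        exposure_s=float(exposure_s), pulse_count=pulses,
        pitch_cm=camera.pitch_cm, meta=meta,
    )


def _accumulate_first_photon(camera, exposure_s, pulses, m, px, py, t_arr, lam, rng):
    """First-photon pileup accumulation: earliest candidate per pixel per frame."""
    nt = camera.nt
    frames = max(pulses // m, 1)
    counts = np.zeros((camera.nx, camera.ny, nt), np.int64)
    noise_per_pixel = (camera.dark_hz + camera.background_hz) * exposure_s
    flat = px * camera.ny + py
    order = np.argsort(flat, kind="stable")
    flat_s, t_s, lam_s = flat[order], t_arr[order], lam[order]
    bounds = np.searchsorted(flat_s, np.arange(camera.nx * camera.ny + 1))
    saturated = False
    total_kept = 0
    for p in range(camera.nx * camera.ny):
        lo, hi = bounds[p], bounds[p + 1]
        lam_p = lam_s[lo:hi]
        sig_total = float(lam_p.sum())
        expected = sig_total + noise_per_pixel
        if expected <= 0:
            continue
        if expected / frames > 1.0:
            saturated = True
        kcand = rng.poisson(expected)
        if kcand == 0:
            continue
        fid = rng.integers(0, frames, kcand)
        is_sig = rng.random(kcand) < sig_total / expected
        times = np.empty(kcand)
        nsig = int(is_sig.sum())
        if nsig:
            ridx = rng.choice(hi - lo, size=nsig, p=lam_p / sig_total) if hi - lo > 1 \
                else np.zeros(nsig, np.int64)
            times[is_sig] = t_s[lo:hi][ridx] + _sample_irf_offsets(camera, nsig, rng)
        times[~is_sig] = rng.random(kcand - nsig) * camera.window_ps
        if camera.wrap_late:
            times = np.mod(times, camera.window_ps)
        else:
            keep = (times >= 0) & (times < camera.window_ps)
            fid, times = fid[keep], times[keep]
            if times.size == 0:
                continue
        srt = np.lexsort((times, fid))
        fid, times = fid[srt], times[srt]
        first = np.ones(fid.size, bool)
        first[1:] = fid[1:] != fid[:-1]
        tw = times[first]
        bins = np.clip(np.floor(tw / camera.tdc_bin_ps).astype(np.int64), 0, nt - 1)
        counts[p // camera.ny, p % camera.ny] += np.bincount(bins, minlength=nt)
        total_kept += tw.size
    if saturated:
        logger.warning("first-photon mode: expected per-pixel per-frame occupancy "
                       "exceeds 1; histograms will be pileup-distorted")
    return counts, {"signal_binned": int(total_kept), "frames": int(frames),
                    "saturated": bool(saturated)}
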