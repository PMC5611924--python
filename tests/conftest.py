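"""Shared fixtures and independent reference helpers for the test suite."""

import numpy as np
import pytest

import fibreloc as fl


# --------------------------------------------------------------------------
# session-scoped simulation runs (reused by many tests)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def lung_run():
    """Lung-like slab, seed 1, full photon budget."""
    sc = fl.get_scenario("lung_slab")
    records, cube = fl.simulate(sc, seed=1)
    return sc, records, cube


@pytest.fixture(scope="session")
def milk_run():
    """Milk-tank colloid scenario, seed 1."""
    sc = fl.get_scenario("milk_tank")
    records, cube = fl.simulate(sc, seed=1)
    return sc, records, cube


@pytest.fixture(scope="session")
def coil_run():
    """Fibre-coil light-in-flight scenario, seed 1."""
    sc = fl.get_scenario("fibre_coil")
    records, cube = fl.simulate(sc, seed=1)
    return sc, records, cube


# --------------------------------------------------------------------------
# synthetic record/cube construction helpers
# --------------------------------------------------------------------------

def make_records(uv, direction, t_transit, weight, n_launched=None,
                 rep_period_ps=12_500.0, n_medium=1.0):
    """Hand-built photon records on the +z face (camera-plane synthetic input)."""
    uv = np.atleast_2d(np.asarray(uv, float))
    n = uv.shape[0]
    d = np.tile(np.asarray(direction, float), (n, 1)) if np.ndim(direction) == 1 \
        else np.asarray(direction, float)
    return fl.PhotonRecords(
        exit_cm=np.column_stack([uv, np.zeros(n)]),
        direction=d,
        path_cm=np.zeros(n),
        t_transit_ps=np.asarray(t_transit, float) * np.ones(n),
        t_emit_ps=np.zeros(n),
        n_scatter=np.zeros(n, np.int32),
        weight=np.asarray(weight, float) * np.ones(n),
        label=np.full(n, -1, np.int8),
        meta={"n_launched": int(n_launched or n), "rep_period_ps": rep_period_ps,
              "n_medium": n_medium, "face_code": 5,
              "normal": np.array([0.0, 0.0, 1.0])},
    )


def make_cube(counts, bin_ps=50.0, exposure_s=1.0, pitch_cm=1.0, meta=None):
    counts = np.asarray(counts)
    return fl.TCSPCCube(
        counts=counts, bin_ps=bin_ps, window_ps=bin_ps * counts.shape[2],
        exposure_s=exposure_s, pulse_count=1000, pitch_cm=pitch_cm,
        meta=dict(meta or {}),
    )


def make_toy_cube(rng, nx=8, ny=8, nt=64, bin_ps=50.0):
    """Noise-free toy cube with known per-pixel first-arrival onsets.

    Injects a shifted pulse (3-bin linear rise, exponential tail) into a
    random subset of pixels; onset bins are unique so the earliest pixel is
    unambiguous.  Returns (cube, true_pixel, onset_bins).
    """
    counts = np.zeros((nx, ny, nt))
    n_lit = int(rng.integers(4, 12))
    pix = rng.choice(nx * ny, size=n_lit, replace=False)
    onsets = rng.choice(np.arange(5, nt - 15), size=n_lit, replace=False)
    shape = np.concatenate([np.array([0.25, 0.6, 1.0]),
                            np.exp(-np.arange(8) / 3.0)])
    for p, onset in zip(pix, onsets):
        amp = rng.uniform(30, 300)
        counts[p // ny, p % ny, onset:onset + len(shape)] += amp * shape
    best = pix[onsets.argmin()]
    return make_cube(counts, bin_ps=bin_ps), (best // ny, best % ny), onsets


def brute_force_edge(trace, bin_ps, f=0.25, min_counts=10.0):
    """Independent scalar leading-edge scan (no smoothing), bin-centred.

    Walks backward from the peak to the last sample below the constant
    fraction, then interpolates the crossing on the rising flank.
    """
    peak = trace.max()
    if peak < min_counts:
        return None
    thr = f * peak
    i_peak = int(trace.argmax())
    j = i_peak - 1
    while j >= 0 and trace[j] >= thr:
        j -= 1
    if j < 0:
        return 0.5 * bin_ps
    prev, cur = trace[j], trace[j + 1]
    return (j + 0.5 + (thr - prev) / (cur - prev)) * bin_ps


def brute_force_locate(cube, f=0.25, min_counts=10.0):
    """Exhaustive earliest-arrival scan over all pixel traces."""
    best, best_t = None, np.inf
    nx, ny, _ = cube.counts.shape
    for x in range(nx):
        for y in range(ny):
            t = brute_force_edge(np.asarray(cube.counts[x, y], float),
                                 cube.bin_ps, f, min_counts)
            if t is not None and t < best_t:
                best, best_t = (x, y), t
    return best, best_t
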