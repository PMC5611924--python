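"""Synthetic experiment builders: milk tank, tissue slabs, fibre-coil loop.

Each builder returns a :class:`Scenario` bundling an optical medium, a fibre
source, a camera and run parameters, so that the full transport -> camera ->
localization chain can be exercised without any external data.  The coil
scenario is special: it is an analytic emission schedule (light circulating
a closed loop of fibre imaged directly in air) rather than a tissue
transport problem.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import yaml

from .camera import CameraModel, TCSPCCube, accumulate_cube
from .transport import (C_CM_PER_NS, PS_PER_CM, FibreSource, OpticalMedium,
                        PhotonRecords, run_transport)


class ScenarioError(ValueError):
    """Invalid scenario geometry or parameters."""


@dataclass
class Scenario:
    """A named, fully parameterized synthetic experiment."""

    name: str
    camera: CameraModel
    medium: Optional[OpticalMedium] = None
    source: Optional[FibreSource] = None
    photons: int = 1_000_000
    seed: int = 1
    exposure_s: float = 10.0
    pulses_per_frame: int = 160
    kind: str = "transport"            # "transport" | "schedule"
    schedule: Optional[dict] = None    # coil: u, v, t_emit_ps, weight, ...
    notes: dict = field(default_factory=dict)

    def true_pixel(self) -> Optional[tuple]:
        """Pixel containing the fibre tip's lateral position (transport kinds)."""
        if self.source is None or self.medium is None:
            return None
        from .transport import _FACE_UV  # local import to avoid cycle noise
        iu, iv = _FACE_UV[self.medium.face_code]
        u = self.source.tip_cm[iu] - self.camera.fov_origin_cm[0]
        v = self.source.tip_cm[iv] - self.camera.fov_origin_cm[1]
        return (int(u // self.camera.pitch_cm), int(v // self.camera.pitch_cm))


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def make_milk_tank(tank_cm: float = 15.0, mus: float = 15.0, mua: float = 0.02,
                   g: float = 0.8, depth_cm: float = 3.0, n: float = 1.33,
                   voxel_cm: float = 0.5, seed: int = 1,
                   photons: int = 300_000, exposure_s: float = 10.0,
                   **camera_kw) -> Scenario:
    """Fibre suspended in a homogeneous colloid tank, axis perpendicular to
    the camera so every detected photon has scattered at least once.

    Defaults emulate semi-skimmed milk at 785 nm (mus ~ 15 cm^-1, weak
    absorption, n = 1.33) with the tip 3 cm below the imaged surface.
    """
    if not 0 < depth_cm < tank_cm:
        raise ScenarioError("source depth must lie inside the tank")
    nvox = max(int(round(tank_cm / voxel_cm)), 1)
    medium = OpticalMedium.homogeneous((nvox, nvox, nvox), voxel_cm,
                                       mua, mus, g, n=n, imaged_face="+z")
    size = nvox * voxel_cm
    tip = np.array([size / 2.0, size / 2.0, size - depth_cm])
    source = FibreSource(tip_cm=tip, axis=(1.0, 0.0, 0.0))
    camera = CameraModel(fov_origin_cm=(size / 2.0 - 15.5, size / 2.0 - 15.5),
                         **camera_kw)
    return Scenario(name="milk_tank", medium=medium, source=source,
                    camera=camera, photons=photons, seed=seed,
                    exposure_s=exposure_s)


def make_slab_phantom(thickness_cm: float = 4.0, mus: float = 10.0,
                      mua: float = 0.05, g: float = 0.9, n: float = 1.4,
                      tip_depth_cm: float = 2.0,
                      tip_lateral_cm: tuple = (15.5, 15.5),
                      lateral_cm: float = 32.0, voxel_cm: float = 0.5,
                      axis: tuple = (1.0, 0.0, 0.0),
                      channel: Optional[dict] = None,
                      name: str = "slab", seed: int = 1,
                      photons: int = 1_000_000, exposure_s: float = 10.0,
                      **camera_kw) -> Scenario:
    """Tissue slab with the fibre tip embedded at a given depth.

    The imaged face is the top (+z) surface; ``tip_depth_cm`` is measured
    down from it.  ``channel`` optionally carves a low-attenuation cylinder
    through the slab (keys: ``centre_cm`` (u, v), ``radius_cm``,
    ``mus_factor``) emulating a preferential scattering path that produces
    bright-but-late pixels.
    """
    nlat = max(int(round(lateral_cm / voxel_cm)), 1)
    nz = max(int(round(thickness_cm / voxel_cm)), 1)
    medium = OpticalMedium.homogeneous((nlat, nlat, nz), voxel_cm,
                                       mua, mus, g, n=n, imaged_face="+z")
    if channel:
        cu, cv = channel["centre_cm"]
        r = float(channel["radius_cm"])
        fac = float(channel.get("mus_factor", 0.1))
        xs = (np.arange(nlat) + 0.5) * voxel_cm
        du, dv = np.meshgrid(xs - cu, xs - cv, indexing="ij")
        mask = du ** 2 + dv ** 2 <= r ** 2
        medium.mus[mask, :] *= fac
    lz = nz * voxel_cm
    tip = np.array([tip_lateral_cm[0], tip_lateral_cm[1], lz - tip_depth_cm])
    if not medium.contains(tip):
        raise ScenarioError("fibre tip must lie strictly inside the slab")
    source = FibreSource(tip_cm=tip, axis=axis)
    camera = CameraModel(fov_origin_cm=(0.0, 0.0), **camera_kw)
    return Scenario(name=name, medium=medium, source=source, camera=camera,
                    photons=photons, seed=seed, exposure_s=exposure_s)


def make_lung_slab(**overrides) -> Scenario:
    """Lung-like preset: tip 2 cm deep, mus = 10 cm^-1, g = 0.9, mua = 0.05."""
    kw = dict(thickness_cm=4.0, mus=10.0, mua=0.05, g=0.9, n=1.4,
              tip_depth_cm=2.0, name="lung_slab", photons=1_000_000,
              exposure_s=10.0)
    kw.update(overrides)
    return make_slab_phantom(**kw)


def make_torso_slab(**overrides) -> Scenario:
    """Torso-like preset: deeper tip, denser scattering, 17 s exposure."""
    kw = dict(thickness_cm=8.0, mus=12.0, mua=0.07, g=0.9, n=1.4,
              tip_depth_cm=4.0, name="torso_slab", photons=1_000_000,
              exposure_s=17.0)
    kw.update(overrides)
    return make_slab_phantom(**kw)


def make_fibre_coil(circumference_cm: float = 16.0, group_index: float = 1.3125,
                    loss_per_circuit: float = 0.5, circuits: int = 5,
                    points_per_circuit: int = 1024, pitch_cm: float = 0.25,
                    pulse_fwhm_ps: float = 10.0, rep_period_ps: float = 12_500.0,
                    seed: int = 1, exposure_s: float = 0.2,
                    **camera_kw) -> Scenario:
    """Light-in-flight around a closed coil of fibre, imaged directly.

    A point at arc position ``s`` on circuit ``k`` emits at
    ``(s + k*C) * n_group / c`` with intensity ``loss_per_circuit**k``;
    every illuminated pixel therefore shows peaks repeating with period
    ``C * n_group / c`` (~700 ps for C = 16 cm at the default group index).
    """
    if not circumference_cm > 0:
        raise ScenarioError("circumference must be > 0")
    if circuits < 1:
        raise ScenarioError("number of circuits must be >= 1")
    camera_kw.setdefault("dark_hz", 10.0)
    camera = CameraModel(pitch_cm=pitch_cm, **camera_kw)
    cx = camera.nx * pitch_cm / 2.0
    cy = camera.ny * pitch_cm / 2.0
    radius = circumference_cm / (2.0 * math.pi)
    npts = int(points_per_circuit) * int(circuits)
    s_arc = (np.arange(npts) + 0.5) / points_per_circuit * circumference_cm
    k = np.floor_divide(np.arange(npts), points_per_circuit)
    theta = 2.0 * math.pi * np.mod(s_arc, circumference_cm) / circumference_cm
    period_ps = circumference_cm * group_index * PS_PER_CM
    schedule = {
        "u_cm": cx + radius * np.cos(theta),
        "v_cm": cy + radius * np.sin(theta),
        "path_cm": s_arc,
        "t_emit_ps": np.zeros(npts),
        "weight": float(loss_per_circuit) ** k,
        "group_index": float(group_index),
        "rep_period_ps": float(rep_period_ps),
        "pulse_fwhm_ps": float(pulse_fwhm_ps),
        "period_ps": float(period_ps),
        "circumference_cm": float(circumference_cm),
        "circuits": int(circuits),
        "loss_per_circuit": float(loss_per_circuit),
        "centre_cm": (cx, cy),
        "radius_cm": radius,
    }
    return Scenario(name="fibre_coil", camera=camera, kind="schedule",
                    schedule=schedule, photons=npts, seed=seed,
                    exposure_s=exposure_s,
                    notes={"period_ps": period_ps})


def schedule_records(scenario: Scenario, seed: Optional[int] = None) -> PhotonRecords:
    """Materialize a schedule scenario as photon exit records.

    Transit times follow the fibre group index exactly; a Gaussian laser
    pulse width is added as the emission-time offset.
    """
    sch = scenario.schedule
    if sch is None:
        raise ScenarioError("scenario has no emission schedule")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(scenario.seed if seed is None else seed), 0xC011]))
    n = sch["u_cm"].size
    sigma = sch["pulse_fwhm_ps"] / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    t_emit = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    zeros = np.zeros(n)
    meta = {
        "n_medium": sch["group_index"],
        "face_code": 5,
        "normal": np.array([0.0, 0.0, 1.0]),
        "n_launched": n,
        "rep_period_ps": sch["rep_period_ps"],
        "scenario": scenario.name,
        "seed": int(scenario.seed if seed is None else seed),
    }
    return PhotonRecords(
        exit_cm=np.column_stack([sch["u_cm"], sch["v_cm"], zeros]),
        direction=np.column_stack([zeros, zeros, np.ones(n)]),
        path_cm=np.asarray(sch["path_cm"], float),
        t_transit_ps=np.asarray(sch["path_cm"], float) * sch["group_index"] * PS_PER_CM,
        t_emit_ps=t_emit,
        n_scatter=np.zeros(n, np.int32),
        weight=np.asarray(sch["weight"], float) * np.ones(n),
        label=np.zeros(n, np.int8),  # unscattered, direct line of sight
        meta=meta,
    )


# --------------------------------------------------------------------------
# simulation driver
# --------------------------------------------------------------------------

def simulate(scenario: Scenario, photons: Optional[int] = None,
             seed: Optional[int] = None, mode: str = "poisson"):
    """Run a scenario end to end; returns ``(records, cube)``."""
    seed = scenario.seed if seed is None else int(seed)
    if scenario.kind == "schedule":
        records = schedule_records(scenario, seed=seed)
    else:
        n = int(photons or scenario.photons)
        records = run_transport(scenario.medium, scenario.source,
                                n_photons=n, seed=seed)
        records.meta["scenario"] = scenario.name
        tp = scenario.true_pixel()
        if tp is not None:
            records.meta["true_pixel"] = list(tp)
    cube = accumulate_cube(records, scenario.camera, scenario.exposure_s,
                           pulses_per_frame=scenario.pulses_per_frame,
                           mode=mode, seed=seed)
    return records, cube


# --------------------------------------------------------------------------
# registry and configuration
# --------------------------------------------------------------------------

REGISTRY: dict[str, Callable[..., Scenario]] = {
    "milk_tank": make_milk_tank,
    "lung_slab": make_lung_slab,
    "torso_slab": make_torso_slab,
    "fibre_coil": make_fibre_coil,
}


def list_scenarios() -> list:
    return sorted(REGISTRY)


def get_scenario(name: str, **overrides) -> Scenario:
    try:
        builder = REGISTRY[name]
    except KeyError:
        raise ScenarioError(
            f"unknown scenario {name!r}; available: {', '.join(list_scenarios())}"
        ) from None
    return builder(**overrides)


def scenario_from_config(cfg: dict) -> Scenario:
    """Build a scenario from a config mapping.

    Either ``{"scenario": name, "overrides": {...}}`` for a registered
    builder, or an explicit description with ``medium`` / ``source`` /
    ``camera`` / ``run`` sections.
    """
    if "scenario" in cfg:
        return get_scenario(cfg["scenario"], **cfg.get("overrides", {}))
    med = cfg["medium"]
    medium = OpticalMedium.homogeneous(
        tuple(med["shape"]), med["voxel_cm"], med["mua"], med["mus"],
        med["g"], n=med.get("n", 1.4), imaged_face=med.get("imaged_face", "+z"))
    src = cfg["source"]
    source = FibreSource(
        tip_cm=src["tip_cm"], axis=src["axis"], na=src.get("na", 0.22),
        wavelength_nm=src.get("wavelength_nm", 785.0),
        rep_period_ps=src.get("rep_period_ps", 12_500.0),
        pulse_fwhm_ps=src.get("pulse_fwhm_ps", 50.0))
    cam_kw = dict(cfg.get("camera", {}))
    if "fov_origin_cm" in cam_kw:
        cam_kw["fov_origin_cm"] = tuple(cam_kw["fov_origin_cm"])
    camera = CameraModel(**cam_kw)
    run = cfg.get("run", {})
    return Scenario(
        name=cfg.get("name", "custom"), medium=medium, source=source,
        camera=camera, photons=int(run.get("photons", 1_000_000)),
        seed=int(run.get("seed", 1)), exposure_s=float(run.get("exposure_s", 10.0)),
        pulses_per_frame=int(run.get("pulses_per_frame", 160)))


def load_config(path) -> dict:
    """Read a YAML or JSON scenario configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
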