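"""Seeded synthetic CEUS cine loops and cohorts.

The generator emulates the statistical structure a bolus-passage
recording presents to the analysis: three spatial compartments — a
vertical artery band, an elliptical tumor blob, and a white-matter
patch on a dark parenchymal background — whose intensity curves follow
a gamma-variate indicator-dilution model with an additive saturating
tail.  The gamma-variate kernel gives the fast wash-in, single peak and
early wash-out of a bolus transit; the tail term creates a
distinguishable late-wash-out plateau, so a single curve exhibits all
five phases (baseline, wash-in, peak, early wash-out, late wash-out).

Defaults encode the clinical picture of intraoperative cerebral CEUS:
the artery enhances first and highest, the tumor is intermediate, white
matter faint and late — arterial onset around 25 s after injection with
a ~7 s wash-in, compartment onsets staggered by 1 s, 45 s clips, and
per-tissue peak levels of 0.584 (artery), 0.436 (tumor) and 0.175
(white matter) on the [0, 1] scale.

Speckle is modelled as multiplicative unit-mean noise (a normalized
Rayleigh factor), so increasing the noise level leaves the expected TIC
unchanged and parameter-recovery tests have unbiased targets.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ceusquant.cine_io import CineLoop
from ceusquant.cohort_stats import CohortTable
from ceusquant.roi_geometry import Roi, rasterize

#: Per-tissue peak-enhancement means on the [0, 1] scale (cohort defaults).
DEFAULT_TISSUE_MEANS = {"artery": 0.584, "tumor": 0.436, "white_matter": 0.175}

#: Per-tissue peak-enhancement standard deviations (cohort defaults).
DEFAULT_TISSUE_SDS = {
    "artery": math.sqrt(0.048),
    "tumor": math.sqrt(0.046),
    "white_matter": math.sqrt(0.034),
}

_RAYLEIGH_SCALE = math.sqrt(2.0 / math.pi)  # unit-mean Rayleigh scale


@dataclass
class CompartmentSpec:
    """One tissue compartment: a region plus its bolus-curve parameters.

    Parameters
    ----------
    label : tissue tag (artery / tumor / white_matter / ...)
    geometry : Roi
        Region the compartment occupies in the frame.
    baseline : float in [0, 1]
        Pre-contrast intensity level.
    amplitude : float in [0, 1 - baseline]
        Peak enhancement above baseline (for tail_level = 0 the curve
        maximum is exactly baseline + amplitude).
    onset_s : float >= 0
        Bolus arrival time in seconds after injection.
    time_to_peak_s : float > 0
        Wash-in duration from onset to the gamma-variate peak.
    shape_alpha : float > 0
        Gamma-variate sharpness; larger alpha gives a narrower bolus.
    tail_level : float in [0, 1]
        Late-wash-out plateau as a fraction of amplitude.
    """

    label: str
    geometry: Roi
    baseline: float
    amplitude: float
    onset_s: float
    time_to_peak_s: float
    shape_alpha: float = 2.0
    tail_level: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.baseline <= 1:
            raise ValueError(f"baseline must be in [0, 1], got {self.baseline}")
        if self.amplitude < 0 or self.baseline + self.amplitude > 1 + 1e-12:
            raise ValueError(
                f"amplitude must satisfy baseline + amplitude <= 1, got "
                f"{self.baseline} + {self.amplitude}"
            )
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if not self.time_to_peak_s > 0:
            raise ValueError(f"time_to_peak_s must be > 0, got {self.time_to_peak_s}")
        if not self.shape_alpha > 0:
            raise ValueError(f"shape_alpha must be > 0, got {self.shape_alpha}")
        if not 0 <= self.tail_level <= 1:
            raise ValueError(f"tail_level must be in [0, 1], got {self.tail_level}")


@dataclass
class SceneSpec:
    """A full synthetic scene: geometry, timing, compartments and noise."""

    frame_shape: tuple[int, int] = (64, 64)
    frame_rate_hz: float = 10.0
    duration_s: float = 45.0
    compartments: Sequence[CompartmentSpec] = field(default_factory=list)
    noise_sigma: float = 0.15
    background_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.compartments:
            raise ValueError("scene requires at least one compartment")
        if self.duration_s * self.frame_rate_hz < 2:
            raise ValueError("scene must span at least 2 frames")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


def bolus_curve(spec: CompartmentSpec, t: float | np.ndarray) -> np.ndarray:
    """Model intensity of a compartment at time(s) ``t`` (seconds).

    For t <= onset the curve sits at the baseline.  After onset, with
    tau = (t - onset) / time_to_peak and alpha the sharpness::

        baseline + amplitude * ((1 - tail) * tau^alpha * exp(alpha * (1 - tau))
                                + tail * (1 - exp(-tau)))

    clipped to [0, 1].  The gamma-variate term peaks at exactly 1 when
    tau = 1 and decays toward 0; the tail term saturates at the plateau
    fraction, producing the late-wash-out shoulder.
    """
    t = np.asarray(t, dtype=float)
    tau = np.maximum(t - spec.onset_s, 0.0) / spec.time_to_peak_s
    a = spec.shape_alpha
    with np.errstate(over="ignore"):
        gamma = np.where(tau > 0, tau**a * np.exp(a * (1.0 - tau)), 0.0)
    tail = 1.0 - np.exp(-tau)
    y = spec.baseline + spec.amplitude * (
        (1.0 - spec.tail_level) * gamma + spec.tail_level * tail
    )
    return np.clip(y, 0.0, 1.0)


def default_scene(seed: int = 0, noise_sigma: float = 0.15) -> SceneSpec:
    """The canonical three-compartment scene at study-default parameters.

    Artery: vertical band, onset 25 s, 7 s to peak, sharp bolus.
    Tumor: elliptical blob, onset 26 s, slower wash-in.
    White matter: lateral patch, onset 27 s, faint prolonged enhancement.
    Rendered peak levels match the per-tissue cohort means (amplitudes
    are pre-divided by the curve family's maximum), late-phase plateaus
    are ordered artery > tumor > white matter so the blood pool stays
    brightest throughout and tissue AUC ratios to the artery fall in
    (0, 1), and every curve crosses the half-peak wash-out cut before
    the clip ends.  The 45 s / 10 Hz clip leaves ~15 s of pre-contrast
    baseline (recording assumed started 10 s after injection).
    """
    ellipse = [
        (32.0 + 11.0 * math.sin(2 * math.pi * k / 40),
         44.0 + 9.0 * math.cos(2 * math.pi * k / 40))
        for k in range(40)
    ]
    compartments = [
        CompartmentSpec(
            label="white_matter",
            geometry=Roi(label="white_matter", shape_kind="rectangle",
                         bounds=(8, 14, 22, 16)),
            baseline=0.04, amplitude=0.146, onset_s=27.0,
            time_to_peak_s=8.0, shape_alpha=2.0, tail_level=0.20,
        ),
        CompartmentSpec(
            label="tumor",
            geometry=Roi(label="tumor", shape_kind="polygon", vertices=ellipse),
            baseline=0.04, amplitude=0.430, onset_s=26.0,
            time_to_peak_s=9.0, shape_alpha=2.0, tail_level=0.22,
        ),
        CompartmentSpec(
            label="artery",
            geometry=Roi(label="artery", shape_kind="rectangle",
                         bounds=(0, 3, 64, 6)),
            baseline=0.04, amplitude=0.598, onset_s=25.0,
            time_to_peak_s=7.0, shape_alpha=3.0, tail_level=0.25,
        ),
    ]
    return SceneSpec(
        compartments=compartments,
        noise_sigma=noise_sigma,
        seed=seed,
    )


#: Clip time of frame 0 relative to injection for generated scenes.
DEFAULT_ORIGIN_TIME_S = 10.0


def generate_cine(
    scene: SceneSpec, origin_time_s: float = DEFAULT_ORIGIN_TIME_S
) -> tuple[CineLoop, list[Roi]]:
    """Render a scene into a seeded, reproducible cine loop.

    Each pixel's clean value at frame k is its compartment's
    :func:`bolus_curve` evaluated at ``origin_time_s + k / frame_rate``
    (background pixels sit at a low constant).  Later compartments
    overwrite earlier ones on overlap; a compartment left with zero
    exclusive pixels triggers a warning.  Speckle multiplies each clean
    value by ``1 + noise_sigma * (R - 1)`` with R a unit-mean Rayleigh
    draw, after which frames are quantized to 8 bits.

    Returns the cine plus the compartment geometries as ROIs, in
    compartment order.
    """
    rng = np.random.default_rng(scene.seed)
    rows, cols = scene.frame_shape
    n_frames = scene.n_frames
    times = origin_time_s + np.arange(n_frames) / scene.frame_rate_hz

    # ownership map: -1 background, else compartment index (later wins)
    owner = np.full((rows, cols), -1, dtype=int)
    for i, comp in enumerate(scene.compartments):
        owner[rasterize(comp.geometry, scene.frame_shape).mask] = i
    for i, comp in enumerate(scene.compartments):
        if not np.any(owner == i):
            warnings.warn(
                f"compartment {comp.label!r} has zero exclusive pixels "
                f"(fully overwritten by later compartments)",
                stacklevel=2,
            )

    clean = np.full((n_frames, rows, cols), scene.background_level, dtype=np.float64)
    for i, comp in enumerate(scene.compartments):
        curve = bolus_curve(comp, times)  # (n_frames,)
        sel = owner == i
        clean[:, sel] = curve[:, None]

    if scene.noise_sigma > 0:
        speckle = rng.rayleigh(_RAYLEIGH_SCALE, size=clean.shape)
        factor = np.maximum(1.0 + scene.noise_sigma * (speckle - 1.0), 0.0)
        clean = clean * factor

    frames = np.clip(np.floor(clean * 255.0 + 0.5), 0, 255).astype(np.uint8)
    cine = CineLoop(
        frames=frames,
        frame_rate_hz=scene.frame_rate_hz,
        origin_time_s=origin_time_s,
    )
    rois = [comp.geometry for comp in scene.compartments]
    return cine, rois


def generate_cohort(
    n_patients: int = 19,
    tissue_means: Mapping[str, float] | None = None,
    tissue_sds: Mapping[str, float] | None = None,
    within_patient_rho: float = 0.8,
    seed: int = 0,
    metric: str = "peak_enhancement",
) -> CohortTable:
    """Draw a correlated per-patient cohort of tissue metric values.

    Each patient p has a latent standard-normal "perfusion factor" z_p
    shared across tissues; the value for tissue j is::

        mean_j + sd_j * (sqrt(rho) * z_p + sqrt(1 - rho) * eps_pj)

    with independent standard-normal eps, then clipped to [0, 1], so
    ``within_patient_rho`` is exactly the induced cross-tissue
    correlation.  The shared factor models the patient-level coupling
    seen clinically: a patient with strong arterial enhancement shows
    elevated values in all ROIs.  Defaults: the per-tissue
    peak-enhancement means and standard deviations of the study
    conditions, rho = 0.8, n = 19.
    """
    if n_patients < 2:
        raise ValueError(f"n_patients must be >= 2, got {n_patients}")
    if not 0 <= within_patient_rho < 1:
        raise ValueError(
            f"within_patient_rho must be in [0, 1), got {within_patient_rho}"
        )
    means = dict(DEFAULT_TISSUE_MEANS if tissue_means is None else tissue_means)
    sds = dict(DEFAULT_TISSUE_SDS if tissue_sds is None else tissue_sds)
    if set(means) != set(sds):
        raise ValueError("tissue_means and tissue_sds must cover the same tissues")
    for label, sd in sds.items():
        if sd < 0:
            raise ValueError(f"sd for {label!r} must be >= 0, got {sd}")

    rng = np.random.default_rng(seed)
    rho = within_patient_rho
    table = CohortTable()
    tissues = sorted(means)
    z = rng.standard_normal(n_patients)
    eps = rng.standard_normal((n_patients, len(tissues)))
    width = len(str(n_patients))
    for p in range(n_patients):
        pid = f"P{p + 1:0{width}d}"
        for j, tissue in enumerate(tissues):
            val = means[tissue] + sds[tissue] * (
                math.sqrt(rho) * z[p] + math.sqrt(1.0 - rho) * eps[p, j]
            )
            table.records.append((pid, tissue, metric, float(np.clip(val, 0.0, 1.0))))
    return table


def scene_from_json(path: str | Path) -> SceneSpec:
    """Load a SceneSpec from JSON (see ``scene_to_json`` for the schema)."""
    with open(path) as fh:
        doc = json.load(fh)
    comps = []
    for rec in doc["compartments"]:
        geom = rec["geometry"]
        kind = geom["shape"]
        if kind == "circle":
            roi = Roi(label=rec["label"], shape_kind="circle",
                      center=tuple(geom["center"]), radius=geom["radius"])
        elif kind == "rectangle":
            roi = Roi(label=rec["label"], shape_kind="rectangle",
                      bounds=tuple(geom["bounds"]))
        else:
            roi = Roi(label=rec["label"], shape_kind="polygon",
                      vertices=[tuple(v) for v in geom["vertices"]])
        comps.append(
            CompartmentSpec(
                label=rec["label"],
                geometry=roi,
                baseline=rec["baseline"],
                amplitude=rec["amplitude"],
                onset_s=rec["onset_s"],
                time_to_peak_s=rec["time_to_peak_s"],
                shape_alpha=rec.get("shape_alpha", 2.0),
                tail_level=rec.get("tail_level", 0.0),
            )
        )
    return SceneSpec(
        frame_shape=tuple(doc.get("frame_shape", (64, 64))),
        frame_rate_hz=doc.get("frame_rate_hz", 10.0),
        duration_s=doc.get("duration_s", 45.0),
        compartments=comps,
        noise_sigma=doc.get("noise_sigma", 0.15),
        background_level=doc.get("background_level", 0.02),
        seed=doc.get("seed", 0),
    )


def scene_to_json(scene: SceneSpec, path: str | Path) -> None:
    """Serialize a SceneSpec to JSON; round-trips through scene_from_json."""
    comps = []
    for c in scene.compartments:
        geom: dict = {"shape": c.geometry.shape_kind}
        if c.geometry.shape_kind == "circle":
            geom["center"] = list(c.geometry.center)
            geom["radius"] = c.geometry.radius
        elif c.geometry.shape_kind == "rectangle":
            geom["bounds"] = list(c.geometry.bounds)
        else:
            geom["vertices"] = [list(v) for v in c.geometry.vertices]
        comps.append(
            {
                "label": c.label,
                "geometry": geom,
                "baseline": c.baseline,
                "amplitude": c.amplitude,
                "onset_s": c.onset_s,
                "time_to_peak_s": c.time_to_peak_s,
                "shape_alpha": c.shape_alpha,
                "tail_level": c.tail_level,
            }
        )
    doc = {
        "frame_shape": list(scene.frame_shape),
        "frame_rate_hz": scene.frame_rate_hz,
        "duration_s": scene.duration_s,
        "compartments": comps,
        "noise_sigma": scene.noise_sigma,
        "background_level": scene.background_level,
        "seed": scene.seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
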