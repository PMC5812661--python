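"""Digital liver phantoms and simulated regeneration cohorts.

Two layers of synthesis drive the pipeline end to end without external data:

* :func:`build_phantom` renders a simple 2-D axial "liver": an ellipsoidal
  parenchyma region with embedded circular vessel cross-sections (so ROI
  placement must avoid large vessels, as in manual ROI drawing), each tissue
  carrying a complete quantitative parameter set.  Geometry is deliberately
  schematic — no registration is performed downstream, so anatomical realism
  adds nothing.
* :func:`simulate_cohort` draws per-animal parameter trajectories for the
  four study groups of the hepatectomy experiment — conventional 70%
  resection (cPH, n=8), extended 86% resection (ePH, n=7), the fatal
  post-hepatectomy liver failure subgroup (PLF, n=4) and SHAM surgery (n=3)
  — across post-operative days 0, 1, 2, 3, 5, 7.  Group means and standard
  deviations default to the study's published summary trajectories; each
  animal deviates from its group mean by a Gaussian random intercept scaled
  to the per-cell SD.  PLF animals die between day 2 and 3 (two each), so
  their records are truncated after day 3; one ePH animal misses the T2
  measurement from day 5 on.

All randomness flows from a single seed; identical seeds give bit-identical
cohort tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .signal_models import (
    DWI,
    IR_TRUEFISP,
    MT_FLASH,
    MULTI_ECHO,
    SequenceMeta,
    VoxelGroundTruth,
    add_rician_noise,
    default_protocol_metas,
    dwi_signal,
    ir_truefisp_signal,
    mt_signal_pair,
    multi_echo_signal,
)

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_PARENCHYMA",
    "LABEL_VESSEL",
    "PhantomSpec",
    "Phantom",
    "CohortSpec",
    "GROUP_TRAJECTORIES",
    "GROUP_SIZES",
    "STUDY_DAYS",
    "PARAMETER_UNITS",
    "build_phantom",
    "simulate_acquisitions",
    "simulate_cohort",
    "AcquisitionSeries",
]

LABEL_BACKGROUND = 0
LABEL_PARENCHYMA = 1
LABEL_VESSEL = 2

STUDY_DAYS = (0, 1, 2, 3, 5, 7)

# MRI cohort sizes per surgical group
GROUP_SIZES = {"cPH": 8, "ePH": 7, "PLF": 4, "SHAM": 3}

PARAMETER_UNITS = {
    "volume_pct": "%",
    "T1": "ms",
    "T2": "ms",
    "ADC": "1e-3 mm^2/s",
    "MTR": "%",
}

# Published group trajectories (mean, SD) per parameter / group / day.
# Volumetry and T1/T2 relaxometry; ADC in 1e-3 mm^2/s; MTR in percent.
# None marks a censored cell (PLF deaths; no data after day 3).
_T = GROUP_TRAJECTORIES = {
    "volume_pct": {
        "cPH": {0: (100.0, 0.0), 1: (46.4, 7.3), 2: (54.0, 8.1), 3: (64.1, 8.3), 5: (77.0, 8.5), 7: (87.1, 6.8)},
        "ePH": {0: (100.0, 0.0), 1: (27.7, 3.6), 2: (32.3, 3.6), 3: (39.3, 7.8), 5: (53.3, 11.6), 7: (68.7, 9.6)},
        "PLF": {0: (100.0, 0.0), 1: (30.9, 1.3), 2: (33.5, 3.1), 3: (36.4, 0.9), 5: None, 7: None},
        "SHAM": {0: (100.0, 0.0), 1: (99.8, 2.0), 2: (99.4, 2.6), 3: (101.6, 1.6), 5: (99.8, 2.0), 7: (100.3, 1.5)},
    },
    "T1": {
        "cPH": {0: (997.0, 104.8), 1: (1180.0, 165.1), 2: (1232.2, 182.1), 3: (1084.8, 112.6), 5: (1069.8, 26.1), 7: (1053.1, 69.2)},
        "ePH": {0: (972.6, 67.7), 1: (1359.7, 152.6), 2: (1451.7, 97.4), 3: (1351.7, 144.8), 5: (1172.6, 68.8), 7: (1083.4, 76.7)},
        "PLF": {0: (991.7, 38.0), 1: (1310.4, 103.4), 2: (1304.2, 180.0), 3: (2060.6, 254.8), 5: None, 7: None},
        "SHAM": {0: (1030.1, 46.0), 1: (1040.4, 58.4), 2: (1033.1, 60.8), 3: (996.9, 5.4), 5: (930.5, 92.5), 7: (934.1, 34.6)},
    },
    "T2": {
        "cPH": {0: (29.9, 3.0), 1: (30.9, 1.4), 2: (32.3, 2.7), 3: (34.5, 1.0), 5: (36.1, 2.9), 7: (32.6, 1.5)},
        "ePH": {0: (32.3, 3.4), 1: (31.7, 1.0), 2: (33.0, 2.6), 3: (35.1, 2.3), 5: (45.6, 8.3), 7: (38.9, 4.4)},
        "PLF": {0: (29.5, 6.1), 1: (34.1, 3.0), 2: (32.9, 1.6), 3: (35.2, 7.6), 5: None, 7: None},
        "SHAM": {0: (32.3, 0.5), 1: (31.2, 1.0), 2: (29.8, 2.9), 3: (28.0, 0.9), 5: (30.4, 3.2), 7: (29.2, 1.2)},
    },
    "ADC": {
        "cPH": {0: (1.54, 0.25), 1: (1.34, 0.24), 2: (1.24, 0.18), 3: (1.42, 0.19), 5: (1.42, 0.22), 7: (1.27, 0.09)},
        "ePH": {0: (1.52, 0.22), 1: (1.04, 0.27), 2: (1.21, 0.17), 3: (1.20, 0.11), 5: (1.35, 0.13), 7: (1.19, 0.13)},
        "PLF": {0: (1.53, 0.18), 1: (1.07, 0.23), 2: (0.93, 0.15), 3: (0.70, 0.13), 5: None, 7: None},
        "SHAM": {0: (1.45, 0.14), 1: (1.40, 0.16), 2: (1.49, 0.18), 3: (1.48, 0.07), 5: (1.34, 0.09), 7: (1.48, 0.07)},
    },
    "MTR": {
        "cPH": {0: (68.5, 1.2), 1: (61.1, 2.7), 2: (64.3, 2.1), 3: (66.8, 2.3), 5: (67.5, 2.8), 7: (68.3, 3.3)},
        "ePH": {0: (66.2, 3.2), 1: (56.4, 3.0), 2: (59.4, 3.3), 3: (62.2, 2.0), 5: (62.9, 1.9), 7: (63.7, 4.6)},
        "PLF": {0: (67.2, 2.0), 1: (55.1, 2.3), 2: (57.4, 2.6), 3: (56.7, 1.6), 5: None, 7: None},
        "SHAM": {0: (66.5, 3.7), 1: (65.1, 2.4), 2: (67.2, 3.6), 3: (67.9, 3.5), 5: (66.2, 3.1), 7: (66.0, 2.0)},
    },
}


@dataclass
class AcquisitionSeries:
    """A stack of magnitude images varying along one acquisition variable.

    ``data`` has shape ``(n_volumes, *spatial)`` with the acquisition variable
    (TI, TE, b or MT state) along axis 0.
    """

    data: np.ndarray
    meta: SequenceMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = 2 if self.meta.contrast in (DWI, MT_FLASH) else len(self.meta.variable_values)
        if self.data.shape[0] != n:
            raise ValueError(
                f"series has {self.data.shape[0]} volumes but metadata defines {n} values"
            )

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[1:]


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of a digital liver phantom.

    The liver (parenchyma + vessels) occupies exactly
    ``round(liver_volume_mm3 / voxel_volume)`` voxels of an ellipse-shaped
    region; ``n_vessels`` circular vessel cross-sections of radius
    ``vessel_radius_vox`` are embedded at seeded positions.
    """

    shape: tuple = (48, 48)
    voxel_size_mm: tuple = (0.234, 0.234, 1.5)
    liver_volume_mm3: float = 56.0
    n_vessels: int = 3
    vessel_radius_vox: float = 2.0
    parenchyma: VoxelGroundTruth = field(default_factory=VoxelGroundTruth)
    vessel: VoxelGroundTruth = field(
        default_factory=lambda: VoxelGroundTruth(
            s0=1200.0, inv=1.95, t1_ms=1800.0, t2_ms=120.0, adc=2.8e-3, mtr=0.05, m0=1200.0
        )
    )
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.liver_volume_mm3 <= 0:
            raise ValueError("liver volume must be positive (degenerate geometry)")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class Phantom:
    """Rendered phantom: label map plus one ground-truth map per parameter."""

    spec: PhantomSpec
    labels: np.ndarray  # int grid: 0 background, 1 parenchyma, 2 vessel
    truth: Dict[str, np.ndarray]  # parameter name -> value grid

    @property
    def liver_mask(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND

    @property
    def parenchyma_mask(self) -> np.ndarray:
        return self.labels == LABEL_PARENCHYMA


_TRUTH_FIELDS = {
    "S0": "s0",
    "INV": "inv",
    "T1": "t1_ms",
    "T1_star": "t1_star_ms",
    "T2": "t2_ms",
    "N": "noise_floor",
    "ADC": "adc",
    "MTR": "mtr",
    "M0": "m0",
}


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Render the label map and ground-truth parameter maps for ``spec``.

    The liver region is the set of ``k`` voxels closest to the grid centre in
    the normalized-ellipse metric, ``k = round(liver_volume_mm3 /
    voxel_volume)``, so the rasterized liver volume matches the requested one
    to within a single voxel volume.  Vessel cross-sections are placed at
    seeded positions in the interior.
    """
    ny, nx = spec.shape
    k = int(round(spec.liver_volume_mm3 / spec.voxel_volume_mm3))
    if k < 1:
        raise ValueError("requested liver volume smaller than one voxel")
    if k > ny * nx:
        raise ValueError("requested liver volume exceeds the grid")

    rows, cols = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    # mildly anisotropic ellipse metric (liver wider than tall)
    metric = ((rows - cy) / 0.85) ** 2 + ((cols - cx) / 1.15) ** 2
    order = np.argsort(metric, axis=None, kind="stable")
    labels = np.zeros(spec.shape, dtype=np.int16)
    labels.flat[order[:k]] = LABEL_PARENCHYMA

    rng = np.random.default_rng(spec.seed)
    liver_idx = np.flatnonzero(labels.flat)
    # place vessels well inside the liver so they never touch the boundary
    interior = order[: max(k // 2, 1)]
    for _ in range(spec.n_vessels):
        pos = interior[rng.integers(0, len(interior))]
        r0, c0 = np.unravel_index(pos, spec.shape)
        disk = (rows - r0) ** 2 + (cols - c0) ** 2 <= spec.vessel_radius_vox**2
        labels[disk & (labels == LABEL_PARENCHYMA)] = LABEL_VESSEL

    truth: Dict[str, np.ndarray] = {}
    for name, attr in _TRUTH_FIELDS.items():
        grid = np.zeros(spec.shape, dtype=float)
        grid[labels == LABEL_PARENCHYMA] = getattr(spec.parenchyma, attr)
        grid[labels == LABEL_VESSEL] = getattr(spec.vessel, attr)
        truth[name] = grid
    return Phantom(spec=spec, labels=labels, truth=truth)


def simulate_acquisitions(
    phantom: Phantom,
    meta: SequenceMeta,
    sigma: Optional[float] = None,
    seed: Optional[int] = None,
) -> AcquisitionSeries:
    """Apply the forward model for ``meta`` voxel-wise, then Rician noise.

    Background voxels carry zero true signal (pure noise after magnitude
    detection).  ``sigma`` is the per-excitation noise SD; the sequence's
    signal averages are applied as complex averaging, so the realised image
    noise is ``sigma / sqrt(meta.n_averages)``.  ``sigma``/``seed`` default
    to the phantom spec's values.
    """
    sigma = phantom.spec.sigma if sigma is None else sigma
    sigma = sigma / np.sqrt(meta.n_averages)
    seed = phantom.spec.seed if seed is None else seed
    t = phantom.truth
    if meta.contrast == IR_TRUEFISP:
        tis = meta.values
        vols = [
            ir_truefisp_signal(t["S0"], t["INV"], np.where(t["T1_star"] > 0, t["T1_star"], 1.0), ti)
            * (t["S0"] > 0)
            for ti in tis
        ]
    elif meta.contrast == MULTI_ECHO:
        tes = meta.values
        vols = [
            multi_echo_signal(t["S0"], np.where(t["T2"] > 0, t["T2"], 1.0), t["N"], te) * (t["S0"] > 0)
            for te in tes
        ]
    elif meta.contrast == DWI:
        bvals = meta.values
        vols = [dwi_signal(t["S0"], t["ADC"], b) for b in bvals]
    elif meta.contrast == MT_FLASH:
        off, on = mt_signal_pair(t["M0"], t["MTR"])
        vols = [off, on]
    else:  # pragma: no cover - SequenceMeta already validates
        raise ValueError(f"unknown contrast {meta.contrast!r}")
    ideal = np.stack(vols, axis=0)
    data = add_rician_noise(ideal, sigma, seed)
    return AcquisitionSeries(data=data, meta=meta)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Statistical design of a simulated regeneration cohort.

    ``trajectories[param][group][day]`` holds (mean, SD) or None for censored
    cells; defaults are the published group trajectories.  ``sd_scale``
    rescales every SD (0 gives deterministic animals).  Per-animal variation
    is one Gaussian intercept per animal and parameter, scaled by the
    per-cell SD, so an animal sits consistently above or below its group mean
    across days; no day-to-day covariance beyond that is imposed.
    """

    group_sizes: Dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    days: tuple = STUDY_DAYS
    trajectories: Dict[str, Dict[str, Dict[int, Optional[tuple]]]] = field(
        default_factory=lambda: GROUP_TRAJECTORIES
    )
    sd_scale: float = 1.0
    seed: int = 0
    # the T2 series of one extended-resection animal is missing from day 5 on
    t2_dropout_group: Optional[str] = "ePH"
    t2_dropout_from_day: int = 5

    def __post_init__(self) -> None:
        if self.sd_scale < 0:
            raise ValueError("sd_scale must be non-negative")
        for param, groups in self.trajectories.items():
            for group, days in groups.items():
                for day, cell in days.items():
                    if cell is None:
                        continue
                    mean, sd = cell
                    if mean <= 0 or sd < 0:
                        raise ValueError(
                            f"invalid (mean, sd) for {param}/{group}/day {day}: {cell}"
                        )


def simulate_cohort(spec: CohortSpec) -> tuple:
    """Draw a long-format cohort table and the per-animal random effects.

    Returns ``(table, effects)``: ``table`` is a DataFrame with columns
    (animal_id, group, day, parameter, value, units), one row per populated
    cell; ``effects`` maps (animal_id, parameter) to the animal's standard-
    normal intercept.  Censored cells (PLF after day 3; the day-5+ T2 dropout)
    are absent from the table, never zero-filled.
    """
    rng = np.random.default_rng(spec.seed)
    params = list(spec.trajectories.keys())
    records = []
    effects: Dict[tuple, float] = {}
    for group in spec.group_sizes:
        n = spec.group_sizes[group]
        for i in range(n):
            animal = f"{group}_{i + 1:02d}"
            z = {p: rng.standard_normal() for p in params}
            for p in params:
                effects[(animal, p)] = z[p]
            for p in params:
                cells = spec.trajectories[p].get(group)
                if cells is None:
                    continue
                for day in spec.days:
                    cell = cells.get(day)
                    if cell is None:
                        continue
                    if (
                        p == "T2"
                        and group == spec.t2_dropout_group
                        and i == 0
                        and day >= spec.t2_dropout_from_day
                    ):
                        continue
                    mean, sd = cell
                    value = mean + z[p] * sd * spec.sd_scale
                    records.append(
                        {
                            "animal_id": animal,
                            "group": group,
                            "day": day,
                            "parameter": p,
                            "value": value,
                            "units": PARAMETER_UNITS.get(p, ""),
                        }
                    )
    table = pd.DataFrame.from_records(
        records, columns=["animal_id", "group", "day", "parameter", "value", "units"]
    )
    return table, effects


def default_metas() -> dict:
    """Alias for the study's four acquisition protocols."""
    return default_protocol_metas()


def reference_signal(truth: VoxelGroundTruth, meta: SequenceMeta) -> float:
    """Parenchyma signal magnitude of the first acquired volume of a series.

    This is the conventional SNR reference in quantitative MRI: the tissue
    signal of the acquired image (not an extrapolated TE=0 or TI=inf value)
    over the noise SD.  ``sigma = reference_signal / SNR`` therefore realises
    a stated image SNR for the series.
    """
    if meta.contrast == IR_TRUEFISP:
        s = ir_truefisp_signal(truth.s0, truth.inv, truth.t1_star_ms, meta.values[0])
    elif meta.contrast == MULTI_ECHO:
        s = multi_echo_signal(truth.s0, truth.t2_ms, truth.noise_floor, meta.values[0])
    elif meta.contrast == DWI:
        s = dwi_signal(truth.s0, truth.adc, meta.values[0])
    else:
        s = truth.m0
    return float(abs(s))
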