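"""Forward signal equations for the four MR contrasts and the magnitude-noise model.

The quantification pipeline measures four tissue parameters of regenerating
liver parenchyma at 4.7 T:

* T1 via segmented inversion-recovery trueFISP: the transient magnitude signal
  follows ``S(TI) = S0 * (1 - INV * exp(-TI / T1_star))`` where ``INV`` is the
  ratio between initial (inverted) and steady-state signal and ``T1_star`` the
  apparent relaxation time, converted to the true T1 by the Schmitt correction
  ``T1 = T1_star * cos(alpha/2) * (INV - 1)``.
* T2 via multi-echo RARE: ``S(TE) = S0 * exp(-TE / T2) + N`` with a constant
  noise-floor offset ``N``.
* ADC via two-point diffusion weighting: ``S(b) = S0 * exp(-b * ADC)``.
* MTR via a spoiled gradient-echo pair with and without MT pre-pulse:
  ``MTR = (M0 - Msat) / M0``.

Signals are simulated as ideal real-valued intensities; magnitude detection
and noise enter only through :func:`add_rician_noise`, so fitters see data as
a scanner would export it.

Units: times in ms, b-values in s/mm^2, ADC in mm^2/s, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContrastKind",
    "SequenceMeta",
    "VoxelGroundTruth",
    "ir_truefisp_signal",
    "t1_from_apparent",
    "multi_echo_signal",
    "dwi_signal",
    "mt_signal_pair",
    "mtr_from_pair",
    "add_rician_noise",
    "default_t1_meta",
    "default_t2_meta",
    "default_dwi_meta",
    "default_mt_meta",
    "default_protocol_metas",
]

# Contrast identifiers used throughout the pipeline.
IR_TRUEFISP = "ir_truefisp"
MULTI_ECHO = "multi_echo"
DWI = "dwi"
MT_FLASH = "mt_flash"
ContrastKind = str

_CONTRAST_KINDS = (IR_TRUEFISP, MULTI_ECHO, DWI, MT_FLASH)


@dataclass(frozen=True)
class SequenceMeta:
    """Acquisition metadata for one series varying along a single variable.

    Parameters
    ----------
    contrast
        One of ``ir_truefisp``, ``multi_echo``, ``dwi``, ``mt_flash``.
    flip_angle_deg
        Excitation flip angle in degrees, in (0, 180).
    tr_ms
        Repetition time in ms.
    variable_name
        Name of the acquisition variable (``TI``, ``TE``, ``b``, ``mt``).
    variable_values
        Strictly increasing TI/TE lists (ms), the pair (0, b>0) for DWI,
        or the pair ("off", "on") for magnetization transfer.
    voxel_size_mm
        In-plane and through-plane voxel dimensions (mm, mm, mm).
    slice_thickness_mm
        Slice thickness in mm.
    n_averages
        Number of signal averages of the sequence; complex averaging before
        magnitude detection reduces the effective noise SD by sqrt(AVG).
    """

    contrast: ContrastKind
    flip_angle_deg: float
    tr_ms: float
    variable_name: str
    variable_values: tuple
    voxel_size_mm: tuple = (0.234, 0.234, 1.5)
    slice_thickness_mm: float = 1.5
    n_averages: int = 1

    def __post_init__(self) -> None:
        if self.n_averages < 1:
            raise ValueError("n_averages must be a positive integer")
        if self.contrast not in _CONTRAST_KINDS:
            raise ValueError(f"unknown contrast kind: {self.contrast!r}")
        if not 0.0 < self.flip_angle_deg < 180.0:
            raise ValueError("flip angle must lie in (0, 180) degrees")
        vals = self.variable_values
        if self.contrast == MT_FLASH:
            if tuple(vals) != ("off", "on"):
                raise ValueError("mt_flash requires the state pair ('off', 'on')")
            return
        arr = np.asarray(vals, dtype=float)
        if self.contrast == DWI:
            if arr.size != 2 or arr[0] != 0.0 or arr[1] <= 0.0:
                raise ValueError("dwi requires exactly b = 0 and one b > 0")
            return
        if np.any(arr <= 0.0) or np.any(np.diff(arr) <= 0.0):
            raise ValueError(f"{self.variable_name} values must be positive and strictly increasing")

    @property
    def values(self) -> np.ndarray:
        if self.contrast == MT_FLASH:
            return np.array([0.0, 1.0])  # off, on
        return np.asarray(self.variable_values, dtype=float)

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "flip_angle_deg": self.flip_angle_deg,
            "tr_ms": self.tr_ms,
            "variable_name": self.variable_name,
            "variable_values": list(self.variable_values),
            "voxel_size_mm": list(self.voxel_size_mm),
            "slice_thickness_mm": self.slice_thickness_mm,
            "n_averages": self.n_averages,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceMeta":
        return cls(
            contrast=d["contrast"],
            flip_angle_deg=float(d["flip_angle_deg"]),
            tr_ms=float(d["tr_ms"]),
            variable_name=d["variable_name"],
            variable_values=tuple(d["variable_values"]),
            voxel_size_mm=tuple(d["voxel_size_mm"]),
            slice_thickness_mm=float(d["slice_thickness_mm"]),
            n_averages=int(d.get("n_averages", 1)),
        )


@dataclass
class VoxelGroundTruth:
    """Complete per-tissue parameter set used by the simulator and scorer.

    ``t1_star_ms`` is derived from ``t1_ms`` (via the inverse Schmitt
    correction) when not given explicitly.
    """

    s0: float = 1000.0
    inv: float = 1.95
    t1_ms: float = 997.0
    t2_ms: float = 29.9
    noise_floor: float = 0.0
    adc: float = 1.54e-3
    mtr: float = 0.685
    m0: float = 1000.0
    t1_star_ms: float = field(default=None)  # type: ignore[assignment]
    flip_angle_deg: float = 60.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if self.s0 < 0 or self.m0 < 0:
            raise ValueError("S0 and M0 must be non-negative")
        if self.inv <= 1:
            raise ValueError("INV must exceed 1 for an inverting preparation")
        if not 0.0 <= self.mtr < 1.0:
            raise ValueError("MTR must lie in [0, 1)")
        if self.adc < 0:
            raise ValueError("ADC must be non-negative")
        if self.t1_star_ms is None:
            # invert T1 = T1* cos(alpha/2) (INV - 1)
            corr = np.cos(np.deg2rad(self.flip_angle_deg) / 2.0) * (self.inv - 1.0)
            object.__setattr__(self, "t1_star_ms", self.t1_ms / corr)


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def ir_truefisp_signal(s0, inv, t1_star_ms, ti_ms):
    """Transient IR-trueFISP signal ``S0 * (1 - INV * exp(-TI/T1*))``.

    May be negative for small TI; magnitude detection is applied only at the
    noise stage so that fitters can model polarity loss explicitly.
    """
    t1_star_ms = np.asarray(t1_star_ms, dtype=float)
    if np.any(t1_star_ms <= 0):
        raise ValueError("T1* must be positive")
    ti = np.asarray(ti_ms, dtype=float)
    return np.asarray(s0) * (1.0 - np.asarray(inv) * np.exp(-ti / t1_star_ms))


def t1_from_apparent(t1_star_ms, inv, alpha_deg):
    """Schmitt correction ``T1 = T1* * cos(alpha/2) * (INV - 1)``.

    Returns the corrected T1 together with a validity flag; voxels with
    ``INV <= 1`` are physically degenerate (no inversion) and flagged invalid
    with T1 = 0 rather than raising, so that map-level batch processing can
    mask them.
    """
    t1_star = np.asarray(t1_star_ms, dtype=float)
    if np.any(t1_star <= 0):
        raise ValueError("T1* must be positive")
    inv = np.asarray(inv, dtype=float)
    valid = inv > 1.0
    t1 = np.where(valid, t1_star * np.cos(np.deg2rad(alpha_deg) / 2.0) * (inv - 1.0), 0.0)
    if t1.ndim == 0:
        return float(t1), bool(valid)
    return t1, valid


def multi_echo_signal(s0, t2_ms, noise_floor, te_ms):
    """Mono-exponential echo decay with noise floor: ``S0 exp(-TE/T2) + N``."""
    t2 = np.asarray(t2_ms, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be positive")
    if np.any(np.asarray(noise_floor) < 0):
        raise ValueError("noise floor must be non-negative")
    te = np.asarray(te_ms, dtype=float)
    return np.asarray(s0) * np.exp(-te / t2) + np.asarray(noise_floor)


def dwi_signal(s0, adc, b):
    """Mono-exponential diffusion attenuation ``S0 exp(-b * ADC)``."""
    if np.any(np.asarray(adc) < 0):
        raise ValueError("ADC must be non-negative")
    if np.any(np.asarray(b) < 0):
        raise ValueError("b-value must be non-negative")
    return np.asarray(s0) * np.exp(-np.asarray(b, dtype=float) * np.asarray(adc, dtype=float))


def mt_signal_pair(m0, mtr):
    """Signal pair (without, with) MT pre-pulse for a given transfer ratio."""
    m0 = np.asarray(m0, dtype=float)
    mtr = np.asarray(mtr, dtype=float)
    if np.any(m0 < 0):
        raise ValueError("M0 must be non-negative")
    if np.any(mtr < 0) or np.any(mtr >= 1):
        raise ValueError("MTR must lie in [0, 1)")
    return m0, m0 * (1.0 - mtr)


def mtr_from_pair(m0, msat):
    """Magnetization transfer ratio ``(M0 - Msat) / M0`` as a fraction."""
    m0 = np.asarray(m0, dtype=float)
    return (m0 - np.asarray(msat, dtype=float)) / m0


def add_rician_noise(signal, sigma: float, seed) -> np.ndarray:
    """Magnitude-detect ``signal`` under complex Gaussian noise of std ``sigma``.

    Returns ``|signal + n_re + i n_im|`` with independent zero-mean Gaussian
    real/imaginary components, the noise model of magnitude MR images.
    Deterministic given ``seed`` (an int or a ``numpy.random.Generator``);
    ``sigma = 0`` returns ``|signal|`` exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return np.abs(signal)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(re, im)


# ---------------------------------------------------------------------------
# Default acquisition protocols (4.7 T small-animal study settings)
# ---------------------------------------------------------------------------

def _default_ti_list(n: int = 60, ti1_ms: float = 90.0, step_ms: float = 144.0) -> tuple:
    """IR-trueFISP inversion times: 60 TIs, TI_1 = 90 ms, 144 ms increments."""
    return tuple(ti1_ms + i * step_ms for i in range(n))


def default_t1_meta() -> SequenceMeta:
    return SequenceMeta(
        contrast=IR_TRUEFISP,
        flip_angle_deg=60.0,
        tr_ms=4.5,
        variable_name="TI",
        variable_values=_default_ti_list(),
        n_averages=4,
    )


def default_t2_meta() -> SequenceMeta:
    # of the protocol's seven TRs only the longest (4000 ms) is simulated;
    # the mono-exponential echo fit carries no TR term
    return SequenceMeta(
        contrast=MULTI_ECHO,
        flip_angle_deg=90.0,
        tr_ms=4000.0,
        variable_name="TE",
        variable_values=(11.0, 33.0, 55.0, 77.0, 99.0),
        n_averages=2,
    )


def default_dwi_meta() -> SequenceMeta:
    return SequenceMeta(
        contrast=DWI,
        flip_angle_deg=90.0,
        tr_ms=3000.0,
        variable_name="b",
        variable_values=(0.0, 800.0),
        n_averages=8,
    )


def default_mt_meta() -> SequenceMeta:
    return SequenceMeta(
        contrast=MT_FLASH,
        flip_angle_deg=12.0,
        tr_ms=18.4,
        variable_name="mt",
        variable_values=("off", "on"),
        n_averages=8,
    )


def default_protocol_metas() -> dict:
    """The four study protocols keyed by contrast kind."""
    return {
        IR_TRUEFISP: default_t1_meta(),
        MULTI_ECHO: default_t2_meta(),
        DWI: default_dwi_meta(),
        MT_FLASH: default_mt_meta(),
    }
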