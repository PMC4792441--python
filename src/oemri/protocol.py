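"""Acquisition constants and shared data contracts.

Units are fixed package-wide: inversion and echo times in milliseconds,
longitudinal relaxation rates (R1, dR1) in s^-1, and the oxygen-induced
effective transverse rate change (dR2*) in ms^-1 — the conventions in
which lung OE-MRI results are usually reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "DEFAULT_INVERSION_TIMES_MS",
    "DEFAULT_ECHO_TIME_MS",
    "GAS_STATES",
    "PARAMETER_NAMES",
    "AcquisitionProtocol",
    "validate_protocol",
    "GroundTruthMaps",
    "ImageSeries",
    "ParameterMaps",
]

#: Inversion times of the segmented IR-UTE protocol, in ms.
DEFAULT_INVERSION_TIMES_MS: tuple[float, ...] = (100.0, 400.0, 700.0, 1800.0, 3000.0, 4500.0, 6000.0)

#: Echo time of the UTE readout, in ms.
DEFAULT_ECHO_TIME_MS: float = 0.5

#: Breathing-gas states, acquisition order: room air first, then 100% oxygen.
GAS_STATES: tuple[str, str] = ("air", "o2")

#: The five lung parameters every ROI / bin statistic is computed for.
PARAMETER_NAMES: tuple[str, ...] = ("s0_air", "r1_air", "r1_o2", "delta_r1", "delta_r2star")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Fixed experimental constants of the two-gas-state IR acquisition.

    Parameters
    ----------
    inversion_times : sequence of float
        Inversion times in ms, strictly increasing, at least four of them
        (the signal model has three parameters; a residual degree of
        freedom is required).
    echo_time : float
        Echo time in ms; dR2* sensitivity scales with it.
    gas_states : tuple of str
        Ordered pair of breathing-state labels.
    noise_sigma : float
        Standard deviation of the simulated magnitude-image noise, in the
        arbitrary signal units of S0.
    """

    inversion_times: tuple[float, ...] = DEFAULT_INVERSION_TIMES_MS
    echo_time: float = DEFAULT_ECHO_TIME_MS
    gas_states: tuple[str, str] = GAS_STATES
    noise_sigma: float = 0.165

    def __post_init__(self) -> None:
        object.__setattr__(self, "inversion_times", tuple(float(ti) for ti in self.inversion_times))
        validate_protocol(self)

    @property
    def n_inversion_times(self) -> int:
        return len(self.inversion_times)

    def to_dict(self) -> dict:
        return {
            "inversion_times": list(self.inversion_times),
            "echo_time": self.echo_time,
            "gas_states": list(self.gas_states),
            "noise_sigma": self.noise_sigma,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionProtocol":
        return cls(
            inversion_times=tuple(d["inversion_times"]),
            echo_time=float(d["echo_time"]),
            gas_states=tuple(d["gas_states"]),
            noise_sigma=float(d["noise_sigma"]),
        )


def validate_protocol(protocol: AcquisitionProtocol) -> AcquisitionProtocol:
    """Validate an :class:`AcquisitionProtocol`, returning it unchanged.

    Raises
    ------
    ValueError
        If the inversion times are not strictly increasing and positive,
        if there are fewer than four of them, if the echo time is not
        positive, or if the noise level is negative.
    """
    tis = np.asarray(protocol.inversion_times, dtype=float)
    if tis.size < 4:
        raise ValueError(
            f"need at least 4 inversion times for a 3-parameter fit, got {tis.size}"
        )
    if not np.all(np.isfinite(tis)) or np.any(tis <= 0):
        raise ValueError("inversion times must be finite and positive")
    if np.any(np.diff(tis) <= 0):
        raise ValueError("inversion times must be strictly increasing")
    if not (np.isfinite(protocol.echo_time) and protocol.echo_time > 0):
        raise ValueError(f"echo time must be positive, got {protocol.echo_time}")
    if protocol.noise_sigma < 0:
        raise ValueError(f"noise_sigma must be nonnegative, got {protocol.noise_sigma}")
    if len(protocol.gas_states) != 2 or len(set(protocol.gas_states)) != 2:
        raise ValueError("gas_states must be an ordered pair of distinct labels")
    return protocol


def _check_grid(mask: np.ndarray, *arrays: np.ndarray) -> None:
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {mask.shape}")
    for a in arrays:
        if a.shape != mask.shape:
            raise ValueError(f"grid mismatch: {a.shape} vs mask {mask.shape}")


@dataclass
class GroundTruthMaps:
    """True per-pixel parameter fields of one synthetic animal.

    ``s0_air`` (a.u.) is the signal at full relaxation under air breathing
    and proxies relative lung proton density; ``r1_air`` (s^-1) is the
    baseline longitudinal relaxation rate; ``delta_r1`` (s^-1) the
    oxygen-induced R1 increase (uptake); ``delta_r2star`` (ms^-1) the
    oxygen-induced R2* increase (alveolar delivery). Values outside the
    lung ``mask`` are ignored by every downstream statistic.
    """

    s0_air: np.ndarray
    r1_air: np.ndarray
    delta_r1: np.ndarray
    delta_r2star: np.ndarray
    mask: np.ndarray
    group: str
    animal_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        for name in ("s0_air", "r1_air", "delta_r1", "delta_r2star"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        _check_grid(self.mask, self.s0_air, self.r1_air, self.delta_r1, self.delta_r2star)
        m = self.mask
        if m.any():
            for name in ("s0_air", "r1_air", "delta_r1", "delta_r2star"):
                if not np.all(np.isfinite(getattr(self, name)[m])):
                    raise ValueError(f"non-finite {name} inside the lung mask")
            if np.any(self.s0_air[m] <= 0):
                raise ValueError("s0_air must be positive inside the mask")
            if np.any(self.r1_air[m] <= 0):
                raise ValueError("r1_air must be positive inside the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def r1_o2(self) -> np.ndarray:
        return self.r1_air + self.delta_r1

    def parameters(self) -> dict[str, np.ndarray]:
        """The five analysis parameters as a name->map dict."""
        return {
            "s0_air": self.s0_air,
            "r1_air": self.r1_air,
            "r1_o2": self.r1_o2,
            "delta_r1": self.delta_r1,
            "delta_r2star": self.delta_r2star,
        }

    def valid(self) -> np.ndarray:
        """Pixels usable for statistics (here: the whole mask)."""
        return self.mask.copy()


@dataclass
class ImageSeries:
    """Magnitude images of one animal, one image per (gas state, TI).

    ``images`` maps each gas-state label to an array of shape
    ``(n_inversion_times, H, W)``, ordered as ``protocol.inversion_times``.
    """

    images: dict[str, np.ndarray]
    protocol: AcquisitionProtocol
    mask: np.ndarray
    group: str
    animal_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if set(self.images) != set(self.protocol.gas_states):
            raise ValueError(
                f"images keyed by {sorted(self.images)}, protocol expects {self.protocol.gas_states}"
            )
        n_ti = self.protocol.n_inversion_times
        for state, stack in self.images.items():
            stack = np.asarray(stack, dtype=float)
            if stack.ndim != 3 or stack.shape[0] != n_ti:
                raise ValueError(
                    f"{state}: expected shape ({n_ti}, H, W), got {stack.shape}"
                )
            if stack.shape[1:] != self.mask.shape:
                raise ValueError(f"{state}: image grid {stack.shape[1:]} != mask {self.mask.shape}")
            if not np.all(np.isfinite(stack)) or np.any(stack < 0):
                raise ValueError(f"{state}: magnitude images must be finite and nonnegative")
            self.images[state] = stack

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class ParameterMaps:
    """Per-pixel fit results for both gas states plus the derived delta maps.

    Per-gas-state dicts hold the fitted signal at full relaxation ``s0``,
    relaxation rate ``r1`` (s^-1), inversion-efficiency factor ``inv_eff``,
    sum of squared residuals ``residual``, and a boolean validity flag
    ``fit_ok``. ``delta_r1`` (s^-1) and ``delta_r2star`` (ms^-1) carry NaN
    wherever either gas state's fit failed; ``delta_valid`` gives that
    joint validity explicitly.
    """

    s0: dict[str, np.ndarray]
    r1: dict[str, np.ndarray]
    inv_eff: dict[str, np.ndarray]
    residual: dict[str, np.ndarray]
    fit_ok: dict[str, np.ndarray]
    delta_r1: np.ndarray
    delta_r2star: np.ndarray
    mask: np.ndarray
    group: str
    animal_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        _check_grid(self.mask, self.delta_r1, self.delta_r2star)
        for d in (self.s0, self.r1, self.inv_eff, self.residual, self.fit_ok):
            for state, arr in d.items():
                _check_grid(self.mask, np.asarray(arr))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def gas_states(self) -> tuple[str, ...]:
        return tuple(self.s0.keys())

    @property
    def delta_valid(self) -> np.ndarray:
        """Pixels where both gas-state fits succeeded."""
        states = list(self.fit_ok)
        v = np.ones(self.shape, dtype=bool)
        for s in states:
            v &= self.fit_ok[s].astype(bool)
        return v & self.mask

    @property
    def delta_r2star_negative(self) -> np.ndarray:
        """Flag map: valid pixels where S0_O2 exceeded S0_air (negative dR2*)."""
        with np.errstate(invalid="ignore"):
            return self.delta_valid & (self.delta_r2star < 0)

    def parameters(self) -> dict[str, np.ndarray]:
        """The five analysis parameters as a name->map dict (NaN = invalid)."""
        air, o2 = self.gas_states[0], self.gas_states[1]
        return {
            "s0_air": self.s0[air],
            "r1_air": self.r1[air],
            "r1_o2": self.r1[o2],
            "delta_r1": self.delta_r1,
            "delta_r2star": self.delta_r2star,
        }

    def valid(self) -> np.ndarray:
        """Pixels usable for statistics: in-mask with both fits valid."""
        return self.delta_valid
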