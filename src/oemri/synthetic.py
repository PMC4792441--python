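"""Digital lung phantoms and simulated two-gas-state IR image series.

The generator produces, per synthetic animal, ground-truth per-pixel fields
(density proxy S0_air, baseline R1, oxygen-induced dR1 and dR2*) on an
ellipse-pair lung mask, and forward-simulates the magnitude inversion-recovery
signal for both breathing states so that the whole downstream analysis chain
is exercisable without any acquired data.

Statistical structure emulated, per group (control vs elastase-challenged):

* group means and within-animal SDs of the five parameters match the
  values reported for the mouse emphysema study this package reanalyses;
* dR1 rises monotonically with local density (steeper, wider-ranging in the
  challenged group, whose lower mean density also shifts it left — jointly
  producing the low-density uptake deficit / high-density excess pattern);
* dR2* is linearly coupled to dR1 within each group (delivery tracks
  uptake), with residual scatter sized to the reported within-animal SDs;
* R1_air is spatially structured but independent of density;
* animal-to-animal variation enters as Gaussian jitter of the template
  means, sized to the reported between-animal SDs.

Within-animal fields are standardized exactly to the requested in-mask mean
and (population) SD, so a phantom's moments are the template's by
construction, not merely in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .protocol import AcquisitionProtocol, GroundTruthMaps, ImageSeries

__all__ = [
    "PhantomSpec",
    "MeanJitter",
    "StudySpec",
    "control_phantom_spec",
    "challenged_phantom_spec",
    "make_lung_mask",
    "make_phantom",
    "ir_magnitude_signal",
    "simulate_signal",
    "make_study",
]

#: Inversion-efficiency factor of an ideal 180-degree global inversion.
PERFECT_INVERSION = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Template for one synthetic animal's ground-truth fields.

    Means/SDs are in-mask within-animal moments: S0_air in arbitrary
    units, R1 in s^-1, dR2* in ms^-1. ``density_uptake_slope`` couples
    dR1 to local density (s^-1 per a.u.); ``uptake_delivery_slope`` is
    the dR1-per-dR2* coupling (s^-1 per ms^-1) that makes delivery track
    uptake linearly. ``spatial_correlation_length`` (pixels) sets the
    patch scale of all fields.
    """

    group: str = "control"
    grid_shape: tuple[int, int] = (64, 64)
    n_pixels_target: int = 1200
    mean_s0_air: float = 3.29
    sd_s0_air: float = 0.62
    mean_r1_air: float = 0.557
    sd_r1_air: float = 0.067
    mean_delta_r1: float = 0.024
    sd_delta_r1: float = 0.094
    mean_delta_r2star: float = 0.071
    sd_delta_r2star: float = 0.205
    density_uptake_slope: float = 0.03
    uptake_delivery_slope: float = 0.46
    spatial_correlation_length: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_s0_air", "sd_r1_air", "sd_delta_r1", "sd_delta_r2star"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_s0_air <= 0 or self.mean_r1_air <= 0:
            raise ValueError("mean_s0_air and mean_r1_air must be positive")
        if self.n_pixels_target < 4:
            raise ValueError("n_pixels_target too small")
        if self.spatial_correlation_length < 0:
            raise ValueError("spatial_correlation_length must be >= 0")
        # Variance budgets: each coupled field's structured part cannot
        # exceed its total requested variance.
        if abs(self.density_uptake_slope) * self.sd_s0_air > self.sd_delta_r1 + 1e-15:
            raise ValueError(
                "density_uptake_slope * sd_s0_air exceeds sd_delta_r1; "
                "no residual variance left for delta_r1"
            )
        if self.uptake_delivery_slope != 0 and self.sd_delta_r1 > 0:
            if self.sd_delta_r1 / abs(self.uptake_delivery_slope) > self.sd_delta_r2star + 1e-15:
                raise ValueError(
                    "sd_delta_r1 / uptake_delivery_slope exceeds sd_delta_r2star; "
                    "no residual variance left for delta_r2star"
                )


def control_phantom_spec(**overrides) -> PhantomSpec:
    """Saline-instilled control template (default values of PhantomSpec)."""
    return PhantomSpec(group="control", **overrides)


def challenged_phantom_spec(**overrides) -> PhantomSpec:
    """Elastase-challenged template: lower mean density, wider spreads,
    steeper density-uptake coupling."""
    defaults = dict(
        group="challenged",
        mean_s0_air=2.90,
        sd_s0_air=0.66,
        mean_r1_air=0.549,
        sd_r1_air=0.081,
        mean_delta_r1=0.025,
        sd_delta_r1=0.110,
        mean_delta_r2star=0.090,
        sd_delta_r2star=0.267,
        density_uptake_slope=0.08,
        uptake_delivery_slope=0.42,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@dataclass(frozen=True)
class MeanJitter:
    """Between-animal SDs of the template means (group-level spread)."""

    s0_air: float = 0.16
    r1_air: float = 0.015
    delta_r1: float = 0.015
    delta_r2star: float = 0.065


@dataclass(frozen=True)
class StudySpec:
    """A full two-group study design: templates, jitter, sizes, protocol."""

    n_control: int = 9
    n_challenged: int = 8
    control_template: PhantomSpec = field(default_factory=control_phantom_spec)
    challenged_template: PhantomSpec = field(default_factory=challenged_phantom_spec)
    control_jitter: MeanJitter = MeanJitter(0.16, 0.015, 0.015, 0.065)
    challenged_jitter: MeanJitter = MeanJitter(0.23, 0.019, 0.018, 0.058)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_challenged < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.n_control + self.n_challenged == 0:
            raise ValueError("study must contain at least one animal")


def make_lung_mask(grid_shape: tuple[int, int], n_pixels_target: int) -> np.ndarray:
    """Ellipse-pair (left/right lung) mask of approximately the target size.

    Raises ``ValueError`` when the grid cannot host ellipses of the
    requested area with a one-pixel margin.
    """
    h, w = grid_shape
    aspect = 1.6  # lungs are taller than wide
    semi_c = np.sqrt(n_pixels_target / (2.0 * np.pi * aspect))
    semi_r = aspect * semi_c
    gap = max(1.5, 0.5 * semi_c)  # mediastinum between the two lungs
    if semi_r + 1 > h / 2 or 2 * semi_c + gap / 2 + 1 > w / 2:
        raise ValueError(
            f"grid {grid_shape} too small for a {n_pixels_target}-pixel lung mask"
        )
    rows, cols = np.mgrid[0:h, 0:w]
    mask = np.zeros(grid_shape, dtype=bool)
    for side in (-1.0, 1.0):
        cc = w / 2.0 - 0.5 + side * (semi_c + gap / 2.0)
        cr = h / 2.0 - 0.5
        mask |= ((rows - cr) / semi_r) ** 2 + ((cols - cc) / semi_c) ** 2 <= 1.0
    return mask


def _standardized_field(
    rng: np.random.Generator, shape: tuple[int, int], mask: np.ndarray, corr_len: float
) -> np.ndarray:
    """Spatially correlated field with exact in-mask mean 0 and SD 1."""
    z = rng.standard_normal(shape)
    if corr_len > 0:
        z = gaussian_filter(z, sigma=corr_len, mode="reflect")
    mu = z[mask].mean()
    sd = z[mask].std()  # population convention; exactness is the point
    if sd == 0:  # pathological (e.g. 1-pixel mask); fall back to zeros
        return np.zeros(shape)
    return (z - mu) / sd


def _orthogonalized(z: np.ndarray, ref: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Remove the in-mask projection of ``z`` on ``ref``; re-standardize."""
    zr, rr = z[mask], ref[mask]
    denom = np.dot(rr, rr)
    if denom > 0:
        z = z - (np.dot(zr, rr) / denom) * ref
    mu = z[mask].mean()
    sd = z[mask].std()
    if sd == 0:
        return np.zeros_like(z)
    return (z - mu) / sd


def make_phantom(spec: PhantomSpec) -> GroundTruthMaps:
    """Build one animal's ground-truth maps from a template.

    Construction, all fields spatially correlated at the template's
    correlation length and standardized exactly within the mask:

    1. ``s0_air``: mean/SD per template.
    2. ``r1_air``: independent of density (no coupling).
    3. ``delta_r1 = mean + density_uptake_slope*(s0_air - mean_s0) + resid``,
       the residual orthogonal to density and sized so the total SD is
       exactly ``sd_delta_r1``.
    4. ``delta_r2star = mean + (delta_r1 - mean_dr1)/uptake_delivery_slope
       + resid``, residual orthogonal to uptake, total SD exactly
       ``sd_delta_r2star`` (uncoupled draw when the slope is 0).

    ``delta_r1`` is clipped so the oxygen-state rate stays positive.
    """
    mask = make_lung_mask(spec.grid_shape, spec.n_pixels_target)
    rng = np.random.default_rng(spec.seed)
    cl = spec.spatial_correlation_length

    z_density = _standardized_field(rng, spec.grid_shape, mask, cl)
    s0_air = spec.mean_s0_air + spec.sd_s0_air * z_density
    s0_air = np.maximum(s0_air, 1e-3)

    z_r1 = _standardized_field(rng, spec.grid_shape, mask, cl)
    r1_air = np.maximum(spec.mean_r1_air + spec.sd_r1_air * z_r1, 1e-3)

    slope_sd = spec.density_uptake_slope * spec.sd_s0_air
    resid_sd = np.sqrt(max(spec.sd_delta_r1**2 - slope_sd**2, 0.0))
    z_u = _orthogonalized(_standardized_field(rng, spec.grid_shape, mask, cl), z_density, mask)
    delta_r1 = (
        spec.mean_delta_r1
        + spec.density_uptake_slope * (s0_air - spec.mean_s0_air)
        + resid_sd * z_u
    )
    delta_r1 = np.maximum(delta_r1, -r1_air + 1e-6)

    z_d_raw = _standardized_field(rng, spec.grid_shape, mask, cl)
    if spec.uptake_delivery_slope != 0 and spec.sd_delta_r1 > 0:
        coupled_sd = spec.sd_delta_r1 / spec.uptake_delivery_slope
        resid2_sd = np.sqrt(max(spec.sd_delta_r2star**2 - coupled_sd**2, 0.0))
        z_d = _orthogonalized(z_d_raw, delta_r1 - spec.mean_delta_r1, mask)
        delta_r2star = (
            spec.mean_delta_r2star
            + (delta_r1 - spec.mean_delta_r1) / spec.uptake_delivery_slope
            + resid2_sd * z_d
        )
    else:
        delta_r2star = spec.mean_delta_r2star + spec.sd_delta_r2star * z_d_raw

    return GroundTruthMaps(
        s0_air=s0_air,
        r1_air=r1_air,
        delta_r1=delta_r1,
        delta_r2star=delta_r2star,
        mask=mask,
        group=spec.group,
        animal_id=f"{spec.group}_{spec.seed}",
    )


def ir_magnitude_signal(
    ti_ms: np.ndarray, s0: np.ndarray, inv_eff: float, r1_per_s: np.ndarray
) -> np.ndarray:
    """Magnitude inversion-recovery signal ``|S0 (1 - B exp(-R1 TI))|``.

    ``ti_ms`` in ms, ``r1_per_s`` in s^-1; broadcasting applies.
    """
    ti_s = np.asarray(ti_ms, dtype=float) / 1000.0
    return np.abs(s0 * (1.0 - inv_eff * np.exp(-np.multiply.outer(ti_s, r1_per_s))))


def simulate_signal(
    gt: GroundTruthMaps,
    protocol: AcquisitionProtocol,
    seed: int,
    inv_eff: float = PERFECT_INVERSION,
    noise_model: str = "gaussian",
) -> ImageSeries:
    """Forward-simulate the two-gas-state magnitude image series.

    Air state: ``S0 = s0_air``, ``R1 = r1_air``. Oxygen state:
    ``R1 = r1_air + delta_r1`` and ``S0 = s0_air * exp(-delta_r2star * TE)``
    — the gaseous-oxygen T2* attenuation at the echo time, whose inverse
    is the dR2* map formula. Outside the mask the noiseless signal is
    zero, so background pixels contain noise only.

    ``noise_model`` is ``"gaussian"`` (magnitude of signal + N(0, sigma));
    ``"rician"`` adds independent noise to the two quadrature channels; or
    ``"none"``.
    """
    if protocol.noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if noise_model not in ("gaussian", "rician", "none"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    ti = np.asarray(protocol.inversion_times, dtype=float)
    air, o2 = protocol.gas_states

    s0_maps = {air: gt.s0_air, o2: gt.s0_air * np.exp(-gt.delta_r2star * protocol.echo_time)}
    r1_maps = {air: gt.r1_air, o2: gt.r1_air + gt.delta_r1}

    sigma = protocol.noise_sigma
    images: dict[str, np.ndarray] = {}
    for state in protocol.gas_states:
        clean = ir_magnitude_signal(ti, s0_maps[state], inv_eff, r1_maps[state])
        clean = np.where(gt.mask[None, :, :], clean, 0.0)
        if sigma == 0 or noise_model == "none":
            noisy = clean
        elif noise_model == "gaussian":
            noisy = np.abs(clean + rng.normal(0.0, sigma, clean.shape))
        else:  # rician
            noisy = np.hypot(
                clean + rng.normal(0.0, sigma, clean.shape),
                rng.normal(0.0, sigma, clean.shape),
            )
        images[state] = noisy
    return ImageSeries(
        images=images, protocol=protocol, mask=gt.mask, group=gt.group, animal_id=gt.animal_id
    )


def _jittered(template: PhantomSpec, jitter: MeanJitter, rng: np.random.Generator,
              seed: int) -> PhantomSpec:
    return replace(
        template,
        mean_s0_air=max(template.mean_s0_air + jitter.s0_air * rng.standard_normal(), 1e-2),
        mean_r1_air=max(template.mean_r1_air + jitter.r1_air * rng.standard_normal(), 1e-3),
        mean_delta_r1=template.mean_delta_r1 + jitter.delta_r1 * rng.standard_normal(),
        mean_delta_r2star=template.mean_delta_r2star
        + jitter.delta_r2star * rng.standard_normal(),
        seed=seed,
    )


def make_study(
    spec: StudySpec, simulate: bool = True
) -> list[tuple[GroundTruthMaps, ImageSeries | None]]:
    """Generate the full two-group study.

    Returns one ``(ground_truth, image_series)`` pair per animal,
    controls first. Per-animal template means are jittered by the
    group's between-animal SDs; all randomness (jitter, fields, noise)
    derives deterministically from ``spec.master_seed``. With
    ``simulate=False`` the image series are ``None`` (ground-truth-only
    studies, e.g. for statistic calibration).
    """
    rng = np.random.default_rng(spec.master_seed)
    out: list[tuple[GroundTruthMaps, ImageSeries | None]] = []
    plan = [("control", spec.control_template, spec.control_jitter, spec.n_control),
            ("challenged", spec.challenged_template, spec.challenged_jitter, spec.n_challenged)]
    for group, template, jitter, n in plan:
        for i in range(n):
            phantom_seed = int(rng.integers(2**31))
            signal_seed = int(rng.integers(2**31))
            animal_spec = _jittered(template, jitter, rng, phantom_seed)
            gt = make_phantom(animal_spec)
            gt.animal_id = f"{group}_{i + 1:02d}"
            series = None
            if simulate:
                series = simulate_signal(gt, spec.protocol, signal_seed)
            out.append((gt, series))
    n_empty = sum(1 for gt, _ in out if not gt.mask.any())
    if n_empty:
        warnings.warn(f"{n_empty} animals have empty lung masks")
    return out
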