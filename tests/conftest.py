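"""Shared fixtures: small phantoms, studies, and the null-calibration run."""

from __future__ import annotations

import numpy as np
import pytest

from oemri import (
    AcquisitionProtocol,
    StudySpec,
    challenged_phantom_spec,
    compare_groups,
    control_phantom_spec,
    make_study,
)
from oemri.binning import BinAssignment, build_pixel_table
from oemri.resampling import permutation_test_bins
from oemri.roi import summarize_roi
from oemri.synthetic import MeanJitter, PhantomSpec


@pytest.fixture(scope="session")
def default_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def noiseless_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol(noise_sigma=0.0)


def small_control_spec(**overrides) -> PhantomSpec:
    """Control template on a small grid, cheap enough for fitting tests."""
    overrides.setdefault("grid_shape", (32, 32))
    overrides.setdefault("n_pixels_target", 200)
    return control_phantom_spec(**overrides)


def small_study_spec(seed: int, n_pixels: int = 300, grid: int = 32) -> StudySpec:
    """Default two-group design with reduced per-animal masks."""
    return StudySpec(
        control_template=control_phantom_spec(
            grid_shape=(grid, grid), n_pixels_target=n_pixels
        ),
        challenged_template=challenged_phantom_spec(
            grid_shape=(grid, grid), n_pixels_target=n_pixels
        ),
        master_seed=seed,
    )


def null_study_spec(seed: int, n_pixels: int = 60, grid: int = 16) -> StudySpec:
    """Both groups drawn from the control template (a true null)."""
    ctrl = control_phantom_spec(grid_shape=(grid, grid), n_pixels_target=n_pixels)
    chal = PhantomSpec(group="challenged", grid_shape=(grid, grid), n_pixels_target=n_pixels)
    return StudySpec(
        control_template=ctrl,
        challenged_template=chal,
        challenged_jitter=MeanJitter(),  # control-level between-animal spread
        master_seed=seed,
    )


N_NULL_STUDIES = 500


@pytest.fixture(scope="session")
def null_calibration() -> dict[str, np.ndarray]:
    """Per-study p-values under the null: single-bin animal-permutation
    test and mean-level Welch t-test on delta_r1, over 500 ground-truth
    studies of 9 vs 8 animals."""
    perm_p = np.empty(N_NULL_STUDIES)
    ttest_p = np.empty(N_NULL_STUDIES)
    for s in range(N_NULL_STUDIES):
        study = make_study(null_study_spec(seed=s), simulate=False)
        gts = [gt for gt, _ in study]
        table = build_pixel_table(gts)
        single_bin = BinAssignment(
            bin_idx=np.zeros(len(table), dtype=int),
            edges=np.array([table["s0_air"].min(), table["s0_air"].max()]),
            n_bins=1,
        )
        res = permutation_test_bins(
            table, single_bin, "delta_r1", n_permutations=1000, seed=s + 1
        )
        perm_p[s] = res.p_value[0]
        cmp = compare_groups([summarize_roi(gt) for gt in gts], statistic="mean")
        ttest_p[s] = cmp.table.loc["delta_r1", "p"]
    return {"perm_p": perm_p, "ttest_p": ttest_p}
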