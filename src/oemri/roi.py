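"""Whole-lung ROI summaries and two-group comparisons.

Per animal, the mean and SD of each of the five parameters (S0_air,
R1_air, R1_O2, dR1, dR2*) are computed over in-mask, fit-valid pixels —
the within-animal mean captures the global level of a parameter, the
within-animal SD its spatial heterogeneity. Group contrasts are
two-sample t-tests on either per-animal statistic; in the emphysema
model the discriminating signal sits in the SDs, not the means.

SD convention: sample SD (n-1 denominator) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .protocol import PARAMETER_NAMES

__all__ = ["ROISummary", "GroupComparison", "summarize_roi", "compare_groups"]


@dataclass
class ROISummary:
    """Per-animal whole-ROI mean and SD of each parameter."""

    animal_id: str
    group: str
    n_valid_pixels: int
    mean: dict[str, float]
    sd: dict[str, float]

    def to_row(self) -> dict:
        row = {"animal_id": self.animal_id, "group": self.group,
               "n_valid_pixels": self.n_valid_pixels}
        for p in self.mean:
            row[f"mean_{p}"] = self.mean[p]
            row[f"sd_{p}"] = self.sd[p]
        return row


@dataclass
class GroupComparison:
    """Per-parameter group contrast of an animal-level statistic.

    ``table`` is indexed by parameter with, per group g, columns
    ``mean_<g>`` / ``sd_<g>`` (mean and SD over animals of the chosen
    per-animal statistic) plus Welch/Student ``t`` and two-tailed ``p``.
    """

    statistic: str
    method: str
    groups: tuple[str, str]
    n_per_group: dict[str, int]
    table: pd.DataFrame


def summarize_roi(maps, mask: np.ndarray | None = None) -> ROISummary:
    """Summarize one animal's parameter maps over its valid ROI pixels.

    ``maps`` is any object exposing ``parameters()``, ``valid()``,
    ``group`` and ``animal_id`` (fitted ``ParameterMaps`` or noiseless
    ``GroundTruthMaps``). An extra ``mask`` restricts the ROI further.
    Raises ``ValueError`` when no valid pixel remains.
    """
    valid = maps.valid()
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
    params = maps.parameters()
    n = int(valid.sum())
    if n == 0:
        raise ValueError(f"{maps.animal_id}: no valid in-mask pixels to summarize")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for name, arr in params.items():
        v = np.asarray(arr, dtype=float)[valid]
        mean[name] = float(np.mean(v))
        sd[name] = float(np.std(v, ddof=1)) if n > 1 else 0.0
    return ROISummary(animal_id=maps.animal_id, group=maps.group,
                      n_valid_pixels=n, mean=mean, sd=sd)


def summaries_to_frame(summaries: list[ROISummary]) -> pd.DataFrame:
    """Tabulate per-animal summaries (one row per animal)."""
    return pd.DataFrame([s.to_row() for s in summaries])


def _two_sample_t(a: np.ndarray, b: np.ndarray, method: str) -> tuple[float, float]:
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        # Degenerate zero-variance groups: identical means are a perfect
        # null (t=0, p=1); distinct means are infinitely separated.
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    with warnings.catch_warnings():
        # near-identical per-animal statistics are legitimate here (exact
        # within-animal SDs); scipy's precision warning is expected
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, equal_var=(method == "student"))
    return float(t), float(p)


def compare_groups(
    summaries: list[ROISummary],
    statistic: str = "mean",
    method: str = "welch",
    parameters: tuple[str, ...] = PARAMETER_NAMES,
) -> GroupComparison:
    """Two-sample t-tests per parameter on an animal-level statistic.

    ``statistic`` selects the per-animal within-ROI ``"mean"`` (global
    level) or ``"sd"`` (heterogeneity). ``method`` is ``"welch"``
    (default; robust to the unequal group variances this model produces)
    or ``"student"`` (pooled variance). Requires exactly two groups with
    at least two animals each.
    """
    if statistic not in ("mean", "sd"):
        raise ValueError(f"statistic must be 'mean' or 'sd', got {statistic!r}")
    if method not in ("welch", "student"):
        raise ValueError(f"method must be 'welch' or 'student', got {method!r}")
    groups: list[str] = []
    for s in summaries:
        if s.group not in groups:
            groups.append(s.group)
    if len(groups) != 2:
        raise ValueError(
            f"group comparison needs exactly two groups, got {groups}; "
            "a single-group study cannot be compared"
        )
    by_group = {g: [s for s in summaries if s.group == g] for g in groups}
    for g, members in by_group.items():
        if len(members) < 2:
            raise ValueError(f"group {g!r} has {len(members)} animal(s); need at least 2")

    rows = []
    for p in parameters:
        vals = {
            g: np.array([getattr(s, statistic)[p] for s in by_group[g]]) for g in groups
        }
        t, pval = _two_sample_t(vals[groups[0]], vals[groups[1]], method)
        row = {"parameter": p}
        for g in groups:
            row[f"mean_{g}"] = float(np.mean(vals[g]))
            row[f"sd_{g}"] = float(np.std(vals[g], ddof=1))
        row["t"] = t
        row["p"] = pval
        rows.append(row)
    table = pd.DataFrame(rows).set_index("parameter")
    return GroupComparison(
        statistic=statistic,
        method=method,
        groups=(groups[0], groups[1]),
        n_per_group={g: len(by_group[g]) for g in groups},
        table=table,
    )
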