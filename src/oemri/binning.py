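"""Equal-count binning of pooled lung pixels and per-bin group means.

Pixels from all animals of both groups are pooled and ranked on a
binning variable — lung density (S0_air) for the density analysis, or
dR2* for the uptake-vs-delivery analysis — and split into n_bins
(default 20) equal-count strata. Group means of the response parameters
are then taken within each common bin, which is what makes per-bin group
differences (and their permutation test) well-defined. A per-group
quantile mode is available for plotting-style curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import PARAMETER_NAMES

__all__ = [
    "PIXEL_TABLE_COLUMNS",
    "BinAssignment",
    "build_pixel_table",
    "assign_bins",
    "bin_group_means",
    "bin_group_means_per_group",
]

PIXEL_TABLE_COLUMNS = ("animal_id", "group") + PARAMETER_NAMES


@dataclass
class BinAssignment:
    """Result of rank-based equal-count binning.

    ``bin_idx`` aligns with the rows of the pixel table it was computed
    from; ``edges`` has length ``n_bins + 1`` (min value, then each bin's
    maximum) and is reported for interpretation — membership is by rank,
    not by edge lookup.
    """

    bin_idx: np.ndarray
    edges: np.ndarray
    n_bins: int
    binning_variable: str | None = None

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.bin_idx, minlength=self.n_bins)


def build_pixel_table(animals) -> pd.DataFrame:
    """One record per valid lung pixel across all animals.

    ``animals`` is an iterable of map objects (``ParameterMaps`` or
    ``GroundTruthMaps``) exposing ``parameters()``, ``valid()``,
    ``group`` and ``animal_id``. Animals contributing zero valid pixels
    are kept out with a warning. Raises ``ValueError`` if no pixels
    remain or an animal_id maps to more than one group.
    """
    frames = []
    seen: dict[str, str] = {}
    for maps in animals:
        if maps.animal_id in seen:
            raise ValueError(f"duplicate animal_id {maps.animal_id!r}")
        seen[maps.animal_id] = maps.group
        valid = maps.valid()
        n = int(valid.sum())
        if n == 0:
            warnings.warn(f"{maps.animal_id}: no valid pixels, contributes no records")
            continue
        data = {"animal_id": maps.animal_id, "group": maps.group}
        for name, arr in maps.parameters().items():
            data[name] = np.asarray(arr, dtype=float)[valid]
        frames.append(pd.DataFrame(data))
    if not frames:
        raise ValueError("no valid pixels in any animal")
    return pd.concat(frames, ignore_index=True)[list(PIXEL_TABLE_COLUMNS)]


def assign_bins(values: np.ndarray, n_bins: int) -> BinAssignment:
    """Rank-based equal-count assignment; counts differ by at most 1.

    Ties are broken deterministically by record order (stable sort).
    When the record count is not divisible by ``n_bins``, the lower bins
    receive the extra records. Raises ``ValueError`` for fewer records
    than bins or ``n_bins < 2``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be a 1D vector")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    n = v.size
    if n < n_bins:
        raise ValueError(f"{n} records cannot fill {n_bins} bins")
    if not np.all(np.isfinite(v)):
        raise ValueError("binning variable must be finite")
    order = np.argsort(v, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    bin_idx = np.empty(n, dtype=int)
    bin_idx[order] = np.repeat(np.arange(n_bins), sizes)
    sorted_v = v[order]
    edges = np.concatenate(([sorted_v[0]], sorted_v[np.cumsum(sizes) - 1]))
    return BinAssignment(bin_idx=bin_idx, edges=edges, n_bins=n_bins)


def bin_group_means(
    table: pd.DataFrame, bins: BinAssignment, response: str
) -> pd.DataFrame:
    """Per-bin per-group means of a response parameter.

    Returns a frame with one row per bin: edges, total pixel count, and
    per group its pixel count and mean (NaN when a group is absent from
    a bin). Requires both groups to be represented overall.
    """
    if response not in table.columns:
        raise ValueError(f"response {response!r} not in pixel table")
    if len(bins.bin_idx) != len(table):
        raise ValueError("bin assignment does not align with pixel table")
    groups = list(dict.fromkeys(table["group"]))
    agg = (
        table.assign(_bin=bins.bin_idx)
        .groupby(["_bin", "group"], sort=False)[response]
        .agg(["mean", "count"])
    )
    rows = []
    for b in range(bins.n_bins):
        row = {
            "bin": b,
            "left_edge": bins.edges[b],
            "right_edge": bins.edges[b + 1],
            "n_pixels": int(bins.counts[b]),
        }
        for g in groups:
            if (b, g) in agg.index:
                row[f"n_{g}"] = int(agg.loc[(b, g), "count"])
                row[f"mean_{g}"] = float(agg.loc[(b, g), "mean"])
            else:
                row[f"n_{g}"] = 0
                row[f"mean_{g}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def bin_group_means_per_group(
    table: pd.DataFrame, variable: str, n_bins: int, response: str
) -> dict[str, pd.DataFrame]:
    """Per-group quantile binning (each group gets its own edges).

    Convenience for plotting per-group curves; the pooled-edge
    :func:`bin_group_means` is what the permutation test is defined on.
    """
    out: dict[str, pd.DataFrame] = {}
    for g, sub in table.groupby("group", sort=False):
        bins = assign_bins(sub[variable].to_numpy(), n_bins)
        bins.binning_variable = variable
        agg = sub.assign(_bin=bins.bin_idx).groupby("_bin")[response].agg(["mean", "count"])
        out[g] = pd.DataFrame(
            {
                "bin": np.arange(n_bins),
                "left_edge": bins.edges[:-1],
                "right_edge": bins.edges[1:],
                "n_pixels": bins.counts,
                "mean": agg["mean"].reindex(range(n_bins)).to_numpy(),
            }
        )
    return out
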