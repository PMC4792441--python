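"""Animal-level permutation test and bootstrap for binned pixel data.

Pixels within an animal are strongly correlated, so the exchangeable
unit for inference is the animal: the permutation test shuffles group
labels across animals (all of an animal's pixels move together) and the
bootstrap resamples animals with replacement within each group. Bin
edges and observed differences are computed once from the unpermuted
data; only labels (or animal multiplicities) move.

The permutation p-value is the fraction of the N random relabelings
whose absolute per-bin group mean difference strictly exceeds the
observed one — no +1 smoothing, so the smallest reportable p is 0 and
the resolution is 1/N. Random relabelings are drawn with replacement
from the label-assignment space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinAssignment

__all__ = ["PermutationResult", "BootstrapResult", "permutation_test_bins", "bootstrap_bin_sd"]

#: Per-bin significance marking threshold used on reports.
SIGNIFICANCE_MARK_P = 0.1


@dataclass
class PermutationResult:
    """Per-bin observed difference (group1 - group2) and two-tailed p."""

    observed_diff: np.ndarray
    p_value: np.ndarray
    n_permutations: int
    seed: int
    groups: tuple[str, str]
    response: str

    @property
    def significant(self) -> np.ndarray:
        """Bins flagged at the report-marking threshold (p < 0.1)."""
        return self.p_value < SIGNIFICANCE_MARK_P


@dataclass
class BootstrapResult:
    """Per-bin per-group SD of the bin mean over bootstrap replicates."""

    sd: dict[str, np.ndarray]
    n_replicates: int
    seed: int
    response: str


def _animal_bin_matrices(
    table: pd.DataFrame, bins: BinAssignment, response: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Per-animal-per-bin response sums and pixel counts.

    Returns (sums, counts) of shape (n_animals, n_bins), the per-animal
    group labels, and the ordered group list. All resampling statistics
    reduce to weighted combinations of these matrices.
    """
    if response not in table.columns:
        raise ValueError(f"response {response!r} not in pixel table")
    if len(bins.bin_idx) != len(table):
        raise ValueError("bin assignment does not align with pixel table")
    animals = list(dict.fromkeys(table["animal_id"]))
    groups = list(dict.fromkeys(table["group"]))
    a_index = {a: i for i, a in enumerate(animals)}
    n_a, n_b = len(animals), bins.n_bins
    sums = np.zeros((n_a, n_b))
    counts = np.zeros((n_a, n_b))
    rows = table["animal_id"].map(a_index).to_numpy()
    np.add.at(sums, (rows, bins.bin_idx), table[response].to_numpy(dtype=float))
    np.add.at(counts, (rows, bins.bin_idx), 1.0)
    labels = np.array(
        [table.loc[table["animal_id"] == a, "group"].iloc[0] for a in animals]
    )
    return sums, counts, labels, groups


def _check_two_groups(labels: np.ndarray, groups: list[str]) -> None:
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    for g in groups:
        if int((labels == g).sum()) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 animals; cannot resample")


def permutation_test_bins(
    table: pd.DataFrame,
    bins: BinAssignment,
    response: str,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Animal-label permutation test of per-bin group mean differences.

    For each of ``n_permutations`` random relabelings (group sizes
    preserved), the per-bin group mean difference is recomputed from the
    fixed bins; p per bin is the fraction of relabelings with |diff|
    strictly greater than observed. Permutations where a group has no
    pixel in a bin contribute an undefined (NaN) difference, which never
    exceeds the observed one.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sums, counts, labels, groups = _animal_bin_matrices(table, bins, response)
    _check_two_groups(labels, groups)
    g1_mask = (labels == groups[0]).astype(float)
    n1 = int(g1_mask.sum())

    def group_diff(sel: np.ndarray) -> np.ndarray:
        # sel: (..., n_animals) 0/1 membership of group 1
        with np.errstate(invalid="ignore", divide="ignore"):
            m1 = (sel @ sums) / (sel @ counts)
            m2 = ((1.0 - sel) @ sums) / ((1.0 - sel) @ counts)
        return m1 - m2

    observed = group_diff(g1_mask)
    rng = np.random.default_rng(seed)
    n_a = labels.size
    p = np.zeros(bins.n_bins)
    chunk = 2000  # keep the permutation matrix small
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        keys = rng.random((m, n_a))
        order = np.argsort(keys, axis=1)
        sel = np.zeros((m, n_a))
        np.put_along_axis(sel, order[:, :n1], 1.0, axis=1)
        diffs = group_diff(sel)
        with np.errstate(invalid="ignore"):
            p += (np.abs(diffs) > np.abs(observed)[None, :]).sum(axis=0)
        done += m
    p /= n_permutations
    return PermutationResult(
        observed_diff=observed,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        groups=(groups[0], groups[1]),
        response=response,
    )


def bootstrap_bin_sd(
    table: pd.DataFrame,
    bins: BinAssignment,
    response: str,
    n_replicates: int = 2000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap SDs of per-bin per-group means, resampling animals.

    Animals are drawn with replacement within their own group; per
    replicate the per-bin group means are recomputed against the fixed
    bins; the SD over replicates (n-1 denominator) estimates the
    sampling spread of each binned mean. Replicates leaving a bin empty
    for a group are ignored for that bin.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    sums, counts, labels, groups = _animal_bin_matrices(table, bins, response)
    _check_two_groups(labels, groups)
    rng = np.random.default_rng(seed)
    sd: dict[str, np.ndarray] = {}
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        n_g = idx.size
        mult = rng.multinomial(n_g, np.full(n_g, 1.0 / n_g), size=n_replicates)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = (mult @ sums[idx]) / (mult @ counts[idx])
        sd[g] = np.nanstd(means, axis=0, ddof=1)
    return BootstrapResult(sd=sd, n_replicates=n_replicates, seed=seed, response=response)
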