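"""Indicator species analysis (IndVal) with permutation significance.

For OTU i and group j the indicator value is the product of

* specificity A_ij — the OTU's abundance concentrated in group j, and
* fidelity   B_ij — the fraction of group-j samples where the OTU occurs;

IV_i = max_j A_ij * B_ij, with the maximizing group reported as the OTU's
indicator group.  An OTU scoring IV = 1 occurs in every sample of one
group and nowhere else.  Significance comes from permuting group labels.

Two specificity conventions are offered: the default computes A from group
total abundances; ``group_equalized=True`` computes it from group mean
abundances, which corrects for unequal group sizes (the two coincide for
balanced designs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import to_relative
from .tables_io import CountTable

__all__ = ["indval", "filter_indicators", "IndicatorResult"]

#: reporting filter used for "good" indicators: IV strictly above 0.3 and
#: p strictly below 0.05
DEFAULT_IV_MIN = 0.3
DEFAULT_P_MAX = 0.05


@dataclass
class IndicatorResult:
    """Tidy per-OTU indicator statistics (one row per OTU)."""

    table: pd.DataFrame  # otu_id, group, iv, p_value, specificity, fidelity, mean abunds
    group_equalized: bool
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _iv_components(values: np.ndarray, onehot: np.ndarray, sizes: np.ndarray,
                   group_equalized: bool):
    """Return (A, B, IV) matrices of shape (n_otus, n_groups)."""
    totals = values @ onehot                      # per-group abundance sums
    if group_equalized:
        totals = totals / sizes                   # group means
    denom = totals.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, totals / denom, 0.0)
    occ = (values > 0).astype(float) @ onehot
    b = occ / sizes
    return a, b, a * b


def indval(table: CountTable, groups, n_permutations: int = 9999,
           seed: int | None = None, group_equalized: bool = False) -> IndicatorResult:
    """Indicator value of every OTU for a grouping of samples.

    ``groups``: mapping/Series/sequence of group labels aligned to the
    table's samples; >= 2 groups, each with >= 2 samples.  The permutation
    p-value uses the (1 + hits)/(1 + permutations) convention on the
    per-OTU maximum IV.
    """
    labels = _labels(groups, table.sample_ids)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("indval needs at least two groups")
    sizes_ser = pd.Series(labels).value_counts()
    singles = sizes_ser[sizes_ser < 2]
    if len(singles):
        raise ValueError(f"singleton group(s): {list(singles.index)}")
    rel = table if table.relative else to_relative(table)
    values = rel.data.to_numpy(dtype=float)
    n_samples = values.shape[1]
    onehot = np.zeros((n_samples, len(uniq)))
    onehot[np.arange(n_samples), codes] = 1.0
    sizes = onehot.sum(axis=0)
    a, b, iv = _iv_components(values, onehot, sizes, group_equalized)
    best = iv.argmax(axis=1)
    obs = iv[np.arange(len(best)), best]
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(obs))
    for _ in range(n_permutations):
        perm = rng.permutation(n_samples)
        _, _, piv = _iv_components(values, onehot[perm], sizes, group_equalized)
        hits += piv.max(axis=1) >= obs - 1e-15
    p = (1 + hits) / (1 + n_permutations)
    group_means = values @ onehot / sizes
    frame = pd.DataFrame({
        "otu_id": rel.otu_ids,
        "group": uniq[best],
        "iv": obs,
        "p_value": p,
        "specificity": a[np.arange(len(best)), best],
        "fidelity": b[np.arange(len(best)), best],
    })
    for j, g in enumerate(uniq):
        frame[f"mean_abundance_{g}"] = group_means[:, j]
    return IndicatorResult(frame, group_equalized=group_equalized,
                           n_permutations=n_permutations)


def filter_indicators(results: IndicatorResult | pd.DataFrame,
                      iv_min: float = DEFAULT_IV_MIN,
                      p_max: float = DEFAULT_P_MAX) -> pd.DataFrame:
    """Keep good indicators: IV strictly > ``iv_min`` and p strictly < ``p_max``,
    sorted by IV descending."""
    frame = results.to_frame() if isinstance(results, IndicatorResult) else results
    if not len(frame):
        return frame.copy()
    kept = frame[(frame["iv"] > iv_min) & (frame["p_value"] < p_max)]
    return kept.sort_values("iv", ascending=False, kind="stable").reset_index(drop=True)


def _labels(groups, ids) -> np.ndarray:
    if isinstance(groups, (pd.Series, dict)):
        series = pd.Series(groups)
        missing = [i for i in ids if i not in series.index]
        if missing:
            raise ValueError(f"no group label for sample(s): {missing}")
        return series.loc[list(ids)].to_numpy()
    labels = np.asarray(list(groups))
    if len(labels) != len(ids):
        raise ValueError("group labels length does not match samples")
    return labels
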