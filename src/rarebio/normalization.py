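"""Read-depth normalization: rarefaction and relative abundance.

Amplicon libraries differ in sequencing depth, so per-sample comparisons
require either rarefying (random subsampling without replacement to a
common depth — a multivariate hypergeometric draw per sample) or dividing
by library size.  The study design this package emulates rarefies to the
minimum library size (14,825 reads) before all downstream analyses, and
separately subsamples to 100 reads per sample for a robustness check at
clone-library sequencing effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CountTable

__all__ = [
    "DEFAULT_DEPTH",
    "ROBUSTNESS_DEPTH",
    "rarefy",
    "subsample_to",
    "rarefaction_curve",
    "expected_richness",
    "to_relative",
    "RarefactionCurve",
]

logger = logging.getLogger(__name__)

#: depth used for the main analysis (minimum per-sample read count in the
#: emulated design)
DEFAULT_DEPTH = 14_825
#: depth of the low-effort robustness resampling
ROBUSTNESS_DEPTH = 100


def rarefy(table: CountTable, depth: int = DEFAULT_DEPTH, seed: int | None = None,
           keep_zero_otus: bool = True) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning.  OTU rows that end up all-zero are retained (and reported at
    debug level) unless ``keep_zero_otus=False``; downstream biosphere
    classification treats zero cells as absent either way.

    Reproducible: the same ``seed`` yields a bit-identical table.
    """
    if table.relative:
        raise ValueError("rarefy requires integer counts, not relative abundances")
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy(dtype=np.int64)
    sums = counts.sum(axis=0)
    keep_cols = sums >= depth
    if not keep_cols.all():
        dropped = [s for s, k in zip(table.sample_ids, keep_cols) if not k]
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    out = np.empty((counts.shape[0], int(keep_cols.sum())), dtype=np.int64)
    j = 0
    for col, k in enumerate(keep_cols):
        if not k:
            continue
        if sums[col] == depth:  # exhaustive draw
            out[:, j] = counts[:, col]
        else:
            out[:, j] = rng.multivariate_hypergeometric(counts[:, col], depth)
        j += 1
    samples = [s for s, k in zip(table.sample_ids, keep_cols) if k]
    df = pd.DataFrame(out, index=table.otu_ids, columns=samples)
    if keep_zero_otus:
        zero = df.index[df.sum(axis=1) == 0]
        if len(zero):
            logger.debug("rarefy: %d OTU(s) with zero reads after rarefaction", len(zero))
    else:
        df = df.loc[df.sum(axis=1) > 0]
    tax = table.taxonomy.loc[df.index] if table.taxonomy is not None else None
    return CountTable(df, taxonomy=tax)


def subsample_to(table: CountTable, depth: int = ROBUSTNESS_DEPTH,
                 seed: int | None = None) -> CountTable:
    """Named pipeline step: rarefy to a shallow depth (default 100 reads).

    Identical contract to :func:`rarefy`; exists so the robustness
    experiment at clone-library effort is an explicit, auditable stage.
    """
    return rarefy(table, depth=depth, seed=seed)


@dataclass
class RarefactionCurve:
    """Mean observed richness of one sample at increasing subsampling depths."""

    sample_id: str
    depths: np.ndarray
    mean_richness: np.ndarray
    replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_id,
            "depth": self.depths,
            "mean_richness": self.mean_richness,
            "replicates": self.replicates,
        })


def rarefaction_curve(table: CountTable, depths, replicates: int = 10,
                      seed: int | None = None) -> list[RarefactionCurve]:
    """Monte-Carlo rarefaction curves, one per sample.

    ``depths`` must be increasing; depths above a sample's total are
    skipped for that sample.
    """
    depths = np.asarray(list(depths), dtype=np.int64)
    if (np.diff(depths) <= 0).any():
        raise ValueError("depths must be strictly increasing")
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(seed)
    curves = []
    counts = table.data.to_numpy(dtype=np.int64)
    for j, sample in enumerate(table.sample_ids):
        col = counts[:, j]
        total = int(col.sum())
        ds = depths[depths <= total]
        rich = np.zeros(len(ds))
        for i, d in enumerate(ds):
            if d == total:
                rich[i] = float((col > 0).sum())
                continue
            acc = 0.0
            for _ in range(replicates):
                sub = rng.multivariate_hypergeometric(col, int(d))
                acc += float((sub > 0).sum())
            rich[i] = acc / replicates
        curves.append(RarefactionCurve(sample, ds, rich, replicates))
    return curves


def expected_richness(counts, depth: int) -> float:
    """Closed-form expected richness under rarefaction (hypergeometric).

    E[S_d] = sum_i (1 - C(N - n_i, d) / C(N, d)) for per-OTU counts n_i and
    library size N.  Used as the analytic oracle for the Monte-Carlo
    rarefaction machinery.
    """
    from scipy.special import gammaln

    n = np.asarray(counts, dtype=np.int64)
    n = n[n > 0]
    N = int(n.sum())
    if depth > N:
        raise ValueError("depth exceeds library size")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = 0.0
    for ni in n:
        if N - ni < depth:
            out += 1.0
        else:
            out += 1.0 - np.exp(log_comb(N - ni, depth) - log_comb(N, depth))
    return float(out)


def to_relative(table: CountTable) -> CountTable:
    """Convert counts to per-sample relative abundances (column-stochastic)."""
    values = table.data.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise ValueError(f"zero-sum sample(s): {bad}")
    df = pd.DataFrame(values / sums, index=table.otu_ids, columns=table.sample_ids)
    return CountTable(df, taxonomy=table.taxonomy, relative=True)
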