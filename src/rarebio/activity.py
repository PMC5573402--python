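"""rRNA:rDNA comparison as a proxy for metabolic activity.

Ribosome content scales with protein synthesis, so an OTU whose relative
abundance in an rRNA (transcript) library exceeds its relative abundance in
the paired rDNA (gene) library is inferred to be disproportionately active.
For the OTUs common to both datasets we regress log10 mean rRNA fraction on
log10 mean rDNA fraction (ordinary least squares); a regression line
displaced above the 1:1 line — a positive mean vertical deviation — marks a
community whose typical member is metabolically active.

Means are taken across all paired samples (zeros included) before the log,
so no pseudocounts are needed: a common OTU has nonzero total reads in both
datasets, hence strictly positive means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biosphere import BiosphereThresholds, ABUNDANT, INTERMEDIATE, RARE, CLASS_NAMES
from .normalization import to_relative
from .tables_io import CountTable

__all__ = ["PairedTables", "ActivityRegression", "common_otu_means",
           "fit_activity", "classify_activity"]


@dataclass
class PairedTables:
    """Aligned rRNA and rDNA count tables sharing OTU identifiers."""

    rna: CountTable
    dna: CountTable

    def __post_init__(self) -> None:
        if not len(self.rna.otu_ids) or not len(self.dna.otu_ids):
            raise ValueError("both paired tables must be nonempty")

    @property
    def common_otus(self) -> list[str]:
        rna_present = {o for o, t in self.rna.data.sum(axis=1).items() if t > 0}
        dna_present = {o for o, t in self.dna.data.sum(axis=1).items() if t > 0}
        return [o for o in self.rna.otu_ids if o in rna_present and o in dna_present]


@dataclass
class ActivityRegression:
    """OLS fit of log10 mean RNA fraction (y) on log10 mean DNA fraction (x)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    mean_deviation: float  #: signed mean of (y - x); >0 means RNA-shifted
    slope_stderr: float
    intercept_stderr: float


def common_otu_means(paired: PairedTables) -> pd.DataFrame:
    """Across-sample mean relative abundance of each common OTU in both datasets.

    Returns a frame indexed by OTU id with columns ``mean_rna`` and
    ``mean_dna``, both strictly positive by the common-OTU definition.
    """
    common = paired.common_otus
    if not common:
        raise ValueError("no OTUs common to the rRNA and rDNA tables")
    rna_rel = paired.rna if paired.rna.relative else to_relative(paired.rna)
    dna_rel = paired.dna if paired.dna.relative else to_relative(paired.dna)
    return pd.DataFrame({
        "mean_rna": rna_rel.data.loc[common].mean(axis=1),
        "mean_dna": dna_rel.data.loc[common].mean(axis=1),
    })


def fit_activity(points: pd.DataFrame) -> ActivityRegression:
    """OLS on log10-log10 axes plus the signed mean deviation from y = x.

    ``points`` needs ``mean_dna`` (x) and ``mean_rna`` (y) columns, all
    strictly positive; at least 3 points are required for a reported fit.
    """
    if len(points) < 3:
        raise ValueError(f"need >= 3 points for a regression, got {len(points)}")
    x = np.log10(points["mean_dna"].to_numpy(dtype=float))
    y = np.log10(points["mean_rna"].to_numpy(dtype=float))
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("activity regression requires strictly positive means")
    res = stats.linregress(x, y)
    return ActivityRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=len(points),
        mean_deviation=float(np.mean(y - x)),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
    )


def _mean_class(value: float, thresholds: BiosphereThresholds) -> str:
    if value > thresholds.abundant_min:
        return CLASS_NAMES[ABUNDANT]
    if value >= thresholds.rare_max:
        return CLASS_NAMES[INTERMEDIATE]
    return CLASS_NAMES[RARE]


def classify_activity(paired: PairedTables,
                      thresholds: BiosphereThresholds = BiosphereThresholds()) -> pd.DataFrame:
    """Place every common OTU on the 3x3 (DNA class x RNA class) grid.

    The same abundance thresholds as the biosphere partition are applied to
    the across-sample *mean* fractions, mirroring the threshold lines drawn
    on an RNA-vs-DNA scatter.  Returns the means frame with ``dna_class``
    and ``rna_class`` columns appended.
    """
    means = common_otu_means(paired)
    means["dna_class"] = [_mean_class(v, thresholds) for v in means["mean_dna"]]
    means["rna_class"] = [_mean_class(v, thresholds) for v in means["mean_rna"]]
    return means
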