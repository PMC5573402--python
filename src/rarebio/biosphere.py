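"""Abundant / intermediate / rare biosphere partitioning and transitions.

Every (OTU, sample) occurrence is classed by its within-sample relative
abundance r:

* abundant:      r > 1%        (strictly above the upper threshold)
* intermediate:  0.01% <= r <= 1%   (closed interval)
* rare:          0 < r < 0.01%      (strictly below the lower threshold)
* absent:        r = 0

Zero counts are "absent", not "rare": the class scheme speaks of reads *in*
a sample, which presupposes presence, and absent cells never enter
transition denominators.

The transition summary asks, for each class c, how the occurrences of the
OTUs ever assigned c distribute over the three classes — the membership-
table census ("all_occurrences").  An alternative pairing tabulates ordered
class pairs between temporally adjacent samples of the same site and depth
("consecutive_months"); both are offered because published descriptions of
this census are ambiguous about pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import to_relative
from .tables_io import CountTable

__all__ = [
    "ABSENT", "RARE", "INTERMEDIATE", "ABUNDANT", "CLASS_NAMES",
    "BiosphereThresholds", "classify", "class_fractions",
    "pooled_richness_fractions", "transitions", "class_subtables",
    "shared_otu_fractions", "modal_class",
]

# integer codes for the per-cell classification matrix
ABSENT, RARE, INTERMEDIATE, ABUNDANT = 0, 1, 2, 3
CLASS_NAMES = {ABSENT: "absent", RARE: "rare", INTERMEDIATE: "intermediate", ABUNDANT: "abundant"}
_PRESENT = (ABUNDANT, INTERMEDIATE, RARE)


@dataclass(frozen=True)
class BiosphereThresholds:
    """Relative-abundance cut-offs separating the three biospheres."""

    abundant_min: float = 0.01
    rare_max: float = 0.0001

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_max < self.abundant_min < 1.0):
            raise ValueError(
                f"require 0 < rare_max < abundant_min < 1, got "
                f"rare_max={self.rare_max}, abundant_min={self.abundant_min}")


@dataclass
class BiosphereClassification:
    """Per-(OTU, sample) biosphere category, stored as integer codes."""

    codes: pd.DataFrame  # int matrix, OTUs x samples
    thresholds: BiosphereThresholds

    @property
    def otu_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.columns)

    def labels(self) -> pd.DataFrame:
        return self.codes.replace(CLASS_NAMES)

    def members(self, code: int) -> list[str]:
        """OTUs assigned the class in at least one sample."""
        mask = (self.codes.to_numpy() == code).any(axis=1)
        return [o for o, m in zip(self.otu_ids, mask) if m]


def classify(table: CountTable,
             thresholds: BiosphereThresholds = BiosphereThresholds()) -> BiosphereClassification:
    """Classify every occurrence by per-sample relative abundance."""
    rel = table if table.relative else to_relative(table)
    r = rel.data.to_numpy(dtype=float)
    codes = np.full(r.shape, ABSENT, dtype=np.int8)
    codes[(r > 0) & (r < thresholds.rare_max)] = RARE
    codes[(r >= thresholds.rare_max) & (r <= thresholds.abundant_min)] = INTERMEDIATE
    codes[r > thresholds.abundant_min] = ABUNDANT
    df = pd.DataFrame(codes, index=rel.data.index, columns=rel.data.columns)
    return BiosphereClassification(df, thresholds)


def class_fractions(cls: BiosphereClassification, table: CountTable) -> pd.DataFrame:
    """Per-sample read-fractions and OTU-richness-fractions of each class.

    Returns a tidy frame with one row per (sample, class) holding
    ``read_fraction`` (reads in the class / total reads of the sample) and
    ``richness_fraction`` (OTUs in the class / present OTUs of the sample).
    Each triple over {abundant, intermediate, rare} sums to 1.
    """
    codes = cls.codes.to_numpy()
    counts = table.data.to_numpy(dtype=float)
    if codes.shape != counts.shape:
        raise ValueError("classification and table shapes differ")
    totals = counts.sum(axis=0)
    present = (codes != ABSENT).sum(axis=0).astype(float)
    rows = []
    for code in (ABUNDANT, INTERMEDIATE, RARE):
        mask = codes == code
        reads = np.where(mask, counts, 0.0).sum(axis=0)
        rich = mask.sum(axis=0)
        for j, sample in enumerate(cls.sample_ids):
            rows.append({
                "sample_id": sample,
                "biosphere": CLASS_NAMES[code],
                "read_fraction": reads[j] / totals[j] if totals[j] else 0.0,
                "richness_fraction": rich[j] / present[j] if present[j] else 0.0,
                "n_otus": int(rich[j]),
            })
    return pd.DataFrame(rows)


def pooled_richness_fractions(cls: BiosphereClassification) -> pd.Series:
    """Fraction of total observed richness ever assigned to each class.

    For class c this is |{OTUs classed c in >=1 sample}| / |{OTUs present
    in >=1 sample}|.  Classes overlap across samples, so the three
    fractions may sum to more than 1.
    """
    codes = cls.codes.to_numpy()
    present_any = (codes != ABSENT).any(axis=1)
    denom = int(present_any.sum())
    out = {}
    for code in (ABUNDANT, INTERMEDIATE, RARE):
        out[CLASS_NAMES[code]] = (codes == code).any(axis=1).sum() / denom if denom else 0.0
    return pd.Series(out, name="richness_fraction")


def transitions(cls: BiosphereClassification, pairing: str = "all_occurrences",
                meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Transition summary among the three biospheres.

    ``all_occurrences``: for each source class c, take the OTUs assigned c
    in at least one sample (the class-c membership table) and tabulate the
    class of *every* present occurrence of those OTUs; report proportions.

    ``consecutive_months``: requires ``meta`` with ``site``, ``month`` and
    ``depth_layer`` columns; tabulates ordered class pairs (class at t ->
    class at t+1) between temporally adjacent samples of the same site and
    depth layer, over occurrences present at both times.

    Returns a frame indexed by source class with columns ``to_abundant``,
    ``to_intermediate``, ``to_rare`` (each row sums to 1) plus the backing
    counts.
    """
    if pairing == "all_occurrences":
        pairs = _occurrence_census(cls)
    elif pairing == "consecutive_months":
        if meta is None:
            raise ValueError("consecutive_months pairing requires sample metadata")
        pairs = _consecutive_pairs(cls, meta)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    rows = []
    for source in (ABUNDANT, INTERMEDIATE, RARE):
        tallies = pairs.get(source, {})
        total = sum(tallies.values())
        row = {"source": CLASS_NAMES[source], "n_occurrences": total}
        for target in (ABUNDANT, INTERMEDIATE, RARE):
            n = tallies.get(target, 0)
            row[f"to_{CLASS_NAMES[target]}"] = n / total if total else np.nan
            row[f"n_to_{CLASS_NAMES[target]}"] = n
        rows.append(row)
    return pd.DataFrame(rows).set_index("source")


def _occurrence_census(cls: BiosphereClassification) -> dict[int, dict[int, int]]:
    codes = cls.codes.to_numpy()
    out: dict[int, dict[int, int]] = {}
    for source in _PRESENT:
        member_rows = (codes == source).any(axis=1)
        occ = codes[member_rows]
        occ = occ[occ != ABSENT]
        vals, counts = np.unique(occ, return_counts=True)
        out[source] = dict(zip(vals.tolist(), counts.tolist()))
    return out


def _consecutive_pairs(cls: BiosphereClassification, meta: pd.DataFrame) -> dict[int, dict[int, int]]:
    codes = cls.codes
    out: dict[int, dict[int, int]] = {s: {} for s in _PRESENT}
    meta = meta.loc[[s for s in cls.sample_ids if s in meta.index]]
    group_cols = [c for c in ("site", "depth_layer") if c in meta.columns]
    if "month" not in meta.columns:
        raise ValueError("consecutive_months pairing requires a 'month' column")
    groups = meta.groupby(group_cols) if group_cols else [(None, meta)]
    for _, grp in groups:
        ordered = grp.sort_values("month")
        samples = list(ordered.index)
        for a, b in zip(samples[:-1], samples[1:]):
            ca = codes[a].to_numpy()
            cb = codes[b].to_numpy()
            both = (ca != ABSENT) & (cb != ABSENT)
            for source in _PRESENT:
                sel = both & (ca == source)
                vals, counts = np.unique(cb[sel], return_counts=True)
                for v, n in zip(vals.tolist(), counts.tolist()):
                    out[source][v] = out[source].get(v, 0) + n
    return out


def class_subtables(cls: BiosphereClassification, table: CountTable) -> dict[str, CountTable]:
    """Count subtables of the OTUs ever assigned to each class.

    An OTU abundant in one sample and rare in another appears in both
    subtables, so the union of subtable OTU sets is the set of all present
    OTUs (with overlaps).  Empty classes yield 0-row tables.
    """
    out = {}
    for code in (ABUNDANT, INTERMEDIATE, RARE):
        members = cls.members(code)
        sub = table.data.loc[members]
        tax = table.taxonomy.loc[members] if table.taxonomy is not None else None
        out[CLASS_NAMES[code]] = CountTable(sub.copy(), taxonomy=tax, relative=table.relative)
    return out


def shared_otu_fractions(tables: dict[str, CountTable]) -> pd.DataFrame:
    """Pairwise and exclusive OTU-overlap fractions between named groups.

    For groups (g, h): shared fraction = |OTUs(g) & OTUs(h)| / |OTUs(g)|
    (relative to the focal group g, hence asymmetric); the exclusive
    fraction of g is the share of its OTUs found in no other group.  An
    OTU counts as present in a group when it has nonzero reads in any of
    the group's samples.
    """
    if len(tables) < 2:
        raise ValueError("need at least two named groups")
    otu_sets = {name: {o for o, nz in zip(t.otu_ids, (t.data.to_numpy() > 0).any(axis=1)) if nz}
                for name, t in tables.items()}
    rows = []
    names = list(otu_sets)
    for g in names:
        others = set().union(*(otu_sets[h] for h in names if h != g))
        denom = len(otu_sets[g])
        for h in names:
            if h == g:
                continue
            rows.append({
                "focal": g, "other": h,
                "shared_fraction": len(otu_sets[g] & otu_sets[h]) / denom if denom else np.nan,
            })
        rows.append({
            "focal": g, "other": "(exclusive)",
            "shared_fraction": len(otu_sets[g] - others) / denom if denom else np.nan,
        })
    return pd.DataFrame(rows)


def modal_class(cls: BiosphereClassification, table: CountTable,
                sample_ids=None) -> pd.Series:
    """Modal (most frequent) present class of each OTU within a sample group.

    Ties break toward the class in which the OTU carries more total reads.
    OTUs absent from every selected sample map to "absent".
    """
    cols = list(sample_ids) if sample_ids is not None else cls.sample_ids
    codes = cls.codes[cols].to_numpy()
    counts = table.data[cols].to_numpy(dtype=float)
    out = {}
    for i, otu in enumerate(cls.otu_ids):
        row = codes[i]
        present = row != ABSENT
        if not present.any():
            out[otu] = "absent"
            continue
        vals, freq = np.unique(row[present], return_counts=True)
        best = freq == freq.max()
        if best.sum() == 1:
            out[otu] = CLASS_NAMES[int(vals[best][0])]
        else:
            tied = vals[best]
            reads = [counts[i][row == v].sum() for v in tied]
            out[otu] = CLASS_NAMES[int(tied[int(np.argmax(reads))])]
    return pd.Series(out, name="modal_class")
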