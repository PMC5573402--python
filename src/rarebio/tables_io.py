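"""Tabular containers and I/O for OTU-by-sample community data.

The central object is :class:`CountTable`: an OTU x sample matrix of
non-negative integer read counts, optionally carrying a per-OTU taxonomy
string.  Sample metadata and environmental measurements travel as plain
:class:`pandas.DataFrame` objects indexed by sample id; helpers here
validate them and align the three inputs onto a common, ordered sample set.

Formats supported: a TSV matrix (header row of sample ids, first column of
OTU ids, optional trailing ``taxonomy`` column, ``#`` comment lines
ignored) and dense BIOM 1.0 JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "ValidationError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_env_table",
    "align_tables",
    "export_network",
]

METADATA_COLUMNS = ("site", "month", "depth_layer", "nucleic_acid", "salinity", "temperature")
DEPTH_LAYERS = ("surface", "middle", "bottom")


class ValidationError(ValueError):
    """Raised when an input table violates its invariants."""


@dataclass
class CountTable:
    """OTU x sample matrix of sequence read counts.

    Parameters
    ----------
    data :
        DataFrame with OTU ids as index, sample ids as columns.  Values are
        non-negative integers unless ``relative=True``, in which case they
        are per-sample fractions.
    taxonomy :
        Optional per-OTU lineage strings (semicolon-delimited ranks),
        indexed like ``data``.
    relative :
        Whether the table stores relative abundances rather than counts.
        Conversion happens in :mod:`rarebio.normalization`; the flag keeps
        the two states from being mixed up silently.
    """

    data: pd.DataFrame
    taxonomy: pd.Series | None = None
    relative: bool = field(default=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU id(s): {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dup}")
        values = df.to_numpy()
        if values.size == 0:
            return
        if np.isnan(values.astype(float)).any():
            raise ValidationError("count table contains missing values")
        if (values.astype(float) < 0).any():
            raise ValidationError("negative values in count table")
        if not self.relative:
            if not np.allclose(values.astype(float), np.round(values.astype(float))):
                raise ValidationError("non-integer counts in a count table")
            self.data = df.astype(np.int64)
            empty = df.columns[values.sum(axis=0) == 0].tolist()
            if empty:
                raise ValidationError(f"sample(s) with zero total reads: {empty}")
        if self.taxonomy is not None and not self.taxonomy.index.equals(df.index):
            self.taxonomy = self.taxonomy.reindex(df.index)

    # -- conveniences ----------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids) -> "CountTable":
        sub = self.data.loc[:, list(sample_ids)]
        return CountTable(sub.copy(), taxonomy=self.taxonomy, relative=self.relative)

    def select_otus(self, otu_ids) -> "CountTable":
        sub = self.data.loc[list(otu_ids)]
        tax = self.taxonomy.loc[list(otu_ids)] if self.taxonomy is not None else None
        return CountTable(sub.copy(), taxonomy=tax, relative=self.relative)

    def copy(self) -> "CountTable":
        tax = self.taxonomy.copy() if self.taxonomy is not None else None
        return CountTable(self.data.copy(), taxonomy=tax, relative=self.relative)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path, format: str = "tsv_matrix", relative: bool = False) -> CountTable:
    """Read a count table from ``path`` in ``tsv_matrix`` or ``biom`` format."""
    if format == "tsv_matrix":
        return _read_tsv_matrix(path, relative=relative)
    if format == "biom":
        return _read_biom_json(path, relative=relative)
    raise ValueError(f"unknown format {format!r}; expected 'tsv_matrix' or 'biom'")


def write_count_table(table: CountTable, path, format: str = "tsv_matrix") -> None:
    if format == "tsv_matrix":
        _write_tsv_matrix(table, path)
    elif format == "biom":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv_matrix' or 'biom'")


def _read_tsv_matrix(path, relative: bool) -> CountTable:
    # '#' marks comment lines, except the QIIME-style '#OTU_ID ...' header
    with open(path, encoding="utf-8") as fh:
        lines = []
        for line in fh:
            if line.startswith("#") and not line.upper().startswith("#OTU"):
                continue
            lines.append(line.lstrip("#"))
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    taxonomy = None
    if len(df.columns) and df.columns[-1].lower() == "taxonomy":
        taxonomy = df.iloc[:, -1].astype(str)
        df = df.iloc[:, :-1]
    return CountTable(df.astype(float), taxonomy=taxonomy, relative=relative)


def _write_tsv_matrix(table: CountTable, path) -> None:
    df = table.data.copy()
    df.index.name = "#OTU_ID"
    if table.taxonomy is not None:
        df = df.assign(taxonomy=table.taxonomy)
    df.to_csv(path, sep="\t")


def _read_biom_json(path, relative: bool) -> CountTable:
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    shape = tuple(doc["shape"])
    if doc.get("matrix_type", "dense") == "dense":
        mat = np.asarray(doc["data"], dtype=float)
    else:  # sparse triplets [row, col, value]
        mat = np.zeros(shape, dtype=float)
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    df = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)
    taxonomy = None
    if doc["rows"] and doc["rows"][0].get("metadata") and "taxonomy" in doc["rows"][0]["metadata"]:
        tax = [";".join(r["metadata"]["taxonomy"]) if isinstance(r["metadata"]["taxonomy"], list)
               else str(r["metadata"]["taxonomy"]) for r in doc["rows"]]
        taxonomy = pd.Series(tax, index=otu_ids)
    return CountTable(df, taxonomy=taxonomy, relative=relative)


def _write_biom_json(table: CountTable, path) -> None:
    rows = []
    for otu in table.otu_ids:
        meta = None
        if table.taxonomy is not None and pd.notna(table.taxonomy.get(otu)):
            meta = {"taxonomy": str(table.taxonomy[otu]).split(";")}
        rows.append({"id": otu, "metadata": meta})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "rarebio",
        "matrix_type": "dense",
        "matrix_element_type": "float" if table.relative else "int",
        "shape": list(table.shape),
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.data.to_numpy().tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (one row per sample id) and validate it."""
    meta = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    meta.index = meta.index.astype(str)
    validate_metadata(meta)
    return meta


def validate_metadata(meta: pd.DataFrame) -> None:
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample id(s) in metadata: {dup}")
    if "salinity" in meta and (meta["salinity"].dropna() < 0).any():
        raise ValidationError("negative salinity in metadata")
    if "month" in meta:
        months = meta["month"].dropna()
        if ((months < 1) | (months > 12)).any():
            raise ValidationError("month outside 1-12 in metadata")
    if "depth_layer" in meta:
        bad = set(meta["depth_layer"].dropna()) - set(DEPTH_LAYERS)
        if bad:
            raise ValidationError(f"unknown depth layer(s): {sorted(bad)}")


def read_env_table(path) -> pd.DataFrame:
    """Read the sample x environmental-variable table (missing values allowed)."""
    env = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    env.index = env.index.astype(str)
    if env.index.has_duplicates:
        dup = env.index[env.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample id(s) in env table: {dup}")
    if env.columns.has_duplicates:
        raise ValidationError("duplicate environmental variable names")
    return env


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentReport:
    """Book-keeping from :func:`align_tables`.

    ``dropped`` maps each cause ("not_in_table" / "not_in_metadata" /
    "not_in_env") to the sample ids dropped for it; ``env_incomplete``
    lists retained samples with >=1 missing environmental value — they stay
    in community-only analyses and are excluded pairwise from
    env-dependent ones.
    """

    dropped: dict[str, list[str]]
    env_incomplete: list[str]

    @property
    def n_dropped(self) -> int:
        return len(set().union(*map(set, self.dropped.values()))) if self.dropped else 0


def align_tables(table: CountTable, meta: pd.DataFrame | None = None,
                 env: pd.DataFrame | None = None):
    """Align a count table, metadata and env table onto shared samples.

    Returns ``(table, meta, env, report)`` with identical sample order
    everywhere (the table's order, restricted to the intersection).
    Samples missing from any provided input are dropped and recorded;
    samples with missing env *values* are retained but flagged.
    """
    order = list(table.sample_ids)
    keep = set(order)
    dropped: dict[str, list[str]] = {}
    if meta is not None:
        missing = sorted(keep - set(meta.index))
        if missing:
            dropped["not_in_metadata"] = missing
        keep &= set(meta.index)
        extra = sorted(set(meta.index) - set(order))
        if extra:
            dropped.setdefault("not_in_table", []).extend(extra)
    if env is not None:
        missing = sorted(keep - set(env.index))
        if missing:
            dropped["not_in_env"] = missing
        keep &= set(env.index)
        extra = sorted(set(env.index) - set(order) - set(dropped.get("not_in_table", [])))
        if extra:
            dropped.setdefault("not_in_table", []).extend(extra)
    shared = [s for s in order if s in keep]
    if not shared:
        raise ValidationError("no overlapping samples across inputs")
    out_table = table.select_samples(shared)
    out_meta = meta.loc[shared].copy() if meta is not None else None
    out_env = env.loc[shared].copy() if env is not None else None
    env_incomplete: list[str] = []
    if out_env is not None:
        mask = out_env.isna().any(axis=1)
        env_incomplete = list(out_env.index[mask])
    report = AlignmentReport(dropped=dropped, env_incomplete=env_incomplete)
    return out_table, out_meta, out_env, report


# ---------------------------------------------------------------------------
# bipartite sample-OTU network export
# ---------------------------------------------------------------------------

def export_network(table: CountTable, min_fraction: float = 0.0,
                   weighted: bool = True, path=None) -> pd.DataFrame:
    """Edge list of the bipartite sample-OTU graph.

    One edge per nonzero (OTU, sample) cell whose within-sample relative
    abundance is >= ``min_fraction``; edge weight is that fraction (or 1.0
    for every edge when ``weighted=False``, the presence/absence variant).
    Written as a 3-column TSV (``sample_id``, ``otu_id``, ``weight``) when
    ``path`` is given; loadable by igraph/networkx/Cytoscape.
    """
    values = table.data.to_numpy(dtype=float)
    col_sums = values.sum(axis=0)
    if (col_sums <= 0).any():
        raise ValidationError("cannot export network: zero-sum sample")
    frac = values / col_sums
    rows, cols = np.nonzero(frac > 0)
    keep = frac[rows, cols] >= min_fraction if min_fraction > 0 else slice(None)
    rows, cols = rows[keep], cols[keep]
    weights = frac[rows, cols] if weighted else np.ones(len(rows))
    edges = pd.DataFrame({
        "sample_id": np.asarray(table.sample_ids, dtype=object)[cols],
        "otu_id": np.asarray(table.otu_ids, dtype=object)[rows],
        "weight": weights,
    })
    edges = edges.sort_values(["sample_id", "otu_id"], kind="stable").reset_index(drop=True)
    if path is not None:
        edges.to_csv(path, sep="\t", index=False)
    return edges
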