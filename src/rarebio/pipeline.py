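"""End-to-end orchestration of the community analysis.

``run_full`` executes the whole battery on one rRNA table (plus optional
paired rDNA table): alignment, rarefaction, zone/season label derivation,
biosphere partitioning and transitions, per-assemblage subtables,
Bray-Curtis + nMDS + axis correlations, global and pairwise ANOSIM on
zone/season/depth, environmental preprocessing, BIOENV and BV-STEP (all
samples and per zone; all OTUs and indicator-only OTUs), a simple +
partial Mantel battery, indicator species analysis, the rRNA:rDNA
activity analysis, and the bipartite network export.  Every stage logs
its inputs and wall time, every table is written as TSV, and a JSON
manifest records config, seeds and input hashes so a rerun reproduces all
numbers exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as act
from . import biosphere as bio
from . import indicators as ind
from . import multivariate as mv
from . import normalization as norm
from . import tables_io as tio
from .tables_io import CountTable

__all__ = ["PipelineConfig", "PipelineResult", "run_full", "derive_zone",
           "derive_season", "robustness_resample"]

logger = logging.getLogger(__name__)

#: salinity-zone bounds (permil): freshwater below 0.5, oligo/mesohaline up
#: to 18, poly/euhaline up to 40
ZONE_BOUNDS = {"F": (0.0, 0.5), "OM": (0.5, 18.0), "PE": (18.0, 40.0)}
COOL_MONTHS = frozenset({2, 4, 12})
WARM_MONTHS = frozenset({6, 8, 10})


def derive_zone(meta: pd.DataFrame) -> pd.Series:
    """Salinity-zone label per sample: F (< 0.5), OM (0.5-18), PE (18-40].

    Salinity above 40 is flagged ``out_of_range``; negative salinity is an
    error (already rejected by metadata validation, re-checked here).
    """
    if "salinity" not in meta.columns:
        raise ValueError("metadata has no 'salinity' column")
    sal = meta["salinity"].astype(float)
    if (sal < 0).any():
        bad = list(meta.index[sal < 0])
        raise ValueError(f"negative salinity for sample(s): {bad}")
    out = pd.Series("out_of_range", index=meta.index, name="zone")
    out[sal < 0.5] = "F"
    out[(sal >= 0.5) & (sal <= 18.0)] = "OM"
    out[(sal > 18.0) & (sal <= 40.0)] = "PE"
    return out


def derive_season(meta: pd.DataFrame) -> pd.Series:
    """Cool ({2,4,12}) / warm ({6,8,10}) season label; other months unassigned."""
    if "month" not in meta.columns:
        raise ValueError("metadata has no 'month' column")
    month = meta["month"].astype(int)
    out = pd.Series("unassigned", index=meta.index, name="season")
    out[month.isin(COOL_MONTHS)] = "cool"
    out[month.isin(WARM_MONTHS)] = "warm"
    return out


@dataclass
class PipelineConfig:
    """Knobs of the full run; defaults follow the emulated study design."""

    output_dir: str | Path = "rarebio_out"
    rarefaction_depth: int = norm.DEFAULT_DEPTH
    abundant_min: float = 0.01
    rare_max: float = 0.0001
    n_permutations: int = 999
    nmds_restarts: int = 8
    iv_min: float = ind.DEFAULT_IV_MIN
    p_max: float = ind.DEFAULT_P_MAX
    bioenv_max_subset: int = 2      #: exhaustive search depth when variables are many
    collinearity_rho: float = 0.90
    network_min_fraction: float = 0.0
    mantel_control: str = "salinity"
    seed: int = 0

    def thresholds(self) -> bio.BiosphereThresholds:
        return bio.BiosphereThresholds(self.abundant_min, self.rare_max)


@dataclass
class PipelineResult:
    """In-memory handles to everything ``run_full`` computed and wrote."""

    tables: dict = field(default_factory=dict)       # name -> DataFrame
    objects: dict = field(default_factory=dict)      # name -> rich result object
    manifest: dict = field(default_factory=dict)
    output_dir: Path | None = None


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(pd.util.hash_pandas_object(df, index=True).values.tobytes()).hexdigest()[:16]


class _Stage:
    """Context manager logging one pipeline stage and timing it."""

    def __init__(self, manifest: dict, name: str, **params):
        self.manifest, self.name, self.params = manifest, name, params

    def __enter__(self):
        logger.info("stage %s: start %s", self.name, self.params)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        entry = {"params": {k: repr(v) for k, v in self.params.items()},
                 "seconds": round(elapsed, 3),
                 "status": "ok" if exc_type is None else f"failed: {exc}"}
        self.manifest.setdefault("stages", {})[self.name] = entry
        if exc_type is not None:
            logger.error("stage %s failed after %.2fs: %s", self.name, elapsed, exc)
            raise PipelineError(self.name, exc) from exc
        logger.info("stage %s: done in %.2fs", self.name, elapsed)
        return False


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the partial-results manifest."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_full(cfg: PipelineConfig, table: CountTable, meta: pd.DataFrame,
             env: pd.DataFrame | None = None,
             paired: act.PairedTables | None = None) -> PipelineResult:
    """Run the complete analysis; returns results and writes a report bundle."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    seeds = {name: int(rng.integers(2 ** 31)) for name in
             ("rarefy", "nmds", "anosim", "mantel", "indval", "bvstep")}
    res = PipelineResult(output_dir=out)
    man = res.manifest
    man["config"] = {k: str(v) if isinstance(v, Path) else v for k, v in asdict(cfg).items()}
    man["seeds"] = seeds
    man["input_hashes"] = {"counts": _hash_frame(table.data),
                          "metadata": _hash_frame(meta)}
    if env is not None:
        man["input_hashes"]["env"] = _hash_frame(env)
    if paired is not None:
        man["input_hashes"]["dna_counts"] = _hash_frame(paired.dna.data)
        man["input_hashes"]["rna_counts"] = _hash_frame(paired.rna.data)

    good = pd.DataFrame()
    penv = None
    try:
        with _Stage(man, "align"):
            table, meta, env, align_rep = tio.align_tables(table, meta, env)
            man["alignment"] = {"dropped": align_rep.dropped,
                                "env_incomplete": align_rep.env_incomplete}
        with _Stage(man, "rarefy", depth=cfg.rarefaction_depth):
            table = norm.rarefy(table, cfg.rarefaction_depth, seed=seeds["rarefy"])
            meta = meta.loc[table.sample_ids]
            if env is not None:
                env = env.loc[table.sample_ids]
        with _Stage(man, "labels"):
            meta = meta.copy()
            meta["zone"] = derive_zone(meta)
            meta["season"] = derive_season(meta)
            _save(res, "sample_labels", meta.reset_index(), out)
        with _Stage(man, "biosphere", thresholds=cfg.thresholds()):
            cls = bio.classify(table, cfg.thresholds())
            res.objects["classification"] = cls
            _save(res, "class_fractions", bio.class_fractions(cls, table), out)
            _save(res, "pooled_richness",
                  bio.pooled_richness_fractions(cls).rename_axis("biosphere").reset_index(), out)
            trans = bio.transitions(cls, "all_occurrences")
            _save(res, "transitions_all_occurrences", trans.reset_index(), out)
            if {"site", "month", "depth_layer"} <= set(meta.columns):
                trans_cm = bio.transitions(cls, "consecutive_months", meta=meta)
                _save(res, "transitions_consecutive_months", trans_cm.reset_index(), out)
            subtables = bio.class_subtables(cls, table)
            res.objects["subtables"] = subtables
            for name, sub in subtables.items():
                tio.write_count_table(sub, out / f"subtable_{name}.tsv")
        with _Stage(man, "distance"):
            dmat = mv.bray_curtis(table)
            res.objects["distance"] = dmat
            pd.DataFrame(dmat.data, index=list(dmat.ids),
                         columns=list(dmat.ids)).to_csv(out / "bray_curtis.tsv", sep="\t")
        with _Stage(man, "nmds", restarts=cfg.nmds_restarts):
            ordn = mv.nmds(dmat, k=2, restarts=cfg.nmds_restarts, seed=seeds["nmds"])
            res.objects["ordination"] = ordn
            coords = ordn.coordinates.copy()
            coords["stress"] = ordn.stress
            _save(res, "nmds_coordinates", coords.rename_axis("sample_id").reset_index(), out)
            axis_rows = []
            for axis, var in ((1, "salinity"), (2, "temperature")):
                source = env if env is not None and var in env.columns else meta
                if var in source.columns:
                    axis_rows.append(mv.axis_env_correlation(ordn, source, var, axis=axis))
            _save(res, "axis_correlations", pd.DataFrame(axis_rows), out)
        with _Stage(man, "anosim", n_permutations=cfg.n_permutations):
            rows, pair_frames = [], []
            for factor in ("zone", "season", "depth_layer"):
                if factor not in meta.columns:
                    continue
                labels = meta[factor]
                ok = labels.value_counts()
                usable = labels.isin(ok[ok >= 2].index) & (labels != "unassigned")
                if usable.sum() < 4 or labels[usable].nunique() < 2:
                    continue
                sub = dmat.filter(list(meta.index[usable]))
                r = mv.anosim(sub, labels[usable], cfg.n_permutations, seed=seeds["anosim"])
                rows.append({"factor": factor, "R": r.r, "p_value": r.p_value,
                             "n_permutations": r.n_permutations})
                if labels[usable].nunique() > 2:
                    pw = mv.pairwise_anosim(sub, labels[usable], cfg.n_permutations,
                                            seed=seeds["anosim"], correction="bonferroni")
                    pw.insert(0, "factor", factor)
                    pair_frames.append(pw)
            _save(res, "anosim_global", pd.DataFrame(rows), out)
            if pair_frames:
                _save(res, "anosim_pairwise", pd.concat(pair_frames, ignore_index=True), out)
        if env is not None:
            with _Stage(man, "env_prepare", collinearity_rho=cfg.collinearity_rho):
                penv, env_rep = mv.env_prepare(
                    env, transform="auto", collinearity_rho=cfg.collinearity_rho,
                    priority=[c for c in ("salinity", "temperature") if c in env.columns])
                res.objects["env_prepared"] = penv
                man["env_prepare"] = env_rep
        with _Stage(man, "indicators", n_permutations=cfg.n_permutations):
            indres = ind.indval(table, meta["zone"], n_permutations=cfg.n_permutations,
                                seed=seeds["indval"])
            res.objects["indicators"] = indres
            _save(res, "indval", indres.to_frame(), out)
            good = ind.filter_indicators(indres, cfg.iv_min, cfg.p_max)
            _save(res, "indval_filtered", good, out)
        if penv is not None:
            with _Stage(man, "bioenv_bvstep"):
                _save(res, "env_subset_selection",
                      _subset_selection_battery(cfg, table, meta, penv, good, seeds), out)
            with _Stage(man, "mantel", n_permutations=cfg.n_permutations):
                _save(res, "mantel_battery",
                      _mantel_battery(cfg, dmat, meta, penv, seeds), out)
        if paired is not None:
            with _Stage(man, "activity"):
                grid = act.classify_activity(paired, cfg.thresholds())
                _save(res, "activity_scatter", grid.rename_axis("otu_id").reset_index(), out)
                fit = act.fit_activity(grid)
                res.objects["activity_fit"] = fit
                _save(res, "activity_regression", pd.DataFrame([asdict(fit)]), out)
        with _Stage(man, "network", min_fraction=cfg.network_min_fraction):
            edges = tio.export_network(table, cfg.network_min_fraction,
                                       path=out / "network_edges.tsv")
            res.tables["network_edges"] = edges
        res.objects["table"] = table
        res.objects["meta"] = meta
        res.objects["env"] = env
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(man, fh, indent=2, default=str)
    return res


def _save(res: PipelineResult, name: str, frame: pd.DataFrame, out: Path) -> None:
    res.tables[name] = frame
    frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)


def _subset_selection_battery(cfg, table, meta, penv, good_indicators, seeds):
    """BIOENV + BV-STEP for all samples and per zone, with all OTUs and
    with indicator OTUs only (two report blocks)."""
    rows = []
    indicator_otus = list(good_indicators["otu_id"]) if len(good_indicators) else []
    blocks = [("all_otus", table)]
    if indicator_otus:
        blocks.append(("indicator_otus", table.select_otus(indicator_otus)))
    scopes = [("all", list(meta.index))]
    for zone in sorted(meta["zone"].unique()):
        ids = list(meta.index[meta["zone"] == zone])
        if len(ids) >= 5:
            scopes.append((zone, ids))
    for block_name, block_table in blocks:
        for scope_name, ids in scopes:
            ids_env = [s for s in ids if s in penv.index]
            if len(ids_env) < 5:
                continue
            sub = block_table.select_samples(ids_env)
            if (sub.data.sum(axis=0) == 0).any():  # indicator subtable may empty a sample
                keep = [s for s, t in sub.sample_sums().items() if t > 0]
                if len(keep) < 5:
                    continue
                sub = sub.select_samples(keep)
                ids_env = keep
            d = mv.bray_curtis(sub)
            env_scope = penv.loc[ids_env]
            env_scope = env_scope.loc[:, env_scope.std(ddof=0) > 0]
            be = mv.bioenv(d, env_scope, max_subset_size=cfg.bioenv_max_subset,
                           allow_large=True)
            bv = mv.bvstep(d, env_scope, seed=seeds["bvstep"])
            rows.append({"otu_block": block_name, "scope": scope_name, "n_samples": len(ids_env),
                         "bioenv_subset": ", ".join(be.best_subset),
                         "bioenv_rho": be.best_rho,
                         "bvstep_subset": ", ".join(bv.best_subset),
                         "bvstep_rho": bv.best_rho})
    return pd.DataFrame(rows)


def _mantel_battery(cfg, dmat, meta, penv, seeds):
    """Simple + partial Mantel of each env variable vs community distance,
    for all samples and the cool/warm subsets, controlling for the
    configured variable (salinity); Bonferroni over the variable family."""
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix

    rows = []
    control_var = cfg.mantel_control
    scopes = [("total", list(penv.index))]
    for season in ("cool", "warm"):
        ids = [s for s in penv.index if meta.loc[s, "season"] == season]
        if len(ids) >= 5:
            scopes.append((season, ids))
    for scope_name, ids in scopes:
        d = dmat.filter(ids)
        env_scope = penv.loc[ids]
        control = None
        if control_var in env_scope.columns:
            control = DistanceMatrix(
                squareform(pdist(env_scope[[control_var]].to_numpy())), ids=ids)
        for var in env_scope.columns:
            vd = DistanceMatrix(squareform(pdist(env_scope[[var]].to_numpy())), ids=ids)
            simple = mv.mantel(d, vd, n_permutations=cfg.n_permutations, seed=seeds["mantel"])
            row = {"scope": scope_name, "variable": var, "mantel_r": simple.r,
                   "mantel_p": simple.p_value}
            if control is not None and var != control_var:
                part = mv.partial_mantel(d, vd, control, n_permutations=cfg.n_permutations,
                                         seed=seeds["mantel"])
                row["partial_r"] = part.r
                row["partial_p"] = part.p_value
                row["controlled_for"] = control_var
            rows.append(row)
    frame = pd.DataFrame(rows)
    m = frame["variable"].nunique()
    frame["mantel_p_bonferroni"] = np.minimum(1.0, frame["mantel_p"] * m)
    if "partial_p" in frame:
        frame["partial_p_bonferroni"] = np.minimum(1.0, frame["partial_p"] * m)
    return frame


def robustness_resample(cfg: PipelineConfig, table: CountTable, meta: pd.DataFrame,
                        env: pd.DataFrame, depth: int = norm.ROBUSTNESS_DEPTH,
                        reps: int = 1) -> pd.DataFrame:
    """Re-run the env subset selection on tables subsampled to a shallow depth.

    Emulates degrading the data to clone-library sequencing effort
    (default 100 reads/sample) to ask whether the selected environmental
    drivers are stable.  Returns one row per repetition with the selected
    subsets and their correlations.
    """
    table, meta, env, _ = tio.align_tables(table, meta, env)
    meta = meta.copy()
    meta["zone"] = derive_zone(meta)
    penv, _ = mv.env_prepare(
        env, transform="auto", collinearity_rho=cfg.collinearity_rho,
        priority=[c for c in ("salinity", "temperature") if c in env.columns])
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(reps):
        sub = norm.subsample_to(table, depth=depth, seed=int(rng.integers(2 ** 31)))
        ids = [s for s in sub.sample_ids if s in penv.index]
        d = mv.bray_curtis(sub.select_samples(ids))
        env_scope = penv.loc[ids]
        bv = mv.bvstep(d, env_scope, seed=int(rng.integers(2 ** 31)))
        be = mv.bioenv(d, env_scope, max_subset_size=cfg.bioenv_max_subset, allow_large=True)
        rows.append({"rep": rep, "depth": depth, "n_samples": len(ids),
                     "bvstep_subset": ", ".join(bv.best_subset), "bvstep_rho": bv.best_rho,
                     "bioenv_subset": ", ".join(be.best_subset), "bioenv_rho": be.best_rho})
    return pd.DataFrame(rows)
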