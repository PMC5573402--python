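"""Distance-based multivariate analysis of community tables.

Implements the machinery used to relate community variability to
environmental gradients:

* Bray-Curtis dissimilarities between samples,
* non-metric multidimensional scaling (nMDS, Kruskal stress-1),
* ANOSIM (Clarke's rank-based R with permutation significance),
* simple and partial Mantel tests,
* BIOENV (exhaustive) and BV-STEP (stepwise) selection of the
  environmental-variable subset whose Euclidean distances best
  rank-correlate with the community distances,
* ordination-axis vs environment correlations,
* environmental preprocessing (normalizing transforms, standardization,
  collinearity pruning).

All permutation tests use the (1 + hits) / (1 + permutations) convention,
so reported p-values are never exactly zero, and every routine takes an
explicit seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .tables_io import CountTable

__all__ = [
    "bray_curtis", "nmds", "OrdinationResult",
    "anosim", "pairwise_anosim", "AnosimResult",
    "mantel", "partial_mantel", "MantelResult",
    "env_prepare", "bioenv", "bvstep", "BioenvResult",
    "axis_env_correlation",
]

logger = logging.getLogger(__name__)

BIOENV_EXHAUSTIVE_GUARD = 15


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); similarity is 1 - d.
    Accepts counts or relative abundances (columns are samples).
    """
    values = table.data.to_numpy(dtype=float).T  # samples x OTUs
    if values.shape[0] < 2:
        raise ValueError("need at least two samples for a distance matrix")
    if (values.sum(axis=1) <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, values.sum(axis=1)) if t <= 0]
        raise ValueError(f"zero-sum sample(s): {bad}")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def _condensed(d: DistanceMatrix) -> np.ndarray:
    data = np.asarray(d.data, dtype=float)
    iu = np.triu_indices(data.shape[0], k=1)
    return data[iu]


# ---------------------------------------------------------------------------
# nMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """nMDS configuration with Kruskal stress-1 diagnostics."""

    coordinates: pd.DataFrame  # samples x dimensions ("dim1", ...)
    stress: float
    iterations: int
    converged: bool
    n_restarts: int

    def axis(self, k: int) -> pd.Series:
        return self.coordinates[f"dim{k}"]


def nmds(d: DistanceMatrix, k: int = 2, restarts: int = 8, max_iter: int = 500,
         tol: float = 1e-9, seed: int | None = None) -> OrdinationResult:
    """Non-metric MDS of a distance matrix, best configuration of ``restarts``.

    Isotonic (monotone) regression of fitted on observed dissimilarities,
    minimizing Kruskal stress-1; the final configuration is centred and
    rotated to its principal axes (so dim1 carries the most spread), with a
    deterministic sign convention.
    """
    n = d.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples {n}")
    model = MDS(
        n_components=k, metric_mds=False, metric="precomputed",
        n_init=restarts, init="random", max_iter=max_iter, eps=tol,
        random_state=None if seed is None else np.random.RandomState(seed),
        normalized_stress=True,
    )
    coords = model.fit_transform(np.asarray(d.data, dtype=float))
    coords = coords - coords.mean(axis=0)
    # vegan-style PCA rotation of the final configuration
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for j in range(coords.shape[1]):  # sign convention: extreme sample positive
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] *= -1
    frame = pd.DataFrame(coords, index=list(d.ids),
                         columns=[f"dim{i + 1}" for i in range(k)])
    return OrdinationResult(
        coordinates=frame,
        stress=float(model.stress_),
        iterations=int(model.n_iter_),
        converged=int(model.n_iter_) < max_iter,
        n_restarts=restarts,
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    """Clarke's analysis of similarities."""

    r: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    p_adjusted: float | None = None


def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    n = rank_matrix.shape[0]
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within = same[iu]
    ranks = rank_matrix[iu]
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return float((r_b - r_w) / (n * (n - 1) / 4.0))


def anosim(d: DistanceMatrix, groups, n_permutations: int = 9999,
           seed: int | None = None) -> AnosimResult:
    """ANOSIM: R = (mean between-group rank - mean within-group rank) / (n(n-1)/4).

    Distances are converted to midranks; significance comes from permuting
    group labels.  ``groups`` is a mapping or sequence aligned to
    ``d.ids``.  R lies in [-1, 1]: 1 means all between-group distances
    exceed all within-group distances.
    """
    labels = _as_labels(groups, d.ids)
    sizes = pd.Series(labels).value_counts()
    if len(sizes) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    singles = sizes[sizes < 2]
    if len(singles):
        raise ValueError(f"singleton group(s): {list(singles.index)}")
    condensed = _condensed(d)
    ranks = squareform(stats.rankdata(condensed))  # midranks, zero diagonal
    codes = pd.factorize(labels)[0]
    observed = _anosim_r(ranks, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _anosim_r(ranks, perm) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(r=observed, p_value=p, n_permutations=n_permutations,
                        group_sizes=sizes.to_dict())


def pairwise_anosim(d: DistanceMatrix, groups, n_permutations: int = 9999,
                    seed: int | None = None, correction: str = "none") -> pd.DataFrame:
    """ANOSIM on every pair of groups, optionally Bonferroni-adjusted.

    Returns one row per unordered group pair with R, raw p and (when
    ``correction='bonferroni'``) p_adjusted = min(1, m * p) for m pairs.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    labels = _as_labels(groups, d.ids)
    uniq = sorted(pd.unique(labels))
    pairs = list(itertools.combinations(uniq, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in pairs:
        keep = [i for i, lab in enumerate(labels) if lab in (g1, g2)]
        sub = d.filter([d.ids[i] for i in keep])
        sub_labels = labels[keep]
        res = anosim(sub, sub_labels, n_permutations=n_permutations,
                     seed=int(rng.integers(2 ** 31)))
        rows.append({"group1": g1, "group2": g2, "R": res.r, "p_value": res.p_value,
                     "n_permutations": n_permutations})
    out = pd.DataFrame(rows)
    if correction == "bonferroni" and len(out):
        out["p_adjusted"] = np.minimum(1.0, out["p_value"] * len(pairs))
    return out


def _as_labels(groups, ids) -> np.ndarray:
    if isinstance(groups, (pd.Series, dict)):
        series = pd.Series(groups)
        missing = [i for i in ids if i not in series.index]
        if missing:
            raise ValueError(f"no group label for sample(s): {missing}")
        return series.loc[list(ids)].to_numpy()
    labels = np.asarray(list(groups))
    if len(labels) != len(ids):
        raise ValueError("group labels length does not match distance matrix")
    return labels


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    """Simple or partial Mantel correlation between distance matrices."""

    r: float
    p_value: float
    method: str
    n_permutations: int
    n_samples: int
    controlled: str | None = None
    p_adjusted: float | None = None


def _corr_vectors(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / denom) if denom else np.nan


def mantel(a: DistanceMatrix, b: DistanceMatrix, method: str = "spearman",
           n_permutations: int = 9999, seed: int | None = None) -> MantelResult:
    """Mantel test: correlation of the strict upper triangles of two
    distance matrices, significance by permuting samples of ``a``."""
    if list(a.ids) != list(b.ids):
        if set(a.ids) != set(b.ids):
            raise ValueError("distance matrices cover different samples")
        b = b.filter(list(a.ids))
    amat = np.asarray(a.data, float)
    n = amat.shape[0]
    iu = np.triu_indices(n, k=1)
    av = amat[iu]
    bv = _condensed(b)
    observed = _corr_vectors(av, bv, method)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pv = amat[np.ix_(perm, perm)][iu]
        if _corr_vectors(pv, bv, method) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return MantelResult(r=observed, p_value=p, method=method,
                        n_permutations=n_permutations, n_samples=n)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_mantel(a: DistanceMatrix, b: DistanceMatrix, control: DistanceMatrix,
                   method: str = "spearman", n_permutations: int = 9999,
                   seed: int | None = None) -> MantelResult:
    """Partial Mantel test of a ~ b after controlling for a third matrix.

    The unrolled triangles (rank-transformed when ``method='spearman'``) of
    ``a`` and ``b`` are each regressed on the control's; the statistic is
    the Pearson correlation of the two residual vectors.  Significance:
    samples of ``a`` are permuted, its residual vector recomputed, and the
    residual correlation re-evaluated.
    """
    ids = list(a.ids)
    for other in (b, control):
        if set(other.ids) != set(ids):
            raise ValueError("distance matrices cover different samples")
    b = b.filter(ids)
    control = control.filter(ids)
    amat = np.asarray(a.data, float)
    n = amat.shape[0]
    iu = np.triu_indices(n, k=1)

    def prep(v):
        return stats.rankdata(v) if method == "spearman" else np.asarray(v, float)

    cv = prep(_condensed(control))
    bres = _residualize(prep(_condensed(b)), cv)
    ares = _residualize(prep(amat[iu]), cv)
    observed = _corr_vectors(ares, bres, "pearson")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pv = _residualize(prep(amat[np.ix_(perm, perm)][iu]), cv)
        if _corr_vectors(pv, bres, "pearson") >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return MantelResult(r=observed, p_value=p, method=method,
                        n_permutations=n_permutations, n_samples=n,
                        controlled="control")


# ---------------------------------------------------------------------------
# environmental preprocessing
# ---------------------------------------------------------------------------

def env_prepare(env: pd.DataFrame, transform: str | dict = "auto",
                collinearity_rho: float = 0.90, priority: list[str] | None = None,
                standardize: bool = True, drop_incomplete: bool = True):
    """Prepare an environmental table for distance-based analysis.

    Steps: (1) optional per-variable normalizing transform — ``'auto'``
    picks, per variable, the member of {identity, sqrt, log10(x + c)} that
    minimizes |skewness| (non-negative variables only); a dict maps
    variable -> {'none','sqrt','log'}; (2) complete-case reduction over the
    retained variables (missing-env samples are only excluded here, from
    env-dependent analyses); (3) z-score standardization; (4) greedy
    removal of one variable from each pair with |Spearman rho| above
    ``collinearity_rho``, keeping the variable earlier in ``priority``
    (default: column order).

    Returns ``(processed, report)`` where report records transforms applied,
    dropped variables (with the partner that doomed them) and dropped
    samples.
    """
    if env.shape[0] < 2:
        raise ValueError("need at least two samples")
    work = env.copy().astype(float)
    report: dict = {"transforms": {}, "dropped_variables": {}, "dropped_samples": []}
    for var in work.columns:
        x = work[var]
        mode = transform.get(var, "none") if isinstance(transform, dict) else transform
        work[var], applied = _apply_transform(x, mode)
        report["transforms"][var] = applied
    if drop_incomplete:
        complete = work.dropna()
        report["dropped_samples"] = sorted(set(work.index) - set(complete.index))
        work = complete
        if work.shape[0] < 2:
            raise ValueError("fewer than two env-complete samples remain")
    order = list(priority) if priority is not None else list(work.columns)
    order += [v for v in work.columns if v not in order]
    rho = work.corr(method="spearman").abs()
    keep = [v for v in order if v in work.columns]
    dropped: dict[str, str] = {}
    for i, v in enumerate(keep):
        if v in dropped:
            continue
        for w in keep[i + 1:]:
            if w in dropped:
                continue
            if rho.loc[v, w] > collinearity_rho:
                dropped[w] = v
    kept = [v for v in work.columns if v not in dropped]
    if not kept:
        raise ValueError("collinearity pruning removed every variable")
    report["dropped_variables"] = dropped
    if dropped:
        logger.info("env_prepare: removed collinear variable(s): %s", dropped)
    out = work[kept]
    if standardize:
        std = out.std(ddof=0)
        constant = std[std == 0].index.tolist()
        if constant:
            out = out.drop(columns=constant)
            for v in constant:
                report["dropped_variables"][v] = "(constant)"
            if out.shape[1] == 0:
                raise ValueError("all variables constant after preprocessing")
            std = std.drop(index=constant)
        out = (out - out.mean()) / std
    return out, report


def _apply_transform(x: pd.Series, mode: str):
    vals = x.astype(float)
    if mode == "none" or mode is None:
        return vals, "none"
    if mode == "sqrt":
        return np.sqrt(vals), "sqrt"
    if mode == "log":
        shift = _log_shift(vals)
        return np.log10(vals + shift), "log"
    if mode == "auto":
        finite = vals.dropna()
        if len(finite) < 3 or (finite < 0).any():
            return vals, "none"
        candidates = {"none": vals, "sqrt": np.sqrt(vals),
                      "log": np.log10(vals + _log_shift(vals))}
        best = min(candidates, key=lambda k: abs(stats.skew(candidates[k].dropna())))
        return candidates[best], best
    raise ValueError(f"unknown transform {mode!r}")


def _log_shift(vals: pd.Series) -> float:
    positive = vals[vals > 0]
    if not len(positive):
        return 1.0
    return float(positive.min()) / 2.0 if (vals <= 0).any() else 0.0


# ---------------------------------------------------------------------------
# BIOENV / BV-STEP
# ---------------------------------------------------------------------------

@dataclass
class BioenvResult:
    """Best environmental subsets relating env distances to community distances."""

    best_subset: tuple[str, ...]
    best_rho: float
    by_size: dict[int, tuple[tuple[str, ...], float]]
    method: str
    correlation: str = "spearman"
    path: list[dict] = field(default_factory=list)


def _subset_rho(env_values: np.ndarray, cols: tuple[int, ...], comm_ranks: np.ndarray) -> float:
    ed = pdist(env_values[:, cols], metric="euclidean")
    return _corr_pre_ranked(ed, comm_ranks)


def _corr_pre_ranked(x: np.ndarray, y_ranks: np.ndarray) -> float:
    xr = stats.rankdata(x)
    xr = xr - xr.mean()
    yr = y_ranks - y_ranks.mean()
    denom = np.sqrt((xr * xr).sum() * (yr * yr).sum())
    return float((xr * yr).sum() / denom) if denom else np.nan


def _align_env(d: DistanceMatrix, env: pd.DataFrame):
    shared = [s for s in d.ids if s in env.index]
    if len(shared) < len(d.ids):
        d = d.filter(shared)
    if len(shared) < 3:
        raise ValueError("fewer than three samples shared between distances and env")
    env = env.loc[shared]
    if env.isna().any().any():
        raise ValueError("env table passed to subset selection must be complete; "
                         "run env_prepare first")
    return d, env


def bioenv(d: DistanceMatrix, env: pd.DataFrame, max_subset_size: int | None = None,
           allow_large: bool = False) -> BioenvResult:
    """Exhaustive BIOENV: the variable subset whose Euclidean distances best
    Spearman-correlate with the community distance matrix.

    Searches every subset up to ``max_subset_size`` (default: all sizes).
    More than 15 variables requires ``allow_large=True`` (or use
    :func:`bvstep`), since the search is exponential.
    """
    d, env = _align_env(d, env)
    n_vars = env.shape[1]
    if n_vars > BIOENV_EXHAUSTIVE_GUARD and not allow_large:
        raise ValueError(
            f"{n_vars} variables exceed the exhaustive guard of "
            f"{BIOENV_EXHAUSTIVE_GUARD}; use bvstep() or pass allow_large=True "
            f"with a small max_subset_size")
    max_size = n_vars if max_subset_size is None else min(max_subset_size, n_vars)
    comm_ranks = stats.rankdata(_condensed(d))
    values = env.to_numpy(dtype=float)
    by_size: dict[int, tuple[tuple[str, ...], float]] = {}
    for size in range(1, max_size + 1):
        best: tuple[tuple[int, ...], float] | None = None
        for cols in itertools.combinations(range(n_vars), size):
            rho = _subset_rho(values, cols, comm_ranks)
            if best is None or rho > best[1]:
                best = (cols, rho)
        names = tuple(env.columns[i] for i in best[0])
        by_size[size] = (names, best[1])
    best_size = max(by_size, key=lambda s: by_size[s][1])
    return BioenvResult(best_subset=by_size[best_size][0], best_rho=by_size[best_size][1],
                        by_size=by_size, method="bioenv")


def bvstep(d: DistanceMatrix, env: pd.DataFrame, start: str = "empty",
           rho_tol: float = 0.001, max_rounds: int = 50,
           seed: int | None = None) -> BioenvResult:
    """BV-STEP: stepwise forward/backward search over variable subsets.

    Each round accepts the single addition or removal that most improves
    the Spearman correlation; stops when no change improves it by more
    than ``rho_tol``.  ``start`` is ``'empty'``, ``'full'`` or ``'random'``
    (seeded).  The search path is recorded in the result.
    """
    d, env = _align_env(d, env)
    n_vars = env.shape[1]
    comm_ranks = stats.rankdata(_condensed(d))
    values = env.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if start == "empty":
        current: set[int] = set()
    elif start == "full":
        current = set(range(n_vars))
    elif start == "random":
        size = int(rng.integers(1, n_vars + 1))
        current = set(rng.choice(n_vars, size=size, replace=False).tolist())
    else:
        raise ValueError(f"unknown start {start!r}")
    current_rho = (_subset_rho(values, tuple(sorted(current)), comm_ranks)
                   if current else -np.inf)
    path: list[dict] = []
    by_size: dict[int, tuple[tuple[str, ...], float]] = {}

    def note(subset: set[int], rho: float):
        if subset:
            names = tuple(env.columns[i] for i in sorted(subset))
            size = len(subset)
            if size not in by_size or rho > by_size[size][1]:
                by_size[size] = (names, rho)

    note(current, current_rho)
    for round_no in range(max_rounds):
        best_change: tuple[str, int, float] | None = None
        for var in range(n_vars):  # forward additions
            if var in current:
                continue
            rho = _subset_rho(values, tuple(sorted(current | {var})), comm_ranks)
            note(current | {var}, rho)
            if best_change is None or rho > best_change[2]:
                best_change = ("add", var, rho)
        if len(current) > 1:
            for var in current:  # backward eliminations
                rho = _subset_rho(values, tuple(sorted(current - {var})), comm_ranks)
                note(current - {var}, rho)
                if best_change is None or rho > best_change[2]:
                    best_change = ("drop", var, rho)
        if best_change is None or best_change[2] <= current_rho + rho_tol:
            break
        op, var, rho = best_change
        current = current | {var} if op == "add" else current - {var}
        current_rho = rho
        path.append({"round": round_no, "op": op, "variable": env.columns[var],
                     "rho": rho, "subset": tuple(env.columns[i] for i in sorted(current))})
    names = tuple(env.columns[i] for i in sorted(current))
    return BioenvResult(best_subset=names, best_rho=current_rho, by_size=by_size,
                        method="bvstep", path=path)


# ---------------------------------------------------------------------------
# ordination axis vs environment
# ---------------------------------------------------------------------------

def axis_env_correlation(ordination: OrdinationResult, env: pd.DataFrame, variable: str,
                         axis: int = 1, p_method: str = "asymptotic",
                         n_permutations: int = 9999, seed: int | None = None) -> dict:
    """Spearman correlation of one nMDS axis with one environmental variable.

    ``p_method`` is ``'asymptotic'`` (scipy's t-approximation) or
    ``'permutation'`` (label shuffles with the +1 convention); the result
    records which was used.
    """
    if variable not in env.columns:
        raise ValueError(f"variable {variable!r} not in env table")
    coords = ordination.axis(axis)
    shared = [s for s in coords.index if s in env.index and pd.notna(env.loc[s, variable])]
    x = coords.loc[shared].to_numpy(dtype=float)
    y = env.loc[shared, variable].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"variable {variable!r} is constant on the aligned samples")
    rho, p_asym = stats.spearmanr(x, y)
    if p_method == "asymptotic":
        p = float(p_asym)
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm_rho, _ = stats.spearmanr(x, rng.permutation(y))
            if abs(perm_rho) >= abs(rho):
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return {"variable": variable, "axis": axis, "rho": float(rho), "p_value": p,
            "p_method": p_method, "n": len(shared)}
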