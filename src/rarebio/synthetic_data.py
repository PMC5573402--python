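"""Synthetic estuarine community generator.

Emulates the sampling design the analysis pipeline expects: 97 samples
from 8 sites along a full salinity gradient, collected bimonthly over one
year at one to three depth layers, sequenced to a fixed read depth, with
an environmental table coupled to the planted community structure and a
paired gene-library (rDNA) / transcript-library (rRNA) subset for the
activity analysis.

Generative model
----------------
Each OTU i carries a lognormal base abundance, a salinity-niche optimum
u_i with Gaussian niche breadth, and a seasonal log-response gamma_i.  A
sample at (scaled) salinity position x in season w (+-1/2 for warm/cool)
has expected relative abundances

    p_i  proportional to  exp(sigma * Z_i)
                        * exp(-c_sal * (x - u_i)^2 / (2 * nu^2))
                        * exp(c_temp * gamma_i * w),

perturbed by a Dirichlet draw (overdispersion between replicate samples of
the same conditions) and observed as a multinomial read vector at the
configured depth.  Samples of the same site and month share one salinity
value across depth layers (a well-mixed water column), so depth layers
replicate the same expected community.

Environmental variables are generated as noisy functions of the same two
latent signals (salinity position and season), which makes salinity and
temperature the planted drivers that BIOENV / BV-STEP should recover;
setting the coupling coefficients to zero severs the community-environment
link entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .activity import PairedTables
from .tables_io import CountTable

__all__ = ["SyntheticConfig", "PlantedTruth", "sample_layout",
           "generate_community", "generate_paired", "planted_truth"]

ZONE_OF_SITE = {"S1": "F", "S2": "F", "S3": "F", "S4": "OM", "S5": "OM",
                "S6": "PE", "S7": "PE", "S8": "PE"}
#: per-site salinity ranges (permil), nested inside the zone definitions
#: F < 0.5, OM 0.5-18, PE 18-40
SITE_SALINITY = {"S1": (0.05, 0.20), "S2": (0.10, 0.35), "S3": (0.15, 0.45),
                 "S4": (1.0, 9.0), "S5": (9.0, 18.0),
                 "S6": (18.5, 26.0), "S7": (25.0, 33.0), "S8": (32.0, 39.5)}
#: sites with a full surface/middle/bottom profile every cruise
PROFILED_SITES = ("S2", "S4", "S6", "S7")

COOL_MONTHS = (2, 4, 12)
WARM_MONTHS = (6, 8, 10)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults emulate the field design."""

    n_otus: int = 548
    months: tuple[int, ...] = (2, 4, 6, 8, 10, 12)
    depth: int = 14_825
    lognormal_sigma: float = 1.8      #: rank-abundance shape (log-scale SD)
    niche_sigma: float = 0.30         #: Gaussian niche breadth on the [0,1] salinity axis
    season_sigma: float = 1.4         #: scale of per-OTU seasonal log-responses
    trait_block: int = 12             #: abundance-stratum size for trait assignment
    dirichlet_alpha: float = 150.0    #: concentration of within-condition replicate noise
    salinity_coupling: float = 1.0    #: community response to the salinity gradient
    temperature_coupling: float = 1.0  #: community response to season
    env_coupling: float = 1.0         #: strength of env-variable links to the latent signals
    cool_temperature: float = 16.5    #: mean cool-season temperature, deg C
    warm_temperature: float = 26.4    #: mean warm-season temperature, deg C
    diadinoxanthin_cool: float = 0.41  #: mean pigment concentration, ug/L
    diadinoxanthin_warm: float = 0.59
    activity_median: float = 2.0      #: median per-OTU rRNA:rDNA activity factor
    activity_sigma: float = 1.0       #: lognormal dispersion of activity factors
    background_share: float = 0.9     #: library fraction held by non-focal eukaryotes
    paired_months: tuple[int, ...] = (2, 6)
    n_paired: int = 26
    env_missing_samples: int = 32     #: samples given a missing env value (97 -> 65 complete)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus <= 0:
            raise ValueError("n_otus must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not self.months:
            raise ValueError("need at least one sampling month")


@dataclass
class PlantedTruth:
    """The latent structure a generated dataset actually contains."""

    zones: dict[str, str]             #: sample id -> salinity zone (F/OM/PE)
    seasons: dict[str, str]           #: sample id -> cool/warm
    driving_variables: tuple[str, ...]
    activity_median: float
    activity_sigma: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        d = dict(d)
        d["driving_variables"] = tuple(d["driving_variables"])
        return cls(**d)


def _season(month: int) -> str:
    if month in COOL_MONTHS:
        return "cool"
    if month in WARM_MONTHS:
        return "warm"
    return "unassigned"


def sample_layout(cfg: SyntheticConfig) -> pd.DataFrame:
    """Deterministic sample frame: 8 sites x months, profiled sites at three
    depths, plus one extra mid-water sample, giving 97 samples at defaults."""
    rows = []
    for month in cfg.months:
        for site in ZONE_OF_SITE:
            layers = ("surface", "middle", "bottom") if site in PROFILED_SITES else ("surface",)
            for layer in layers:
                rows.append({"site": site, "month": month, "depth_layer": layer})
    first_month = cfg.months[0]
    rows.append({"site": "S5", "month": first_month, "depth_layer": "middle"})
    frame = pd.DataFrame(rows)
    frame["sample_id"] = [f"{r.site}-m{r.month:02d}-{r.depth_layer}"
                          + ("-x" if i == len(frame) - 1 else "")
                          for i, r in enumerate(frame.itertuples())]
    frame = frame.set_index("sample_id")
    frame["zone"] = frame["site"].map(ZONE_OF_SITE)
    frame["season"] = frame["month"].map(_season)
    return frame


def _rngs(cfg: SyntheticConfig) -> dict[str, np.random.Generator]:
    keys = ("otus", "salinity", "community", "env", "missing", "activity", "rna")
    children = np.random.SeedSequence(cfg.seed).spawn(len(keys))
    return {k: np.random.default_rng(s) for k, s in zip(keys, children)}


def _otu_params(cfg: SyntheticConfig, rng: np.random.Generator):
    """Per-OTU traits: lognormal base abundance, salinity optimum, season response.

    Optima and seasonal responses are assigned by stratified (Latin-
    hypercube style) sampling within blocks of ``trait_block`` consecutive
    abundance ranks: within every stratum of the rank-abundance curve the
    optima cover the whole gradient and the seasonal responses are
    symmetric.  This is the species-packing assumption — dominance is not
    concentrated at one end of the gradient or in one season — and it
    keeps the planted spatial and seasonal signals present at every
    abundance level in every realization.
    """
    n = cfg.n_otus
    base = cfg.lognormal_sigma * rng.standard_normal(n)
    order = np.argsort(-base)
    optima = np.empty(n)
    season_resp = np.empty(n)
    block = max(1, cfg.trait_block)
    for start in range(0, n, block):
        idx = order[start:start + block]
        m = len(idx)
        pos = -0.1 + 1.2 * (np.arange(m) + rng.uniform(0, 1, m)) / m
        optima[idx] = rng.permutation(pos)
        grid = np.linspace(-np.sqrt(3), np.sqrt(3), m) if m > 1 else np.zeros(1)
        season_resp[idx] = cfg.season_sigma * rng.permutation(grid)
    return base, optima, season_resp


def _salinity_position(salinity: np.ndarray) -> np.ndarray:
    return np.log10(1.0 + salinity) / np.log10(41.0)


def generate_community(cfg: SyntheticConfig):
    """Generate ``(CountTable, metadata, env_table)`` for the full design."""
    rngs = _rngs(cfg)
    layout = sample_layout(cfg)
    base, optima, season_resp = _otu_params(cfg, rngs["otus"])

    # one salinity per (site, month), shared by depth layers
    sal_rng = rngs["salinity"]
    site_month_sal = {}
    for month in cfg.months:
        for site, (lo, hi) in SITE_SALINITY.items():
            site_month_sal[(site, month)] = sal_rng.uniform(lo, hi)
    salinity = np.array([site_month_sal[(r.site, r.month)] for r in layout.itertuples()])
    x = _salinity_position(salinity)
    w = np.where(layout["season"].to_numpy() == "warm", 0.5, -0.5)

    comm_rng = rngs["community"]
    counts = np.empty((cfg.n_otus, len(layout)), dtype=np.int64)
    for j in range(len(layout)):
        log_mu = (base
                  - cfg.salinity_coupling * (x[j] - optima) ** 2 / (2 * cfg.niche_sigma ** 2)
                  + cfg.temperature_coupling * season_resp * w[j])
        mu = np.exp(log_mu - log_mu.max())
        mu /= mu.sum()
        q = comm_rng.dirichlet(cfg.dirichlet_alpha * mu)
        if q.sum() <= 0 or not np.isfinite(q).all():  # degenerate Dirichlet guard
            q = mu
        counts[:, j] = comm_rng.multinomial(cfg.depth, q / q.sum())

    otu_ids = [f"OTU_{i + 1}" for i in range(cfg.n_otus)]
    table = CountTable(pd.DataFrame(counts, index=otu_ids, columns=layout.index))

    env = _environment(cfg, layout, salinity, x, w, rngs["env"])
    meta = layout.copy()
    meta["nucleic_acid"] = "rRNA"
    meta["salinity"] = salinity
    meta["temperature"] = env["temperature"]

    miss_rng = rngs["missing"]
    n_missing = min(cfg.env_missing_samples, len(layout))
    if n_missing:
        victims = miss_rng.choice(len(layout), size=n_missing, replace=False)
        missable = [c for c in env.columns if c not in ("salinity", "temperature")]
        for v in victims:
            col = missable[int(miss_rng.integers(len(missable)))]
            env.iloc[int(v), env.columns.get_loc(col)] = np.nan
    return table, meta, env


def _environment(cfg: SyntheticConfig, layout: pd.DataFrame, salinity, x, w,
                 rng: np.random.Generator) -> pd.DataFrame:
    n = len(layout)
    c = cfg.env_coupling
    fresh = 1.0 - x  # freshwater influence

    def noise(scale):
        return rng.normal(0.0, scale, size=n)

    env = pd.DataFrame(index=layout.index)
    env["salinity"] = salinity
    season_mean = np.where(w > 0, cfg.warm_temperature, cfg.cool_temperature)
    env["temperature"] = season_mean + noise(1.0)
    env["chl_a"] = np.exp(0.5 + c * (0.8 * w + 0.5 * fresh) + noise(0.35))
    env["bacteria"] = 1e6 * np.exp(c * (0.6 * w + 0.4 * fresh) + noise(0.45))
    env["no3_n"] = np.clip(5.0 + c * 55.0 * fresh + noise(6.0), 0.05, None)
    env["no2_n"] = np.clip(0.2 + c * 1.8 * fresh + noise(0.3), 0.01, None)
    env["nh4_n"] = np.clip(2.0 + c * 22.0 * fresh + noise(3.5), 0.05, None)
    env["dtn"] = env["no3_n"] + env["nh4_n"] + np.clip(8.0 + noise(2.0), 0.5, None)
    env["drp"] = np.clip(0.3 + c * (1.5 * fresh + 0.3 * w) + noise(0.35), 0.01, None)
    dia_span = cfg.diadinoxanthin_warm - cfg.diadinoxanthin_cool
    env["diadinoxanthin"] = np.clip(
        cfg.diadinoxanthin_cool + dia_span * (w + 0.5) * c + noise(0.06), 0.0, None)
    env["fucoxanthin"] = np.clip(0.8 + c * (0.5 * (1 - fresh) + 0.4 * w) + noise(0.25), 0.0, None)
    env["violaxanthin"] = np.clip(0.15 + c * (0.2 * w + 0.1 * (1 - fresh)) + noise(0.05), 0.0, None)
    env["zeaxanthin"] = np.clip(0.2 + c * (0.25 * w) + noise(0.07), 0.0, None)
    env["lutein"] = np.clip(0.12 + c * (0.18 * fresh + 0.1 * w) + noise(0.05), 0.0, None)
    env["chlorophyll_b"] = np.clip(0.3 + c * (0.4 * fresh + 0.15 * w) + noise(0.1), 0.0, None)
    env["chlorophyllide_a"] = np.clip(0.1 + c * 0.15 * w + noise(0.05), 0.0, None)
    env["chlorophyll_c2"] = np.clip(0.25 + c * (0.2 * (1 - fresh) + 0.1 * w) + noise(0.08), 0.0, None)
    env["neoxanthin"] = np.clip(0.08 + c * 0.1 * fresh + noise(0.03), 0.0, None)
    env["alloxanthin"] = np.clip(0.15 + c * (0.12 * w + 0.08 * (1 - fresh)) + noise(0.05), 0.0, None)
    # phytoplankton size-fraction proxies: a softmax keeps them in [0,1], summing to 1
    micro = c * (0.8 * fresh + 0.3 * w) + noise(0.3)
    nano = noise(0.3)
    pico = c * (0.8 * (1 - fresh)) + noise(0.3)
    logits = np.stack([micro, nano, pico])
    ratios = np.exp(logits - logits.max(axis=0))
    ratios /= ratios.sum(axis=0)
    env["micro_ratio"], env["nano_ratio"], env["pico_ratio"] = ratios
    return env


BACKGROUND_ID = "NONFOCAL_POOL"


def generate_paired(cfg: SyntheticConfig, dna_table: CountTable) -> PairedTables:
    """Paired rRNA/rDNA tables on the configured paired-month subset.

    The given table provides the gene-library (rDNA) counts of the focal
    community.  Both output tables additionally carry a ``NONFOCAL_POOL``
    row: the share of the sequencing library (``background_share``) held
    by non-focal eukaryotes, with reference activity 1.  Relative
    abundances are thereby measured against the whole library, which is
    what makes the absolute activity level observable — in a table
    renormalized over focal OTUs alone, a common activity factor would
    cancel out.

    Per-OTU activity factors ``a_i ~ lognormal(median, sigma)`` scale each
    sample's DNA fractions into expected RNA fractions (background fixed
    at activity 1), renormalized and multinomially resampled at the
    library size.  The expected log10 RNA:DNA offset of OTU i is
    ``log10(a_i / Z)`` with ``Z = bg + (1 - bg) * sum_j p_j a_j``.
    """
    rngs = _rngs(cfg)
    month_tags = tuple(f"-m{m:02d}-" for m in cfg.paired_months)
    candidates = [s for s in dna_table.sample_ids if any(t in s for t in month_tags)]
    if not candidates:
        candidates = list(dna_table.sample_ids)
    chosen = candidates[:cfg.n_paired]
    focal = dna_table.select_samples(chosen)
    bg = cfg.background_share
    if not (0.0 <= bg < 1.0):
        raise ValueError("background_share must be in [0, 1)")
    focal_counts = focal.data.to_numpy(dtype=float)
    depths = focal_counts.sum(axis=0)
    bg_counts = np.round(depths * bg / (1.0 - bg)).astype(np.int64) if bg else np.zeros(
        len(chosen), dtype=np.int64)
    dna_df = pd.concat([
        focal.data,
        pd.DataFrame([bg_counts], index=[BACKGROUND_ID], columns=chosen),
    ])
    dna = CountTable(dna_df)
    act_rng = rngs["activity"]
    factors = np.exp(np.log(cfg.activity_median)
                     + cfg.activity_sigma * act_rng.standard_normal(len(focal.otu_ids)))
    all_factors = np.concatenate([factors, [1.0]])  # background at reference activity
    dna_all = dna.data.to_numpy(dtype=float)
    dna_frac = dna_all / dna_all.sum(axis=0)
    rna_rng = rngs["rna"]
    expected = dna_frac * all_factors[:, None]
    expected /= expected.sum(axis=0)
    totals = dna_all.sum(axis=0).astype(np.int64)
    rna_counts = np.empty_like(dna_all, dtype=np.int64)
    for j in range(expected.shape[1]):
        rna_counts[:, j] = rna_rng.multinomial(int(totals[j]), expected[:, j])
    rna = CountTable(pd.DataFrame(rna_counts, index=dna.otu_ids, columns=chosen))
    return PairedTables(rna=rna, dna=dna)


def planted_truth(cfg: SyntheticConfig) -> PlantedTruth:
    """The latent structure of a dataset generated from ``cfg``."""
    layout = sample_layout(cfg)
    driving = []
    if cfg.salinity_coupling != 0:
        driving.append("salinity")
    if cfg.temperature_coupling != 0:
        driving.append("temperature")
    return PlantedTruth(
        zones=layout["zone"].to_dict(),
        seasons=layout["season"].to_dict(),
        driving_variables=tuple(driving),
        activity_median=cfg.activity_median,
        activity_sigma=cfg.activity_sigma,
    )
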