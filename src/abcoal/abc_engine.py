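"""Rejection + GLM-adjusted ABC: reference tables, model choice, robustness.

The engine reduces observed and simulated multilocus datasets to the ordered
statistic vector of :mod:`abcoal.sumstats`, builds per-model reference tables
by drawing from explicit priors and simulating with the coalescent kernels,
and then performs

* standardized-Euclidean rejection (stable tie-breaking by row index),
* local-linear (GLM) regression adjustment with Epanechnikov weights on an
  unconstrained transform of each bounded parameter,
* model choice from each model's share of the jointly retained nearest
  simulations (equal model priors), with Bayes factors and a
  logistic-regression cross-check,
* robustness: the fraction of pseudo-observed datasets assigned back to
  their generating model,
* the two hierarchical comparison plans (SI vs IM within topologies then
  topologies under IM; continuous-vs-recent temporal variants).

Every stochastic operation takes an explicit seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coalsim import (
    DemographicModel,
    LociConfig,
    ModelParams,
    TOPOLOGIES,
    fast_stat_blocks,
)
from .sumstats import StatConfig, StatVector, assemble_vector

logger = logging.getLogger(__name__)

__all__ = [
    "PriorDist",
    "PriorSpec",
    "ABCConfig",
    "SimulationTable",
    "default_priors",
    "params_from_draw",
    "sample_prior",
    "build_reference_table",
    "PLSProjector",
    "reject",
    "glm_adjust",
    "model_posterior",
    "model_posterior_logistic",
    "robustness",
    "hierarchical_selection",
    "build_model_tables",
    "prune_correlated",
    "abc_mcmc_sample",
]

_SPECIES = ("a", "b", "c")  # generic labels for the three modelled species
_PAIRS = [(0, 1), (0, 2), (1, 2)]


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorDist:
    """One parameter's prior: uniform/log-uniform/fixed, optionally a
    (log-)uniform *factor* applied to the mean of earlier parameters."""

    kind: str                       # uniform | loguniform | fixed
    lo: float = 0.0
    hi: float = 0.0
    value: float = 0.0
    bases: tuple[str, ...] = ()     # factor parameters: value = draw * mean(bases)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "loguniform", "fixed"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind != "fixed":
            if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
                raise ValueError(f"bounds must be finite and ordered: {self}")
            if self.kind == "loguniform" and self.lo <= 0:
                raise ValueError("log-uniform bounds must be positive")


@dataclass
class PriorSpec:
    """Ordered parameter priors; factor parameters must follow their bases."""

    params: dict[str, PriorDist]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, dist in self.params.items():
            for b in dist.bases:
                if b not in seen:
                    raise ValueError(f"{name}: base {b!r} not defined earlier (cycle?)")
            seen.add(name)

    @property
    def free_names(self) -> list[str]:
        return [n for n, d in self.params.items() if d.kind != "fixed"]

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Primitive draws: factor parameters hold the *factor*, not the value."""
        cols = {}
        for name, d in self.params.items():
            if d.kind == "fixed":
                cols[name] = np.full(n, d.value)
            elif d.kind == "uniform":
                cols[name] = rng.uniform(d.lo, d.hi, size=n)
            else:
                cols[name] = np.exp(rng.uniform(math.log(d.lo), math.log(d.hi), size=n))
        return pd.DataFrame(cols)

    def realize(self, draws: pd.DataFrame) -> pd.DataFrame:
        """Resolve factor parameters into values (keeps draw columns' order)."""
        out = {}
        for name, d in self.params.items():
            v = draws[name].to_numpy(dtype=float)
            if d.bases:
                base = np.mean([out[b] for b in d.bases], axis=0)
                v = v * base
            out[name] = v
        return pd.DataFrame(out, index=draws.index)

    # --- unconstrained transform for regression adjustment ---------------

    def _scaled(self, name: str, x: np.ndarray) -> np.ndarray:
        d = self.params[name]
        if d.kind == "loguniform":
            return (np.log(x) - math.log(d.lo)) / (math.log(d.hi) - math.log(d.lo))
        return (x - d.lo) / (d.hi - d.lo)

    def _unscaled(self, name: str, u: np.ndarray) -> np.ndarray:
        d = self.params[name]
        if d.kind == "loguniform":
            return np.exp(math.log(d.lo) + u * (math.log(d.hi) - math.log(d.lo)))
        return d.lo + u * (d.hi - d.lo)

    def transform(self, draws: pd.DataFrame) -> np.ndarray:
        """Logit of the (log-)bound-scaled free parameters -> unbounded Z."""
        zs = []
        for name in self.free_names:
            u = np.clip(self._scaled(name, draws[name].to_numpy(float)), 1e-12, 1 - 1e-12)
            zs.append(np.log(u / (1 - u)))
        return np.column_stack(zs) if zs else np.empty((len(draws), 0))

    def inverse_transform(self, z: np.ndarray, template: pd.DataFrame) -> pd.DataFrame:
        """Back-map adjusted Z to primitive draws (bounds guaranteed)."""
        out = template.copy()
        for j, name in enumerate(self.free_names):
            u = 1.0 / (1.0 + np.exp(-z[:, j]))
            out[name] = self._unscaled(name, u)
        return out

    def log_density_z(self, z: np.ndarray) -> np.ndarray:
        """Log prior density on the transformed scale (up to a constant)."""
        u = 1.0 / (1.0 + np.exp(-z))
        return np.sum(np.log(u) + np.log(1 - u), axis=-1)


def sample_prior(spec: PriorSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Realized i.i.d. prior draws (derived constraints hold by construction)."""
    return spec.realize(spec.sample(n, rng))


_MIG_NAMES = [f"twoNm_{_SPECIES[i]}{_SPECIES[j]}" for i in range(3) for j in range(3) if i != j]


def default_priors(
    model: DemographicModel,
    mu: float = 1e-9,
    mig_low: float = 0.1,
    mig_high: float = 3.0,
) -> PriorSpec:
    """The documented default prior space for the three-species model family.

    Current sizes log-uniform [1e6, 2e8]; ancestral sizes log-uniform
    fractions [1/30, 1/2] of the mean descendant size; t1 uniform
    [9.1e6, 3.6e7] generations (about 1-4 MY at 0.11 yr/gen) with
    t0 = U(0.2, 0.9) * t1; directed 2Nm log-uniform [mig_low, mig_high]
    under IM; recent-expansion size ratio log-uniform [1/30, 1/3].
    """
    si, sj = TOPOLOGIES[model.topology]
    third = 3 - si - sj
    p: dict[str, PriorDist] = {}
    for s in _SPECIES:
        p[f"N_{s}"] = PriorDist("loguniform", 1e6, 2e8)
    p["N_anc_pair"] = PriorDist(
        "loguniform", 1 / 30, 1 / 2,
        bases=(f"N_{_SPECIES[si]}", f"N_{_SPECIES[sj]}"),
    )
    p["N_root"] = PriorDist(
        "loguniform", 1 / 30, 1 / 2, bases=("N_anc_pair", f"N_{_SPECIES[third]}")
    )
    p["t1"] = PriorDist("uniform", 9.1e6, 3.6e7)
    p["t0"] = PriorDist("uniform", 0.2, 0.9, bases=("t1",))
    if model.gene_flow == "IM":
        for name in _MIG_NAMES:
            p[name] = PriorDist("loguniform", mig_low, mig_high)
    if model.recent_expansion:
        p["pre_exp_ratio"] = PriorDist("loguniform", 1 / 30, 1 / 3)
    p["mu"] = PriorDist("fixed", value=mu)
    return PriorSpec(p)


def params_from_draw(model: DemographicModel, row: Mapping[str, float]) -> ModelParams:
    """Realized prior row -> ModelParams (2Nm converted to recipient-fraction m)."""
    sizes = np.array([row[f"N_{s}"] for s in _SPECIES])
    mig = np.zeros((3, 3))
    if model.gene_flow == "IM":
        for i in range(3):
            for j in range(3):
                if i != j:
                    key = f"twoNm_{_SPECIES[i]}{_SPECIES[j]}"
                    if key in row:
                        mig[i, j] = row[key] / (2.0 * sizes[j])
    return ModelParams(
        sizes=sizes,
        n_anc_pair=float(row["N_anc_pair"]),
        n_root=float(row["N_root"]),
        t0=float(row["t0"]),
        t1=float(row["t1"]),
        mig=mig,
        mu=float(row["mu"]),
        pre_exp_ratio=float(row.get("pre_exp_ratio", 1.0)),
    )


# ---------------------------------------------------------------------------
# configuration and tables
# ---------------------------------------------------------------------------

@dataclass
class ABCConfig:
    """Knobs of the ABC runs (desk-scale defaults)."""

    n_sims: int = 10_000
    retain: int = 500
    tolerance: float | None = None      # retained fraction; overrides `retain`
    pls_components: int = 0             # 0 = no projection
    n_pseudo: int = 200                 # pseudo-observed datasets per model
    samples: tuple[int, int, int] = (20, 18, 17)
    loci: LociConfig = field(default_factory=LociConfig)
    mutation_model: str = "infinite_sites"
    stat_config: StatConfig = field(default_factory=StatConfig)
    mcmc_proposal: float = 1.0          # ABC-MCMC proposal range (phi)
    mcmc_length: int = 10_000
    mcmc_delta: float = 0.1             # ABC-MCMC tolerance quantile (delta)
    n_workers: int = 1

    def n_retain(self, table_size: int) -> int:
        r = (
            max(int(round(self.tolerance * table_size)), 1)
            if self.tolerance is not None
            else self.retain
        )
        if r < 10:
            raise ValueError("retain at least 10 simulations")
        return min(r, table_size)


@dataclass
class SimulationTable:
    """(model id, parameter draw, statistic vector) rows + standardization."""

    model: DemographicModel
    prior: PriorSpec
    draws: pd.DataFrame          # primitive draws (factors unresolved)
    stats: np.ndarray            # (n, n_stats)
    stat_names: list[str]
    seed: int
    species: tuple[str, ...] = _SPECIES

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.shape[0] != len(self.draws):
            raise ValueError("draws and stats must have equal length")
        self._mean = self.stats.mean(axis=0)
        sd = self.stats.std(axis=0, ddof=1)
        self._sd = sd
        self.kept_columns = sd > 0
        dropped = int((~self.kept_columns).sum())
        if dropped:
            logger.info(
                "%s: dropped %d zero-variance statistic columns", self.model.label, dropped
            )

    @property
    def n_rows(self) -> int:
        return self.stats.shape[0]

    def standardize(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x[:, self.kept_columns] - self._mean[self.kept_columns]) / self._sd[
            self.kept_columns
        ]

    def realized(self) -> pd.DataFrame:
        return self.prior.realize(self.draws)

    def to_tsv(self, path: str | Path) -> None:
        header = {
            "model": self.model.label,
            "stat_names": self.stat_names,
            "mean": self._mean.tolist(),
            "sd": self._sd.tolist(),
            "seed": self.seed,
        }
        df = pd.concat(
            [self.draws.reset_index(drop=True),
             pd.DataFrame(self.stats, columns=self.stat_names)],
            axis=1,
        )
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            df.to_csv(fh, sep="\t", index=False)


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    return (np.random.SeedSequence(int(seed)).generate_state(n) & 0x7FFFFFFF).astype(
        np.int64
    )


def _simulate_rows(
    model: DemographicModel,
    cols: dict[str, np.ndarray],
    sim_seeds: np.ndarray,
    cfg: ABCConfig,
) -> np.ndarray:
    stats = None
    for i in range(len(sim_seeds)):
        row = {k: v[i] for k, v in cols.items()}
        params = params_from_draw(model, row)
        blocks = fast_stat_blocks(
            model,
            params,
            cfg.samples,
            int(sim_seeds[i]),
            loci=cfg.loci,
            mutation_model=cfg.mutation_model,
        )
        vec = assemble_vector(blocks, _SPECIES, cfg.stat_config)
        if stats is None:
            stats = np.empty((len(sim_seeds), len(vec.values)))
        stats[i] = vec.values
    return stats


def build_reference_table(
    model: DemographicModel,
    prior: PriorSpec,
    cfg: ABCConfig,
    seed: int,
) -> SimulationTable:
    """Simulate ``cfg.n_sims`` datasets from the prior and summarise each.

    Deterministic for a given seed regardless of ``cfg.n_workers``: every
    simulation's seed is a counter-derived function of (seed, row index) and
    results are concatenated in row order.
    """
    rng = np.random.default_rng(seed)
    draws = prior.sample(cfg.n_sims, rng)
    realized = prior.realize(draws)
    sim_seeds = _derive_seeds(seed + 1, cfg.n_sims)
    cols = {k: realized[k].to_numpy() for k in realized.columns}
    if cfg.n_workers > 1 and cfg.n_sims >= 4 * cfg.n_workers:
        from joblib import Parallel, delayed

        bounds = np.linspace(0, cfg.n_sims, cfg.n_workers + 1).astype(int)
        chunks = Parallel(n_jobs=cfg.n_workers)(
            delayed(_simulate_rows)(
                model,
                {k: v[lo:hi] for k, v in cols.items()},
                sim_seeds[lo:hi],
                cfg,
            )
            for lo, hi in zip(bounds[:-1], bounds[1:])
        )
        stats = np.vstack(chunks)
    else:
        stats = _simulate_rows(model, cols, sim_seeds, cfg)
    stat_names = cfg.stat_config.layout(_SPECIES)
    return SimulationTable(
        model=model, prior=prior, draws=draws, stats=stats,
        stat_names=stat_names, seed=seed,
    )


def simulate_pseudo_stats(
    model: DemographicModel, prior: PriorSpec, cfg: ABCConfig, n: int, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """n pseudo-observed datasets drawn from the prior, reduced to vectors."""
    sub = replace(cfg, n_sims=n)
    t = build_reference_table(model, prior, sub, seed)
    return t.draws, t.stats


def prune_correlated(stats: np.ndarray, stat_names: Sequence[str], n_keep: int) -> list[str]:
    """Iteratively drop the statistic with the largest maximum absolute
    correlation until ``n_keep`` remain (deterministic redundancy pruning)."""
    names = list(stat_names)
    x = np.asarray(stats, dtype=float)
    keep = [i for i in range(x.shape[1]) if np.std(x[:, i]) > 0]
    while len(keep) > n_keep:
        sub = x[:, keep]
        c = np.abs(np.corrcoef(sub, rowvar=False))
        np.fill_diagonal(c, 0.0)
        worst = int(np.argmax(c.max(axis=1)))
        keep.pop(worst)
    return [names[i] for i in keep]


# ---------------------------------------------------------------------------
# projection, rejection, adjustment
# ---------------------------------------------------------------------------

class PLSProjector:
    """Partial-least-squares projection of statistics fitted on a table.

    Components are extracted by regressing the (transformed) parameters on
    the standardized statistics (NIPALS, via scikit-learn); ``k = 0`` is the
    identity.
    """

    def __init__(self, k: int):
        self.k = k
        self._pls = None

    def fit(self, x_std: np.ndarray, z_params: np.ndarray) -> "PLSProjector":
        if self.k == 0:
            return self
        if self.k > x_std.shape[1]:
            raise ValueError(f"k={self.k} exceeds {x_std.shape[1]} statistics")
        from sklearn.cross_decomposition import PLSRegression

        self._pls = PLSRegression(n_components=self.k, scale=False)
        self._pls.fit(x_std, z_params)
        return self

    def transform(self, x_std: np.ndarray) -> np.ndarray:
        if self.k == 0:
            return x_std
        return self._pls.transform(np.atleast_2d(x_std))


@dataclass
class RejectionResult:
    indices: np.ndarray
    distances: np.ndarray        # for the retained rows, ascending
    x_retained: np.ndarray       # retained rows in the rejection space
    x_obs: np.ndarray            # observed point in the rejection space


def _obs_values(obs: StatVector | np.ndarray) -> np.ndarray:
    return obs.values if isinstance(obs, StatVector) else np.asarray(obs, dtype=float)


def reject(
    obs: StatVector | np.ndarray,
    table: SimulationTable,
    cfg: ABCConfig,
    projector: PLSProjector | None = None,
) -> RejectionResult:
    """Standardized-Euclidean rejection; ties broken by stable row index."""
    obs_v = _obs_values(obs)
    if obs_v.shape[-1] != len(table.stat_names):
        raise ValueError("observed vector layout does not match the table")
    x = table.standardize(table.stats)
    xo = table.standardize(obs_v)
    if projector is not None:
        x = projector.transform(x)
        xo = projector.transform(xo)
    d = np.sqrt(((x - xo) ** 2).sum(axis=1))
    r = cfg.n_retain(table.n_rows)
    order = np.argsort(d, kind="stable")[:r]
    return RejectionResult(indices=order, distances=d[order], x_retained=x[order],
                           x_obs=xo[0])


def glm_adjust(
    table: SimulationTable,
    rej: RejectionResult,
    cfg: ABCConfig | None = None,
) -> pd.DataFrame:
    """Local-linear regression adjustment of the retained parameter draws.

    Each free parameter (on its unbounded transform) is regressed on the
    retained statistics with Epanechnikov weights in distance and shifted to
    the observed point; back-mapping guarantees prior bounds.  Returns
    *realized* parameter values.
    """
    draws = table.draws.iloc[rej.indices].reset_index(drop=True)
    z = table.prior.transform(draws)
    n_free = z.shape[1]
    if len(draws) < 10 * max(n_free, 1):
        logger.warning("few retained rows (%d) for %d parameters", len(draws), n_free)
    dmax = rej.distances.max()
    if dmax <= 0:
        return table.prior.realize(draws)
    w = 1.0 - (rej.distances / (dmax * (1 + 1e-12))) ** 2
    a = np.column_stack([np.ones(len(draws)), rej.x_retained])
    sw = np.sqrt(np.maximum(w, 1e-12))
    try:
        beta, *_ = np.linalg.lstsq(a * sw[:, None], z * sw[:, None], rcond=None)
    except np.linalg.LinAlgError:
        logger.warning("singular design in GLM adjustment; returning unadjusted sample")
        return table.prior.realize(draws)
    if not np.isfinite(beta).all():
        logger.warning("non-finite GLM coefficients; returning unadjusted sample")
        return table.prior.realize(draws)
    z_adj = z - (rej.x_retained - rej.x_obs) @ beta[1:]
    adj_draws = table.prior.inverse_transform(z_adj, draws)
    return table.prior.realize(adj_draws)


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelComparisonResult:
    labels: list[str]
    posterior: np.ndarray
    counts: np.ndarray
    n_retained: int

    def __post_init__(self) -> None:
        s = self.posterior.sum()
        if not math.isclose(s, 1.0, rel_tol=1e-9):
            raise AssertionError("posterior probabilities must sum to 1")

    def prob(self, label: str) -> float:
        return float(self.posterior[self.labels.index(label)])

    def bayes_factor(self, a: str, b: str) -> float:
        return self.prob(a) / self.prob(b)

    def bayes_factors(self) -> pd.DataFrame:
        bf = self.posterior[:, None] / self.posterior[None, :]
        return pd.DataFrame(bf, index=self.labels, columns=self.labels)

    @property
    def best(self) -> str:
        return self.labels[int(np.argmax(self.posterior))]


def _pooled_standardize(tables: Sequence[SimulationTable]) -> tuple[np.ndarray, np.ndarray]:
    pooled = np.vstack([t.stats for t in tables])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf  # zero-variance columns carry no distance
    return mean, sd


def model_posterior(
    obs: StatVector | np.ndarray,
    tables: Sequence[SimulationTable],
    cfg: ABCConfig,
) -> ModelComparisonResult:
    """Posterior model probabilities from the jointly retained simulations.

    All tables are standardized with pooled constants; the ``cfg`` retained
    count applies to the pooled table, and each model's probability is its
    share of the retained rows (equal model priors; a model retained zero
    times gets the floor 1/(n_retained+1))."""
    names = tables[0].stat_names
    for t in tables[1:]:
        if t.stat_names != names:
            raise ValueError("tables have mismatched statistic layouts")
    obs_v = _obs_values(obs)
    mean, sd = _pooled_standardize(tables)
    xo = (obs_v - mean) / sd
    dist_all = []
    labels = []
    model_idx = []
    for mi, t in enumerate(tables):
        x = (t.stats - mean) / sd
        dist_all.append(np.sqrt(((x - xo) ** 2).sum(axis=1)))
        labels.append(t.model.label)
        model_idx.append(np.full(t.n_rows, mi))
    d = np.concatenate(dist_all)
    midx = np.concatenate(model_idx)
    r = cfg.n_retain(len(d))
    order = np.argsort(d, kind="stable")[:r]
    counts = np.bincount(midx[order], minlength=len(tables)).astype(float)
    probs = counts / r
    if (probs == 0).any():
        logger.warning("model(s) with zero retained rows; applying probability floor")
        probs = np.maximum(probs, 1.0 / (r + 1))
        probs /= probs.sum()
    return ModelComparisonResult(
        labels=labels, posterior=probs, counts=counts, n_retained=r
    )


def model_posterior_logistic(
    obs: StatVector | np.ndarray, tables: Sequence[SimulationTable], cfg: ABCConfig
) -> np.ndarray:
    """Multinomial-logistic cross-check of the retained-share estimator."""
    from sklearn.linear_model import LogisticRegression

    mean, sd = _pooled_standardize(tables)
    x = np.vstack([(t.stats - mean) / sd for t in tables])
    y = np.concatenate([np.full(t.n_rows, i) for i, t in enumerate(tables)])
    xo = (_obs_values(obs) - mean) / sd
    clf = LogisticRegression(max_iter=2000, C=1.0)
    clf.fit(x, y)
    return clf.predict_proba(xo[None, :])[0]


# ---------------------------------------------------------------------------
# robustness and hierarchical plans
# ---------------------------------------------------------------------------

@dataclass
class RobustnessResult:
    """Fractions of pseudo-observed datasets assigned to their generating side."""

    label_a: str
    label_b: str
    frac_a: float
    frac_b: float
    n_pseudo: int

    @property
    def mean(self) -> float:
        return 0.5 * (self.frac_a + self.frac_b)


ModelAndPrior = tuple[DemographicModel, PriorSpec]


def _classify_side(
    stats: np.ndarray,
    tables_a: Sequence[SimulationTable],
    tables_b: Sequence[SimulationTable],
    cfg: ABCConfig,
) -> np.ndarray:
    """P(side A) for each pseudo vector: mean member probability per side,
    renormalized across the two sides."""
    out = np.empty(stats.shape[0])
    tables = list(tables_a) + list(tables_b)
    na = len(tables_a)
    for i in range(stats.shape[0]):
        res = model_posterior(stats[i], tables, cfg)
        pa = res.posterior[:na].mean()
        pb = res.posterior[na:].mean()
        out[i] = pa / (pa + pb)
    return out


def robustness(
    side_a: ModelAndPrior | Sequence[ModelAndPrior],
    side_b: ModelAndPrior | Sequence[ModelAndPrior],
    cfg: ABCConfig,
    seed: int,
    tables: Mapping[str, SimulationTable] | None = None,
) -> RobustnessResult:
    """Two-sided classification robustness between model sets.

    ``cfg.n_pseudo`` pseudo-observed datasets are simulated from the prior on
    each side (split evenly over a side's members), classified against
    reference tables (fresh ones are built unless supplied), and the fraction
    assigned to the generating side is reported per direction; ties count 0.5.
    """
    def _aslist(s):
        return [s] if isinstance(s, tuple) and isinstance(s[0], DemographicModel) else list(s)

    a_list, b_list = _aslist(side_a), _aslist(side_b)
    seeds = _derive_seeds(seed, 2 * (len(a_list) + len(b_list)) + 2)
    tables = dict(tables) if tables else {}
    si = 0
    for m, p in a_list + b_list:
        if m.label not in tables:
            tables[m.label] = build_reference_table(m, p, cfg, int(seeds[si]))
        si += 1
    ta = [tables[m.label] for m, _ in a_list]
    tb = [tables[m.label] for m, _ in b_list]

    def _pseudo(side: list[ModelAndPrior], base: int) -> np.ndarray:
        per = cfg.n_pseudo // len(side)
        extra = cfg.n_pseudo - per * len(side)
        chunks = []
        for j, (m, p) in enumerate(side):
            nj = per + (1 if j < extra else 0)
            _, stats = simulate_pseudo_stats(m, p, cfg, nj, int(seeds[base + j]))
            chunks.append(stats)
        return np.vstack(chunks)

    off = len(a_list) + len(b_list)
    pa = _pseudo(a_list, off)
    pb = _pseudo(b_list, off + len(a_list))
    sa = _classify_side(pa, ta, tb, cfg)
    sb = _classify_side(pb, ta, tb, cfg)

    def _frac_correct(scores: np.ndarray, want_a: bool) -> float:
        s = scores if want_a else 1.0 - scores
        return float(((s > 0.5).sum() + 0.5 * (s == 0.5).sum()) / len(s))

    return RobustnessResult(
        label_a="+".join(m.label for m, _ in a_list),
        label_b="+".join(m.label for m, _ in b_list),
        frac_a=_frac_correct(sa, True),
        frac_b=_frac_correct(sb, False),
        n_pseudo=cfg.n_pseudo,
    )


def build_model_tables(
    models: Mapping[str, ModelAndPrior], cfg: ABCConfig, seed: int
) -> dict[str, SimulationTable]:
    """One reference table per model, with per-model derived seeds."""
    seeds = _derive_seeds(seed, len(models))
    return {
        label: build_reference_table(m, p, cfg, int(s))
        for (label, (m, p)), s in zip(models.items(), seeds)
    }


@dataclass
class SelectionStep:
    description: str
    result: ModelComparisonResult
    robustness: RobustnessResult | None = None


@dataclass
class SelectionReport:
    plan: str
    steps: list[SelectionStep]
    selected: DemographicModel

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            for lbl, p in zip(s.result.labels, s.result.posterior):
                rows.append(
                    {
                        "step": s.description,
                        "model": lbl,
                        "posterior": p,
                        "robustness": s.robustness.mean if s.robustness else math.nan,
                    }
                )
        return pd.DataFrame(rows)


def hierarchical_selection(
    obs: StatVector | np.ndarray,
    plan: str,
    cfg: ABCConfig,
    seed: int,
    mu: float = 1e-9,
    topology: str = "top2",
    tables: Mapping[str, SimulationTable] | None = None,
    with_robustness: bool = False,
) -> SelectionReport:
    """The two hierarchical comparison plans.

    Plan 1: SI vs IM within each topology, then the three topologies under
    IM.  Plan 2 (at a fixed topology): continuous-migration/continuous-
    expansion against each non-contiguous temporal variant, then the best two
    head-to-head.
    """
    if plan == "plan1":
        models: dict[str, ModelAndPrior] = {}
        for topo in TOPOLOGIES:
            for gf in ("SI", "IM"):
                m = DemographicModel(topology=topo, gene_flow=gf)
                models[m.label] = (m, default_priors(m, mu=mu))
        tables = dict(tables) if tables else build_model_tables(models, cfg, seed)
        steps = []
        winners = {}
        for topo in TOPOLOGIES:
            pair = [models[f"{topo}-SI-CmigCexp"], models[f"{topo}-IM-CmigCexp"]]
            res = model_posterior(obs, [tables[m.label] for m, _ in pair], cfg)
            rob = (
                robustness(pair[0], pair[1], cfg, seed + 11, tables=tables)
                if with_robustness
                else None
            )
            steps.append(SelectionStep(f"SI vs IM within {topo}", res, rob))
            winners[topo] = res.best
        im_models = [models[f"{t}-IM-CmigCexp"] for t in TOPOLOGIES]
        res = model_posterior(obs, [tables[m.label] for m, _ in im_models], cfg)
        steps.append(SelectionStep("topologies under IM", res))
        best_topo = res.best.split("-")[0]
        selected_label = winners[best_topo]
        selected = models[selected_label][0]
        return SelectionReport(plan="plan1", steps=steps, selected=selected)
    if plan == "plan2":
        temporals = ("CmigCexp", "CmigRexp", "RmigCexp", "RmigRexp")
        models = {}
        for tv in temporals:
            m = DemographicModel(topology=topology, gene_flow="IM", temporal=tv)
            models[m.label] = (m, default_priors(m, mu=mu))
        tables = dict(tables) if tables else build_model_tables(models, cfg, seed)
        base_label = f"{topology}-IM-CmigCexp"
        steps = []
        alt_probs = {}
        for tv in temporals[1:]:
            lbl = f"{topology}-IM-{tv}"
            pair = [models[base_label], models[lbl]]
            res = model_posterior(obs, [tables[m.label] for m, _ in pair], cfg)
            rob = (
                robustness(pair[0], pair[1], cfg, seed + 13, tables=tables)
                if with_robustness
                else None
            )
            steps.append(SelectionStep(f"CmigCexp vs {tv}", res, rob))
            alt_probs[lbl] = res.prob(lbl)
        beating = [l for l, p in alt_probs.items() if p > 0.5]
        if len(beating) >= 2:
            top2 = sorted(beating, key=lambda l: alt_probs[l], reverse=True)[:2]
            pair = [models[top2[0]], models[top2[1]]]
            res = model_posterior(obs, [tables[m.label] for m, _ in pair], cfg)
            rob = (
                robustness(pair[0], pair[1], cfg, seed + 17, tables=tables)
                if with_robustness
                else None
            )
            steps.append(SelectionStep(f"head-to-head {top2[0]} vs {top2[1]}", res, rob))
            selected_label = res.best
        elif beating:
            selected_label = beating[0]
        else:
            selected_label = base_label
        return SelectionReport(
            plan="plan2", steps=steps, selected=models[selected_label][0]
        )
    raise ValueError(f"unknown plan {plan!r}")


# ---------------------------------------------------------------------------
# optional ABC-MCMC sampler (parameter estimation only)
# ---------------------------------------------------------------------------

def abc_mcmc_sample(
    obs: StatVector | np.ndarray,
    model: DemographicModel,
    prior: PriorSpec,
    cfg: ABCConfig,
    seed: int,
    pilot_table: SimulationTable | None = None,
) -> pd.DataFrame:
    """Likelihood-free MCMC in the prior's unconstrained transform.

    The acceptance threshold is the ``cfg.mcmc_delta`` distance quantile of a
    pilot reference table; proposals are uniform with half-width
    ``cfg.mcmc_proposal`` times the pilot posterior SD per coordinate.
    Model choice never uses this sampler.
    """
    rng = np.random.default_rng(seed)
    table = pilot_table or build_reference_table(model, prior, cfg, seed + 1)
    rej = reject(obs, table, replace(cfg, tolerance=None, retain=max(cfg.retain, 100)))
    eps = np.quantile(
        np.sqrt(
            ((table.standardize(table.stats) - table.standardize(_obs_values(obs))) ** 2).sum(
                axis=1
            )
        ),
        cfg.mcmc_delta,
    )
    z_ret = prior.transform(table.draws.iloc[rej.indices])
    scale = cfg.mcmc_proposal * np.maximum(z_ret.std(axis=0), 1e-3)
    # start at the closest retained draw
    z = z_ret[0].copy()
    template = table.draws.iloc[[rej.indices[0]]].reset_index(drop=True)
    sim_seeds = _derive_seeds(seed + 2, cfg.mcmc_length)
    out = np.empty((cfg.mcmc_length, z.shape[0]))
    logp = prior.log_density_z(z)
    accepted = 0
    for it in range(cfg.mcmc_length):
        zp = z + rng.uniform(-scale, scale)
        logp_p = prior.log_density_z(zp)
        if math.log(rng.random() + 1e-300) < logp_p - logp:
            draw = prior.inverse_transform(zp[None, :], template)
            row = prior.realize(draw).iloc[0]
            params = params_from_draw(model, row)
            blocks = fast_stat_blocks(
                model, params, cfg.samples, int(sim_seeds[it]), loci=cfg.loci,
                mutation_model=cfg.mutation_model,
            )
            vec = assemble_vector(blocks, _SPECIES, cfg.stat_config)
            d = float(
                np.sqrt(
                    ((table.standardize(vec.values) - table.standardize(_obs_values(obs))) ** 2).sum()
                )
            )
            if d <= eps:
                z = zp
                logp = logp_p
                accepted += 1
        out[it] = z
    logger.info("ABC-MCMC acceptance rate %.3f", accepted / cfg.mcmc_length)
    draws = prior.inverse_transform(out, pd.concat([template] * cfg.mcmc_length,
                                                   ignore_index=True))
    return prior.realize(draws)
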