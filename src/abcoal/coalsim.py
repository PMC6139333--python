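"""Structured-coalescent simulation over a three-species model space.

The model space covers three rooted topologies over species (a, b, c), strict
isolation (SI) versus isolation-with-migration (IM), and four temporal
variants crossing continuous/recent migration with continuous/recent
population expansion around a fixed changepoint (3,000 generations by
default).  Two split times bound the demography: ``t0`` (the recent split,
joining the sister pair into an ancestor of size ``n_anc_pair``) and ``t1``
(the older split, joining everything into the root of size ``n_root``).

Conventions (documented in docs/methods.md):
  * diploid sizes; pairwise coalescence rate 1/(2N) per generation;
    theta = 4*N*mu;
  * forward migration rate m[i->j] is the fraction of the *recipient*
    population j replaced by migrants from i each generation, so a lineage in
    j moves (backward in time) to i at rate m[i->j];
  * migration acts only among the three sampled species, i.e. more recently
    than t0 (and than t_mig under recent-migration variants);
  * recent expansion multiplies the three species sizes by ``pre_exp_ratio``
    more anciently than ``t_exp``; ancestral sizes are not affected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _fast
from .data_model import LocusAlignment, MultilocusDataset

__all__ = [
    "TOPOLOGIES",
    "TEMPORAL_MODELS",
    "DemographicModel",
    "ModelParams",
    "Calibration",
    "Genealogy",
    "LociConfig",
    "build_epochs",
    "simulate_genealogy",
    "simulate_panmictic",
    "mutate",
    "simulate_dataset",
    "to_natural_units",
    "calibrate_mu",
    "wf_forward_oracle",
]

#: sister pair (indices into the species order) for each topology
TOPOLOGIES = {"top1": (0, 1), "top2": (0, 2), "top3": (1, 2)}
TEMPORAL_MODELS = ("CmigCexp", "CmigRexp", "RmigCexp", "RmigRexp")

_STIRLING = _fast.log_stirling_table(128)


class InfiniteSitesExhausted(RuntimeError):
    """More mutations than sites; use the finite-sites model instead."""


@dataclass(frozen=True)
class DemographicModel:
    """A point in the discrete model space: topology x gene flow x temporal."""

    topology: str = "top1"
    gene_flow: str = "IM"  # SI | IM
    temporal: str = "CmigCexp"
    t_mig: float = 3000.0  # migration-onset changepoint, generations
    t_exp: float = 3000.0  # expansion changepoint, generations

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.gene_flow not in ("SI", "IM"):
            raise ValueError(f"unknown gene flow mode {self.gene_flow!r}")
        if self.temporal not in TEMPORAL_MODELS:
            raise ValueError(f"unknown temporal model {self.temporal!r}")

    @property
    def recent_migration(self) -> bool:
        return self.gene_flow == "IM" and self.temporal.startswith("Rmig")

    @property
    def recent_expansion(self) -> bool:
        return self.temporal.endswith("Rexp")

    @property
    def label(self) -> str:
        return f"{self.topology}-{self.gene_flow}-{self.temporal}"


@dataclass
class ModelParams:
    """Continuous parameters of a demographic model.

    ``sizes`` are current diploid effective sizes (individuals) of the three
    species; ``mig[i, j]`` is the forward migration rate i->j (fraction of the
    recipient j replaced per generation); ``mu`` is the per-site
    per-generation mutation rate.
    """

    sizes: np.ndarray            # (3,)
    n_anc_pair: float
    n_root: float
    t0: float                    # generations, recent split
    t1: float                    # generations, older split
    mig: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    mu: float = 1e-9
    pre_exp_ratio: float = 1.0

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.mig = np.asarray(self.mig, dtype=float)
        if not (0 < self.t0 < self.t1):
            raise ValueError(f"need 0 < t0 < t1, got t0={self.t0}, t1={self.t1}")
        if (self.sizes <= 0).any() or self.n_anc_pair <= 0 or self.n_root <= 0:
            raise ValueError("all population sizes must be positive")
        if (self.mig < 0).any():
            raise ValueError("migration rates must be non-negative")
        if not np.isfinite(self.mig).all() or not np.isfinite(self.sizes).all():
            raise ValueError("non-finite parameters")
        if self.pre_exp_ratio <= 0:
            raise ValueError("pre_exp_ratio must be positive")

    def two_n_m(self) -> np.ndarray:
        """Population-scaled migration 2Nm[i->j] = 2 * N_j * m[i->j]."""
        return 2.0 * self.sizes[None, :] * self.mig


@dataclass(frozen=True)
class Calibration:
    """Absolute-time calibration: clade split age and generation time."""

    clade_split_years: float = 36e6   # Tephritidae split
    generation_time_years: float = 0.11

    def __post_init__(self) -> None:
        if self.clade_split_years <= 0 or self.generation_time_years <= 0:
            raise ValueError("calibration values must be positive")


def build_epochs(model: DemographicModel, params: ModelParams):
    """Backward-time piecewise-constant epochs for the kernel.

    Returns (t_starts, sizes[K,3], mig_back[K,3,3], merge_src[K], merge_dst[K]).
    """
    if model.gene_flow == "SI" and (params.mig != 0).any():
        raise ValueError("SI model requires all migration rates to be zero")
    si, sj = TOPOLOGIES[model.topology]
    third = 3 - si - sj
    bounds = {0.0, params.t0, params.t1}
    if model.recent_expansion:
        if not model.t_exp < params.t0:
            raise ValueError("t_exp must be more recent than t0")
        bounds.add(model.t_exp)
    if model.recent_migration:
        if not model.t_mig < params.t0:
            raise ValueError("t_mig must be more recent than t0")
        bounds.add(model.t_mig)
    t_starts = np.array(sorted(bounds))
    K = len(t_starts)
    sizes = np.ones((K, 3))
    mig_back = np.zeros((K, 3, 3))
    merge_src = np.full(K, -1, dtype=np.int64)
    merge_dst = np.full(K, -1, dtype=np.int64)
    mig_end = model.t_mig if model.recent_migration else params.t0
    for e, ts in enumerate(t_starts):
        expanded_back = model.recent_expansion and ts >= model.t_exp
        ratio = params.pre_exp_ratio if expanded_back else 1.0
        if ts < params.t0:
            for p in range(3):
                sizes[e, p] = params.sizes[p] * ratio
            if model.gene_flow == "IM" and ts < mig_end:
                for a in range(3):
                    for b in range(3):
                        if a != b:
                            # lineage in a traces to b at the forward rate b->a
                            mig_back[e, a, b] = params.mig[b, a]
        elif ts < params.t1:
            sizes[e, si] = params.n_anc_pair
            sizes[e, third] = params.sizes[third] * ratio
            if ts == params.t0:
                merge_src[e] = sj
                merge_dst[e] = si
        else:
            sizes[e, si] = params.n_root
            if ts == params.t1:
                merge_src[e] = third
                merge_dst[e] = si
    return t_starts, sizes, mig_back, merge_src, merge_dst


@dataclass
class Genealogy:
    """A coalescent tree over pop-blocked samples.

    Nodes 0..n-1 are leaves (ordered by population block); internal nodes are
    numbered in coalescence-time order, the root last.  ``node_pop`` is the
    population each node was created in; ``migrations`` rows are
    (time, node, from_pop, to_pop), oldest events possibly truncated at the
    logging cap (``n_migrations`` is always the true count).
    """

    parent: np.ndarray
    times: np.ndarray
    node_pop: np.ndarray
    samples_per_pop: tuple[int, ...]
    migrations: np.ndarray
    n_migrations: int

    @property
    def n_leaves(self) -> int:
        return (self.parent.shape[0] + 1) // 2

    @property
    def tmrca(self) -> float:
        return float(self.times[-1])

    def branch_lengths(self) -> np.ndarray:
        v = np.arange(self.parent.shape[0] - 1)
        return self.times[self.parent[v]] - self.times[v]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def validate(self) -> None:
        n = self.n_leaves
        internal_times = self.times[n:]
        if not (np.diff(internal_times) >= 0).all():
            raise AssertionError("coalescence times must be non-decreasing")
        if (self.parent[:-1] <= np.arange(self.parent.shape[0] - 1)).any():
            raise AssertionError("parents must postdate children")


def _as_kernel_seed(seed: int) -> int:
    return int(seed) & 0x7FFFFFFF


def simulate_genealogy(
    model: DemographicModel,
    params: ModelParams,
    samples: Sequence[int],
    seed: int,
    log_migrations: bool = True,
) -> Genealogy:
    """Draw one genealogy under the structured coalescent."""
    npp = np.asarray(samples, dtype=np.int64)
    if len(npp) != 3 or (npp < 0).any() or npp.sum() < 2:
        raise ValueError("need three per-species sample counts summing to >= 2")
    t_starts, sizes, mig_back, merge_src, merge_dst = build_epochs(model, params)
    return _run_tree(npp, t_starts, sizes, mig_back, merge_src, merge_dst, seed,
                     log_migrations)


def _run_tree(npp, t_starts, sizes, mig_back, merge_src, merge_dst, seed,
              log_migrations=True) -> Genealogy:
    n = int(npp.sum())
    n_nodes = 2 * n - 1
    parent = np.empty(n_nodes, dtype=np.int64)
    times = np.empty(n_nodes)
    node_pop = np.empty(n_nodes, dtype=np.int64)
    mig_log = np.zeros((_fast.MIG_LOG_CAP if log_migrations else 1, 4))
    n_mig = _fast.sim_tree(
        _as_kernel_seed(seed), npp, t_starts, sizes, mig_back,
        merge_src, merge_dst, parent, times, node_pop, mig_log, log_migrations,
    )
    return Genealogy(
        parent=parent,
        times=times,
        node_pop=node_pop,
        samples_per_pop=tuple(int(x) for x in npp),
        migrations=mig_log[: min(n_mig, mig_log.shape[0])].copy(),
        n_migrations=int(n_mig),
    )


def simulate_panmictic(n: int, N: float, seed: int) -> Genealogy:
    """Single constant-size population: the analytic reference case."""
    npp = np.array([n, 0, 0], dtype=np.int64)
    t_starts = np.array([0.0])
    sizes = np.array([[float(N), 1.0, 1.0]])
    mig = np.zeros((1, 3, 3))
    none = np.array([-1], dtype=np.int64)
    return _run_tree(npp, t_starts, sizes, mig, none, none, seed)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _matrix_to_sequences(mat: np.ndarray) -> list[str]:
    return [bytes(_BASES[row.astype(np.intp)]) .decode() for row in mat]


def mutate(
    g: Genealogy,
    locus_length: int,
    mu_locus: float,
    seed: int,
    model: str = "finite_sites_JC",
    locus_id: str = "locus",
    species: Sequence[str] = ("spA", "spB", "spC"),
) -> LocusAlignment:
    """Drop mutations on a genealogy and return the resulting alignment.

    ``mu_locus`` is the per-site per-generation rate.  ``infinite_sites``
    assigns every mutation its own site (ancestral base random, derived base a
    random different one); ``finite_sites_JC`` allows parallel and back
    mutation with equal-rate base changes.
    """
    if locus_length <= 0:
        raise ValueError("locus_length must be positive")
    n = g.n_leaves
    kseed = _as_kernel_seed(seed)
    if model == "finite_sites_JC":
        mat = _fast.mutate_finite(kseed, g.parent, g.times, n, mu_locus, locus_length)
    elif model == "infinite_sites":
        hits = _fast.mutate_infinite(kseed, g.parent, g.times, n, mu_locus * locus_length)
        m = hits.shape[1]
        if m > locus_length:
            raise InfiniteSitesExhausted(
                f"{m} mutations for {locus_length} sites; use finite_sites_JC"
            )
        rng = np.random.default_rng(kseed)
        anc = rng.integers(0, 4, size=locus_length).astype(np.int8)
        pos = rng.choice(locus_length, size=m, replace=False)
        derived = (anc[pos] + 1 + rng.integers(0, 3, size=m)) % 4
        mat = np.tile(anc, (n, 1))
        for j in range(m):
            mat[hits[:, j] == 1, pos[j]] = derived[j]
    else:
        raise ValueError(f"unknown mutation model {model!r}")
    labels = []
    for p, cnt in enumerate(g.samples_per_pop):
        labels += [species[p]] * cnt
    return LocusAlignment(
        locus_id=locus_id,
        sequences=_matrix_to_sequences(mat),
        species_labels=labels,
        sample_ids=[f"{locus_id}_{sp}_{i}" for i, sp in enumerate(labels)],
    )


@dataclass
class LociConfig:
    """Per-dataset locus layout: counts, lengths and rate heterogeneity."""

    n_loci: int = 20
    length: int = 384
    rate_mult: np.ndarray | None = None      # per-locus relative rates, mean 1
    rate_shape: float = 2.0                  # Gamma shape when drawing them

    def multipliers(self, rng: np.random.Generator) -> np.ndarray:
        if self.rate_mult is not None:
            r = np.asarray(self.rate_mult, dtype=float)
            if r.shape != (self.n_loci,):
                raise ValueError("rate_mult must have one entry per locus")
        else:
            r = rng.gamma(self.rate_shape, 1.0 / self.rate_shape, size=self.n_loci)
        r = r / r.mean()
        return r


def locus_seeds(seed: int, n_loci: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Counter-based per-locus (tree, mutation) seeds from a master seed.

    Seeds depend only on (master seed, locus index), so parallel and serial
    execution agree.
    """
    state = np.random.SeedSequence(int(seed)).generate_state(2 * n_loci + 1)
    tree_seeds = (state[:n_loci] & 0x7FFFFFFF).astype(np.int64)
    mut_seeds = (state[n_loci : 2 * n_loci] & 0x7FFFFFFF).astype(np.int64)
    aux_seed = int(state[-1] & 0x7FFFFFFF)
    return tree_seeds, mut_seeds, aux_seed


def simulate_dataset(
    model: DemographicModel,
    params: ModelParams,
    samples: Sequence[int],
    seed: int,
    loci: LociConfig | None = None,
    species: Sequence[str] = ("spA", "spB", "spC"),
    mutation_model: str = "finite_sites_JC",
) -> MultilocusDataset:
    """Simulate a multilocus dataset of independent loci (deterministic by seed)."""
    loci = loci or LociConfig()
    tree_seeds, mut_seeds, aux = locus_seeds(seed, loci.n_loci)
    mult = loci.multipliers(np.random.default_rng(aux))
    alignments = []
    for li in range(loci.n_loci):
        g = simulate_genealogy(model, params, samples, int(tree_seeds[li]),
                               log_migrations=False)
        alignments.append(
            mutate(
                g,
                loci.length,
                params.mu * mult[li],
                int(mut_seeds[li]),
                model=mutation_model,
                locus_id=f"locus{li:03d}",
                species=species,
            )
        )
    truth = {
        "model": model.label,
        "params": {
            "sizes": params.sizes.tolist(),
            "n_anc_pair": params.n_anc_pair,
            "n_root": params.n_root,
            "t0": params.t0,
            "t1": params.t1,
            "mig": params.mig.tolist(),
            "mu": params.mu,
            "pre_exp_ratio": params.pre_exp_ratio,
        },
        "rate_mult": mult.tolist(),
        "seed": int(seed),
    }
    return MultilocusDataset(
        loci=alignments, species=list(species), provenance="simulated", truth=truth
    )


def fast_stat_blocks(
    model: DemographicModel,
    params: ModelParams,
    samples: Sequence[int],
    seed: int,
    loci: LociConfig | None = None,
    mutation_model: str = "infinite_sites",
) -> np.ndarray:
    """Per-locus statistic blocks without materialising sequences.

    Uses the same kernels and per-locus seed stream as
    :func:`simulate_dataset`, so for the finite-sites model the blocks equal
    ``sumstats.locus_stat_block`` applied to the simulated alignments; for
    infinite sites the 0/1 mutation matrix is statistically equivalent to the
    placed-site alignment for every statistic computed here.
    """
    loci = loci or LociConfig()
    tree_seeds, mut_seeds, aux = locus_seeds(seed, loci.n_loci)
    mult = loci.multipliers(np.random.default_rng(aux))
    t_starts, sizes, mig_back, merge_src, merge_dst = build_epochs(model, params)
    npp = np.asarray(samples, dtype=np.int64)
    return _fast.dataset_blocks(
        tree_seeds,
        mut_seeds,
        npp,
        t_starts,
        sizes,
        mig_back,
        merge_src,
        merge_dst,
        params.mu * mult,
        loci.length,
        mutation_model == "infinite_sites",
        _STIRLING,
    )


def write_ms_style(ds: MultilocusDataset, path) -> None:
    """ms-style segregating-sites output (0/1 haplotypes per locus) for
    cross-tool checks; the ancestral state is taken as each site's first
    allele."""
    lines = [f"ms {ds.loci[0].n_sequences} {ds.n_loci}", "0 0 0", ""]
    for al in ds.loci:
        mat = al.matrix()
        keep = np.flatnonzero((mat < 4).all(axis=0))
        seg = [j for j in keep if len(np.unique(mat[:, j])) > 1]
        lines.append("//")
        lines.append(f"segsites: {len(seg)}")
        if seg:
            lines.append(
                "positions: "
                + " ".join(f"{(j + 0.5) / al.length:.5f}" for j in seg)
            )
            for row in mat:
                lines.append("".join("01"[int(row[j] != mat[0, j])] for j in seg))
        lines.append("")
    from pathlib import Path

    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# unit conversion and calibration
# ---------------------------------------------------------------------------

def generations_to_mya(generations, cal: Calibration = Calibration()):
    return np.asarray(generations, dtype=float) * cal.generation_time_years / 1e6


def mya_to_generations(mya, cal: Calibration = Calibration()):
    return np.asarray(mya, dtype=float) * 1e6 / cal.generation_time_years


def to_natural_units(params: ModelParams, cal: Calibration = Calibration()) -> dict:
    """Demographic-scale report: times in MYA, sizes in individuals, migration
    both as m and as 2Nm of the recipient population."""
    return {
        "t0_mya": float(generations_to_mya(params.t0, cal)),
        "t1_mya": float(generations_to_mya(params.t1, cal)),
        "sizes": params.sizes.tolist(),
        "n_anc_pair": params.n_anc_pair,
        "n_root": params.n_root,
        "m": params.mig.tolist(),
        "two_n_m": params.two_n_m().tolist(),
    }


def jukes_cantor(p: float) -> float:
    if not (0 <= p < 0.75):
        raise ValueError("proportion of differences must be in [0, 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def calibrate_mu(outgroup_divergence: float, cal: Calibration = Calibration()) -> float:
    """Per-site per-generation mutation rate from outgroup divergence.

    mu = JC(divergence) / (2 * clade_split_years) * generation_time_years.
    """
    if not (0.0 < outgroup_divergence < 1.5):
        raise ValueError("divergence must be in (0, 1.5)")
    if outgroup_divergence >= 0.75:
        raise ValueError("divergence saturates the Jukes-Cantor correction")
    k = jukes_cantor(outgroup_divergence)
    return k / (2.0 * cal.clade_split_years) * cal.generation_time_years


# ---------------------------------------------------------------------------
# forward Wright-Fisher oracle (test-scale)
# ---------------------------------------------------------------------------

def wf_forward_oracle(
    N: int,
    samples: Sequence[int] | int,
    n_reps: int,
    seed: int,
    migration: float = 0.0,
    chunk: int | None = None,
) -> dict:
    """Discrete-generation Wright-Fisher oracle with explicit parent tracking.

    One or two demes of ``2N`` gene copies each (diploid size N); each copy
    picks a uniform parent, from the other deme with probability
    ``migration``.  Emits TMRCA draws and the coalescence time of the first
    two sampled copies for comparison with the continuous simulator.
    Deliberately small-scale: refuses N > 500.
    """
    if N > 500:
        raise ValueError("oracle is deliberately small-scale; use N <= 500")
    if isinstance(samples, int):
        samples = [samples]
    n_demes = len(samples)
    if n_demes not in (1, 2):
        raise ValueError("one or two demes only")
    if n_demes == 1 and migration:
        raise ValueError("migration needs two demes")
    rng = np.random.default_rng(seed)
    two_n = 2 * N
    chunk = chunk or min(2000, max(100, 20 * N))
    tmrca = np.empty(n_reps)
    pair_time = np.empty(n_reps)
    for rep in range(n_reps):
        # each sampled copy's current ancestral (deme, copy) state; because a
        # generation's parent assignment is a stored table, coalesced lineages
        # share a state and automatically keep following the same parents
        demes = np.concatenate([np.full(s, d) for d, s in enumerate(samples)])
        copies = np.concatenate([np.arange(s) for s in samples])
        gen = 0
        first_pair_t = math.nan
        while True:
            done = (demes == demes[0]).all() and (copies == copies[0]).all()
            if done:
                break
            # one chunk of forward multinomial generations, parents recorded
            par_copy = rng.integers(0, two_n, size=(chunk, n_demes, two_n))
            if n_demes == 2:
                par_flip = rng.random(size=(chunk, n_demes, two_n)) < migration
            for g in range(chunk):
                new_copies = par_copy[g, demes, copies]
                if n_demes == 2:
                    flip = par_flip[g, demes, copies]
                    demes = np.where(flip, 1 - demes, demes)
                copies = new_copies
                gen += 1
                if math.isnan(first_pair_t) and len(demes) > 1:
                    if demes[0] == demes[1] and copies[0] == copies[1]:
                        first_pair_t = gen
                if (demes == demes[0]).all() and (copies == copies[0]).all():
                    break
        tmrca[rep] = gen
        pair_time[rep] = first_pair_t if not math.isnan(first_pair_t) else gen
    return {"tmrca": tmrca, "pair_time": pair_time}
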