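"""Standard model-discrimination benchmarks at the package's desk scale.

Each benchmark measures classification robustness — the fraction of
pseudo-observed multilocus datasets assigned back to their generating model
by ABC posterior probability — for one of the comparisons the pipeline runs:
strict isolation vs isolation-with-migration, the sister-pair topology, and
recent vs continuous expansion.  Conditions follow the documented defaults:
20 loci x 384 sites, samples 20/18/17, mu = 1e-9, default priors, 10,000-row
reference tables with 500 retained, 200 pseudo-datasets per model side.
"""

from __future__ import annotations

from dataclasses import replace

from .abc_engine import ABCConfig, RobustnessResult, default_priors, robustness
from .coalsim import DemographicModel, LociConfig

__all__ = [
    "desk_config",
    "robustness_si_vs_im",
    "robustness_topology",
    "robustness_recent_expansion",
]


def desk_config(**overrides) -> ABCConfig:
    cfg = ABCConfig(
        n_sims=10_000,
        retain=500,
        n_pseudo=200,
        samples=(20, 18, 17),
        loci=LociConfig(n_loci=20, length=384),
    )
    return replace(cfg, **overrides) if overrides else cfg


def _mp(mu: float = 1e-9, **kw):
    m = DemographicModel(**kw)
    return m, default_priors(m, mu=mu)


def robustness_si_vs_im(
    seed: int, cfg: ABCConfig | None = None, topology: str = "top1"
) -> RobustnessResult:
    """SI vs IM discrimination within one topology (directed 2Nm prior
    log-uniform [0.1, 3] under IM)."""
    cfg = cfg or desk_config()
    return robustness(
        _mp(topology=topology, gene_flow="SI"),
        _mp(topology=topology, gene_flow="IM"),
        cfg,
        seed,
    )


def robustness_topology(seed: int, cfg: ABCConfig | None = None) -> RobustnessResult:
    """The preferred sister-pair topology vs the two alternatives, all under
    IM (pseudo-datasets for the alternative side split between them)."""
    cfg = cfg or desk_config()
    return robustness(
        _mp(topology="top2", gene_flow="IM"),
        [_mp(topology="top1", gene_flow="IM"), _mp(topology="top3", gene_flow="IM")],
        cfg,
        seed,
    )


def robustness_recent_expansion(
    seed: int, cfg: ABCConfig | None = None, topology: str = "top2"
) -> RobustnessResult:
    """Continuous-migration recent-expansion vs continuous-expansion under IM
    (pre-expansion/current size ratio log-uniform [1/30, 1/3])."""
    cfg = cfg or desk_config()
    return robustness(
        _mp(topology=topology, gene_flow="IM", temporal="CmigRexp"),
        _mp(topology=topology, gene_flow="IM", temporal="CmigCexp"),
        cfg,
        seed,
    )
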