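"""ABC posterior estimation of demographic parameters in natural units.

Under the selected isolation-with-migration model, estimates split times,
effective sizes and migration rates by rejection + GLM adjustment, and prints
posterior modes with 95% HPD intervals: split times in MY (0.11 yr per
generation), sizes in millions of individuals, migration as 2Nm of the
recipient.  The generating truth is t0 = 1.3 MY, t1 = 2.6 MY.
"""

from abcoal.abc_engine import ABCConfig, default_priors
from abcoal.coalsim import DemographicModel, LociConfig
from abcoal.demog_inference import estimate_parameters
from abcoal.sumstats import stat_vector
from abcoal.synthetic_data import StudyLikeConfig, generate_study_like

cfg = StudyLikeConfig(seed=21)
ds, _ = generate_study_like(cfg, report=False)
obs = stat_vector(ds)

model = DemographicModel(topology="top2", gene_flow="IM")
prior = default_priors(model, mu=cfg.mu)
abc = ABCConfig(n_sims=5000, retain=500, samples=cfg.samples,
                loci=LociConfig(n_loci=cfg.n_loci, length=cfg.length))
post = estimate_parameters(obs, model, prior, abc, seed=2)

gen_to_my = 0.11 / 1e6
for p in ("t0", "t1"):
    s = post.summary.loc[p]
    print(f"{p}: mode {s['mode'] * gen_to_my:.2f} MY "
          f"(95% HPD {s['hpd_lo'] * gen_to_my:.2f}-{s['hpd_hi'] * gen_to_my:.2f})")
for p in ("N_a", "N_b", "N_c"):
    s = post.summary.loc[p]
    print(f"{p}: mode {s['mode'] / 1e6:.1f}M "
          f"(95% HPD {s['hpd_lo'] / 1e6:.1f}-{s['hpd_hi'] / 1e6:.1f}M)")
for p in ("twoNm_ba", "twoNm_ab"):
    s = post.summary.loc[p]
    flag = " [prior-like: weakly identified]" if s["prior_like"] else ""
    print(f"{p}: mode {s['mode']:.2f} (95% HPD {s['hpd_lo']:.2f}-{s['hpd_hi']:.2f})"
          f"{flag}")
print("\nHPDs are shortest intervals holding 95% of the adjusted posterior "
      "sample; 'prior-like' marks parameters the data barely update.")
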