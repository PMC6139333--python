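"""Structured-coalescent simulation under competing speciation models.

Simulates multilocus datasets under strict isolation (SI) and isolation with
migration (IM) at the same sizes and split times, and contrasts the mean
pairwise Phi_ST and shared/fixed polymorphism counts: deep SI drives Phi_ST
toward 1 with fixed differences, while migration keeps polymorphism shared
and Phi_ST moderate.
"""

import numpy as np

from abcoal.coalsim import DemographicModel, LociConfig, ModelParams, simulate_dataset
from abcoal.sumstats import pair_locus_stats

sizes = np.array([2e4, 3e4, 1e4])
common = dict(sizes=sizes, n_anc_pair=1.5e4, n_root=1e4, t0=2e5, t1=4e5, mu=5e-8)
mig = np.zeros((3, 3))
mig[0, 1] = 1.0 / (2 * sizes[1])   # 2Nm = 1 into species b from a
mig[1, 0] = 1.0 / (2 * sizes[0])

for label, model, params in (
    ("SI", DemographicModel(gene_flow="SI"), ModelParams(**common)),
    ("IM", DemographicModel(gene_flow="IM"), ModelParams(mig=mig, **common)),
):
    ds = simulate_dataset(model, params, (10, 10, 10), seed=7,
                          loci=LociConfig(n_loci=10, length=400))
    phis, sps_, fps = [], [], []
    for al in ds.loci:
        p = pair_locus_stats(al, "spA", "spB", n_perm=0, frame=None)
        phis.append(p.phi_st)
        sps_.append(p.sp)
        fps.append(p.fp)
    print(f"{label}: mean Phi_ST(a,b) = {np.nanmean(phis):.2f}, "
          f"shared polymorphisms/locus = {np.mean(sps_):.1f}, "
          f"fixed differences/locus = {np.mean(fps):.1f}")
print("\nMigration (2Nm = 1) erases fixed differences and keeps Phi_ST low; "
      "strict isolation at the same depth does the opposite.")
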