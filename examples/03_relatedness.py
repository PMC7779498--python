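"""Microsatellite screening and Wang pairwise relatedness.

Each locus gets an exact Hardy-Weinberg test and a heterozygote-deficit
null-allele estimate; a locus is dropped only when both flags fire.  The
retained loci feed the Wang moment estimator, whose W values range from -1
(less related than average) to 1, with ~0.5 for first-degree relatives.
"""

import numpy as np

from convergekit import filter_loci, screen_loci, simulate_study, wang_pairwise
from convergekit.relatedness import reports_frame

study = simulate_study(seed=4)
genotypes = study.genotypes

reports = screen_loci(genotypes, hwe_alpha=0.05, null_threshold=0.05, hwe_mc=20_000, seed=1)
frame = reports_frame(reports)
print(frame[["locus", "n_alleles", "Ho", "He", "hwe_p", "null_freq", "excluded"]]
      .head(5).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
retained = filter_loci(reports)
print(f"{len(retained)} of {len(genotypes.loci)} loci retained")

W = wang_pairwise(genotypes.subset_loci(retained))
w = W.condensed()
kin = study.true_kinship.condensed()
print(f"W over {len(w)} dyads: range [{w.min():.2f}, {w.max():.2f}]")
for label, level in (("full sibs", 0.5), ("half sibs", 0.25), ("pedigree-unrelated", 0.0)):
    sel = kin == level
    if sel.any():
        print(f"  mean W for {label} (n={sel.sum()}): {w[sel].mean():.3f}")
print("negative values mean a dyad shares fewer alleles than two random "
      "members of the sample")
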