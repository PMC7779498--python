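"""Simulate a complete study population and inspect its structure.

Builds the default population — 27 males in two gangs of two parties each
(6, 7, 5 and 9 males) — then draws a call-level acoustic feature table and
microsatellite genotypes with elevated within-party relatedness.
"""

import numpy as np

from convergekit import simulate_study

study = simulate_study(seed=1)
s = study.structure

print(f"individuals: {s.n} in {len(s.parties)} parties / {len(s.gangs)} gangs")
for party in s.parties:
    print(f"  {party}: {len(s.party_members(party))} males (gang {s.gang_of[s.party_members(party)[0]]})")

counts = study.features.counts()
print(f"calls: {counts.sum()} total, per male {counts.min()}-{counts.max()} "
      f"(mean {counts.mean():.1f}), {len(study.features.feature_names)} acoustic features")

kin = study.true_kinship.condensed()
print(f"genotypes: {len(study.genotypes.loci)} loci; "
      f"{int((kin == 0.5).sum())} full-sib and {int((kin == 0.25).sum())} half-sib dyads "
      f"of {len(kin)} total")

# Within-party dyads should be more related than cross-gang dyads
party = s.party_labels()
gang = s.gang_labels()
iu = np.triu_indices(s.n, k=1)
same_party = (party[:, None] == party[None, :])[iu]
cross_gang = (gang[:, None] != gang[None, :])[iu]
print(f"mean pedigree kinship: within party {kin[same_party].mean():.3f}, "
      f"across gangs {kin[cross_gang].mean():.3f}")
print("(the generator couples genotypes and calls only through this shared structure)")
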