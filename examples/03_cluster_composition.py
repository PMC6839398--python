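"""Cluster angle profiles and summarize sex-chromosome composition.

Generates a Yq-deletion population of 600 nuclei with the planted
Y-worse-than-X effects, Ward-clusters the 100-point angle profiles into a
"normal-shaped" and a "deviant" group, and reports the X proportion of
each with its standard error. The normal-shaped cluster should be
X-enriched (around 58-59%) and the deviant cluster Y-enriched.
"""

import numpy as np

from spermshape import (cluster_profiles, cluster_sex_composition,
                        rank_clusters_by_reference)
from spermshape.pipeline import build_measured_population

wt = build_measured_population("WT", 250, seed=3)
yq = build_measured_population("YQDEL", 600, seed=4)

reference = np.mean([r.profile for r in wt], axis=0)
profiles = np.array([r.profile for r in yq])
sex = np.array([r.sex for r in yq])

assignment = cluster_profiles(profiles, k=2)
composition = cluster_sex_composition(assignment, sex)
ranking = rank_clusters_by_reference(assignment, profiles, reference)

print(composition.to_string(index=False))
print()
for i, row in ranking.iterrows():
    tag = "most wild-type-like" if i == 0 else "most deviant"
    cl = int(row.cluster)
    comp = composition[composition.cluster == cl].iloc[0]
    print(f"cluster {cl} ({tag}): X% = {100 * comp.x_proportion:.1f} "
          f"+/- {100 * comp.se_proportion:.1f}")

print("\nX-enrichment of the normal cluster and Y-enrichment of the "
      "deviant cluster reflect the planted 'Y-bearing cells are more "
      "malformed' effect.")
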