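"""Ordinate genomes by COG presence/absence with non-metric MDS.

Two functional groups of genomes share most of their COG repertoires
within-group; NMDS on the Euclidean distances between binary profiles
should place the groups apart. Kruskal stress-1 below ~0.1 indicates a
faithful 2-D picture of the distance structure. Pathway completeness is
the fraction of a pathway's genes found in a genome's annotations.
"""

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

import streampop as sp

rng = np.random.default_rng(3)
core_a = {f"COG{i:04d}" for i in range(40)}
core_b = {f"COG{i:04d}" for i in range(30, 70)}
profiles = {}
for i in range(4):
    profiles[f"pyro{i}"] = core_a | {f"COG9{i}{j}" for j in range(3)}
    profiles[f"therm{i}"] = core_b | {f"COG8{i}{j}" for j in range(3)}

matrix = sp.cog_matrix(profiles)
D = pd.DataFrame(squareform(pdist(matrix.to_numpy())), index=matrix.index, columns=matrix.index)
result = sp.nmds(D, dims=2, n_restarts=20, seed=0)
print(f"NMDS stress (Kruskal stress-1): {result.stress:.4f}")
print(result.coords.round(2))

pathway = sp.default_pathways()["cobalamin_synthesis"]
present = sorted(pathway.required)[:10]
frac = sp.pathway_completeness(present, pathway)
print(f"cobalamin pathway completeness with 10/{len(pathway.required)} genes: {frac:.2f}")
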