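"""Generate a synthetic patient cohort and cluster it on (T1m, T2m).

Two classes of subjects are generated with biomarker means at the cluster
averages observed in patients — control-like (67.9, 77.7) degC and
glaucoma-like (64.6, 79.3) degC — then pushed through peak extraction and
2-means clustering. The lower-T1m center is named the POAG-like cluster.
"""

from tfdp import CohortConfig, cross_tab, generate_cohort, kmeans_two
from tfdp.features import extract_cohort

dataset = generate_cohort(CohortConfig(seed=1))
table = extract_cohort(dataset.runs)
print(f"{len(table)} subjects, {int(table['complete'].sum())} with both peaks detected")

points = table.loc[table["complete"], ["t1m", "t2m"]].to_numpy(float)
result = kmeans_two(points, n_restarts=50, seed=1)
poag_center = result.centers[result.poag_like_cluster]
other_center = result.centers[1 - result.poag_like_cluster]
print(f"POAG-like cluster center: T1m {poag_center[0]:.1f}, T2m {poag_center[1]:.1f} degC")
print(f"control-like center:      T1m {other_center[0]:.1f}, T2m {other_center[1]:.1f} degC")

contingency, positive = cross_tab(result, table.loc[table["complete"], "label"].to_numpy())
print("\ncluster x label counts:")
print(contingency)
print("\nfraction of each label in the POAG-like cluster:")
print(positive.round(3))
print(
    "\nWith well-separated class means, nearly all glaucoma-like subjects fall"
    "\ninto the lower-T1m/higher-T2m cluster, reproducing the clustering logic"
    "\nused on patient biomarkers."
)
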