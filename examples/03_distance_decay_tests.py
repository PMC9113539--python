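"""ANOSIM, Mantel and partial Mantel tests of what structures beta diversity.

The partial Mantel test asks whether community dissimilarity tracks
elevation change after controlling for horizontal (geodesic) distance —
the key test separating environmental filtering from simple distance decay.
"""

import elevassembly as ea

ds = ea.simulate_dataset(design="wm", regime="selection", seed=1)
uf = ea.unweighted_unifrac(ds.table, ds.tree)

zones = ea.assign_zones(ds.metadata["elevation"])
res = ea.anosim(uf, zones, n_perm=999, seed=2)
print(f"ANOSIM by zone: R = {res['R']:.3f}, p = {res['p']:.4f}")

dm_elev = ea.env_distance_matrix(ds.metadata["elevation"], "elevation")
dm_geo = ea.geodesic_matrix(ds.metadata)

mt = ea.mantel(uf, dm_elev, n_perm=999, seed=3)
print(f"Mantel (UniFrac ~ elevation): r = {mt.statistic:.3f}, p = {mt.p_value:.4f}")

pm = ea.partial_mantel(uf, dm_elev, dm_geo, n_perm=999, seed=4)
print(
    f"partial Mantel (elevation | space): r = {pm.statistic:.3f}, "
    f"p = {pm.p_value:.4f}"
)
cg = ea.mantel_correlogram(uf, dm_geo, n_perm=199, seed=5)
print("correlogram (positive r nearby = distance decay):")
print(cg[["midpoint", "n_pairs", "r", "p_holm"]].round(3).to_string(index=False))
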