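"""Fit and evaluate the three suitability algorithms on one record set.

Shows the individual stages the pipeline chains per temporal window:
PCA scores, envelope pseudo-absences, background, checkerboard
evaluation, thresholding and the 0-3 agreement ensemble.
"""

import numpy as np

import decade_enm as de

land = de.generate_landscape((0, 0, 1, 1), 100, 100, 4, seed=1)
truth = de.define_virtual_species(land, np.array([2.0, -1.5, 1.0, -0.5]), 0.0)
centers = de.place_research_centers((0, 0, 1, 1), 5, seed=2)
plan = de.SamplingPlan(decade_breaks=[1900, 2020], records_per_period=[200],
                       bias_strength=0.0, seed=42)
occ = de.sample_occurrences(truth, centers, plan)

scores, pca = de.pca_transform(land.raster_stack, var_threshold=0.95)
print(f"PCA kept {pca.n_retained}/{land.raster_stack.n_layers} axes "
      f"(cumulative variance {np.cumsum(pca.variance_fraction)[pca.n_retained-1]:.3f})")

pres = de.thin_to_cells(occ, scores)
pres_xy = pres[["longitude", "latitude"]].to_numpy()
pres_env = de.extract_values(scores, pres_xy)

envelope = de.build_envelope(pres_env)
pa_xy = de.sample_pseudo_absences(scores, envelope, n=50, seed=7)
bg_xy = de.sample_background(scores, n=10_000, seed=8)
pa_env = de.extract_values(scores, pa_xy)
bg_env = de.extract_values(scores, bg_xy)

partition = de.checkerboard_partition(scores, block_size=12)
binaries = []
for alg in ("MXT", "RDF", "SVM"):
    cxy, cenv = (bg_xy, bg_env) if alg == "MXT" else (pa_xy, pa_env)
    ev = de.evaluate_model(alg, pres_xy, pres_env, cxy, cenv,
                           partition, scores, seed=9)
    print(f"{alg}: TSS={ev.tss:.3f} (sens {ev.sensitivity:.3f}, "
          f"spec {ev.specificity:.3f}), threshold={ev.threshold:.3f}")
    model = de.fit_model(alg, pres_env, cenv, seed=9)
    binaries.append(de.binarize(de.predict_suitability(model, scores), ev.threshold))

ens = de.ensemble_sum(binaries)
print(f"conservative area (all 3 agree):   {de.area_proportion(ens, 'conservative'):.3f}")
print(f"non-conservative area (any of 3):  {de.area_proportion(ens, 'nonconservative'):.3f}")
# TSS = sensitivity + specificity - 1 on the spatially held-out fold;
# the area proportions are shares of the landscape's non-nodata cells.
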