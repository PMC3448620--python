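# isoassign

Isoscape-based geographic assignment of migratory birds from multi-isotope
feather measurements.

Where a migratory bird molted its feathers can be inferred from the stable
isotope ratios (δ²H, δ¹³C, δ¹⁵N, in ‰) locked into the keratin at growth:
each isotope varies systematically across the landscape, and spatial
predictions of those ratios — *isoscapes* — turn a feather measurement into
a likelihood surface over candidate molt origins. `isoassign` implements
the full inference chain used to place Palearctic–Afrotropical migrants
(the motivating case is house martins breeding in the Netherlands and
wintering in Africa) into isotopically distinct wintering regions:

1. **Calibration** — convert environmental isoscapes to the feather scale:
   a linear rainfall-to-feather calibration for δ²H
   (δ²H_f = −6.77 + 1.42·δ²H_p, from known-origin birds) and additive
   diet-to-tissue discrimination offsets for δ¹³C (+2‰) and δ¹⁵N (+5‰).
2. **Clustering** — k-means over the standardized three-layer stack derives
   K isotopically distinct regions; zonal statistics give each region's
   expected feather isotope mean vector μ_k.
3. **Assignment** — the feather covariance Σ is estimated by maximum
   likelihood under a multivariate normal with missing values (EM); each
   complete feather triplet x is scored by the MVN density f(x; μ_k, Σ) and
   normalized across clusters, p_k = f(x; μ_k, Σ) / Σ_j f(x; μ_j, Σ).
   With the shared Σ and equal priors this is nearest-mean assignment in
   Mahalanobis distance.
4. **Uncertainty** — the assignment is repeated over n_sims draws
   x\* ~ MVN(x, Σ_sim), reporting per-cluster mean ± SD counts across
   replicates and per-individual assignment frequencies.
5. **Single-isotope mode** — a spatially continuous posterior origin
   surface from δ²H alone: cell likelihood N(δ²H_f; cell value, σ),
   normalized over the raster, with odds-ratio region delineation.
6. **Ring-recovery band** — OLS of recovery longitude on ringing longitude
   with a t-based 95% prediction interval, intersected with the cluster map
   to bound the wintering region longitudinally.

A synthetic-data module generates complete worlds (isoscapes with known
region structure, feather cohorts with known memberships and covariance,
ring recoveries with known slope) so every stage is testable end to end
without external downloads.

## Worked example

The `demo` subcommand runs the whole pipeline on a synthetic world:

```sh
isoassign demo --seed 3 --n-sims 1000 --outdir demo_out
```

prints (abridged):

```json
{
  "cluster_agreement_with_truth": 0.9317,
  "modal_assignment_accuracy": 0.9415,
  "population_mean_counts": [111.5, 29.7, 19.5, 10.2],
  "population_sd_counts": [5.1, 4.0, 3.4, 2.7],
  "predicted_longitude": 10.76,
  "prediction_interval": [-8.97, 30.50]
}
```

Reading this: k-means on the noisy synthetic isoscapes reproduces 93% of
the true region map; 94% of the 171 synthetic birds are point-assigned to
their true cluster; across 1000 simulation replicates an average of
111.5 ± 5.1 birds land in cluster 1 (and so on — the means sum to the
cohort size); and the ring-recovery regression evaluated at the colony
longitude (5.4°E) predicts a wintering longitude of 10.8° with a 95%
prediction interval of roughly −9.0° to 30.5°.

Individual stages are available as `calibrate`, `cluster`, `zones`,
`assign`, `surface`, `band`, `tstat`, and `simulate`, exchanging CSV and
raster files; the same operations are importable from Python
(`from isoassign import fit_mvn_missing, simulate_assignments, ...`).

A quick scalar check, straight from published group summaries:

```sh
$ isoassign tstat --a-mean -21.4 --a-sd 1.3 --a-n 48 \
                  --b-mean -16.7 --b-sd 1.3 --b-n 212
|t| = 22.6181, df = 258 (pooled)
```

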