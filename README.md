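# netenergy

Structural-balance **energy** analysis of signed, weighted functional
connectivity networks.

For a symmetric signed weight matrix `S` (zero diagonal, weights in
[-1, 1]) the network energy is

```
U = -(1 / C(N,3)) * Σ_triangles cbrt(S_ij * S_ik * S_jk)
```

with the real (signed) cube root. Balanced triangles (positive weight
product) push `U` toward -1 (coordinated, stable organization);
imbalanced triangles (negative product) push it toward +1 (conflicting,
unstable organization). The package computes `U` at whole-network and
canonical sub-network level, rest→task energy changes `ΔU = U_task -
U_rest`, random-topology null comparisons, cross-parcellation
reliability (ICC), nonparametric group statistics, and SVM-based
cognitive-state classification / age regression — all exercisable on a
bundled synthetic-cohort generator, so no external data are needed.

## Layout

| module | contents |
| --- | --- |
| `netenergy.core_energy` | `ConnectivityMatrix`, `Parcellation`, `signed_cbrt`, `network_energy` (trace identity), `brute_force_energy` (enumeration oracle), `triangle_census`, `subnetwork_energy`, `energy_delta`, `energy_table` |
| `netenergy.null_models` | weight-permutation / sign-shuffle surrogates, `null_energy_ensemble` |
| `netenergy.graph_measures` | comparator metrics: weighted global clustering, global efficiency, Louvain modularity |
| `netenergy.stats_inference` | Friedman test (asymptotic + exact), pairwise Wilcoxon with Holm/BH correction, actual-vs-null Wilcoxon, ICC(3,k) |
| `netenergy.predictive_models` | feature assembly, subject-wise LOOCV RBF-SVM classification & regression, permutation feature importance |
| `netenergy.synthetic_data` | seeded cohort generator: community-structured correlation matrices with tunable triangle frustration, condition effects, age effects, re-parcellation with shared latents |
| `netenergy.cli` | `energy` command-line pipeline |

## CLI

```bash
energy simulate --config params.yaml --out data/           # synthetic cohort
energy compute --matrices data/ --parcellation data/parcellation.tsv \
       --out energies.csv                                  # U and ΔU, long CSV
energy nulls --matrices data/ --n-perms 100 --seed 1 --out nulls.csv
energy graph-measures --matrices data/ --parcellation data/parcellation.tsv \
       --out measures.csv
energy stats --energies energies.csv --nulls nulls.csv --out stats/
energy features --energies energies.csv --task classify_state --out features.csv
energy ml classify --features features.csv --seed 1 --out report.json
energy run-all --config params.yaml --seed 1 --out run/    # everything + manifest
```

Matrices are square numeric CSV/TSV files named
`<subject>_<condition>.csv` with conditions from `{nback0, nback1,
nback2, gng_initiation, gng_inhibition, shifting, rest}`; the
parcellation is a TSV with columns `region_id`, `network_label`.

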