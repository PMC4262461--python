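# podsoc

Social-structure inference from photo-identification sighting records of
individually recognisable animals — built for the analysis chain used in
small-cetacean field studies (bottlenose dolphins and similar fission–fusion
societies), where the raw data are dated group sightings of photo-identified
individuals.

Given a long-format sighting table (one row per group sighting × individual,
with sex, age class, observed group size, number identified and habitat
covariates), the package runs the complete inference chain:

1. **Filtering** — daily de-duplication (first sighting per individual per
   day), removal of large poorly-identified groups (>8 animals with <80%
   identified), calves, and individuals seen fewer than 6 times; then the
   binary group-by-individual (GBI) matrix under the gambit of the group.
2. **Association** — the half-weight index for each dyad,
   `HWI = 2N / (N_A + N_B)`, where `N` counts joint sightings and `N_A`,
   `N_B` each animal's total sightings; per-individual and per-sex-pairing
   summaries; preferred (HWI ≥ 2 × mean) and avoided (HWI = 0) dyads.
3. **Permutation tests** — the within-day group-permutation null
   (checkerboard flips preserving group sizes and daily individual totals,
   sampled along one long flip chain): a high observed SD of HWIs indicates
   preferred/avoided companions, a high CV indicates long-term preferences.
   Plus a seeded Mantel test and a dyad-class chi-square.
4. **Network metrics** — strength (Σ HWI), weighted clustering coefficient,
   affinity, their permutation significance and group-bootstrap standard
   errors; social differentiation `S` (CV of the *true* association
   indices) by beta-binomial maximum likelihood with a jackknife SE.
5. **Community division** — average-linkage hierarchical clustering of the
   HWI matrix, cophenetic correlation (≥0.80 = adequate), and the
   dendrogram cut maximising Newman modularity `Q` (standard or
   gregariousness-controlled), with the `Q > 0.3` usefulness convention.
6. **Temporal stability** — the lagged association rate
   `g(τ) = P(still associated τ days later)`, its null rate under random
   mixing, and an eight-model exponential-decay family built from constant
   companions (CC), casual acquaintances (CA) and rapid disassociations
   (RD), fitted by binomial quasi-likelihood, ranked by QAIC and given
   delete-one-date-block jackknife errors. The selected three-component
   model is `g(τ) = a₂ + a₃·exp(−a₁·τ)`.
7. **Simulation** — a fission–fusion society generator with planted ground
   truth (social units, CC pairs, CA alliance decay, residency classes,
   trammel-net covariates) so every stage is verifiable by recovery tests.

## Worked example

```python
from podsoc import *
from podsoc.synthetic import SocietyConfig

society = generate_society(SocietyConfig(seed=11))   # ~34 animals, 8 summers
table = daily_dedup(simulate_sightings(society))
table, report = apply_inclusion_filters(table)
gbi = build_gbi(table)

am = hwi_matrix(gbi)
dyads = classify_dyads(am)
perm = permutation_test(gbi, n_permutations=1000,
                        flips_per_permutation=1000, seed=11)
sd = social_differentiation(am)
part = best_cut(am)
lar = LaggedAssociationModel(gbi).fit(seed=11)
```

This prints (via the objects' summaries), for the seed shown:

```
analysable individuals: 25, group sightings: 126
mean HWI: 0.163; preferred-association threshold: 0.326
preferred dyads: 33, avoided: 45 of 300
SD: observed 0.13262, permuted mean 0.11267, P(permuted >= observed) = 0.0010
CV: observed 0.81238, permuted mean 0.69365, P(permuted >= observed) = 0.0010
social differentiation S = 0.615 (SE 0.073); well differentiated: True
communities: 6 at cut similarity 0.155, Q = 0.131, cophenetic r = 0.853
best LAR model: RD+CC; a2=0.303
```

Reading: the observed SD and CV of association indices exceed essentially
every value in their permutation nulls, so this simulated population has
non-random, long-term preferred companions; `S = 0.615 > 0.5` marks a
well-differentiated society. With only ~126 group sightings the modularity
of the best dendrogram cut is low (`Q = 0.131 < 0.3`) — the division is
reported but flagged as not useful, exactly the behaviour expected of a
sparse photo-ID record — and the QAIC-best temporal model at this sampling
intensity keeps only constant companions plus rapid disassociation. The
permutation-test p-values use the add-one convention, so `0.0010` is the
smallest value attainable with 1000 permutations.

The same chain runs from the shell:

```sh
podsoc --seed 11 --outdir out report           # simulate + full pipeline
podsoc --config my_study.yaml --outdir out report   # your own CSV input
```

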