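# badgenet

Analysis pipeline linking **face-to-face interaction-network structure** in
the workplace to **depressive symptoms**, built for per-minute streams from
sociometric badges (name-tag wearables that detect mutual infrared contact
and body movement as accelerometer zero-cross counts) together with CES-D
questionnaire responses.

It is aimed at computational social scientists and occupational-health
researchers who want a tested, reusable implementation of this analysis —
and, because real badge datasets are rarely shareable, it ships a synthetic
badge-data generator with plantable effects so every stage can be validated
end-to-end without any data download.

## What it computes

**Preprocessing.** Per-minute dyadic detections are merged into interaction
*episodes*: two detection minutes of a dyad belong to the same episode iff
the empty interval between them is shorter than 5 minutes (an exact 5-minute
gap splits). Participants with under 5 h of device wear or under 1 h of
interaction time are excluded. Each organization's interaction network
weights every link by the average number of episodes per day,
w_ij = episodes(i,j) / days. Episodes are classified *active* (both members'
mean zero-cross ≥ threshold), *inactive* (both below) or *mixed*, and
sub-networks are rebuilt after removing one class.

**Network characteristics (11).** Individual scale: degree k_i and weight
s_i = Σ_j w_ij. Surrounding scale: the clustering coefficient
C_i = 2T_i / k_i(k_i−1) and its three weighted variants on *unnormalized*
weights —

- Barrat: (1/k_i(k_i−1)) Σ_{j,k} (w_ij+w_ik)/(2⟨w_i⟩) · a_ij a_jk a_ik,
  with ⟨w_i⟩ = s_i/k_i (scale-invariant; emphasizes direct tie strength),
- Onnela: (1/k_i(k_i−1)) Σ_{j,k} (w_ij w_jk w_ik)^{1/3},
- Zhang: Σ_{j,k} w_ij w_jk w_ik / Σ_{j≠k} w_ij w_ik (emphasizes indirect
  tie strength).

Organizational scale: closeness (n−1)/Σ_j d(j,i), betweenness
2/((n−1)(n−2)) Σ σ_jk(i)/σ_jk (unweighted and Dijkstra on distance 1/w),
and eigenvector centrality (binary and weighted adjacency), each computed
per connected component.

**Community structure.** Weighted modularity
Q = (1/2W) Σ_ij (w_ij − s_i s_j/2W) δ(c_i,c_j), maximized by a Louvain
implementation with seeded node-visit order, run as a randomized-order
ensemble (5000 runs by default); link weights are raised to the power 1/4
before detection only.

**Inference.** Pearson/Spearman correlations of all 11 characteristics with
the CES-D total (0–60; 16 negative items plus 4 reverse-keyed positive
items), Benjamini–Hochberg-adjusted across the 11 features per family;
within-organization means with 1000-sample bootstrap CIs; community- and
organization-scale permutation nulls that compare the Spearman correlation
over group means against size-matched random groups (add-one one-tailed
empirical p); an activity-threshold sweep of the clustering–CES-D
correlations; N-consecutive-day window subsampling; and per-item
correlations.

## Worked example

```python
import badgenet as bn

cfg = bn.SimConfig(seed=1)            # 449 persons, 10 organizations, 5 workdays
data = bn.simulate_study(cfg)         # simulate -> merge -> networks -> metrics -> CES-D
corr = bn.individual_correlations(data.features)
cols = ["feature", "pearson_r", "pearson_p_adj", "spearman_r", "spearman_p_adj"]
print(corr[cols].round(3).to_string(index=False))

nd = bn.organization_level_test(data.features, n_null=1000, seed=1)
print(f"\norganization-scale Spearman r = {nd.observed:.2f} "
      f"(one-tailed p = {nd.empirical_p_one_tailed:.3f})")
```

prints

```
        feature  pearson_r  pearson_p_adj  spearman_r  spearman_p_adj
         Degree      0.229          0.000       0.209           0.000
         Weight      0.042          0.410       0.028           0.611
     Clustering     -0.232          0.000      -0.209           0.000
Clustering w(B)     -0.238          0.000      -0.216           0.000
Clustering w(O)     -0.231          0.000      -0.203           0.000
Clustering w(Z)     -0.195          0.000      -0.185           0.000
      Closeness      0.224          0.000       0.205           0.000
    Betweenness      0.231          0.000       0.210           0.000
  Betweenness w      0.097          0.050       0.121           0.013
    Eigenvector      0.223          0.000       0.198           0.000
  Eigenvector w     -0.006          0.907      -0.017           0.713

organization-scale Spearman r = -0.25 (one-tailed p = 0.472)
```

The generator plants a negative effect of standardized Barrat clustering on
the latent CES-D score (default calibrated to a population correlation of
about −0.18), so the surrounding-scale clustering coefficients come out
negatively and significantly correlated with the depression score, while
Weight and the weighted centralities stay near zero. The positive Degree /
Closeness / Betweenness correlations are induced: in these networks hubs
have low clustering, so a clustering-linked outcome correlates positively
with centrality. The organization-scale test is null here because the
default generator plants no between-organization structure.

The same pipeline is scriptable from the shell (`badgenet full-run --seed 7
--out out/` plus stagewise `simulate`, `preprocess`, `metrics`,
`communities`, `correlate`, `group-null`, `sweep` subcommands reading and
writing plain CSV).

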