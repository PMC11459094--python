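# toporank

Degree-based topological indices, QSPR correlation weighting, and
VIKOR/SAW multi-criteria ranking for drug prioritization.

## The problem

When several drugs treat the same condition, choosing among them can be
framed as a multi-criteria decision: each drug is an *alternative*, and
numerical molecular descriptors are the *criteria*. `toporank` implements
that pipeline end to end for degree-based topological indices:

1. **Molecular graphs.** A molecule is a hydrogen-suppressed simple graph
   `H = (V, E)`: heavy atoms are vertices, every covalent bond one edge.
   The graph reduces to its *edge partition* — the count `|E_{a,b}|` of
   edges whose endpoint degrees are `{a, b}` — which is a sufficient
   statistic for all nine indices.
2. **Indices.** Each index is `Σ_{uv ∈ E} φ(d_u, d_v)` for a symmetric
   per-edge term φ: Randić `1/√(d_u d_v)`, atom-bond connectivity
   `√((d_u+d_v−2)/(d_u d_v))`, first/second Zagreb `d_u+d_v` / `d_u d_v`,
   sum-connectivity `1/√(d_u+d_v)`, forgotten `d_u²+d_v²`,
   geometric–arithmetic `2√(d_u d_v)/(d_u+d_v)`, harmonic `2/(d_u+d_v)`,
   and hyper-Zagreb `(d_u+d_v)²`.
3. **QSPR weighting.** Pearson correlations `r_i` between a
   physicochemical property (boiling point, enthalpy of vaporization) and
   each index become criterion weights by *ratio weighting*,
   `w_i = r_i / Σ_j r_j`; criteria with `w_i` above a threshold are
   *beneficial* (maximize), the rest *non-beneficial* (minimize).
4. **Ranking.** VIKOR computes, per alternative *j*, the group utility
   `S_j = Σ_i w_i (f_i⁺−f_ij)/(f_i⁺−f_i⁻)`, the individual regret
   `R_j = max_i` of the same terms, and the compromise index
   `Q_j = v(S_j−S⁺)/(S⁻−S⁺) + (1−v)(R_j−R⁺)/(R⁻−R⁺)` with `v = 0.5`;
   smaller Q is better. SAW (simple additive weighting) is provided as a
   configurable weighted-sum alternative.

The package bundles its motivating case study: a 16-drug lung-disorder
panel (bronchodilators, corticosteroids, leukotriene-pathway drugs) with
the 16×9 index matrix and the per-index correlations against boiling
point (BP) and enthalpy of vaporization (EV).

## Worked example

```python
from toporank import parse_smiles, edge_partition, compute_all

graph = parse_smiles("CNCC(O)c1ccc(O)c(O)c1")   # epinephrine
partition = edge_partition(graph)
print(dict(partition))
print({k.value: round(v, 6) for k, v in compute_all(partition).items()})
```

prints

```
{(1, 2): 1, (1, 3): 3, (2, 2): 2, (2, 3): 5, (3, 3): 2}
{'RA': 6.147066, 'ABC': 9.439677, 'M1': 60.0, 'M2': 67.0, 'SCI': 6.129915,
 'F': 152.0, 'GA': 12.439865, 'H': 5.833333, 'HM': 286.0}
```

Epinephrine's 13 bonds fall into five degree-pair classes; e.g. `M1 = 60`
sums the degree pairs and `M2 = 67` their products, and the hyper-Zagreb
identity `HM = F + 2·M2` (286 = 152 + 134) holds by construction.

Running the full case study:

```python
from toporank import lung_disorder_case_study

report = lung_disorder_case_study()
print(report.bp.table.loc[["Salmeterol", "Epinephrine"]].round(6))
print(report.n_concordant)
```

```
                    S         R         Q  rank
Salmeterol   0.361888  0.055945  0.000239     1
Epinephrine  0.638244  0.135220  1.000000    16
8
```

Salmeterol is the compromise-best drug under both properties; epinephrine
— the smallest molecule, at the unfavourable extreme of every criterion —
ranks last, and 8 of the 16 drugs get identical BP and EV ranks.
`docs/methods.md` explains an important subtlety of how the bundled
case-study weights are assigned to the matrix columns.

More narrative walk-throughs live in `examples/` (one script per
capability); the same functionality is exposed on the command line as
`topo-rank indices | qspr | rank | synth | reproduce`.

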