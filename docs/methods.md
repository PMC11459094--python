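# Methods

## Molecular graphs and edge partitions

Molecules are hydrogen-suppressed simple graphs: heavy atoms as vertices,
every covalent bond — single, double, triple or aromatic — as exactly one
edge. This convention is what makes the bundled epinephrine reference
values reconcile: its 13 heavy atoms and 13 bonds give the edge partition
`{(1,2):1, (1,3):3, (2,2):2, (2,3):5, (3,3):2}`. Stereochemistry,
charges, isotopes and bond orders are ignored throughout; SMILES input
(via RDKit) is reduced to plain connectivity.

Graphs must be connected (a single molecule). Disconnected input is an
error by default; `on_disconnected="largest"` keeps the largest component
with a warning for users feeding salt/mixture records. Vertex identifiers
are opaque; nothing downstream depends on atom ordering, and all nine
indices depend on the graph only through the degree-pair edge partition.

## Index evaluation

Every index is a count-weighted sum of a symmetric per-edge term over the
partition. All arithmetic is double precision with no intermediate
rounding. Degenerate cases: the ABC term of a (1,1) edge is `sqrt(0) = 0`
(defined, not an error); an empty partition sums to 0. Two identities are
used as internal cross-checks rather than assumptions: `HM = F + 2·M2`
and the edge/vertex forms of the first Zagreb index
(`Σ_E (d_u+d_v) = Σ_V d_v²`).

## QSPR stage

`pearson_r` is the sample product-moment correlation (n ≥ 3, non-constant
vectors). `regression_se` is the *standard error of estimate* of the
simple least-squares fit of property on index, `sqrt(SSE/(n−2))`; the
slope-uncertainty alternative was considered and rejected because the
estimate form is the conventional regression summary for QSPR tables.
The bundled case-study correlations are shipped as data: the underlying
raw boiling-point and enthalpy-of-vaporization measurements are not
distributed, so the package uses the correlation vectors as inputs and
makes no attempt to re-derive them.

Ratio weighting `w_i = r_i/Σr_j` requires every `r_i > 0` and rejects
non-positive correlations explicitly rather than taking absolute values —
a negative correlation would need a sign-aware orientation decision the
scheme does not encode.

### The beneficial threshold

Criteria are beneficial when `w_i >` threshold. The default threshold is
**0.11**. A round 0.10 looks more natural, but the bundled case study's
published S/R values are arithmetically consistent only with the M1
column (weight 0.1022 under BP, 0.1075 under EV) being *non*-beneficial,
which any threshold in (0.1075, 0.1171) reproduces; 0.11 is the midpoint
choice. The threshold is a parameter, and per-criterion orientation
overrides are exposed for users who want a different split.

### Column-weight assignment in the bundled case study

While validating the bundled reference rankings we found that the
published S/R/Q values are **not** reproducible by matching each
correlation to the index of the same name. They are reproduced exactly
(to the printed precision) when the correlation vector, in its original
tabulation order (RA, ABC, M1, M2, SCI, F, GA, H, HM), is assigned
*positionally* onto the decision-matrix column order (ABC, RA, M1, M2,
HM, H, SCI, F, GA) — so, for example, the H column carries the F
correlation 0.693 and the HM column carries the SCI correlation 0.443.
Name matching and positional assignment coincide on the two extreme drugs
(epinephrine, the column-wise minimum, and ciclesonide, the column-wise
maximum), which is why the discrepancy is invisible on those rows; we
confirmed the positional assignment on multiple mid-field drugs under
both properties.

The package therefore bundles the positional vectors
(`bp_ranking_correlations` / `ev_ranking_correlations`) as part of the
case-study data and uses them by default in `lung_disorder_case_study`,
so that the published tables are recovered cell for cell. The
name-matched vectors (`bp_correlations` / `ev_correlations`) remain the
default for every generic API, and
`lung_disorder_case_study(weight_assignment="by_name")` runs the case
study under name matching for comparison. Under either assignment the
effective beneficial weight set is the same five values
{0.615, 0.678, 0.693, 0.657, 0.628}/5.125 for BP (analogously for EV);
only which column carries which weight differs.

## VIKOR

Ideal points: beneficial criteria take `f⁺ = max`, `f⁻ = min` over
alternatives, non-beneficial the reverse. `S`, `R`, `Q` follow the
standard formulas with `S⁺ = min S`, `S⁻ = max S` (and likewise for R);
`v` defaults to 0.5 and is exposed. Numerical edge cases:

- a criterion constant across alternatives would give 0/0; it is dropped
  with a warning by default (configurable to a hard error). Remaining
  weights are *not* renormalized — the dropped criterion simply
  contributes nothing, which keeps the other terms comparable across
  configurations.
- if all alternatives share the same S (or R), Q is undefined and a
  `DegenerateSpreadError` is raised.
- ranks are competition-style (1, 2, 2, 4) over ascending Q (and,
  reported alongside, over S and R). The reference panel has no ties.

The classical compromise-set conditions (acceptable advantage
`Q(2nd) − Q(1st) ≥ 1/(m−1)` and acceptable stability) are available as an
informational report (`VikorResult.compromise_report()`) but never alter
the ranks, which are by Q alone.

Properties verified in the test suite: `Q ∈ [0, 1]`; the alternative
attaining both `S⁻` and `R⁻` has `Q = 1`; `v = 1`/`v = 0` collapse the Q
ranking onto the S/R rankings; per-criterion positive affine transforms
leave S, R, Q unchanged; `R_j ≤ max_i w_i` and `S_j ∈ [0, 1]` when
weights sum to 1; and a brute-force direct-summation oracle agrees to
1e-12 on random matrices.

## SAW

Defaults: linear-ratio normalization (`f/f_max` for beneficial,
`f_min/f` for non-beneficial — zero denominators raise) with descending
rank direction (highest total = rank 1). Min–max normalization and
ascending ranking are options because conventions genuinely vary in
practice. The bundled case study's published SAW scores could not be
traced to any normalization/direction combination of the stated
procedure, so no SAW reference values are asserted anywhere; SAW is
validated on self-consistent examples (additivity, orientation
inversion, bounds) instead.

## Synthetic data

`random_molecular_graph` builds a random spanning tree — each new vertex
attaches uniformly to a vertex with spare capacity — plus a few random
ring-closing edges, under a degree cap of 4 (the common heavy-atom
valence). This emulates the size and degree range of small drug-like
molecules (defaults: 13 atoms, matching the smallest drug in the bundled
panel; 16 molecules per panel). It does **not** emulate real chemistry:
no valence rules per element, no realistic ring-size statistics, no
aromaticity. Passing tests on synthetic panels therefore demonstrate the
*pipeline arithmetic* (partition totals, index identities, weight
recovery, ranking invariants) — not chemical validity of any prediction.

`correlated_property` constructs a property vector whose sample Pearson
correlation with a descriptor is *exactly* the target: noise is projected
orthogonal to the descriptor (and the constant), both parts are
standardized and blended as `r·z_x + sqrt(1−r²)·z_⊥`. Exactness makes the
correlation → weight → ranking round trip deterministic (asserted at
1e-10); a `noise_sd` option degrades it deliberately for power-style
experiments. One integer seed drives a single `numpy` generator for all
randomness.

## Problem sizes

The default test and reproduction runs use the bundled 16×9 panel, the
13-edge epinephrine partition, random graphs of 13–30 atoms (1000 seeds
in the invariant sweeps), and 4×3 random matrices for the VIKOR oracle —
all chosen to exercise every code path at the scale of the case study
while keeping the whole suite near-instant.

## Known limitations

- Only degree-based indices; distance-, eccentricity- and
  neighborhood-sum-based descriptors are out of scope.
- Ratio weighting cannot express negatively correlated criteria.
- The QSPR stage is univariate simple regression; no multivariate models
  or significance testing.
- Reproduction of the case-study correlation tables themselves is not
  possible without the raw property measurements, which are not
  distributed.
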