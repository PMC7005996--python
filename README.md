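# coexland

Gene-pair coexpression landscapes from stochastic two-gene regulatory
network models, a PCA "shape-space" for classifying those landscapes,
and projection of single-cell RNA-seq gene-pair distributions into that
space to follow — and cluster — how gene-gene relationships evolve
across developmental stages.

## Who this is for

Systems biologists analyzing single-cell transcriptomics who want a
mechanistic, noise-aware reading of pairwise gene relationships: not
just "are these genes correlated", but "what stochastic regulatory
interaction could produce this bivariate count distribution, and how
does it change over development" — e.g. detecting multilineage priming
(transient coexpression of lineage-antagonistic genes followed by
antagonistic expression).

## The model

Two genes X and Y are modeled as a discrete stochastic reaction
network. Each gene's promoter carries two binding sites — one for its
own transcription-factor dimer, one for the other gene's — giving four
promoter states (nothing bound, self bound, other bound, both bound).
Each state maps to a transcription level g_hi or g_lo; the 16
symmetric level assignments form the "Two-Gene Flex" family of
regulatory logics, which contains the mutual-inhibition/
self-activation (MISA) motif {g_lo, g_hi, g_lo, g_lo} as the member
where self-binding activates and cross-binding silences. The reactions
are

- synthesis: X_ij → X_ij + x at rate g_ij (zero when the count sits at
  the cap M − 1: reflecting boundary),
- degradation: x → ∅ at rate k·n_x,
- promoter-state changes: binding at rate h·n²/2 (TFs bind as
  homodimers; protein is proxied by mRNA count with the proportionality
  folded into h) and unbinding at rate f.

The joint state (n_x, n_y, s_x, s_y) has N = M × M × 4 × 4 states
(7,056 for the default M = 21). Its chemical master equation
dp/dt = K p is assembled as a sparse generator and solved exactly for
the stationary distribution π; summing π over promoter states yields
the M × M **coexpression landscape** π(n_x, n_y), and
φ = −ln(max(π, 10⁻⁶)) is the **quasipotential landscape** whose
valleys are stable cell states.

Sweeping kinetic parameters (table below) and logic variants produces
a landscape library; a mean-centered PCA over the library — one model
per replicate, one grid cell per feature — defines the shape-space.
Empirical landscapes are estimated from annotated per-cell count
tables by binning a gene pair's counts (truncated at M − 1) per
developmental stage, log-transformed with the same 10⁻⁶ pseudo-
probability, and projected into the model-trained space. The
stage-ordered coordinates form an m-stages × n-components trajectory
matrix; trajectories are compared by the Frobenius distance
‖A − B‖_F = √Σ_ij (A_ij − B_ij)² and clustered hierarchically.

Default kinetic ranges (rates per hour; h in hr⁻¹·mRNA⁻²):

| parameter | value |
|---|---|
| g_hi | 0.8 – 1.4 |
| g_lo | 0.001 |
| k | 0.2 |
| f (fast / slow) | 10 – 10⁵ / 10⁻⁶ – 10 |
| h (fast / slow) | 10 – 500 / 10⁻⁶ – 10 |

## Worked example

```python
import coexland as cx

# a MISA model in the fast promoter regime
params = cx.KineticParameters(g_hi_x=1.4, g_hi_y=1.4, h_a=100.0,
                              f_a=1000.0, h_r=100.0, f_r=100.0,
                              regime="fast")
model = cx.make_misa_model(params, M=21)
land = cx.compute_landscape(model)            # 21 x 21 probability grid
print(cx.metric_report(land))

# shape-space from a small fast-regime MISA quasipotential sweep
cfg = cx.default_misa_config(g_hi_values=(0.8, 1.4),
                             h_a_values=(10., 500.), h_r_values=(10., 500.),
                             f_a_values=(10., 1e5), f_r_values=(10., 1e5))
lib = cx.compute_landscape_library(cx.generate_misa_grid(cfg),
                                   cfg.representation)
space = cx.fit_shape_space(lib, n_components=3)
print(space.explained_variance_ratio)

# synthetic cells sampled from the model landscape, re-projected
table = cx.simulate_cells({8: land, 10: land}, 20000, seed=1)
spec = cx.LineageSpec("gene_x", "gene_y",
                      {8: {"synthetic"}, 10: {"synthetic"}})
traj = cx.build_trajectory(table, spec, space)
print(traj.coords.round(2))
```

This prints (numbers from an actual run):

```
{'shannon_entropy': 0.0917..., 'mutual_information': 2.26e-06,
 'pearson_correlation': -0.00137, 'coexpression_index': 0.00302}
[0.67028972 0.1819847  0.07410522]
[[-12.95  -1.71  -1.08]
 [-13.39  -1.47   0.08]]
```

Reading it: with strong fast cross-repression this MISA model sits
almost entirely in the lo/lo state (near-zero entropy and coexpression
index). The 64-model training sweep concentrates 67% of landscape
covariance in an overall-expression component and 18% in a
coexpression-vs-antagonism component. The two synthetic "stages"
sampled from one fixed landscape project to nearly identical
coordinates — a flat trajectory, as they should.

The same steps are scriptable from the shell: `coexland landscape`,
`coexland sweep`, `coexland metrics`, `coexland shapespace fit|project`,
`coexland trajectories`, `coexland cluster`,
`coexland simulate-cells --seed`, `coexland ssa --seed`.

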