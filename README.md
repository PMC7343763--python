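# ddlswitch

Stochastic analysis of a *double-deck loop* (DDL) gene switch: a two-state
gene (off/on) coupled to the copy number `m` of a repressor protein. The
repressor is synthesized at rate `a*k3` and degraded at rate `m*k4`; the
gene switches off→on at rate `kon + a*k1` and on→off at rate
`koff + m*k2`, where `a` is the strength of an upstream activating
signal. All rates are normalized by `k4`, so time is measured in `1/k4`.

The package provides:

- **`model_core`** — parameters, the `(gene, m)` lattice, and the sparse
  Markov generator (reflecting truncation chosen from the Poisson tail).
- **`analytic`** — the exact closed-form stationary distribution
  `P0(m), P1(m)` in terms of Kummer's confluent hypergeometric function,
  its normalization constant, and the exact Poisson(`a*k3`) marginal of `m`.
- **`cme_numeric`** — an independent numerical oracle: stationary solution
  via the generator's null space and transient integration of the master
  equation with a stiff (BDF) scheme.
- **`ssa`** — exact Gillespie (direct-method) simulation on the unbounded
  lattice and a dwell-time-weighted stationary estimator with an explicit
  overflow bin.
- **`thermo`** — entropy production at the non-equilibrium steady state:
  a generic transition sum, a model-specific closed form, and the
  decomposition into off-strand moves (EP1), on-strand moves (EP2) and
  gene switching (EP3), with `EPm = EP1 + EP2` the synthesis–degradation
  share.
- **`phase`** — Mode I/II classification (off- vs on-mass dominance), the
  peak-height dominance factor δ, `(a, k3)` phase-plane scans, and
  bisection location of the mode boundary.
- **`cli_io`** — TOML/JSON configs, TSV results with a JSON metadata
  header, and the `ddlswitch` command-line interface.

## Command line

Configs are flat TOML or JSON files with keys `k1 k2 k3 k4 kon koff a`
(raw rates; `k4` defaults to 1, i.e. already normalized) plus optional run
options (`method`, `tail_tol`, `seed`, `n_traj`, `t_end`, `burn_in`, ...).
An example lives at `examples/reference.toml`.

```sh
ddlswitch stationary --config examples/reference.toml --out dist.tsv
ddlswitch stationary --config examples/reference.toml --method cme
ddlswitch simulate   --config examples/reference.toml --seed 7 --n-traj 20 --t-end 500
ddlswitch ep         --config examples/reference.toml --decompose
ddlswitch phase      --config examples/reference.toml --a-grid 0.5:4:8 --k3-grid 1:5:9 --ep
ddlswitch boundary   --config examples/reference.toml --a 1 --a 2 --bracket 0.5 5
```

Every output is a TSV table preceded by one `# {...}` JSON metadata line
(parameters, method, tolerances, seed, version), so results are
reproducible from their own header. Outputs carry no timestamps; repeated
runs with the same seed are byte-identical.

## Reference parameters

The published study this package reimplements gives its rate constants
only in supplementary material that is not redistributed here. The
packaged set (`ddlswitch.reference_params()`: `k1 = 2.1`, `k2 = 1`,
`kon = koff = 10`, `k4 = 1`) is a documented **reconstruction** chosen to
reproduce the published qualitative structure — Mode I at `k3 = 5`,
Mode II at `k3 = 1.5`, and a nearly horizontal mode boundary at
`k3 ≈ k1/k2 = 2.1`. All quantitative checks against it are
reconstruction-level, not comparisons to the original table.

## Entropy-production conventions

`thermo.ep_decomposition` supports two conventions. The default
`"flux"` convention uses the standard per-pair NESS terms
`J·ln(P_i q_ij / P_j q_ji)`; each class is non-negative and the three
classes sum to the total entropy production at stationarity. The
`"rate"` convention puts only the rate ratio in the logarithm; its
classes sum to the same total, but because the `m`-marginal is exactly
Poisson the strand terms cancel bond-by-bond, making `EPm` identically
zero — so only the flux convention yields a meaningful
synthesis–degradation share (and it is the one behind target t2).

## Known limitations

On the packaged reconstruction, two published qualitative trends are not
reproducible, and the corresponding acceptance tests are deliberately left
failing rather than weakened:

- δ in Mode II is not monotonically decreasing in `a`
  (`test_criterion6_delta_decreasing_in_mode_ii`): with `kon = koff`
  (forced by the near-horizontal boundary) δ starts at 0 and must first
  rise; it decreases only for slow basal switching, which is incompatible
  with a flat boundary.
- Total EP cannot rise with `a` in Mode I while falling in Mode II over
  one common `a` grid (`test_criterion6_ep_trends_by_mode`): EP(a) is
  unimodal and the Mode-I peak precedes the Mode-II peak throughout the
  reconstruction family.

Both would require different (unpublished) parameter sets per figure.
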