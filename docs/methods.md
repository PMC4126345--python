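# Methods

## Model

Nucleated linear self-assembly of enzyme tetramers coupled to two-ligand
exchange. States of a tetramer: free (ligand-free, UTP-bound, or
CTP-bound) or polymerized (CTP-bound or empty). All species are ideal
and the solution is well mixed; ligands are clamped (free
concentrations, not depleted by binding), reflecting the mM-ligand /
μM-enzyme excess of the assays the model describes. Polymerized enzyme
has exactly zero activity; the dimer–tetramer equilibrium upstream of
assembly is not modeled (assays pre-form tetramers), so the polymerizing
unit is the tetramer and `E_tot` counts tetramers.

Reference species: the ligand-free free tetramer, concentration `b`
(μM). Binding polynomials

- free, competitive (default): `P_f = 1 + U/K_uf + C/K_cf` — UTP and
  CTP contend for overlapping sites;
- free, noncompetitive: `P_f = (1 + U/K_uf)(1 + C/K_cf)`;
- polymerized subunit: `P_p = 1 + C/K_cp` — the filament binds CTP only;
  its substrate site is occluded.

Filament statistical weights: `c_n = K_e·σ·zⁿ` for `n ≥ 2`, with
`z = b·P_p/K_e` and `σ = exp(−E_nuc)` applied once per filament
regardless of length. At `E_nuc = 0` this is the standard isodesmic
ladder (`c_{n+1}/c_n = z`). The minimal filament is two tetramers.
Closed forms: `M_poly = K_e σ z²(2−z)/(1−z)²`,
`N_fil = K_e σ z²/(1−z)`, `⟨n⟩ = (2−z)/(1−z)`.

Mass balance `b·P_f + M_poly(b) = E_tot` is strictly increasing in `b`
on `[0, K_e/P_p)`, so the equilibrium is unique. Active fraction
`a = b·(U/K_uf)/E_tot` (the free, UTP-bound, CTP-free species is the
catalytically competent one in both mechanisms); apparent specific
activity `kcat_obs = k_max·a`.

Units package-wide: concentrations μM, time s, energies k_B·T
(temperature never appears explicitly).

## Numerics

- Root-finding for `b`: Brent's method on
  `[0, min(E_tot/P_f, (K_e/P_p)(1−ε))]`, `ε = 1e−12`, relative
  tolerance 1e−12, 200-iteration budget. Failures raise a solver error
  carrying the bracket and residuals.
- Degenerate regimes: if the polymer term underflows and the upper
  bracket residual rounds an ulp below zero, the root is taken at the
  bracket edge (polymer negligible). If `σ` is so small that the
  mass-balance knee in `z` is narrower than machine epsilon
  (`E_nuc ≳ 70` at μM scales) while `E_tot` exceeds the critical
  concentration `K_e·P_f/P_p`, the free pool is pinned analytically at
  `b = K_e/P_p` and `1−z = √(K_e σ/M_poly)` is computed in closed form
  so filament statistics remain finite.
- IC50: linear interpolation between the two grid points flanking half
  of the zero-dose response, never a sigmoidal fit — this mirrors how
  the anchoring measurements were themselves reduced. Exact grid hits
  are returned as-is; zero or multiple crossings raise typed errors
  (the ambiguity error reports every crossing).
- `[CtpS]_0.5`: the maximum of `kcat_obs` over enzyme is located on a
  400-point log grid on (1e−4, 100] μM (for a polymerizing enzyme it
  sits at the dilute end), then the half-crossing is solved by Brent to
  1e−10.
- Response coefficient `R = C_10/C_90`: quantiles of `a(C)/a(0)` by
  dense log-grid bracketing plus Brent refinement at relative 1e−12, so
  the ratio is accurate to ~1e−9 and the Michaelian value 81 is
  reproduced to 1e−6.

## Calibration of the default parameters

`calibrate_defaults()` pins `E_nuc = 9` (the filament-length-based
estimate) and `K_uf = 600 μM`, and solves the remaining constants
against printed wild-type anchors, each by bracketed 1-D root-finding to
relative 1e−8:

1. `K_e` from `[CtpS]_0.5 = 3.3 μM` at zero CTP. At `C = 0` this
   anchor involves neither CTP constant, so `K_e` separates cleanly.
2. `(K_cf, K_cp)` by nested root-finding: the inner loop re-solves
   `K_cf` so the model IC50 at 0.2 μM enzyme equals 360 μM; the outer
   loop moves `K_cp` until `[CtpS]_0.5` at 800 μM CTP equals 1.4 μM.
   Three anchors, three constants; the zero-CTP anchor alone cannot pin
   `K_cp` (it cancels at `C = 0`), which is why the 800 μM midpoint is
   used as the third anchor.
3. `k_max = 13.4 s⁻¹` in closed form, so the dilute-limit specific
   activity at assay UTP equals the observed maximum 6.7 s⁻¹ (UTP is
   half-saturating at `U = K_uf`).

The result (`K_cf ≈ 180 μM`, `K_cp ≈ 122 μM`, `K_e ≈ 0.832 μM`) is
deterministic, cached, and shipped in `data/default_params.toml`; a test
asserts the shipped file matches recomputation.

Why `K_uf = 600 μM`: the three anchors are jointly consistent with the
linkage direction `K_cp < K_cf` only if UTP occupancy under assay
conditions is moderate. In the competitive mechanism the dilute-enzyme
IC50 fixes `K_cf·(1 + U/K_uf) = 360 μM` while the midpoint shift
3.3 → 1.4 μM fixes `K_cp ≈ 122 μM` almost independently of `K_uf`, so
`U/K_uf ≲ 2` is required; UTP binding with substantial positive
cooperativity in the real enzyme makes a single-site effective constant
of this size a reasonable coarse-graining. Half-occupancy at the
standard 600 μM assay UTP is the documented choice.

## Where the ultrasensitivity lives

Above the zero-CTP assembly onset the free pool is buffered at
`b = K_e/P_p`, which makes `a(C)/a(0)` Michaelian again (`R → 81` from
below). Genuine sharpening occurs in the enzyme window between the
high-CTP and zero-CTP critical concentrations — about 0.55–1.6 μM at
the calibrated defaults with 600 μM UTP — where raising CTP switches
polymerization on. There `R` drops to ≈ 39–60 depending on conditions,
and `R` decreases monotonically with `E_nuc` (at fixed zero-CTP
midpoint, re-solving `K_e` per barrier) until it saturates near
`E_nuc ≈ 9`.

## Kinetic closure

The assay simulator integrates `dU/dt = −v`, `dC/dt = +v` (1:1
stoichiometry; ATP and glutamine saturating and untracked) and
`dM/dt = (M_eq(U, C) − M)/τ_poly`: polymerization is a single-timescale
relaxation to the equilibrium manifold, with `τ_poly = 2 s` by default
(observed disassembly/reassembly completes within seconds). The
synthesis rate re-partitions the instantaneous free pool
`f = E_tot − M` across ligation states with `P_f`. Integration uses
LSODA at rtol 1e−8 with events (substrate additions, catalytic
inactivation as a `k_max` jump) applied as state jumps between
segments. Proxies: scattering = `M·⟨n⟩_eq` (Rayleigh-like second-moment
weighting; a pure-mass proxy by flag), transmittance = `exp(−C/500 μM)`;
both in arbitrary units. This closure is phenomenological — no rate law
was measured — and is validated only by qualitative properties
(conservation, quasi-equilibrium limit at small `τ_poly`, the
dip/spike/recovery response to substrate addition), never by matching
recorded traces.

## Synthetic data

Rate observables (specific activity, velocity) carry multiplicative
lognormal noise, `y_obs = y_true·exp(η)`, `η ~ N(0, cv)` — positive and
heteroscedastic, as enzymological rate data are; pellet fractions carry
additive Gaussian noise truncated to [0, 1]. The sources report
standard-error bars but no noise model, so these are stated stand-ins.
Generators are pure functions of (params, design, noise, seed) with the
RNG algorithm (PCG64) recorded in the metadata; default designs mirror
the assays (enzyme 0.05–10 μM log-spaced; CTP 0 plus 0.1 μM–10 mM).
What the generators do not emulate: instrument drift, photobleaching,
cross-instrument scaling, or UTP cooperativity — so passing recovery
tests demonstrate correctness of the inference machinery under the
stated noise model, not robustness to real-instrument artifacts.

## Parameter fitting and the recovery study

`fit_parameters` minimizes Σ(log(y_obs+ε) − log(y_model+ε))²,
`ε = 1e−6` of each dataset's observed median (responses span decades;
the log loss weights them evenly and the ε-floor avoids −∞ at zero
response). Dissociation constants and `k_max` are fitted in log10 space
within [1e−4, 1e6] μM; `E_nuc` linearly within [0, 30]. Multi-start
(default 8) jitters the constants log-uniformly ±1 decade around the
initial value (`E_nuc`: uniform ±3, clipped); the best local optimum
wins, so added restarts never increase the loss. A finite-difference
sensitivity check warns when a free parameter moves no supplied dataset
(e.g. `K_cf` against a zero-CTP titration alone).

Identifiability shapes the recovery study. Equilibrium observables are
nearly independent of `E_nuc` except near an assembly onset: below
onset the (tiny) polymer mass is proportional to `σ`; above onset the
free pool correction is only `√(K_e σ/M)`. Measured sensitivity
`∂log y/∂E_nuc` peaks at ~0.018 per k_B·T and is concentrated in the
0.55–1.6 μM switchable window. The study design is therefore sized by
this sensitivity analysis: a 12-point enzyme titration, inhibition
curves at 0.2 μM (pins `K_cf`) and 4 μM (pins `K_cp`), and a series of
inhibition curves at 14 enzyme concentrations across the window
(30-point CTP grids) — 458 observations per replicate at 5% CV. With
`{E_nuc, K_cf, K_cp}` free (`K_uf`, `K_e`, `k_max` held, since `K_e`
and `σ` are confounded through a single onset), 20 seeded replicates
recover `E_nuc` within ±1 k_B·T and both CTP constants within ±25%.
Sparser designs — e.g. one titration plus one inhibition curve — leave
`E_nuc` with a standard error of several k_B·T and admit a spurious
optimum at the `E_nuc` upper bound; the sensitivity-sized design removes
both failure modes.

## Known limitations

- Single effective UTP site; the real enzyme binds UTP cooperatively.
- No GTP allosteric site, ammonia-channel conformational detail, or
  dimer–tetramer step; structure enters only as "polymer ⇒ inactive".
- Ligand clamping breaks down if enzyme and ligand concentrations are
  comparable.
- The kinetic module's relaxation closure has no microscopic
  nucleation/elongation rates; `τ_poly` is a phenomenological constant.
- Fits report point estimates only (no bootstrap or posterior).
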