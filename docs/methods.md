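# Methods

## Model

`mirlung` simulates early non-small-cell lung cancer (NSCLC) driven by three
over-expressed microRNAs: miR-21 and miR-205 (pooled into one variable pair
`m1`/`m1i`) and miR-155 (`m2`/`m2i`).  Each miR exists in an exosomal pool
(`m1`, `m2`, shed by cancer cells inside exosomes `E_C` and released on
contact with cells) and a cellular pool (`m1i`, `m2i`, produced by the cancer
cells directly).  All concentrations are mass densities in g/cm³; time is in
days.

Inside cancer cells a six-protein network runs (all productions and
degradations scaled by `C/C_0`, so signaling is proportional to the local
cancer-cell density):

- **E** (EGF–EGFR): produced at `lam_E/(1 + M/K_ME)` — negative feedback from
  ERK, represented by the MAPK variable; degrades at `d_E`.
- **M** (MAPK pathway): activated by E, resisted by the inhibitor T:
  `lam_M·E/(1 + T/K_TM)`.
- **A** (AKT pathway): activated by E through PI3K (quasi-steady-state,
  folded into `lam_A`), inhibited by PTEN (P) and T, enhanced by the Ras
  branch: `lam_A·E/[(1+P/K_PA)(1+T/K_TA)]·(1 + lam_MA·M/(K_MA+M))`.
- **T** (tyrosine-kinase inhibitor): production blocked by miR-21, which is
  half of the pooled m1 signal: `lam_T/(1 + ½(m1+m1i)/K_mT)`.
- **P** (PTEN): blocked by the full miR-21/205 pool:
  `lam_P/(1 + (m1+m1i)/K_mP)`.
- **Ap** (Apaf-1–caspase-9 apoptosome): blocked by miR-155:
  `lam_Ap/(1 + (m2+m2i)/K_m2)`.

Cancer cells grow logistically at a rate driven by both pathways,
`(lam_C1·M/(K_M+M) + lam_C2·A/(K_A+A))·C·(1 − (C+εN)/C_M)`, and die by
apoptosome-mediated damage death `d_D·C·Ap/(K_Ap+Ap)` plus natural death
`d_C·C`.

Two phases are modelled separately:

- **Invasion** (`mirlung.invasion`): a planar tumor front on x ∈ [0, 2] cm.
  Transported species diffuse; cancer cells additionally migrate down their
  own density gradient through the conservative nonlinear flux
  `χ·C·∂C/∂x` (directed migration, χ ∈ [3·10⁻⁴, 3·10⁻²] cm⁵ g⁻¹ day⁻¹).
  Boundary: Dirichlet steady-state values at x = 0 (the established tumor
  bulk: `E_C0`, `m_10`, `m_20`, `C_0`, and `γ·m_10`, `γ·m_20` for the
  cellular pools), no-flux at x = 2; zero initial conditions.
- **Proliferation** (`mirlung.proliferation`): a radially symmetric sphere of
  radius R(t), inside which the total cell density is constrained,
  C + N = θ = 0.6 g/cm³ (N = normal cells).  The constraint generates a
  radial velocity `u(r) = (1/θr²)∫₀ʳ ξ²·(net cell production) dξ`, and the
  free boundary moves with the cells, dR/dt = u(R).  Normal cells grow
  logistically at `lam_N` and die at `d_DN·N·Ap/(K_Ap+Ap) + d_N·N`.

An instructive emergent feature: in the invasion phase the advancing front is
*gated by the exosomal-miR cloud*.  Ahead of the diffusing miR profile, the
inhibitors T, P and the apoptosome rise toward their uninhibited levels
(28.5–56× the steady state) and net growth is negative; the front can only
advance into tissue that the miRs have pre-conditioned.  This is why anti-miR
treatment slows invasion far more than its direct effect on growth rates
would suggest.

## Parameters

All rates derive from literature constants by exact closed-form inversion of
the steady-state conditions (`mirlung.params`):

- degradations `d_X = ln 2 / t_half`;
- unit conversions 1 nM of an m-kDa species = m·10⁻⁹ g/cm³, and copy numbers
  via Avogadro's number;
- productions by setting each equation's RHS to zero at the tabulated steady
  state with the half-saturation convention K_X = X₀ (miR half-saturations
  `m_X0/5`), e.g. `lam_T = 28.5·d_T·T_0`, `lam_Ap = 56·d_Ap·Ap_0`;
- cell rates from `lam_C = 0.46 day⁻¹`: `lam_C1 = (4/3)lam_C`,
  `lam_C2 = (2/3)lam_C`, `d_D = 0.9·lam_C`, `d_C = 0.05·lam_C`.

The working defaults keep full precision; `data/printed_tables.yaml` is the
4-significant-figure printed record, and `validate()` checks every derived
identity to relative 10⁻³ (absorbing that rounding).  Points where the
source record is internally inconsistent, and the package's resolutions:

- **K_ME**: the tabulated value (3.936·10⁻⁵, the ERK concentration)
  contradicts the derivation `lam_E = 2·d_E·E_0`, which requires
  K_ME = M₀ = 8.4·10⁻⁶.  The package uses M₀; otherwise the steady state
  would not annihilate the E equation.
- **lam_N, d_N**: tabulated (0.092, 0.023) vs text-derived
  (0.8·lam_C = 0.368, 1.1·d_C = 0.0253).  Both are available via
  `default_parameter_set(..., normal_cell_rates="table"|"derived")`.  A local
  fixed-point analysis of the incompressible C/N competition shows only the
  derived variant admits a coexistence plateau near C = 0.46, N = 0.14
  g/cm³; with the tabulated variant normal cells die out (N → 0, C → 0.6).
  The proliferation workflows therefore default to the derived variant; both
  are exercised in the test suite.
- **lam_m1i, lam_m2i** (cellular miR production) are never tabulated; they
  are closed from the steady-state convention `m1i₀ = γ·m_10` with γ = 10:
  `lam_m1i = d_m1·γ·m_10/C_0 ≈ 3.88·10⁻¹² day⁻¹`.
- **χ for invasion** defaults to 3·10⁻², the value used by all the
  comparative invasion results.

**Treatment convention.**  An anti-miR drug antagonizes its target miR in
every compartment, so the builtin `anti_m1`/`anti_m2` scenarios scale the
production of *both* pools (`lam_m1` and `lam_m1i`) by the same factor; the
sensitivity driver treats a sampled miR production rate the same way.
Scaling only the exosomal rate would change the pooled inhibition signal
`m1 + m1i` by under 5% (the cellular pool is γ = 10 times larger) and no
treatment effect of the published size could arise.  The x = 0 boundary
values of the invasion model stay at the untreated steady state in all
scenarios: they represent the long-established tumor bulk.

## Numerics

**Invasion** (`dx = 0.01` cm, `dt = 10⁻³` day by default): second-order
central differences; implicit linear diffusion (banded solves), explicit
reactions and χ-flux (flux form at half-nodes, arithmetic-mean coefficient).
`dt` is halved automatically (up to 6 times) if a step produces negatives
beyond round-off; round-off negatives below 10⁻⁶ of a field's scale are
clipped to zero.  The scheme reproduces the exact traveling-wave speed
`c = √(r·χ·K/2)` of the degenerate-diffusion logistic benchmark to < 1%, and
halving both dx and dt moves the day-60 front by < 0.1%.

**Proliferation** (101 nodes, `tau = 10⁻³` day by default): moving mesh
advected by u (Lagrangian frame: the advection term is absorbed into node
motion, leaving the dilution term −(∇·u)·X, with ∇·u = (net source)/θ used
exactly so the constraint C + N = θ is preserved by construction).  Fully
implicit stepping by Picard iteration: each spatial field's linear self-decay
and dilution are inside its tridiagonal solve, productions and
cross-couplings are lagged; proteins update pointwise implicitly.  Iteration
cap 50, relative tolerance 5·10⁻¹³ with round-off-plateau detection; the
per-step discrete residual stays below 10⁻¹⁰ (normalized by field scale).
The spherical Laplacian uses 3-point nonuniform-grid formulas with the
symmetry limit 6(f₁−f₀)/h² at r = 0 and a mirrored ghost at r = R.  If node
spacing collapses below 10⁻⁴·R the fields are re-interpolated onto a fresh
uniform mesh (monotone cubic).  On a frozen mesh the solver matches a
method-of-lines reference integration to first order in tau (verified to
10⁻⁴ relative at tau = 5·10⁻⁵).

**Problem sizes used by the shipped workflows.**  The acceptance script runs
the invasion comparisons at the production resolution (201 nodes,
dt = 10⁻³) and the proliferation run at 101 nodes, tau = 10⁻³.  The test
suite uses the same invasion resolution, a 51-node/5·10⁻³ proliferation run
(day-60 metrics differ from the fine run by < 10⁻⁴ g/cm³), and a scaled-down
sensitivity study of n = 100 samples at 21 nodes and tau = 5·10⁻² day
(R(60) within 0.6% of the fine solution — ample for rank statistics; the
published study used n = 1000, which `mirlung sens --n 1000` reproduces
offline).

## Sensitivity analysis

Latin hypercube sampling (`scipy.stats.qmc`, exactly one draw per
equal-probability stratum per parameter) over [value/2, 2·value] for the
production rates `lam_E, lam_M, lam_A, lam_MA, lam_T, lam_P, lam_Ap,
lam_Ec, lam_m1, lam_m2` and the fitted `d_Ec`; one proliferation run per
sample; PRCC of R(60) against each parameter.  PRCC is computed by
rank-transforming all columns, regressing out the other parameters by least
squares and correlating the residuals; p-values come from
`t = prcc·√((n−k−1)/(1−prcc²))` with n−k−1 degrees of freedom.  Ties are
broken by average rank.  The implementation is cross-checked in the tests
against an explicit normal-equations oracle (to 10⁻¹⁰) and against
`pingouin.partial_corr`.

## What the defaults do and do not emulate

The default parameter sets *are* the study conditions: no external data is
read, and the initial/boundary conditions are the published ones.  Passing
tests therefore demonstrate internal reproduction of the model, not fidelity
to any patient data.  Known limitations, inherited from the model scope:
no immune response, no angiogenesis or nutrient limitation, spherical
symmetry in the proliferation phase, a planar front in 1-D for invasion,
and no pharmacokinetics for the drug scenarios (drugs are constant
multiplicative rate changes).

Where the package's converged day-60 invasion comparisons differ from the
published approximate percentages (they sit between this transient and the
model's traveling-wave asymptotics), the numbers reported by
`scripts/acceptance.py` are the package's own computed values; nothing is
calibrated to the published figures.
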