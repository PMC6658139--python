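# Methods

## Model

Two species share a batch culture founded each cycle with fresh Resource.
The Helper (H) grows on Resource with Monod kinetics and releases a
Byproduct proportionally to its growth; the Manufacturer (M) requires both
Resource and Byproduct, combined by the Mankad–Bungay dual-substrate law

g_M(R, B) = g_Mmax · (R_M B_M / (R_M + B_M)) · (1/(R_M+1) + 1/(B_M+1)),

with R_M = R/K_MR and B_M = B/K_MB, which reduces to single-substrate
Monod kinetics when either substrate saturates and gives g_max/2 at
R_M = B_M = 1. M diverts a fraction f_P of its potential growth to an
extracellular Product; community function is P(T), the Product accumulated
by the maturation time T. All chemical quantities are scaled: Resource in
units of the Newborn supply, Byproduct in units of the release per Helper
biomass grown, Product in units of the make per Manufacturer biomass of
cost. Affinities are stored as 1/K so that a loss-of-function mutation is
exactly 0. A mutualistic variant multiplies Helper growth by exp(−B/B0)
(Byproduct toxic to H); B0 = None selects the commensal model.

Dimensionless parameter values (defaults; "preadapted" = evolutionary
upper bounds):

| parameter | ancestral | preadapted / bound | meaning |
|---|---|---|---|
| g_Hmax | 0.25 | 0.30 | Helper max growth rate (1/time) |
| g_Mmax | 0.58 | 0.70 | Manufacturer max growth rate |
| 1/K_HR | 1 | 5 | H affinity for Resource |
| 1/K_MR | 1 | 3 | M affinity for Resource |
| 1/K_MB | 0.006 | 0.03 | M affinity for Byproduct |
| f_P | 0.10 | ≤ 1 (start 0.13) | cost fraction |
| c_RM = c_RH | 1e-4 | fixed | Resource per potential biomass |
| c_BM | 1/3 | fixed | Byproduct per potential M biomass |
| δ_M, δ_H | 3.5e-3, 1.5e-3 | fixed | death rates |

R(0) = 1 supports 1e4 total biomass (10 supports 1e5, used when fast
Helper bounds require more head-room). The fast-Helper scenario raises the
g_Hmax bound to 0.8, above M's 0.7.

## Agent simulation

Maturation divides T (default 17) into steps of Δτ = 0.05. Within a step,
cell biomasses are frozen and the Resource/Byproduct pool is integrated
with an embedded Cash–Karp 4(5) pair (rtol 1e-6, atol 1e-9, states clipped
at 0); the growth integral ∫g dt of every phenotype group is carried as an
augmented ODE state of the same solve, so it is exactly consistent with
the evolving chemicals. Cells sharing a bitwise-identical growth-parameter
vector form one group (mutation creates discrete classes, so exact
grouping is lossless; f_P does not enter the chemical solve and stays
per-cell). Then, per cell: length multiplies by exp(∫g dt) for H and
exp((1−f_P)∫g dt) for M, each M cell adds f_P/(1−f_P)·ΔL to the shared
Product (analytic limit L·∫g dt at f_P = 1, where biomass does not grow);
each cell dies with probability δΔτ; survivors with length ≥ 2 split into
two half-length cells (daughters appended after the mothers, in order, so
replay is deterministic; re-checked next step — a double division in one
step is unreachable at Δτ = 0.05); each mutable phenotype of each freshly
divided cell then mutates independently with probability P_mut = 2e-3.

Mutation effects: null (phenotype → 0) with probability 0.5, otherwise
multiply by 1 + Δ with Δ drawn by inverse CDF from a bilateral exponential
truncated at −1 (enhancing mean s₊ = 0.050, diminishing mean s₋ = 0.067;
the truncation mass e^(−1/s₋) ≈ 3e-7 is carried exactly). Diminishing-
returns epistasis optionally rescales both means by 1 + g·(f_P/f_P,init −
1). Results clamp to [0, bound]. Product made by a cell that dies in the
same step is retained (Product is extracellular); death acts after the
step's growth has accrued.

Two engines implement the identical step sequence: a compiled kernel (the
production path for selection runs, ~25 ms per standard maturation) and a
numpy composition of the public per-step operations. With death and
mutation disabled they agree to ~1e-9 relative; each is bit-reproducible
from its community seed (they consume different RNG streams, so their
stochastic paths are compared statistically, not draw for draw). The
mutation-free agent simulation agrees with the coupled continuous-biomass
ODE within 0.3% on BM(T) and P(T) at Δτ = 0.05 (tolerance asserted: 1%);
the only discrepancies are operator splitting and death stochasticity.

## Selection cycles

Each cycle: every Newborn matures (per-community seed logged), Adults are
scored by P(T) (or P(T)/M(T); undefined scores for M-extinct Adults rank
last), optional Gaussian measurement noise with SD a fixed fraction of the
*ancestral* P(T) (the deterministic function of the cycle-1 configuration,
computed once) is added, and the chosen Adults are partitioned into the
next cycle's n_tot Newborns. Strategies: top-dog (the best Adult
contributes all ⌊BM(T)/BM_target⌋ Newborns it can, then the runner-up,
with a uniform random subset topping up to n_tot), top-tier (best
n_chosen contribute n_tot/n_chosen each; shortfalls cascade down the
ranking), and a random control. Ties break toward the lower community
index. Reproduction methods: pipetting (each cell assigned a uniform
aliquot 1..n_D; empty aliquots retained — they mature trivially and score
0), biomass sorting (greedy closest-without-exceeding fills of
BM_target·φ_M and the complement; skipped cells stay available for later
Newborns), cell-number sorting (⌊BM_target·φ/1.5⌋ cells per species),
fix-BM-only / fix-φM-only, and fixed-fold dilution. Chemicals always reset
to fresh Newborn conditions.

All randomness derives from the master seed through a counter-based seed
tree (`SeedSequence` keyed on cycle and community index), so results are
independent of execution order, archives are replayable exactly, and
per-community parallelism could not change results.

Monoculture group selection founds each Newborn group from a single M cell
of biomass 1 drawn from the chosen Adult, with Byproduct treated as
saturating — implemented as the Monod limit in Resource rather than as a
large finite B, avoiding consumption bookkeeping of an arbitrary constant.
Pregrowth of the founder culture is a two-type branching process in
population counts: contributors (cost 0.13, growth 0.87× the null rate)
divide synchronously; at each division mother and daughter independently
convert to null with probability 1e-3; null clones compound at the faster
rate; growth stops at 2^23 ≈ 8.4e6 cells (~23 contributor doublings). The
replicate null-load distribution is strongly right-skewed (rare early
conversions found jackpot clones): median ≈ 2.9%, mean ≈ 4.5%.

## Deterministic analyses

The coupled equations (death included) are solved with LSODA (rtol 1e-6,
atol 1e-9), supporting several phenotype groups per species for
within-community competition experiments. On them are built: the
community-function landscape P(T) over f_P = 0.01·i, φ_M(0) = 0.01·j
(i, j = 1..99; BM(0) = 100, T = 17) with its unique interior maximum at
(0.41, 0.54) — a 0.05 pre-scan with hill-climbing 0.01 refinement returns
the same argmax ~25× faster; the closed-form steady-state composition
φ_M,SS = (1−f_P)/(1−f_P+c_BM), valid while B is depleted within a cycle
(f_P below ~0.4), and the iterated cycle map that converges to it; the
monoculture optimum (grid argmax 0.14, adjacent to the exact optimizer
0.130 of the closed-form criterion 1/∫g_M dt = f_P(1−f_P) at the realized
∫g_M dt ≈ 8.8 — the peak is flat to 0.2% between 0.13 and 0.15); and the
pipetting fluctuation statistics SD[BM(0)] = √(BM_target·L̄) and
Var[M/H] = φ(1−φ)⁻³·L̄/BM_target (a first-order propagation formula,
accurate to ~10–15% at BM_target = 100).

Of note, integrating the coupled equations from the standard 40H+60M
Newborn at f_P = 0.13 to T = 17 consumes ~82% of the supplied Resource,
not ≤70%: biomass reaches ~7400 ≈ 74% of the 1e4-biomass capacity, and
Resource consumption is proportional to *potential* (pre-cost) growth, a
further factor 1/(1−f_P) for M, plus death-and-regrowth turnover.  The
short-maturation design intent (avoiding stationary phase) still holds —
R(T) ≈ 0.18 remains.

## Scaled-down property experiments

The full-scale selection experiments (100 communities × thousands of
cycles) are far beyond a single-CPU test budget, so the test suite asserts
the qualitative outcomes at deliberately scaled conditions — 30
communities (15–20 for the heaviest scenarios), 5–100 cycles, three
independent master seeds per arm — chosen once on mechanistic grounds:

* **Reproduction method** (100 cycles): top-dog + pipetting shows no
  improvement of the chosen-lineage mean cost (at this community number
  the trajectory in fact drifts downward — weaker intercommunity
  selection than at full scale) and ends far below the 0.41 optimum;
  top-dog + biomass sorting produces a rising trajectory ending clearly
  above it; top-tier + pipetting lands in between.
* **Random control** (50 cycles): mean cost collapses to ~0.
* **P(T)/M(T) scoring** (60 cycles): started at f_P = 0.45, near the
  coexistence boundary, so the runaway selection for ever-higher cost
  resolves within the run: cost rises and the Manufacturer fraction of
  chosen Adults crashes below 1/BM_target.
* **Fixed-fold dilution in excess Resource** (5 cycles, R(0) = 10,
  20-fold): chosen-lineage Newborn biomass inflates several-fold while
  the cost does not improve.
* **Measurement noise** (10% of ancestral P(T), 60 cycles): top-dog +
  sorting collapses; top-tier + sorting retains the cost.
* **Coexistence enforcement** (30 cycles): communities founded with a
  minority (2 of 40) of fast Helpers at g_Hmax = 0.55 — beyond the
  deterministic coexistence boundary (the cycle map at g_Hmax 0.45/0.50/
  0.55 gives φ_M fixed points 0.72/0.40/extinction) — with every
  phenotype mutable and the Helper bound at 0.8. Mutation-driven sweeps
  from a uniform start are far too slow to separate the arms at desk
  scale (no reliable divergence after 100 cycles), so the discriminating
  variation is supplied as standing variation instead.  The asymmetry is
  the claim: under sorting the communities that purged the fast Helper
  score best and coexistence is preserved in every run; under pipetting
  the choice cannot reliably prevent the takeover, and the fast Helper
  sweeps with composition collapse in roughly half the runs (the test
  requires it in at least one of five seeds, plus the arm-mean ordering).
  Resource is at the standard 1 unit here: with fast-Helper head-room
  capacity (10 units) every Adult saturates the 1e5-biomass capacity,
  which both contradicts the short-maturation design intent at these
  growth rates and costs ~20× the compute.

What these scaled runs do **not** show: quantitative trajectories (rates
of cost improvement, plateau values), full convergence of the sorting arm
to f_P*, or mutation-limited dynamics at realistic waiting times; they
establish the orderings and failure modes only. Real microbial systems
additionally violate model assumptions documented as non-goals: no
spatial structure, no lag/stationary-phase physiology, no
rate-vs-affinity trade-offs, fixed consumption coefficients, and a single
well-mixed chemical pool.

## Numerical choices

Chemical step and trajectory tolerances rtol 1e-6 / atol 1e-9 (halving
tolerances changes P(T) by <1e-5 relative); states clipped at 0; the
chemical step accepts a forced minimal substep (1e-12·Δτ) as a fail-safe.
Landscape and monoculture optima use 0.01 grids exactly; ties in Adult
ranking break toward the lower index; f_P = 1 uses the analytic Product
limit; the cycle map flags extinction at φ_M < 1/BM_target. Phenotype
group tables rebuild when they exceed 16k entries (never reached in
practice).
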