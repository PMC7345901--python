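# Methods

`radars` implements a radial model of the antibody interaction repertoire:
antibody specificity is a **direction** in a continuous shape space, and
affinity — the binding free energy ΔG — is the **radial coordinate**. This
note records the model as implemented, the parameter choices, and the
numerical decisions, in enough detail to reproduce or challenge them.

## 1. Thermodynamic conventions (`radars.thermo`)

ΔG is stored as the magnitude of the free-energy decrease on binding
(ΔG ≥ 0), so a larger ΔG always means a better binder, and

    K_D = exp(−ΔG/RT),    K_A = exp(+ΔG/RT),    K_sys = K_A/⟨K_A⟩.

The default context uses the per-mole gas constant with energies in kJ/mol
and T = 310 K (RT ≈ 2.577 kJ/mol); a dimensionless `kBT` mode sets RT = 1.
310 K is not arbitrary: it is the temperature at which the characteristic
mean binding energy of 27.67 kJ/mol corresponds to K_D ≈ 2×10⁻⁵ (at 298 K
it would not).

The characteristic energy itself comes from the lognormal construction: a
Gaussian log-energy with μ = 0 and σ numerically equal to RT in kJ/mol
(≈ 2.577) has mean exp(σ²/2) ≈ 27.7 kJ/mol. The "σ equals the numeric value
of RT" reading is dimensionally awkward but is the only one that reproduces
both printed anchors (27.67 kJ/mol and K_D = 2×10⁻⁵); it is implemented as a
documented interpretation, not asserted as physical necessity.

The regulatory principle of the model is **[Ag] ≈ K_D**: the steady-state
free concentration of an antigen equals the dissociation constant of the
antibody controlling it. `regulated_antigen_concentration` is therefore
bit-for-bit the dissociation branch of `k_from_dg` — the identity is the
point, and a test enforces it.

## 2. The double-Pareto system constant (`radars.distributions`)

A binding surface with `r` noncovalent bonds has Gaussian free energy with
variance r·ΔE² (random-energy picture). Antigen availability decays
exponentially with rate λ, so `r` is itself exponentially distributed. The
implemented construction is, per draw:

    r ~ Exponential(rate λ)
    ΔG_sys | r ~ Normal(0, r·2/λ)      (dimensionless log units)
    K_sys = exp(ΔG_sys)

The per-unit-`r` variance 2/λ is the calibration that makes the upper tail
exponent exactly 1 + λ; equivalently the per-bond fluctuation ΔE² equals
1/λ in these units. Marginally log K_sys is Laplace(0, 1/λ) — the
killed-Brownian-motion identity. The tests use this identity, and direct
numerical quadrature of the exponential-lognormal mixture, as *independent*
oracles; the sampler itself never takes the Laplace shortcut.

The closed-form density is the symmetric double-Pareto

    f(k) = (λ/2)·k^(−1−λ)  for k ≥ 1,     f(k) = (λ/2)·k^(λ−1)  for k < 1,

with median 1 and mass ½ per branch. Only the upper branch is forced by the
power-law statement; the lower branch is taken symmetric, as the
Reed–Mitzenmacher exponential-sampling mechanism implies. Whether the lower
branch should instead be truncated is not determinable from the model
statement; symmetry is the canonical choice for this construction.

Tail exponents are estimated with the Hill (continuous Pareto ML) estimator,
α̂ = 1 + n/Σln(vᵢ/k_min), with stderr (α̂−1)/√n and a minimum of 10 tail
points. For *integer* degree data the cutoff is shifted to k_min − ½
(the standard continuous approximation for discrete power laws); the
approximation is accurate for k_min ≥ 3, which is the default cutoff —
at k_min = 2 the discretisation bias reaches several percent.

## 3. The repertoire simulation (`radars.repertoire`)

Shape space is the unit sphere in D = 8 dimensions; the continuous
"infinity of directions" is discretised only by the sampled antigen panel.
Each antigen has a direction and a base availability ~ Exponential(λ);
each clone has a direction, a bond count `r`, and energy ΔG.

Fixed structural rules:

* **Energy per bond.** ΔG grows by ε₀·alignment per acquired bond, with
  ε₀ = RT ≈ 2.577 kJ/mol for a perfectly aligned bond. Ten to eleven bonds
  then reach the 27.67 kJ/mol system mean, consistent with binding energy
  being carried by the number and strength of noncovalent contacts. Fresh
  bone-marrow emigrants carry r₀ = 3 bonds at ΔG = r₀·ε₀ exactly.
* **Resolution cap.** A clone recognises an antigen only within angular
  distance θ(ΔG) = c/ΔG. The constant c is set so that an emigrant's cap
  covers 1% of the sphere at D = 8 (c ≈ 5.59); higher energy means narrower
  discrimination.
* **Engagement.** Within the cap, engagement probability is receptor
  occupancy [Ag]/([Ag] + K_D), capped at 1.
* **GC entry.** An engaged clone (occupancy ≥ ½) enters a germinal center
  if its energy *shell* (width ε₀) is at or above the shell containing the
  population mean energy. Quantising the threshold to shells matters: the
  mean sits an ε above the emigrant energy as soon as any clone matures, and
  a strict mean comparison would permanently close the frontier after the
  first wave. Shells are the discrete iso-energy levels of the model, so the
  "at or beyond the mean" rule is applied at shell resolution. A fixed
  threshold can be configured instead (`mean_system_dg`).
* **Mutation–selection.** Per GC cycle a Gaussian angular proposal
  (sd 0.15 rad) is accepted iff it strictly improves alignment with the
  driving antigen; acceptance adds one bond and ε₀·alignment of energy.
  Strict selection is the simplest rule consistent with affinity maturation;
  a Metropolis-style tolerance would be a straightforward extension. With
  sd 0.15 and a budget of 10 cycles, realised GC gains are ~1–5 bonds
  (≈ 2–12 kJ/mol, i.e. a 10–100-fold affinity improvement), which is the
  magnitude affinity maturation actually delivers and which produces a
  heavy-tailed K_sys distribution rather than a runaway one.
* **Retraction.** A GC cohort (all clones driving the same antigen) retracts
  once the antigen is cleared — free level within a factor 3 (half a log10)
  of the best clone's K_D — or the cycle budget is spent. The top clone
  becomes the subnetwork's LLPC; an incumbent LLPC is displaced only by a
  higher-energy challenger (niche competition keeps exactly one per
  subnetwork). The rest become MBC at minimal size; excess effector cells
  are removed as apoptosis in the cell ledger.
* **Antigen regulation.** Each antigen relaxes geometrically (factor
  ρ = 0.5 per step) toward min(base, K_D of the best covering secretor).
  Secretors are LLPC (within their cap) and active GC cohorts on their
  driving antigen — the latter standing in for short-lived plasma-cell
  output during the response. Without a secretor, free returns to base.
* **B1 cells.** A configurable influx fraction (5%) is innate-like: no GC,
  no maturation, negligible death — a stable low-energy population. The
  model text is ambiguous about whether B1 affinity is minimal or maximal;
  the default places them at the base energy (minimal network degree), and
  `b1_mode="high"` exposes the alternative reading.

Division and death are binomial per clone and stage, division scaled by
engagement and a logistic factor (carrying capacity 1000 cells/clone); the
model statement supplies no rates or population sizes, so all are free
parameters with defaults chosen to give steady bone-marrow turnover (influx
20 clones/step, naive death 8%/step, ~10³ living clones) and full
regulation of the reachable antigen panel within 500 steps on one CPU
(~1 s wall time). Cells are created only by influx and division, removed
only by death/apoptosis, and a per-run ledger balance is asserted in tests.

What the generator does *not* emulate: isotype switching, explicit T-cell
help (folded into the GC-entry threshold), antibody secretion kinetics,
anatomical compartments, and real sequence→structure constraints. Passing
tests therefore demonstrate internal consistency of the model's mechanism —
regulation toward [Ag] ≈ K_D, radial monotonicity, heavy-tailed emergent
K_sys — not agreement with sequencing data.

## 4. Network metrics (`radars.network`)

Degrees are integerised as k = max(1, round(K_sys)) — every clone keeps at
least one link, since a molecule with no interactions would leave the
system — and the rounding preserves the tail index.

The hierarchical construction makes, within each subnetwork (structural
direction): a star from the LLPC to every member, plus one link from each
node to the angularly nearest node in the next occupied shell above (ties
by id). Links are directed from lower to higher energy — the direction of
antigen hand-off. No link crosses subnetworks. A subnetwork with no LLPC
uses its highest-shell node as hub, with a warning.

Box covering uses the greedy colouring formulation: nodes at shortest-path
distance ≥ l_B conflict, boxes are colour classes, with 10 random restarts
keeping the minimum. N_B(1) = N and N_B(diameter+1) = 1 by construction,
and the dimension d_B is the log–log slope fitted only where 1 < N_B < N.
On deterministic fractals the box sizes should follow the renormalisation
sequence (powers of 2 for the (2,2)-flower, whose dimension is exactly 2);
tests verify the greedy cover is within 2× of an exhaustive minimum on all
small fixture graphs.

The consistency relation d_B = (γ−1)/(γ−2) has its fixed point at
γ = φ + 1 = φ² ≈ 2.6180 (φ the golden ratio), computed by bisection and
verified against the closed form to 1e−10. Note the map is *not* an
involution — applying it twice gives 1/(3−γ); only the fixed point returns
to itself. The related map γ ↦ γ/(γ−1), which also has fixed point φ², is
the self-inverse one.

Degree-proportional (preferential-attachment) growth is provided for
contrast: its asymptotic exponent is ≈ 3, not φ², and the package makes no
claim that one generator produces the other's exponent — the ideal network
is a variational statement (γ = d_B), not the limit of the growth process.

## 5. Numerical choices

* Quadrature of the exponential-lognormal mixture splits the integration
  range at the integrand's peak r* = |ln k|/√(2λ) and demands relative
  error ≲ 1e−10, giving ≤ 1e−6 disagreement with the closed form over
  k ∈ [0.01, 100].
* One `numpy` Generator per run, seeded from `SeedSequence(seed)`; identical
  seeds give byte-identical CSV exports. The acceptance script derives
  independent child seeds (< 2³¹) from its `--seed`.
* Degenerate cases: r = 0 gives a point-mass energy distribution (zero
  interaction probability off the mean); γ ≤ 2 maps to d_B = ∞; tail fits
  refuse < 10 points; box-dimension fits refuse < 3 unsaturated sizes.

## 6. Known limitations

The simulation's K_sys distribution is heavy-tailed but its exponent
(≈ 1.7–1.9 at the default configuration) is not tuned to, and does not
equal, the analytic 1 + λ of the sampling construction: the agent-based
dynamics are a mechanistic sketch, not a derivation. The global simulated
network is a forest of subnetwork stars (no cross-subnetwork links), so its
diameter is too small for a meaningful box-dimension fit; fractal scaling is
validated on reference topologies instead. Empirical repertoire (NGS)
comparisons are out of scope.
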