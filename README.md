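# radars

A radial interaction-space model of the antibody repertoire, as a tested
simulator and analysis library.

The humoral immune system regulates the concentration of an enormous number
of antigens with a finite set of antibodies. This package implements a model
in which every antibody specificity is a **direction** in shape space and
its affinity — binding free energy ΔG — is the **radial coordinate**:
moving outward means recognising a shape at higher structural resolution.
B cells develop radially (bone-marrow influx at a base energy, clonal
expansion proportional to antigen availability, germinal-center
mutation–selection, retraction into memory cells and plasma cells), and the
system is driven toward the regulatory equilibrium **[Ag] ≈ K_D**: each
antigen's free concentration settles at the dissociation constant of the
antibody controlling it.

At the system level the model predicts:

* energies and equilibrium constants are linked by ΔG = −RT ln K; the
  characteristic mean binding energy exp(σ²/2) with σ = RT(310 K) is
  27.67 kJ/mol, i.e. K_D ≈ 2×10⁻⁵;
* the **system equilibrium constant** K_sys = K_A/⟨K_A⟩, built by
  exponential sampling of Gaussian bond energies (r ~ Exp(λ),
  ΔG_sys | r ~ N(0, 2r/λ)), follows a **double-Pareto (log-Laplace)**
  law, f(K_sys) = (λ/2)·K_sys^(−1−λ) for K_sys ≥ 1;
* identifying node degree with K_sys gives a scale-free antibody
  interaction network, p(k) ~ k^(−γ) with γ = 1 + λ, whose fractal box
  dimension obeys d_B = (γ−1)/(γ−2); the self-consistent "ideal" network
  has γ = d_B = φ + 1 = φ² ≈ 2.618 (φ the golden ratio).

Modules: `radars.thermo` (unit-safe energy/affinity conversions),
`radars.distributions` (random-energy Gaussian, double-Pareto sampler/pdfs,
Hill tail estimation), `radars.repertoire` (agent-based simulation),
`radars.network` (hierarchical network construction, degree-exponent and
box-covering metrics, golden-ratio identities), `radars.config` /
`radars.pipeline` / `radars.cli` (reproducible runs).

## Worked example

Convert the characteristic mean binding energy to a dissociation constant
at body temperature:

```bash
$ radars thermo --dg 27.67
{"dg": 27.67, "k": 2.1750474776347834e-05, "kind": "dissociation", "temperature": 310.0}
```

— 27.67 kJ/mol corresponds to K_D ≈ 2.18×10⁻⁵, the model's lower limit of
useful antibody affinity (2×10⁻⁵ at one significant figure).

Sample system constants at λ = φ and fit the upper tail:

```bash
$ radars sample-ksys --lam 1.618034 --n 100000 --seed 0 --out ksys.csv
$ radars fit-tail --in ksys.csv --kmin 1.0
{"alpha_hat": 2.6170845014742, "stderr": 0.007221070350321236, "k_min": 1.0, "n_tail": 50149}
```

— the fitted exponent 2.617 ± 0.007 matches the predicted γ = 1 + λ =
φ² ≈ 2.618: the degree exponent of the ideal network.

Run the full pipeline (500-step simulation, network, metrics; ~2 s):

```bash
$ radars run --out-dir run0
$ python -c "import json; r=json.load(open('run0/report.json')); print(json.dumps(r['network'], indent=1))"
{
 "n_nodes": 944,
 "n_links": 520,
 "ideal_gamma": 2.6180339887498514,
 "ksys_tail_exponent": 1.7425290195029217,
 "ksys_tail_stderr": 0.08690644826903997,
 ...
 "gamma_hat": 1.8881469865758542,
 "gamma_stderr": 0.11101837332198178,
 ...
}
```

— after 500 steps the default simulation holds ~944 living clones
(56 plasma-cell hubs, each regulating its antigen to within numerical
precision of [Ag] = K_D), and the emergent K_sys > 1 tail is heavy with
exponent ≈ 1.7: the agent-based dynamics produce scale-free-like structure
without being tuned to the analytic construction.

Library use mirrors the CLI:

```python
from radars import DoubleParetoModel, sample_ksys, fit_tail_exponent
k = sample_ksys(DoubleParetoModel(lam=1.618034), 100_000, seed=0)
fit_tail_exponent(k, k_min=1.0).alpha_hat   # 2.617...
```

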