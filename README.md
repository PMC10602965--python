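# npgsim

A lattice kinetic Monte Carlo model of integrin clustering and focal-adhesion
(FA) formation on nanoporous gold (NPG) substrates, for researchers studying
how nanoscale surface topography steers cell adhesion.

Cells adhere more weakly to NPG the smaller its pores — the opposite of the
classic ligand-spacing trend on other nanopatterned surfaces. `npgsim`
implements the computational model behind that observation: integrins on a
membrane patch undergo three reversible reactions whose energetics feel the
substrate,

    activation:   k_a+/k_a− = exp(−E_a),            E_a = 3 kT
    binding:      k_b+/k_b− = exp(+E_b),            E_b = α c B / r_p + A c
    association:  k_c+/k_c− = exp(+E_c),            E_c = β c r_p / r_max + C

with A = 3.5 kT, B = −12 kT·nm, C = 5.2 kT, r_max = 150 nm, forward rates
k_a+ = k_b+ = 10 s⁻¹ and k_c+ = 1 s⁻¹. Because B < 0, small pores (r_p)
weaken integrin–ECM binding; the association (clustering) energy grows with
pore size too. 1000 integrins diffuse and react on a 100 × 100 periodic
lattice spanning 6 × 6 µm² in 10 ms sweeps; clusters of associated integrins
are the model's FAs, summarised by the number of clustered integrins and the
mean area of the largest 10% of clusters.

The package also provides:

- **substrate fields** — Cahn–Hilliard phase separation generates
  bicontinuous NPG-like morphologies, calibrated by structure-factor
  characteristic length to a target pore size (20 nm parent, rescaled to
  50–150 nm) plus a flat-gold control;
- **morphometry** — local-width (inscribed-disc) pore/ligament sizing of
  binary images, the pore–ligament least-squares relation, and cell
  circularity 4πA/L²;
- **scenario sweeps** — the four coupling conditions (`fig5b`–`fig5e`)
  crossed with pore sizes and the flat control, with seeded replicates.

See `docs/methods.md` for the model's assumptions, parameters and numerical
choices.

## Worked example

```python
import math
import npgsim as N

# substrate-dependent energies at two pore sizes (pure gold, c = 1)
p = N.EnergyParams()
print(N.binding_energy(20.0, 1.0, p), N.binding_energy(150.0, 1.0, p))
# 2.9 3.42                      <- binding is 0.52 kT weaker on 20 nm pores
print(N.association_energy(150.0, 1.0, p))
# 6.2                           <- the flat-gold / 150 nm association energy

# recover the activation energy from an activation-only simulation
cfg = N.SimConfig(binding_enabled=False, association_enabled=False, seed=1)
st = N.initialize(cfg)
N.run_steps(st, 20_000)                          # burn-in
rec = N.run_steps(st, 200_000, record_every=10)  # (step, active, bound, assoc)
f = rec[:, 1].mean() / 1000
print(round(math.log((1 - f) / f), 3))
# 3.0                           <- ln((1-f)/f) returns E_a = 3 kT

# compare clustering on small-pore vs large-pore substrates (scenario fig5c)
df = N.sweep_fig5(scenarios=["fig5c"], pore_sizes_nm=(20.0, 150.0),
                  include_flat=False, n_replicates=3, base_seed=100)
print(N.aggregate_sweep(df)[["pore_nm", "n_clustered_mean", "fa_area_mean"]])
#    pore_nm  n_clustered_mean  fa_area_mean
# 0     20.0        946.333333     14.476780
# 1    150.0        978.000000     14.557734
```

At equal simulated time (2000 s), the 20 nm substrate holds clearly fewer
clustered integrins than the 150 nm substrate; the difference in
large-cluster area is subtler and resolves with more replicates (at 10
replicates the test suite measures mean top-decile areas of 13.3 vs 14.7
integrins, both differences one-sided significant). This is the model's
explanation for weaker cell adhesion on small-pore NPG: the substrate
suppresses FA density *and* FA size when it couples to both the binding and
the association energies.

A command-line interface mirrors the library
(`npgsim substrate|morph|sim|analyze|pipeline`, try `npgsim --help`).

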