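# Methods

`npgsim` is a computational model of why nanoporous gold (NPG) substrates
reduce focal-adhesion (FA) formation as their pore size shrinks. It couples
three components: a phase-field generator of NPG-like surface morphologies, a
three-reaction thermodynamic model of integrin behaviour whose energies depend
on pore size, and a fixed-time-step lattice Monte Carlo engine that evolves
1000 integrins on a patch of cell membrane until their clustering statistics
are stationary. A small morphometry toolbox reproduces the standard
image-analysis quantities used to characterise such substrates (pore and
ligament sizes, their linear relation, cell circularity).

## Substrate model

NPG is a bicontinuous pore/ligament structure produced by dealloying; its
geometry is statistically equivalent to a late-stage spinodal decomposition
pattern. We therefore generate substrates by evolving the Cahn–Hilliard
equation

    dc/dt = M ∇²( f'(c) − κ ∇²c ),   f(c) = c²(1−c)²,

for the conserved gold fraction c(x,y) on a periodic square, with the
semi-implicit Fourier-spectral update (nonlinear term explicit, biharmonic
term implicit), which is unconditionally stable and conserves the spatial mean
of c to machine precision. Defaults: mobility M = 1, interface coefficient
κ = 1, dimensionless step dt_ch = 0.5, mean composition 0.5, initial noise
amplitude 0.05, 512 px parent field. The symmetric composition 0.5 is chosen
because it produces the bicontinuous morphology in which ligament width tracks
pore width, as NPG does; the 3:7 Au:Ag ratio of the pre-dealloying alloy
describes chemistry that the dealloying step removes and is not a good
estimate of the post-dealloying solid fraction. The composition is
configurable.

The equation is dimensionless, so physical units are attached by calibration:
the field is evolved until its characteristic length reaches 8 px (so features
are well resolved), binarized at c = 0.5 (the symmetric threshold of the
double well), lightly smoothed (Gaussian, σ = 1 px), and the pixel size is
then fixed so that the measured characteristic length equals the requested
pore size (20 nm by default) exactly. Larger pore sizes (50–150 nm) are
produced by uniformly rescaling the 20 nm parent field — pixel values
untouched, pixel size multiplied — mirroring self-similar coarsening under
heat treatment.

**Characteristic length.** The pore-scale length is 2π/k₁ · (pixel size)/2,
where k₁ is the first moment of the radially averaged structure factor of the
mean-subtracted field. The half-wavelength convention reports the width of one
phase domain (a pore or a ligament) rather than the pore+ligament repeat; on a
pure sinusoid of period 20 px it returns 10 px. It is undefined (and raises)
on a structureless field such as flat gold.

## Integrin energetics

Three reversible reactions, all energies in kT (temperature never appears
separately):

| reaction     | ratio                  | forward rate | energy |
|--------------|------------------------|--------------|--------|
| activation   | k_a+/k_a− = exp(−E_a)  | 10 s⁻¹       | E_a = 3 |
| binding      | k_b+/k_b− = exp(+E_b)  | 10 s⁻¹       | E_b = αcB/r_p + Ac |
| association  | k_c+/k_c− = exp(+E_c)  | 1 s⁻¹        | E_c = βc·r_p/r_max + C |

with A = 3.5 kT, B = −12 kT·nm, C = 5.2 kT, r_max = 150 nm. Activation is
substrate independent (inside-out signalling). Binding is weakened by small
pores (B < 0) and association likewise (r_p/r_max < 1); both energies are
monotone increasing in pore size and stay within the physically admissible
0–10 kT band for all scenario intensity factors (α ∈ {0.5, 1, 2.5},
β ∈ {0.5, 1, 2}). Flat gold is the r_p → ∞ limit for binding (E_b = A·c) and
maps to the r_p = r_max value for association (E_c = 6.2 kT at c = 1, β = 1),
so the flat control and the 150 nm substrate are nearly equivalent
(ΔE_b = 0.08 kT).

Four scenario presets cover the simulated conditions: `fig5b` (E_c frozen at
6.2 kT; only binding feels the substrate), `fig5c` (both energies
pore-dependent, α = β = 1), `fig5d` (weak coupling, α = β = 0.5) and `fig5e`
(strong coupling, α = 2.5, β = 2).

**Gold-concentration modes.** Whether c is a scalar substrate composition or
a spatial field is genuinely open; both are implemented. The default
`uniform` mode sets c = 1 on every lattice site (NPG is pure gold after
dealloying; this reading also makes the flat ≈ 150 nm equivalence hold). The
`field` mode samples c per 60 nm membrane site by block-averaging a substrate
field (tiled periodically when the field is smaller than the membrane — both
are periodic), so integrins over pores see c ≈ 0 and lose their substrate
coupling locally.

## Rate → probability mapping

With the model's own constants the inactivation rate gives k_a−·dt ≈ 2.01 at
the 10 ms step, so the naive linear mapping p = k·dt is not a probability,
and the per-channel Poisson form p = 1 − exp(−k·dt) distorts every
equilibrium ratio whose rates are not small (it would put the activation
equilibrium at logit 2.21 kT instead of 3 kT). The engine therefore samples
each reversible pair with the exact transition probabilities of its two-state
continuous-time chain observed at interval dt:

    p± = k± / (k+ + k−) · (1 − exp(−(k+ + k−)·dt)).

This keeps the stationary ratio of every rung equal to the prescribed
Boltzmann factor at any finite dt, reduces to k±·dt as dt → 0, and keeps the
per-sweep channel probabilities summing below 1 (asserted at configuration
time, with an error that names dt). The single-channel Poisson form is still
available as `step_probability` for isolated channels.

## Monte Carlo engine

A 6 × 6 µm² membrane patch is a 100 × 100 periodic lattice (60 nm sites), one
ECM ligand per site, 1000 integrins placed uniformly at random on distinct
sites, all inactive. Each 10 ms sweep updates every integrin once in a
freshly shuffled order: at most one reaction event is sampled from the
integrin's eligible channels (INACTIVE: activate; ACTIVE: inactivate or bind;
BOUND: unbind, or associate if a BOUND/ASSOCIATED 4-neighbour exists;
ASSOCIATED: disassociate); if no event fired and the integrin is not
associated, it attempts one diffusion hop to a uniformly chosen 4-neighbour,
rejected if the target is occupied (hard-core exclusion — one integrin per
site, required for adjacency-based association to be meaningful). Bound but
unassociated integrins diffuse carrying their bound state; ligands are
uniform, so one is always available at the destination.

The state ladder INACTIVE ↔ ACTIVE ↔ BOUND ↔ ASSOCIATED admits only
adjacent-rung transitions: a bound integrin cannot deactivate without
unbinding, an associated integrin cannot unbind or move without
disassociating. Association nucleates pairwise: a bound integrin that fires
the association channel becomes associated and, if none of its neighbours is
yet associated, recruits one uniformly chosen bound neighbour, so clusters
are always lattice-connected sets of size ≥ 2. After every sweep an orphan
cleanup (iterated to a fixed point) demotes associated integrins left
without an associated neighbour back to bound.

Diffusion is one hop attempt per sweep for every non-associated integrin (no
diffusion coefficient is prescribed by the model; the hop attempt rate is the
natural lattice unit and is configurable via `diffusion_enabled`).

The inner loop is JIT-compiled (numba) and consumes a single seeded
`numpy.random.Generator`, so runs are bit-reproducible from (config, seed)
and ~10⁴ sweeps of 1000 integrins take about a second on one core.

**Equilibrium detection.** A run is declared equilibrated when the
least-squares slope of the associated count over the trailing 5000 sweeps
falls below 10⁻³ (relative change per 1000 sweeps). Runs that exhaust
`max_steps` (default 2 × 10⁵) without passing are flagged, never silently
accepted. The associated count turns stationary within ~10⁴ sweeps, but the
cluster-size distribution keeps ripening far longer (evaporation–condensation
through the slow disassociation channel, k_c− ≈ 2 × 10⁻³ s⁻¹), and a finite
system's true size-distribution equilibrium lies beyond any practical run.
The scenario sweep therefore compares conditions at equal simulated time:
`sweep_fig5` fixes `min_steps = max_steps` (2 × 10⁵ sweeps = 2000 s) so every
condition experiences the same ripening time, with the stationarity flag
still recorded per replicate.

## Cluster statistics

An FA is a 4-connected cluster of associated integrins on the periodic
lattice (components are merged across the wrap seams, so a seam-spanning
cluster is counted once); its area is its integrin count. Two outputs:
`n_clustered`, the number of integrins in clusters, and
`mean_fa_area_top10`, the mean size of the ⌈0.10·n_clusters⌉ largest
clusters (ceiling, so a nonempty cluster set always contributes at least one;
ties are broken by stable order and cannot change the mean). The labelling is
verified exactly against a brute-force periodic flood fill.

The sweep runs every (scenario, pore size ∈ {20, 50, 75, 100, 150 nm} ∪
{flat}, replicate) combination with replicate seeds `base_seed + replicate`,
and reports per-replicate rows plus mean ± s.e. aggregates. Replicate counts
and error bars are a choice of this package (10 replicates for trend tests),
made for statistical interpretability.

## Morphometry

Feature sizes of binary images are local widths: each regional maximum of the
Euclidean distance transform of the foreground contributes one feature of
size twice its distance value (the largest inscribed-disc diameter), the same
idea as ImageJ local thickness. This works on bicontinuous phases where
connected-component sizing would collapse to one number; on a disc array it
returns the disc diameter to within a pixel. The reported s.e.m. is the
sample standard deviation over features divided by √n. On the binarized 20 nm
Cahn–Hilliard field, local-width sizing and the spectral characteristic
length agree within 25% — they are different definitions of "pore size" and
exact agreement is not expected.

Circularity is 4πA/L² computed from exact area and perimeter supplied by the
caller (1 for a circle, π/4 for a square, scale invariant); a separate
pixel-mask estimator is provided but flagged approximate, since digitised
perimeters are biased by a few percent. The pore–ligament relation is an
ordinary least-squares fit of ligament size on pore size; on the five
packaged mean size pairs it gives slope ≈ 1.082 and R² ≈ 0.9957. (A fit on
the underlying per-feature measurements, which are not available, would
differ slightly.)

## What the synthetic data does and does not emulate

The Cahn–Hilliard fields reproduce the two-phase, single-length-scale
geometry of NPG but not dealloying chemistry, surface curvature distributions
of a 3-D sponge projected to 2-D, or SEM imaging artefacts; morphometry
results on them validate the estimators, not any instrument. The lattice
model abstracts integrins as lattice tokens: no force-dependent (catch-bond)
kinetics, no explicit adaptor proteins, no membrane mechanics, no inside-out
regulation of E_a. Passing tests demonstrate internal consistency of the
model and reproduction of its closed-form limits and qualitative pore-size
trends — not agreement with any particular wet-lab measurement.

## Numerical choices and degenerate inputs

- Semi-implicit spectral Cahn–Hilliard: free energy is checked non-increasing
  to 10⁻⁸ per step; divergence (|c − 0.5| > 10) raises an error naming dt_ch.
- Uniform fields are fixed points of the dynamics and raise on
  characteristic-length queries.
- Zero integrins: an empty, immediately equilibrated trajectory.
- Empty cluster sets: zeroed summary with an explicit `empty` flag.
- Probability-sum guard: any state whose channel probabilities could exceed 1
  raises at initialisation with a message naming dt.
- Problem sizes for validation runs were chosen to keep every check cheap on
  one core: 2 × 10⁵ sweeps for closed-form recovery (sampling error on the
  recovered E_a ≈ 0.01 kT), 3 × 10⁴ sweeps for scenario comparisons that only
  involve the (fast-equilibrating) clustered-integrin count, 2 × 10⁵ for
  comparisons involving the slowly ripening FA area.

## Known limitations

- Association is a contact reaction with a pairwise nucleation rule; other
  microscopic schemes (neighbour-count-dependent rates, bond-per-edge models)
  are plausible and would shift absolute cluster numbers, though not the
  monotone dependence on E_b and E_c.
- The FA-area statistic depends on ripening time; only equal-time comparisons
  between conditions are meaningful, and the sweep enforces that.
- `field` mode ties the substrate length scale to the 60 nm site spacing;
  pores much smaller than a site average out to an effective concentration
  rather than an explicit geometry.
- 2-D substrate fields only; no 3-D porosity, no dealloying kinetics, no
  surface-potential (hyperpolarisation) effects.
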