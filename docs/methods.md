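# Methods

This note records the model, its parameters, the numerical choices, and
what the synthetic data can and cannot show. Units throughout: length in
μm, drug kinetics in days and nM, oxygen transport in seconds and mmHg.

## Blood flow and haematocrit

Blood is a one-dimensional continuum. Each vessel segment obeys
Poiseuille's law with conductance `G = π d⁴ / (128 μ_app L)` for a
circular lumen and `G = π a³b³ / (4 μ_app L (a² + b²))` for a compressed
(elliptical) lumen. The apparent viscosity is the empirical in-vitro
law: `μ_rel = 1 + (μ*₄₅ − 1)·[(1−H)^C − 1]/[0.55^C − 1]` with the
standard diameter-dependent `μ*₄₅(d)` and shape exponent `C(d)`; it is
kept in one small coefficient block so an alternative parameterisation
can be swapped in. Pressures solve the nodal Kirchhoff system with an
arbitrary inlet pressure and zero at the outlet; because there is a
single inlet and a single outlet, the haematocrit distribution is
invariant to the inlet pressure (verified as a test).

**Phase separation.** At a diverging bifurcation the fractional
red-blood-cell flux into a daughter follows the empirical logit law with
coefficients

    A  = −13.29 · (d₁² − d₂²)/(d₁² + d₂²) · (1 − H)/d_p
    B  = 1 + 6.98 (1 − H)/d_p
    X₀ = 0.964 (1 − H)/d_p

(diameters in μm, H the feeding discharge haematocrit). Daughters below
the flow fraction X₀ receive pure plasma. Red-cell flux is conserved
exactly; a daughter haematocrit that would exceed 1 is capped with the
overflow rerouted to its sibling.

**Compression.** Two effects, both switchable:

* *Geometry.* A compressed vessel is an ellipse with aspect ratio 4.26.
  The default deformation convention is **perimeter-preserving**: the
  endothelial wall is treated as inextensible, so squeezing flattens the
  cross section and reduces lumen area (for 4.26 the area falls to ~51%
  and conductance to ~12% of the circular value). The alternative
  **area-preserving** convention (`BloodModelParams.compression_geometry
  = "area"`, conductance 44%) is provided; the perimeter convention was
  adopted as the mechanically natural reading of wall deformation and
  because lumen loss is what makes compressed vessels a meaningful
  transport barrier.
* *Partitioning.* Bifurcations fed by a compressed vessel use an
  amplified logit slope, `B → B(1 + g(1 − H))` with gain g = 1 by
  default. This is a deliberately simple, haematocrit-dependent hook
  emulating the stronger cell–plasma separation observed downstream of
  squeezed lumens (the bias is strongest at low haematocrit and vanishes
  at g = 0, which restores the standard law exactly).

**Coupling.** Viscosity depends on haematocrit and partitioning on flow,
so the solver alternates pressure solves with downstream haematocrit
propagation (topological order of the flow-directed graph; flux-weighted
mixing at converging nodes), under-relaxed with factor 0.3, until the
max per-vessel haematocrit change is below 1e-6 (at most 1000 outer
iterations; non-convergence raises with the residual history). Vessels
with |Q| < 1e-12 × mean|Q| are flagged unperfused, carry H = 0 and are
excluded from transport sources. If a transient flow-direction cycle
appears mid-coupling, propagation falls back to iterative sweeps instead
of a topological sort.

## Tissue transport

The tissue is a uniform raster (default cell 10 μm, below the smallest
vessel diameter of 15 μm) with zero-flux outer boundaries; analysis
masks exclude the boundary-affected rim, so the boundary condition
choice is immaterial to reported metrics. Vessels enter as line sources:

    oxygen   D_O2 ∇²C + π d γ (β_ref H_l/H_ref − C) δ − κ C = 0
    drug     D ∇²C + π d P (C_plasma − C/ε) δ − k_eff C = 0

Both problems are linear; they are assembled as sparse 5-point systems
and solved by direct factorisation. The matrix depends only on source
geometry — not on haematocrit or plasma concentration — so sweeps over
inlet haematocrit or time reuse one factorisation with new right-hand
sides, and the time sweep additionally exploits the exact linearity of
the drug field in C_plasma (one solve, rescaled per time point).

**Source regularisation.** The default rasterisation spreads each
vessel's exchange uniformly over the cells covered by its lumen
footprint (a rectangle of width d), encoded as equivalent lengths that
still sum to the vessel length. A pure axis-line kernel is available
(`mode="line"`), but for the drug problem — whose wall conductance is
comparable to the diffusive capacity near the vessel — the line kernel's
self-field is log-divergent under refinement and does not converge to
the finite-radius solution; the footprint kernel does. Against the
exact single-vessel solution the footprint scheme is accurate to <1%
for oxygen at 4 μm cells and <0.5% for the drug at 1 μm cells (the drug
penetration depth √(D/k_eff) ≈ 23.5 μm sets the resolution demand);
at the production 10 μm grid, near-vessel values are grid-regularised
and all metrics are computed on the same grid for both variants.

**Exact single-vessel solutions.** Two closed forms ship with the
package. The *planar* geometry — the vessel lying in the 2D tissue
plane, which is what the solver discretises — has a piecewise
cosh/exponential profile across the vessel with continuity of value and
flux at the lumen edge and zero flux at the domain edge; this is the
oracle the solvers are validated against. The classical *cylindrical*
geometry (modified-Bessel K₀ exterior with a Robin wall condition) is
also provided for cross-sectional analyses; it is checked against an
independent radial finite-difference solve in the tests rather than
against the planar solver, because the two geometries genuinely differ.

**Full drug model.** The three coupled fields (free, bound,
internalised) form a stiff linear system; it is integrated with a
θ-scheme (θ = 0.55, slightly dissipative to damp the fast binding modes)
on a geometrically growing step ladder from 2e-5 to 0.02 day, one sparse
LU per distinct step size. Mass bookkeeping (free + bound +
internalised vs cumulative extravasation) closes to the trapezoidal
accumulation accuracy and is reported per output time. On the
single-vessel fixture the quasi-steady reduction matches the full model
to ~3% mean from 1 day onwards and diverges strongly (>20%) at 0.05 day,
which is the expected domain of validity of the reduction.

## Pharmacokinetic parameters

Printed, directly adopted: `C_plasma(t) = 810·e^(−0.2105 t)` nM;
`t_on = ε/(k_on C_r) = 7.68e-4` day; `t_off = 1/k_off = 7.82e-5` day;
`t_int = 1/k_int = 1.32e-2` day. Transport constants are fixed uniquely
by the characteristic-timescale ranges over the network geometry
(h ∈ [100, 1000] μm, d ∈ [15, 110] μm): `D = 4233.6 μm²/day`
(0.049 μm²/s, t_diff 2.36–236 day) and `P = 241.92 μm/day` (2.8e-3 μm/s,
t_ev 0.12–87.7 day). Only the combination k_on·C_r/ε enters any
computed quantity; its split into ε = 0.24 (antibody-accessible void
fraction), C_r = 100 nM and k_on = 3.125 /(nM·day) follows typical
antibody-in-tumour values. The resulting effective uptake rate is
`k_eff = 7.67 /day` (t_eff = 0.13 day), and the slow/fast timescale
separation that justifies the reduction holds with a factor ≈9 even at
the worst corner of the (h, d) rectangle (largest vessel at the smallest
gap) and >100 elsewhere.

## Oxygen parameters

`D_O2 = 2410 μm²/s` is the standard tissue value. The remaining three
constants are effective, network-scale parameters chosen once:
`β_ref = 40 mmHg` (intravascular pO2 at the reference discharge
haematocrit 0.45 — arteriolar scale), `κ = 0.12 /s` (oxygen consumption
giving a diffusion distance √(D/κ) ≈ 142 μm, within the 100–200 μm
range of observed oxygen penetration around tumour microvessels), and
`γ = 0.2 μm/s` (effective wall transfer velocity, set so that at 30%
inlet haematocrit the uncompressed core operates at a mean pO2 of
~11 mmHg — the physiological tumour-adjacent scale that places typical
tissue near the 8 mmHg hypoxia threshold, where compression-induced
haematocrit changes are consequential). All four live in
`microperf/data/parameters.yaml` with per-entry units.

## Synthetic networks

The generator emulates the summary statistics of mesh-grown tumour
vasculature rather than any particular growth algorithm: a jittered
honeycomb lattice (edge 300 μm, jitter 0.25) cropped to the domain, a
single-vessel inlet trunk at the bottom-left corner and outlet trunk at
the top-right, dead-end chains removed. Diameters come from a
unit-conductance potential flow between the terminals with ±10%
conductance noise (which also breaks lattice symmetries that could
otherwise produce zero-flow vessels): `d = d_max (Q/Q_max)^(1/3)`
floored at 15 μm, so d³ is proportional to flow and Murray's law holds
exactly at every junction not touched by the floor (median junction
residual ~1e-14; >90% of junctions within 30% even counting floored
branches). Empirical inter-vessel gaps fall in 100–1000 μm for ≥95% of
sampled tissue points. One integer seed drives the two random draws in
a documented order (node jitter, then conductance noise), making
generated networks byte-identical across runs.

What the generator does **not** emulate: dendritic/hierarchical
branching morphology, avascular pockets from 2D growth limits (a
configurable future extension; the honeycomb perfuses the domain fairly
evenly), vessel tortuosity, and leakiness. Consequently the absolute
tissue fractions this package computes depend on the synthetic
substrate; the meaningful outputs are the *differences and orderings*
between the compressed and uncompressed variants on the same network,
which are stable across seeds. The directions — higher core hypoxia,
lower efficacious fraction with the loss appearing as
drug-sufficient-but-hypoxic tissue, weaker drug–oxygen spatial
correlation under compression — are asserted in the test suite at full
scale.

## Analysis conventions

* Core = cells within 1000 μm of the domain centre (vessels are core if
  both endpoints are within that radius, boundary inclusive); periphery
  = equal-area annulus with outer radius √2 × 1000 μm; tissue beyond is
  excluded as boundary-affected.
* Classification inequalities are strict; a cell exactly at a threshold
  counts as insufficient (measure-zero at float precision).
* Overlap-index maxima are taken over the analysed region (core mask) so
  boundary-affected cells cannot set the normalisation.
* Moran's I uses row-standardised queen (8-neighbour) raster weights;
  the reported statistic is the symmetric average of the two lag
  directions. Both choices are exposed as arguments.
* The t test is the classical pooled-variance Student's t (Welch via
  flag). Per-cell samples are spatially autocorrelated, which inflates
  nominal significance; this is reported as-is, not corrected.
* Default drug evaluation time is 1 day after the bolus — the earliest
  time at which the quasi-steady reduction is accurate.

## Problem sizes

Production runs use the 5000 μm domain at a 10 μm grid (250k unknowns
per steady solve; a two-variant comparison takes ~10 s on one core).
Unit and property tests use smaller domains (200–3000 μm) and the
single-vessel fixture; the full-scale two-variant comparison runs once,
shared across the direction assertions in the test suite.

## Known limitations

* 2D tissue transport overestimates hypoxia relative to 3D (no
  contribution from out-of-plane vessels); trends, not absolute
  fractions, are the robust output.
* The compressed-bifurcation partitioning gain is a phenomenological
  one-parameter hook, not a fitted law.
* Oxygen saturation dynamics (haemoglobin binding kinetics) are
  deliberately omitted; the intravascular oxygen level is proportional
  to discharge haematocrit.
* The quasi-steady drug model is invalid in the first hours after a
  bolus and for extreme large-vessel/small-gap configurations; both
  regimes are excluded by the defaults and flagged by
  `compute_timescales`.
* Receptor concentration is fixed (no target-mediated depletion), and
  plasma decay is single-exponential.
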