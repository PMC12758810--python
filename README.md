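# microperf

Coupled microvascular blood flow, oxygen and drug transport in 2D tumour
tissue — quantifying how tumour-induced vessel compression degrades the
spatial overlap between regions with *sufficient oxygen* and regions with
*sufficient drug*.

## The problem

Some anti-cancer drugs need oxygen to act. Trastuzumab emtansine (T-DM1),
an antibody–drug conjugate for HER2+ breast cancer, loses cytotoxicity
under hypoxia because its internalisation is impaired. Oxygen rides on
red blood cells; the drug rides in plasma. In a tumour, compressed
vessels perturb red-blood-cell partitioning at bifurcations and starve
parts of the tissue of oxygen *without* correspondingly changing drug
delivery — so "enough drug" and "enough oxygen" can stop overlapping.
`microperf` simulates this mechanism end to end, for researchers studying
tumour perfusion, hypoxia and pharmacokinetic barriers to therapy.

## The model

On a planar vascular network (single inlet, single outlet):

1. **Blood flow.** Poiseuille's law per segment with the empirical
   in-vitro apparent-viscosity law μ_rel(d, H_d) (Fåhraeus–Lindqvist
   effect) and Kirchhoff conservation at nodes. Red blood cells
   partition at diverging bifurcations by the empirical logit law
   logit F_rbc = A + B·logit[(x−X₀)/(1−2X₀)], with plasma skimming below
   the threshold X₀. Compressed vessels (core region, aspect ratio 4.26,
   perimeter-preserving elliptical lumen) have reduced conductance and an
   amplified partitioning nonlinearity. Flow and haematocrit are coupled
   through viscosity and solved to a fixed point.
2. **Oxygen** (steady reaction–diffusion, vessels as line sources):
   `D_O2 ∇²C + π d γ (β_ref H_l/0.45 − C) δ_network − κ C = 0`, in mmHg.
3. **Drug** (three phases: free C, bound B, internalised I). Because
   binding/unbinding/internalisation (minutes) are far faster than
   diffusion, extravasation and plasma decay (days), the full model
   reduces to a quasi-steady equation for the free drug:
   `0 = D ∇²C + π d P (C_plasma(t) − C/ε) δ_network − k_eff C`, with
   `C_plasma(t) = 810 e^(−0.2105 t) nM` and
   `k_eff = t_off / (t_on (t_off + t_int))`. The full time-dependent
   model is also implemented and used to validate the reduction
   (agreement within a few percent from 1 day after the bolus).
4. **Efficacy metrics.** Each tissue cell is classified against the
   hypoxia threshold (8 mmHg) and the drug IC50 (2.9 or 6.8 nM); the
   package reports class fractions in a core disk (radius 1000 μm) and an
   equal-area periphery annulus, the overlap index
   `O = C·C_O2 / (max C · max C_O2)`, bivariate Moran's I of the two
   fields, and a two-sample t test between variants.

A built-in generator produces synthetic networks with the target summary
statistics (5000 × 5000 μm domain, diameters 15–110 μm assigned so that
d³ ∝ flow — Murray's law — inter-vessel gaps 100–1000 μm, no dead ends),
so the whole pipeline runs without external data.

## Worked example

```python
from microperf import ExperimentConfig, compare_variants

cfg = ExperimentConfig(seed=1)          # 5000 um domain, 10 um grid
results = compare_variants(cfg)         # same network, +/- compression
for variant, res in results.items():
    m = res.metrics
    print(f"{variant}:")
    print(f"  core hypoxic fraction   {m['hypoxic_fraction_core']:.3f}")
    print(f"  core mean pO2 (mmHg)    {m['mean_o2_core']:.2f}")
    print(f"  efficacious fraction    {m['class1_core']:.3f}")
    print(f"  bivariate Morans I      {m['morans_I_core']:.3f}")
```

prints

```
core_compressed:
  core hypoxic fraction   0.405
  core mean pO2 (mmHg)    9.15
  efficacious fraction    0.556
  bivariate Morans I      0.665
core_uncompressed:
  core hypoxic fraction   0.150
  core mean pO2 (mmHg)    10.90
  efficacious fraction    0.699
  bivariate Morans I      0.796
```

Compressing the core vessels raises the hypoxic fraction of the core
from 15% to 40%, cuts the fraction of tissue with *both* sufficient drug
and sufficient oxygen ("efficacious fraction", class 1) from 70% to 56%,
and weakens the spatial correlation between the two fields — while drug
sufficiency itself barely changes: the efficacy loss is oxygen-driven.

The same experiments are scriptable from a shell:

```sh
microperf generate-network --seed 1 --out net.txt
microperf flow net.txt --out flow.csv
microperf run-all --seed 1 --both-variants --out runs/
microperf sweep-h --seed 1 --out sweep_h.csv      # inlet haematocrit 5-30%
microperf sweep-time --seed 1 --out sweep_t.csv   # 0-21 days after bolus
```

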