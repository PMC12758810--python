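# Default transport and kinetic constants for the coupled oxygen / T-DM1
# tissue transport model.  Canonical units: length um, time day for drug
# kinetics, time s for oxygen transport, concentrations nM (drug) and
# mmHg (oxygen).  Each entry records its unit; loaders check the tag.
#
# Drug constants describe trastuzumab emtansine (T-DM1), a ~150 kDa
# antibody-drug conjugate: slow interstitial diffusion, low vessel-wall
# permeability, fast HER2 binding/unbinding and receptor-mediated
# internalisation, and first-order depletion from plasma after a bolus.
drug:
  D:                {value: 4233.6,    units: um^2/day, note: free-drug diffusivity in tissue (0.049 um^2/s)}
  P:                {value: 241.92,    units: um/day,   note: trans-endothelial permeability (2.8e-3 um/s)}
  epsilon:          {value: 0.24,      units: "1",      note: effective interstitial void fraction accessible to antibody}
  C_r:              {value: 100.0,     units: nM,       note: HER2 receptor concentration, held fixed}
  k_on:             {value: 3.125,     units: 1/(nM day), note: association rate; epsilon/(k_on*C_r) = 7.68e-4 day}
  k_off:            {value: 12787.723785166240, units: 1/day, note: dissociation rate; 1/k_off = 7.82e-5 day}
  k_int:            {value: 75.75757575757576,  units: 1/day, note: internalisation rate; 1/k_int = 1.32e-2 day}
  C_plasma_initial: {value: 810.0,     units: nM,       note: plasma concentration immediately after bolus}
  b:                {value: 0.2105,    units: 1/day,    note: exponential plasma decay rate}

# Oxygen constants: line-source exchange between vessel lumen and tissue,
# linear consumption.  The vessel-side oxygen level is proportional to the
# local discharge haematocrit, beta_ref * H_l / H_ref, i.e. beta_ref is the
# intravascular oxygen partial pressure at the reference haematocrit 0.45.
oxygen:
  D_O2:     {value: 2410.0, units: um^2/s, note: oxygen diffusivity in tissue}
  gamma:    {value: 0.2,    units: um/s,   note: effective vessel-wall oxygen transfer velocity}
  beta_ref: {value: 40.0,   units: mmHg,   note: intravascular pO2 at reference haematocrit}
  H_ref:    {value: 0.45,   units: "1",    note: reference discharge haematocrit}
  kappa:    {value: 0.12,   units: 1/s,    note: first-order tissue oxygen consumption rate; diffusion distance sqrt(D/kappa) ~ 142 um}
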