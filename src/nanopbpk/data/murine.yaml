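# Synthetic murine default parameter set for the nanoparticle PBPK models.
#
# All values are order-of-magnitude realistic for a ~25 g mouse and are the
# package's documented defaults (see docs/methods.md for the rationale behind
# each choice).  Every block declares its units explicitly; the loader refuses
# files without unit annotations.
schema_version: 1
species: mouse

units:
  Q: L/min          # organ blood flow
  V: L              # all volumes
  K: 1/s            # all first-order rate constants
  weight: g         # organ wet weight
  length: m         # diameters / layer thicknesses
  diameter: nm      # nanoparticle diameter
  T: K
  eta: Pa.s
  dose: mol

systemic:
  V_total: 2.146e-3        # total murine blood volume (2146 uL)
  K_deg_vein: 2.0e-5
  K_deg_art: 2.0e-5
  dose: 1.0e-9             # injected bolus, placed in the vein at t = 0

# Per-organ physiology.  Q is the systemic (parallel-branch) flow; in the
# model-B wiring the lung is perfused in series by the full cardiac output,
# which is computed as the sum of the systemic flows of the other organs.
organs:
  lung:   {Q: 2.0e-3,  V_bl: 5.2e-5, V_T: 3.0e-5, weight: 0.15,
           K_NS: 4.0e-3, K_up: 8.0e-3, K_deg: 1.0e-4}
  heart:  {Q: 2.8e-4,  V_bl: 9.0e-6, V_T: 3.0e-5, weight: 0.15,
           K_NS: 5.0e-4, K_up: 2.0e-3, K_deg: 5.0e-5}
  kidney: {Q: 2.6e-3,  V_bl: 3.4e-5, V_T: 8.0e-5, weight: 0.40,
           K_NS: 2.0e-3, K_up: 5.0e-3, K_deg: 2.0e-4}
  liver:  {Q: 7.0e-4,  V_bl: 1.1e-4, V_T: 2.6e-4, weight: 1.30,
           K_NS: 3.0e-3, K_up: 8.0e-3, K_deg: 2.0e-4}
  spleen: {Q: 9.0e-5,  V_bl: 8.0e-6, V_T: 2.0e-5, weight: 0.10,
           K_NS: 1.5e-3, K_up: 5.0e-3, K_deg: 1.0e-4}
  gut:    {Q: 1.5e-3,  V_bl: 5.0e-5, V_T: 5.0e-4, weight: 2.50,
           K_NS: 2.0e-3, K_up: 4.0e-3, K_deg: 1.0e-4}
  other:  {Q: 8.0e-3,  V_bl: 5.0e-4, V_T: 4.0e-3, weight: 20.0,
           K_NS: 1.0e-3, K_up: 3.0e-3, K_deg: 5.0e-5}

# Endothelial-layer geometry; V_EC per organ is derived at load time as
# V_EC = phi_EC * V_T * l_NC_b / D_EC.
endothelium:
  phi_EC: 0.3              # endothelial volume fraction of target tissue
  D_EC: 5.0e-6             # endothelial cell diameter (m)
  l_NC_b: 5.0e-8           # binding-competent receptor layer height (m)

nanoparticle:
  diameter: 100.0          # nm
  n_antibodies: 162
  T: 310.0                 # K
  eta: 1.2e-3              # plasma viscosity, Pa.s
  l_glyco: 5.0e-7          # glycocalyx thickness (m)

# log10(K_EC) as a linear function of particle diameter, anchored at the
# 800 nm Monte-Carlo point; per-organ anchors express organ-specific ICAM-1
# surface density.
kec_relation:
  slope: 5.0e-3            # d log10(K_EC) / d diameter (1/nm)
  anchor_diameter: 800.0   # nm
  anchor_logKec: 9.0       # default anchor
  log_base: 10
  per_organ_anchor:
    lung: 9.5
    heart: 8.5
    kidney: 8.8
    liver: 9.2
    spleen: 8.6
    gut: 8.7
    other: 8.4

# Steady-state (%ID/g) model fixture.  Association constants are effective
# model-unit values (synthetic; chosen once so %ID/g lands in the 1-100
# range typical of targeted nanoparticle biodistribution), one per membrane
# condition per organ at the reference antibody density of 100; K_EC scales
# linearly with antibody count.
steady_state:
  kappa_p: 0.05            # non-specific binding coefficient
  phi_EC: 0.3
  D_EC: 5.0e-6             # m
  D_M: 2.1e-5              # macrophage diameter (m)
  L_EC_b: 5.0e-8           # m
  L_M_b: 5.0e-8            # m
  L_cap: 5.0e-6            # capillary cell-free layer (m)
  C_out: 1.0e-6            # injected NP concentration (mol/L)
  antibody_reference: 100
  antibody_exponent: 1.0
  conditions:
    flat:
      phi_M: 0.0
      K_M: 0.0
      K_EC: {lung: 2.0e-5, heart: 6.0e-6, kidney: 1.0e-5, liver: 1.5e-5, spleen: 8.0e-6}
    membrane:
      phi_M: 0.0
      K_M: 0.0
      K_EC: {lung: 4.0e-5, heart: 1.2e-5, kidney: 2.0e-5, liver: 3.0e-5, spleen: 1.6e-5}
    membrane_macrophages:
      phi_M: 0.05
      K_M: 1.0e-5
      K_EC: {lung: 4.0e-5, heart: 1.2e-5, kidney: 2.0e-5, liver: 3.0e-5, spleen: 1.6e-5}
    membrane_active_macrophages:
      phi_M: 0.05
      K_M: 3.0e-5
      K_EC: {lung: 4.0e-5, heart: 1.2e-5, kidney: 2.0e-5, liver: 3.0e-5, spleen: 1.6e-5}

# Branching-element geometry (murine main artery down to red-blood-cell size).
vascular_tree:
  d0: 600.0                # um
  d_min: 15.0              # um
  k: 3.0
  beta: 3.0
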