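# Reference DEB parameter set for Laternula elliptica.
# All rate parameters refer to the reference temperature T_ref = 273.15 K.
# Units: energies J, lengths cm, masses g AFDW, times d, temperatures K.

p_Am      = 87.752    # maximum surface-area-specific assimilation rate, J d-1 cm-2
p_M       = 6.861     # volume-specific somatic maintenance rate, J d-1 cm-3
E_G       = 2371      # volume-specific cost of structure, J cm-3
kappa     = 0.659     # fraction of mobilised energy allocated to soma, -
v         = 0.023     # energy conductance, cm d-1
k_J       = 0.001     # maturity maintenance rate coefficient, d-1
E_Hb      = 3.371     # maturity at birth (onset of feeding), J
E_Hp      = 2116      # maturity at puberty (first gametogenesis), J
delta_M   = 0.341     # post-metamorphic shape coefficient, -
delta_M_lrv = 7.227   # pre-metamorphic (D-larva) shape coefficient, -
d_V       = 0.09      # density of structure, g cm-3
rho_E     = 4.35e-5   # weight-energy coupler for reserve, g J-1
w_E       = 23.9      # molar weight of reserve, g mol-1
mu_E      = 550       # chemical potential of reserve, kJ mol-1
kappa_R   = 0.95      # reproduction efficiency, -

# Arrhenius temperature sensitivity (lower-boundary three-parameter form)
T_A       = 4832      # Arrhenius temperature, K
T_AL      = 19966     # Arrhenius temperature at the lower boundary, K
T_L       = 271       # lower boundary temperature, K
T_ref     = 273.15    # reference temperature, K

# Population-level scaled functional responses (site annotations)
f_MC      = 0.332     # Marian Cove
f_PC      = 0.384     # Potter Cove
f_R       = 0.8       # Rothera
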