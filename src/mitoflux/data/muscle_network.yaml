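# Default one-compartment skeletal-muscle carbon network for dynamic
# 13C mass-isotopomer modeling of a [2-13C]acetate infusion.
#
# Atom-map convention: letters in parentheses name carbons in molecule
# order (C1 first).  Citrate synthase follows the standard map
# oaa (abcd) + accoa (ef) -> cit (dcbfea), so that on the first turn the
# acetyl methyl carbon (acetate C2) arrives at alpha-ketoglutarate C4 and
# the CO2 released at isocitrate dehydrogenase derives from OAA C1.
# Succinate and fumarate are symmetric: the simulator averages the two
# carbon orientations 50/50 at formation.
#
# Pool sizes are literature-scale defaults in umol/g wet weight; they are
# configuration parameters, not fitted.  Fluxes are in umol/g/sec; the
# free parameters are F_TCA (TCA cycle flux), F_X (2-oxoglutarate <->
# glutamate exchange) and F_ASPX (OAA <-> aspartate exchange); every other
# flux is derived from them by the steady-state balance expressions below.
# Transporter Vmax values are calibrated at build time so the
# Michaelis-Menten rate at the stated concentrations equals the
# steady-state flux.
name: muscle-default
metabolites:
  - {name: glc_ext, carbons: 6, extracellular: true}
  - {name: ace_ext, carbons: 2, extracellular: true,
     enrichment: [0.0, tracer]}          # [2-13C]acetate: C2 labeled
  - {name: co2, carbons: 1, extracellular: true}   # unlabeled sink/source
  - {name: oaa_sink, carbons: 4, extracellular: true}  # cataplerotic efflux
  - {name: glc, carbons: 6, pool: 2.0}
  - {name: pyr, carbons: 3, pool: 0.1}
  - {name: ace, carbons: 2, pool: 0.2}
  - {name: accoa, carbons: 2, pool: 0.02}
  - {name: cit, carbons: 6, pool: 0.3}
  - {name: akg, carbons: 5, pool: 0.2}
  - {name: succoa, carbons: 4, pool: 0.05}
  - {name: suc, carbons: 4, pool: 0.3, symmetric: true}
  - {name: fum, carbons: 4, pool: 0.1, symmetric: true}
  - {name: mal, carbons: 4, pool: 0.3}
  - {name: oaa, carbons: 4, pool: 0.05}
  - {name: glu, carbons: 5, pool: 2.0}
  - {name: asp, carbons: 4, pool: 0.5}
  - {name: ana_src, carbons: 4, extracellular: true}  # unlabeled anaplerotic source

parameters:
  F_TCA: 0.018      # TCA cycle flux (citrate synthase), free / fitted
  F_X: 0.06         # akg <-> glu exchange flux, free / fitted
  F_ASPX: 0.02      # oaa <-> asp exchange flux, fixed config value

flux_exprs:
  F_ACS: "0.25 * F_TCA"            # acetate contribution to acetyl-CoA
  F_PDH: "F_TCA - F_ACS"
  F_PC: "0.05 * F_TCA"             # pyruvate carboxylase
  F_ME: "F_PC"                     # malic enzyme balances PC recycling
  F_GLY: "0.5 * (F_PDH + F_PC - F_ME)"
  F_ANA: "0.05 * F_TCA"            # anaplerosis at succinyl-CoA
  F_CATA: "F_ANA"                  # balancing OAA efflux
  F_SCS: "F_TCA + F_ANA"
  F_SDH: "F_SCS"
  F_FUMASE: "F_SCS"
  F_MDH: "F_SCS - F_ME"

reactions:
  - name: glut4
    equation: "glc_ext (abcdef) -> glc (abcdef)"
    flux: F_GLY
    pathway: transport
    kinetics: {type: michaelis_menten_transport, km: 5.0, s_out: 8.0, s_in: 1.0,
               reversible: true}
  - name: glycolysis
    equation: "glc (abcdef) -> pyr (cba) + pyr (def)"
    flux: F_GLY
    pathway: glycolysis
  - name: mct
    equation: "ace_ext (ab) -> ace (ab)"
    flux: F_ACS
    pathway: transport
    kinetics: {type: michaelis_menten_transport, km: 2.0, s_out: 1.0, s_in: 0.2,
               reversible: false}
  - name: acs
    equation: "ace (ab) -> accoa (ab)"
    flux: F_ACS
    pathway: acetyl_coa_synthetase
  - name: pdh
    equation: "pyr (abc) -> accoa (bc) + co2 (a)"
    flux: F_PDH
    pathway: glycolysis
  - name: citrate_synthase
    equation: "oaa (abcd) + accoa (ef) -> cit (dcbfea)"
    flux: F_TCA
    pathway: tca_cycle
  - name: idh
    equation: "cit (abcdef) -> akg (abcde) + co2 (f)"
    flux: F_TCA
    pathway: tca_cycle
  - name: akgdh
    equation: "akg (abcde) -> succoa (bcde) + co2 (a)"
    flux: F_TCA
    pathway: tca_cycle
  - name: scs
    equation: "succoa (abcd) -> suc (abcd)"
    flux: F_SCS
    pathway: tca_cycle
  - name: sdh
    equation: "suc (abcd) -> fum (abcd)"
    flux: F_SDH
    pathway: tca_cycle
  - name: fumarase
    equation: "fum (abcd) -> mal (abcd)"
    flux: F_FUMASE
    pathway: tca_cycle
  - name: mdh
    equation: "mal (abcd) -> oaa (abcd)"
    flux: F_MDH
    pathway: tca_cycle
  - name: pc
    equation: "pyr (abc) + co2 (d) -> oaa (abcd)"
    flux: F_PC
    pathway: pyruvate_carboxylase
  - name: malic_enzyme
    equation: "mal (abcd) -> pyr (abc) + co2 (d)"
    flux: F_ME
    pathway: malic_enzyme
  - name: akg_to_glu
    equation: "akg (abcde) -> glu (abcde)"
    flux: F_X
    pathway: exchange
  - name: glu_to_akg
    equation: "glu (abcde) -> akg (abcde)"
    flux: F_X
    pathway: exchange
  - name: oaa_to_asp
    equation: "oaa (abcd) -> asp (abcd)"
    flux: F_ASPX
    pathway: exchange
  - name: asp_to_oaa
    equation: "asp (abcd) -> oaa (abcd)"
    flux: F_ASPX
    pathway: exchange
  - name: anaplerosis_succoa
    equation: "ana_src (abcd) -> succoa (abcd)"
    flux: F_ANA
    pathway: anaplerosis
  - name: cataplerosis
    equation: "oaa (abcd) -> oaa_sink (abcd)"
    flux: F_CATA
    pathway: anaplerosis
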