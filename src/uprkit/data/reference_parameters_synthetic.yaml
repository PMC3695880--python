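# Reference parameterisation of the UPR model (arbitrary units: acu, atu).
#
# SYNTHETIC RECONSTRUCTION: these values were calibrated by the package
# authors against the model's qualitative design targets -- fast
# protein-protein kinetics versus slow genetic regulation, a 3-4x BiP
# induction range of the IRE1alpha branch, splicing of the majority of XBP1
# mRNA under stress, a translation-attenuation midpoint at a 90% drop of
# active eIF2alpha, a Hopf pair over activated PERK, a bistable BAX switch
# aligned with the intermediate CHOP range, and low/intermediate/high
# activity at stress rates mUFPT = 12/15/18 -- not transcribed from a
# published table.
#
# Groups are organisational only; parameter names are globally unique.
parameters:
  bip_binding:
    konBiP: 10.0        # association of BiP with receptors and UFP (fast)
    koffBiPIRE1: 0.08
    koffBiPPERK: 0.08
    koffBiPATF6: 0.05
    koffBiPUFP: 0.005
  receptor_activation:
    kfIRE1: 10.0
    krIRE1: 1.0
    nIRE1: 4            # monomers per active IRE1alpha complex (quadromer)
    kfPERK: 10.0
    krPERK: 1.0
    nPERK: 2
  receptor_turnover:
    ksIRE1: 0.2
    kdIRE1: 0.02
    ksPERK: 0.3
    kdPERK: 0.02
    ksATF6: 0.06
    kdATF6: 0.01
    kdRact: 0.02        # turnover of active receptor complexes
  atf6_processing:
    kwfs1: 0.002        # WFS1-enhanced ATF6 degradation (per acu per atu)
    ktransfer: 0.005      # ER -> Golgi translocation (slow membrane remodelling)
    kcleave: 10.0       # Golgi cleavage (fast enzymatic step, >> ktransfer)
    kdATF6p50: 0.002
  wfs1:
    kcWFS1: 0.5
    KmWFS1: 2.0
    kdWFS1: 0.02
  unfolded_protein:
    mUFPT: 0.0          # stress input: constant UFP accumulation rate
    kdUFP: 0.1          # clearance of free UFP
    kdbUFP: 0.05        # co-clearance of chaperone-bound UFP (consumes BiP)
  xbp1:
    kcXbas: 0.35         # constitutive activator term of the XBP1 promoter
    KmXbas: 1.0
    kcXatf6: 6.0
    KmXatf6: 1.1
    kdmXBP1: 0.2
  splicing:
    kcSplice: 1.0
    KmSplice: 1.0
    nCatalytic: 2       # catalytic domains per active IRE1alpha quadromer
    kdmXBP1s: 0.2
    ktlXBP1: 1.6
    kdXBP1s: 0.2
  bip_expression:
    ksBiP: 0.34
    kcBxbp: 24.0
    KmBxbp: 10.0
    kcBatf6: 14.0
    KmBatf6: 0.08
    kdBiP: 0.01
  eif2a_cycle:
    eIF2aT: 100.0       # conserved total eIF2alpha
    kphos: 2.0
    kmChop: 50.0        # CHOP level halving the phosphorylation capacity
    KmEif2a: 1.0        # shared saturation constant of the kinase/phosphatase pair
    kdephos: 2.0
    CReP: 2.0           # constitutive phosphatase level
  atf4:
    ktlATF4: 3.0
    kATF4: 10.0         # = 0.1 * eIF2aT: translation attenuated at a 90% drop
    nh: 4.0
    kdATF4: 0.6
  chop:
    kcCatf4: 3.0
    kmAtff: 1.0         # potency of CHOP activation by ATF4
    kcCatf6: 0.6
    KmCatf6: 5.0
    kcCxbp: 0.6
    KmCxbp: 50.0
    kdmCHOP: 0.3
    ktlCHOP: 0.6
    kdCHOP: 0.3
  gadd34:
    kcGchop: 3.0
    KmGchop: 5.0
    kdmGADD34: 0.3
    ktlGADD34: 0.06
    kdGADD34: 0.15
  apoptosis:
    ksBH3: 0.02
    kaBH3: 0.02
    kdBH3: 0.1
    ksBcl2: 0.1
    KrCHOP: 6.0
    hrCHOP: 4.0
    kdBcl2: 0.05
    kaBAX: 0.002
    kfbBAX: 0.6
    KfbBAX: 0.45
    BAXT: 1.0
    kiBAX: 0.2
    kdBAXa: 0.04
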