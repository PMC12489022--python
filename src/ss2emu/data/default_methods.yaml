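# Default method registry for the EMU engine.
#
# CYP factors follow the globally accepted couple-years-of-protection
# conversion factors (USAID/MSH list): 15 pill cycles, 120 condoms or
# 4 DMPA-IM doses per CYP; 4.6 CYP per Copper-T 10-year IUD insertion,
# 3.8 per 5-year implant, 10 per sterilization procedure.
#
# Continuation curves: Con(x) is the proportion of adopters still using the
# method in their x-th year of use. The Copper-T anchors Con(1)=0.92,
# Con(2)=0.77, Con(3)=0.65 are the published values behind the 4.6 CYP
# factor; later years extend those anchors at their observed year-over-year
# retention ratio (~0.84). Implant curves are scaled to the CYP continuation
# literature for the 5-year levonorgestrel implant. Sterilization is
# permanent: its slow decline represents women aging out of reproductive
# age rather than discontinuation.
#
# All values here are program parameters, editable per country.
schema_version: 1
methods:
  - name: pill
    category: short_term
    units_per_cyp:
      commodities_clients: 15
      commodities_facilities: 15
      visits: 15
  - name: condom
    category: short_term
    excludable: true
    units_per_cyp:
      commodities_clients: 120
      commodities_facilities: 120
      visits: 120
  - name: injectable_dmpa_im
    category: short_term
    units_per_cyp:
      commodities_clients: 4
      commodities_facilities: 4
      visits: 4
  - name: lam
    category: short_term
    excludable: true
    units_per_cyp:
      visits: 4
  - name: iud_copper_t
    category: long_acting_reversible
    duration_years: 10
    cyp_per_service: 4.6
    continuation: [0.92, 0.77, 0.65, 0.546, 0.459, 0.386, 0.324, 0.272, 0.229, 0.192]
  - name: implant
    category: long_acting_reversible
    duration_years: 5
    cyp_per_service: 3.8
    continuation: [0.90, 0.78, 0.66, 0.55, 0.45]
  - name: sterilization_female
    category: permanent
    duration_years: 10
    cyp_per_service: 10.0
    continuation: [1.0, 0.98, 0.96, 0.93, 0.90, 0.87, 0.83, 0.79, 0.75, 0.70]
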