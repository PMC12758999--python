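# Per-organ EUD/NTCP parameters: volume-effect exponent a, tolerance dose
# D50 (Gy) and normalised slope gamma50.
#
# Entries tagged "literature" are commonly used defaults from the EUD-based
# NTCP compilation of Gay & Niemierko (Phys Med 2007) and the Emami/Burman
# tolerance tables; they are starting points, not clinical recommendations,
# and every value can be overridden by a user file of the same layout.
#
# Entries tagged "pair-derived" were obtained with fit_ntcp_params from
# published (mean dose, NTCP) pairs for this treatment context and use a = 1
# (mean-dose organ), since only mean organ doses accompany those NTCPs.
- organ: heart
  a: 1.0
  d50_gy: 18.79
  gamma50: 1.318
  endpoint: late cardiac mortality
  source: pair-derived (16 Gy @ 30%, 6.6 Gy @ 0.4%)
- organ: thyroid
  a: 1.0
  d50_gy: 62.50
  gamma50: 0.596
  endpoint: thyroid dysfunction
  source: pair-derived (27.1 Gy @ 12%, 8.7 Gy @ 0.9%)
- organ: lungs
  a: 1.0
  d50_gy: 24.5
  gamma50: 2.0
  endpoint: pneumonitis
  source: literature (Gay & Niemierko 2007)
- organ: kidneys
  a: 1.0
  d50_gy: 28.0
  gamma50: 1.4
  endpoint: nephropathy
  source: literature (Emami/Burman)
- organ: spinal_cord
  a: 13.0
  d50_gy: 66.5
  gamma50: 4.0
  endpoint: myelitis
  source: literature (Gay & Niemierko 2007)
- organ: brainstem
  a: 7.0
  d50_gy: 65.1
  gamma50: 2.4
  endpoint: necrosis
  source: literature (Gay & Niemierko 2007)
- organ: brain
  a: 5.0
  d50_gy: 60.0
  gamma50: 3.0
  endpoint: necrosis
  source: literature (Emami/Burman)
- organ: lens
  a: 3.0
  d50_gy: 18.0
  gamma50: 1.0
  endpoint: cataract
  source: literature (Emami/Burman)
- organ: parotids
  a: 0.5
  d50_gy: 46.0
  gamma50: 1.8
  endpoint: xerostomia
  source: literature (Gay & Niemierko 2007)
- organ: liver
  a: 0.7
  d50_gy: 40.0
  gamma50: 1.2
  endpoint: liver failure
  source: literature (Emami/Burman)
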