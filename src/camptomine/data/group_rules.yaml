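# Alkaloid group rules: a diagnostic fragment ion plus characteristic
# neutral losses.  Each entry of `required` is a slot listing the nominal
# losses (Da) that can satisfy it; `logic: ALL` demands every slot, `ANY`
# at least one.  The evidence score a spectrum receives for a group is the
# number of satisfied slots, diagnostic ion presence is always mandatory.
#
# CG  camptothecin series           diagnostic m/z 168, cleavage -56 or -70
# PG  pumiloside series             diagnostic m/z 158, cleavage -70 and -96
# SG  strictosidinic acid series    diagnostic m/z 144, cleavage -17 and -70
# VG  vincosamide/strictosamide     diagnostic m/z 144, cleavage -70 and -96
# VC  vincosamide-camptothecin      diagnostic m/z 144, cleavage -44 and
#     hybrid series                 -56 (a -42 in place of -56 marks a
#                                   20-dehydroxy variant)
rules:
  - group: CG
    diagnostic_nominal: 168
    diagnostic_exact: 168.0690
    logic: ANY
    required: [[56], [70]]
  - group: PG
    diagnostic_nominal: 158
    diagnostic_exact: 158.0597
    logic: ALL
    required: [[70], [96]]
  - group: SG
    diagnostic_nominal: 144
    diagnostic_exact: 144.0808
    logic: ALL
    required: [[17], [70]]
  - group: VG
    diagnostic_nominal: 144
    diagnostic_exact: 144.0808
    logic: ANY
    required: [[70], [96]]
  - group: VC
    diagnostic_nominal: 144
    diagnostic_exact: 144.0808
    logic: ANY
    required: [[44], [56, 42]]
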