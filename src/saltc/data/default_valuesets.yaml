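# Default value sets for categorical laboratory result standardization.
#
# Five categories of categorical laboratory tests, each with its canonical
# result values. Per entry:
#   label             display form of the canonical value (unique per category)
#   snomed_id         SNOMED CT concept identifier. These are curated defaults
#                     sourced by the package authors; entries without one are
#                     left unmapped. Override with a site-specific config for
#                     production terminology work.
#   comparison_string the abbreviated text the matcher vectorizes; chosen to
#                     share as few characters as possible with the other
#                     values of the same category (e.g. negative -> "neg-",
#                     positive -> "posi").
#   triggers          normalized strings whose exact presence among a test's
#                     main values assigns the test to this category. Kept
#                     deliberately narrow for values whose notations collide
#                     across categories ("negative" appears in urine dipstick
#                     and presence-finding tests alike; its triggers live only
#                     under presence-finding, the later category in the
#                     evaluation order).
urine_color:
  - {label: clear, triggers: [clear]}
  - {label: cloudy, triggers: [cloudy]}
  - {label: orange, triggers: [orange]}
  - {label: purple, triggers: [purple]}
  - {label: brown, triggers: [brown]}
  - {label: green, triggers: [green]}
  - {label: blue, triggers: [blue]}
  - {label: red, triggers: [red]}
  - {label: black, triggers: [black]}
  - {label: yellow, triggers: [yellow]}
  - {label: dark yellow, triggers: [dark yellow]}
  - {label: pink, triggers: [pink]}
  - {label: turbid, triggers: [turbid]}
  - {label: milky white, triggers: [milky white]}
  - {label: amber, triggers: [amber]}
  - {label: straw, triggers: [straw]}
  - {label: colorless, triggers: [colorless]}
  - {label: bloody, triggers: [bloody]}
urine_dipstick:
  - {label: negative, snomed_id: "260385009", comparison_string: neg-, triggers: []}
  - {label: normal, snomed_id: "17621005", comparison_string: norm, triggers: []}
  - {label: trace, snomed_id: "260405006", comparison_string: tr, triggers: [trace, tr]}
  - {label: "+", snomed_id: "260347006", triggers: []}
  - {label: "++", snomed_id: "260348001", triggers: ["++"]}
  - {label: "+++", snomed_id: "260349009", triggers: ["+++"]}
  - {label: "++++", snomed_id: "260350009", triggers: ["++++"]}
blood_type:
  - {label: rh+, triggers: [rh+, rh +, rh]}
  - {label: rh-, triggers: [rh-, rh -]}
  - {label: weak d, triggers: [weak d]}
  - {label: partial d, triggers: [partial d]}
  - {label: variant d, triggers: [variant d]}
  - {label: a, triggers: [a]}
  - {label: b, triggers: [b]}
  - {label: ab, triggers: [ab]}
  - {label: o, triggers: [o]}
  - {label: cis-ab, triggers: [cis-ab, cisab]}
presence_finding:
  - {label: positive, snomed_id: "10828004", comparison_string: posi,
     triggers: [positive, posi, pos]}
  - {label: negative, snomed_id: "260385009", comparison_string: neg-,
     triggers: [negative, neg, neg -]}
  - {label: weakly positive, snomed_id: "260408008", comparison_string: w posi,
     triggers: [weakly positive, weakly-positive, weak positive, w pos]}
pathogenesis:
  - {label: reactive, snomed_id: "11214006", comparison_string: react,
     triggers: [reactive, react]}
  - {label: nonreactive, snomed_id: "131196009", comparison_string: nonreact,
     triggers: [nonreactive, non-reactive, non-react, nonreact]}
  - {label: weakly reactive, comparison_string: w react,
     triggers: [weakly reactive, weakly-reactive, w-react, w react, w-reactive]}
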