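# Prescriber-style degradation model: the inverse of the normalization
# rules plus typos and casing noise.  Used to emulate raw e-scribe text.
abbreviations:
  by mouth: [po, "p.o."]
  under the tongue: [sl]
  subcutaneously: [subq, sc]
  intramuscularly: [im]
  by inhalation: [inh]
  via nebulizer: [neb]
  once daily: [qd, "q.d."]
  twice daily: [bid, "b.i.d."]
  three times daily: [tid]
  four times daily: [qid]
  every morning: [qam]
  every evening: [qpm]
  every four hours: [q4h]
  every six hours: [q6h]
  every eight hours: [q8h]
  every twelve hours: [q12h]
  every other day: [qod]
  once weekly: [qw]
  at bedtime: [qhs, hs]
  as needed: [prn]
  tablets: [tabs]
  tablet: [tab]
  capsules: [caps]
  capsule: [cap]
  drops: [gtts]
  drop: [gtt]
  one: ["1"]
  two: ["2"]
  three: ["3"]
  four: ["4"]
  five: ["5"]
  seven: ["7"]
typo_rate: 0.02
casing: mixed
seed: 0
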