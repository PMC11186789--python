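# Pharmalexical normalization rules, applied in listed order.
# kind: literal rules match whole words case-insensitively; regex rules
# are raw patterns (set word_boundary: false when the pattern manages its
# own boundaries).  The production rule inventory is proprietary domain
# knowledge; this set documents the format and covers the common Latin
# sig abbreviations.

# --- dotted Latin abbreviations (before their undotted forms) ----------
- {id: dotted-po, kind: regex, match: '(?<!\w)p\.o\.(?!\w)', replace: 'by mouth', word_boundary: false}
- {id: dotted-bid, kind: regex, match: '(?<!\w)b\.i\.d\.(?!\w)', replace: 'twice daily', word_boundary: false}
- {id: dotted-tid, kind: regex, match: '(?<!\w)t\.i\.d\.(?!\w)', replace: 'three times daily', word_boundary: false}
- {id: dotted-qid, kind: regex, match: '(?<!\w)q\.i\.d\.(?!\w)', replace: 'four times daily', word_boundary: false}
- {id: dotted-qd, kind: regex, match: '(?<!\w)q\.d\.(?!\w)', replace: 'once daily', word_boundary: false}
- {id: dotted-hs, kind: regex, match: '(?<!\w)h\.s\.(?!\w)', replace: 'at bedtime', word_boundary: false}

# --- route abbreviations ----------------------------------------------
- {id: abbr-po, kind: literal, match: po, replace: by mouth}
- {id: abbr-sl, kind: literal, match: sl, replace: under the tongue}
- {id: abbr-pr, kind: literal, match: pr, replace: rectally}
- {id: abbr-subq, kind: literal, match: subq, replace: subcutaneously}
- {id: abbr-sc, kind: literal, match: sc, replace: subcutaneously}
- {id: abbr-sq, kind: literal, match: sq, replace: subcutaneously}
- {id: abbr-im, kind: literal, match: im, replace: intramuscularly}
- {id: abbr-inh, kind: literal, match: inh, replace: by inhalation}
- {id: abbr-neb, kind: literal, match: neb, replace: via nebulizer}

# --- frequency abbreviations ------------------------------------------
- {id: abbr-qd, kind: literal, match: qd, replace: once daily}
- {id: abbr-qday, kind: literal, match: qday, replace: once daily}
- {id: abbr-bid, kind: literal, match: bid, replace: twice daily}
- {id: abbr-tid, kind: literal, match: tid, replace: three times daily}
- {id: abbr-qid, kind: literal, match: qid, replace: four times daily}
- {id: abbr-qam, kind: literal, match: qam, replace: every morning}
- {id: abbr-qpm, kind: literal, match: qpm, replace: every evening}
- {id: abbr-q4h, kind: literal, match: q4h, replace: every four hours}
- {id: abbr-q6h, kind: literal, match: q6h, replace: every six hours}
- {id: abbr-q8h, kind: literal, match: q8h, replace: every eight hours}
- {id: abbr-q12h, kind: literal, match: q12h, replace: every twelve hours}
- {id: abbr-qod, kind: literal, match: qod, replace: every other day}
- {id: abbr-qw, kind: literal, match: qw, replace: once weekly}
- {id: abbr-qhs, kind: literal, match: qhs, replace: at bedtime}
- {id: abbr-hs, kind: literal, match: hs, replace: at bedtime}
- {id: abbr-prn, kind: literal, match: prn, replace: as needed}

# --- dose-form abbreviations ------------------------------------------
- {id: abbr-tabs, kind: literal, match: tabs, replace: tablets}
- {id: abbr-tab, kind: literal, match: tab, replace: tablet}
- {id: abbr-caps, kind: literal, match: caps, replace: capsules}
- {id: abbr-cap, kind: literal, match: cap, replace: capsule}
- {id: abbr-gtts, kind: literal, match: gtts, replace: drops}
- {id: abbr-gtt, kind: literal, match: gtt, replace: drop}
- {id: abbr-tsp, kind: literal, match: tsp, replace: teaspoonful}
- {id: abbr-ud, kind: literal, match: ud, replace: as directed}
- {id: abbr-with, kind: regex, match: 'w/(?=\s|$)', replace: with, word_boundary: false}
- {id: duration-x, kind: regex, match: '\bx\s+(?=\d|one\b|two\b|three\b|four\b|five\b|seven\b|ten\b)', replace: 'for ', word_boundary: false}

# --- standalone numerals to words (after token abbreviations) ----------
- {id: num-1, kind: regex, match: '(?<![\w./])1(?![\w./])', replace: one, word_boundary: false}
- {id: num-2, kind: regex, match: '(?<![\w./])2(?![\w./])', replace: two, word_boundary: false}
- {id: num-3, kind: regex, match: '(?<![\w./])3(?![\w./])', replace: three, word_boundary: false}
- {id: num-4, kind: regex, match: '(?<![\w./])4(?![\w./])', replace: four, word_boundary: false}
- {id: num-5, kind: regex, match: '(?<![\w./])5(?![\w./])', replace: five, word_boundary: false}
- {id: num-6, kind: regex, match: '(?<![\w./])6(?![\w./])', replace: six, word_boundary: false}
- {id: num-7, kind: regex, match: '(?<![\w./])7(?![\w./])', replace: seven, word_boundary: false}
- {id: num-8, kind: regex, match: '(?<![\w./])8(?![\w./])', replace: eight, word_boundary: false}
- {id: num-9, kind: regex, match: '(?<![\w./])9(?![\w./])', replace: nine, word_boundary: false}
- {id: num-half, kind: regex, match: '(?<![\w./])1/2(?![\w./])', replace: half, word_boundary: false}
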