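[
 {"pattern": ["verb", "dose", "route", "frequency"], "count": 30},
 {"pattern": ["verb", "dose", "route", "frequency", "auxi-indic"], "count": 20},
 {"pattern": ["verb", "dose", "route", "frequency", "auxi-time"], "count": 10},
 {"pattern": ["verb", "dose", "route", "frequency", "auxi-period"], "count": 8},
 {"pattern": ["verb", "dose", "frequency"], "count": 6},
 {"pattern": ["verb", "route", "frequency"], "count": 5},
 {"pattern": ["verb", "dose", "route", "frequency", "auxi-indic", "auxi-period"], "count": 5},
 {"pattern": ["verb", "dose", "route", "frequency", "auxi-time", "auxi-action"], "count": 3},
 {"pattern": ["verb", "dose", "route", "frequency", "auxi-maxdose"], "count": 3},
 {"pattern": ["verb", "dose", "route", "frequency", "auxi-action"], "count": 3},
 {"pattern": ["verb", "dose", "frequency", "auxi-time"], "count": 3},
 {"pattern": ["verb", "dose", "route", "frequency", "auxi-time", "auxi-period"], "count": 3},
 {"pattern": ["dose", "auxi-time"], "count": 2},
 {"pattern": ["verb", "route", "frequency", "auxi-period"], "count": 2},
 {"pattern": ["verb", "dose", "route", "frequency", "auxi-indic", "auxi-maxdose"], "count": 2},
 {"pattern": ["verb", "dose", "route", "frequency", "auxi-indic", "auxi-time", "auxi-period", "auxi-action", "auxi-maxdose"], "count": 1}
]
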