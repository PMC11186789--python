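drug_id	description	dose_form	strength	active_ingredients	required	default_verb	default_dose	default_route	default_frequency	default_aux
d001	metformin hcl 500 mg oral tablet	tablet	500 mg	metformin hydrochloride	verb;dose;route;frequency	take		by mouth
d002	amoxicillin 250 mg oral capsule	capsule	250 mg	amoxicillin	verb;dose;route;frequency	take		by mouth
d003	hydrocortisone 1% topical cream	cream	1 %	hydrocortisone	verb;route;frequency	apply		to the affected area
d004	montelukast 4 mg chewable tablet	tablet	4 mg	montelukast sodium	verb;dose;route;frequency	chew		by mouth
d005	insulin glargine 100 units/ml pen-injector	pen-injector	100 units/ml	insulin glargine	dose;route;frequency	inject		subcutaneously		auxi-time=at bedtime
d006	albuterol sulfate 90 mcg inhaler	aerosol	90 mcg/actuation	albuterol sulfate	verb;dose;route;frequency	inhale		by inhalation
d007	latanoprost 0.005% ophthalmic solution	solution	0.005 %	latanoprost	verb;dose;route;frequency	instill		into the affected eye
d008	methotrexate 2.5 mg oral tablet	tablet	2.5 mg	methotrexate	verb;dose;route;frequency	take		by mouth	once weekly
d009	ondansetron 4 mg oral tablet	tablet	4 mg	ondansetron	verb;dose;route;frequency	take		by mouth
d010	fluticasone 50 mcg nasal spray	spray	50 mcg/actuation	fluticasone propionate	verb;dose;route;frequency	spray		in each nostril
d011	nitroglycerin 0.4 mg sublingual tablet	tablet	0.4 mg	nitroglycerin	verb;dose;route;frequency	dissolve		under the tongue
d012	omeprazole 20 mg oral capsule	capsule	20 mg	omeprazole	verb;dose;route;frequency	take		by mouth		auxi-time=before breakfast
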