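{
 "verb": {
  "take": "take", "chew": "chew", "apply": "apply", "inhale": "inhale",
  "inject": "inject", "instill": "instill", "insert": "insert",
  "dissolve": "dissolve", "swallow": "swallow", "give": "give",
  "administer": "administer", "spray": "spray", "use": "use",
  "drink": "drink", "wear": "wear", "rinse": "rinse", "place": "place",
  "unwrap": "unwrap"
 },
 "dose": {
  "one tablet": "one tablet", "two tablets": "two tablets",
  "three tablets": "three tablets", "four tablets": "four tablets",
  "half tablet": "half tablet", "one capsule": "one capsule",
  "two capsules": "two capsules", "three capsules": "three capsules",
  "five ml": "five ml", "ten ml": "ten ml", "fifteen ml": "fifteen ml",
  "one teaspoonful": "one teaspoonful", "two teaspoonfuls": "two teaspoonfuls",
  "one puff": "one puff", "two puffs": "two puffs", "three puffs": "three puffs",
  "one drop": "one drop", "two drops": "two drops", "three drops": "three drops",
  "one patch": "one patch", "one spray": "one spray", "two sprays": "two sprays",
  "one suppository": "one suppository", "one applicatorful": "one applicatorful",
  "one ring": "one ring", "20 mg": "20 mg", "40 mg": "40 mg",
  "500 mg": "500 mg", "10 units": "10 units", "20 units": "20 units"
 },
 "route": {
  "by mouth": "by mouth", "orally": "by mouth",
  "under the tongue": "under the tongue", "topically": "topically",
  "to the affected area": "to the affected area",
  "into the affected eye": "into the affected eye",
  "into each eye": "into each eye",
  "into the affected ear": "into the affected ear",
  "into each ear": "into each ear", "in each nostril": "in each nostril",
  "rectally": "rectally", "vaginally": "vaginally",
  "subcutaneously": "subcutaneously", "intramuscularly": "intramuscularly",
  "by inhalation": "by inhalation", "via nebulizer": "via nebulizer",
  "on the scalp": "on the scalp", "to the skin": "to the skin",
  "via the feeding tube": "via the feeding tube"
 },
 "frequency": {
  "once daily": "once daily", "daily": "once daily",
  "every day": "once daily", "twice daily": "twice daily",
  "three times daily": "three times daily",
  "four times daily": "four times daily", "every morning": "every morning",
  "every evening": "every evening", "every four hours": "every four hours",
  "every six hours": "every six hours", "every eight hours": "every eight hours",
  "every twelve hours": "every twelve hours",
  "every other day": "every other day", "once weekly": "once weekly",
  "twice weekly": "twice weekly", "once monthly": "once monthly",
  "as needed": "as needed", "nightly": "nightly"
 },
 "auxi-indic": {
  "for pain": "for pain", "for anxiety": "for anxiety",
  "for high blood pressure": "for high blood pressure",
  "for cholesterol": "for cholesterol", "for diabetes": "for diabetes",
  "for inflammation": "for inflammation", "for allergies": "for allergies",
  "for nausea": "for nausea", "for sleep": "for sleep",
  "for infection": "for infection", "for fever": "for fever",
  "for heartburn": "for heartburn", "for seizures": "for seizures",
  "for cough": "for cough", "for migraine": "for migraine",
  "for itching": "for itching", "for swelling": "for swelling"
 },
 "auxi-time": {
  "in the morning": "in the morning", "at bedtime": "at bedtime",
  "before meals": "before meals", "after meals": "after meals",
  "with food": "with food", "without food": "without food",
  "on an empty stomach": "on an empty stomach",
  "before breakfast": "before breakfast", "after dinner": "after dinner",
  "thirty minutes before meals": "thirty minutes before meals",
  "at noon": "at noon", "before procedure": "before procedure",
  "before surgery": "before surgery", "with breakfast": "with breakfast",
  "with dinner": "with dinner", "after lunch": "after lunch"
 },
 "auxi-period": {
  "for five days": "for five days", "for seven days": "for seven days",
  "for ten days": "for ten days", "for fourteen days": "for fourteen days",
  "for thirty days": "for thirty days", "for one week": "for one week",
  "for two weeks": "for two weeks", "for three weeks": "for three weeks",
  "for one month": "for one month", "for three months": "for three months",
  "for six months": "for six months", "until finished": "until finished",
  "until gone": "until gone"
 },
 "auxi-action": {
  "do not crush": "do not crush", "do not chew": "do not chew",
  "swallow whole": "swallow whole",
  "shake well before use": "shake well before use",
  "take with plenty of water": "take with plenty of water",
  "avoid sunlight": "avoid sunlight", "do not drive": "do not drive",
  "rinse mouth after use": "rinse mouth after use",
  "protect from light": "protect from light", "avoid alcohol": "avoid alcohol",
  "do not take with dairy": "do not take with dairy",
  "use as directed": "use as directed",
  "may cause drowsiness": "may cause drowsiness",
  "do not stop abruptly": "do not stop abruptly"
 },
 "auxi-maxdose": {
  "do not exceed four doses daily": "do not exceed four doses daily",
  "do not exceed six doses daily": "do not exceed six doses daily",
  "do not exceed eight tablets daily": "do not exceed eight tablets daily",
  "maximum four grams daily": "maximum four grams daily",
  "maximum two sprays daily": "maximum two sprays daily",
  "maximum three doses daily": "maximum three doses daily",
  "not to exceed 3000 mg daily": "not to exceed 3000 mg daily",
  "do not exceed twelve tablets daily": "do not exceed twelve tablets daily",
  "maximum six tablets in twenty-four hours": "maximum six tablets in twenty-four hours",
  "no more than two patches weekly": "no more than two patches weekly"
 }
}
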