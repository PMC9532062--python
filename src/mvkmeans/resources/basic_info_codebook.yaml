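# Code book for the basic-information view (view 1).
# Categorical survey values -> integer codes; codes are unique per attribute.
"Gender":
  "Male": 11
  "Female": 12
"Grade":
  "Freshman": 21
  "Sophomore": 22
  "Junior year": 23
  "Senior year": 24
"Character":
  "Introverted": 31
  "Outgoing": 32
  "Inside and outside": 33
"Household income":
  "Low": 41
  "Middle": 42
  "High": 43
"From rural/urban":
  "Rural": 51
  "City": 52
"Is it an only child?":
  "Yes": 61
  "No": 62
"GPA":
  "Failed": 71
  "Pass": 72
  "Medium": 73
  "Good": 74
  "Excellent": 75
"Attendance in class":
  "Failed": 81
  "Pass": 82
  "Medium": 83
  "Good": 84
  "Excellent": 85
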