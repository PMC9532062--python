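# Code book for the questionnaire view (view 2).
# The survey instrument has no published numeric code book, so options are
# encoded option-index style: A -> 1, B -> 2, ...
"Gender":
  "A": 1
  "B": 2
"Grade":
  "A": 1
  "B": 2
  "C": 3
  "D": 4
"Do you feel stressed?":
  "A": 1
  "B": 2
  "C": 3
  "D": 4
"Source of stress":
  "A": 1
  "B": 2
  "C": 3
  "D": 4
  "E": 5
  "F": 6
"How to deal with mental problems":
  "A": 1
  "B": 2
  "C": 3
  "D": 4
  "E": 5
"Whether to attend a mental health education seminar or class?":
  "A": 1
  "B": 2
  "C": 3
"How to reduce stress?":
  "A": 1
  "B": 2
  "C": 3
  "D": 4
  "E": 5
"Can mental health be managed?":
  "A": 1
  "B": 2
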