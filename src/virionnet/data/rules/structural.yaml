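# Keyword rules for the broad structural-protein training set.
# Positive keywords name virion components; annotations carrying an
# uninformative qualifier are discarded outright. The exclusion list keeps
# cellular host proteins that match a structural keyword by accident out of
# the positive pool; the shipped list is a reconstruction (the canonical
# description gives it only as examples) and is user-editable.
name: structural
positive_keywords:
  - capsid
  - tape measure
  - portal
  - tail
  - fiber
  - baseplate
  - connector
  - neck
  - collar
exclusion_keywords:
  - bacteria
  - human
  - mouse
exclusion_to_negative: false
uninformative_keywords:
  - hypothetical protein
  - unnamed
  - probable
  - putative
  - similar to
min_length: 200
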