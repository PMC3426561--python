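# Keyword rules for the major capsid protein (MCP) set. A positive must
# carry both "major" and "capsid" ('+' joins substrings that must co-occur).
# Cross-exclusion: anything mentioning "tail" is removed from the positive
# set and routed to the negative pool instead.
name: capsid
positive_keywords:
  - major+capsid
exclusion_keywords:
  - tail
exclusion_to_negative: true
uninformative_keywords:
  - unknown
  - conceptual translation
  - capsid-like
  - conceptual
  - similar to
  - presumed
  - precursor
  - possible
  - putative
  - synthetic construct
  - probable
  - unnamed
  - hypothetical
  - predicted
  - implied
  - assumed
  - provisional
  - uncharacterized
min_length: 300
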