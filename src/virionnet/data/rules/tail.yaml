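# Keyword rules for the tail-protein set (tube, sheath, fibers, baseplate).
# Cross-exclusion: head/capsid annotations leave the tail positive set and
# are routed to the negative pool.
name: tail
positive_keywords:
  - tail
exclusion_keywords:
  - head
  - capsid
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
min_length: 150
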