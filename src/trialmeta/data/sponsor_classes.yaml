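# Keyword dictionaries for five-way lead-sponsor classification.
#
# Keywords are matched at word boundaries against the Unicode-normalised,
# case-folded sponsor name; a keyword ending in "." also matches without the
# dot at end of name ("Pfizer Inc" == "Pfizer Inc."). Diacritics are
# significant, so multilingual entries are listed explicitly. Priority is
# highest first: a name matching several classes takes the highest-priority
# one ("University Hospital" is hos, not edu). Names matching nothing fall
# back to the registry's own agency class.
#
# The sets below seed a working classifier; they are data, not code, and are
# meant to be extended/refined for a given corpus.
priority: [hos, edu, com, gov, col]
classes:
  hos:
    - hospital
    - hospitals
    - hôpital
    - hôpitaux
    - clinic
    - clinics
    - klinik
    - klinikum
    - kliniken
    - medical center
    - medical centre
    - health center
    - infirmary
    - hospice
    - ospedale
    - hospices
    - sjukhus
    - ziekenhuis
  edu:
    - university
    - universities
    - college
    - università
    - universität
    - université
    - universidad
    - universidade
    - universiteit
    - uniwersytet
    - academy
    - academia
    - school of medicine
    - medical school
    - institute
    - institut
    - instituto
  com:
    - company
    - inc.
    - corp.
    - corporation
    - ltd.
    - limited
    - llc
    - gmbh
    - co.
    - s.a.
    - a/s
    - pharmaceutical
    - pharmaceuticals
    - pharma
    - therapeutics
    - biosciences
    - biotech
    - laboratories
  gov:
    - national
    - ministry
    - government
    - federal
    - nih
    - u.s.
    - veterans affairs
    - public health service
    - agency
    - bureau
    - municipal
    - county
    - state of
  col:
    - network
    - association
    - consortium
    - alliance
    - collaborative
    - collaboration
    - cooperative
    - foundation
    - society
    - working group
    - study group
fallback:
  Industry: com
  NIH: gov
  U.S. Fed: gov
  Other: unclassified
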