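"""Classify lead-sponsor names into the five institutional classes.

Shows the prioritised keyword matching (hospital terms outrank university
terms), multilingual keywords, and the agency-class fallback for names no
keyword matches.
"""

from trialmeta import classify_sponsor

EXAMPLES = [
    ("University Hospital Basel", "Other"),
    ("Università di Bologna", "Other"),
    ("Hôpitaux de Paris", "Other"),
    ("Acme Pharmaceuticals Inc.", "Industry"),
    ("Xyzzy Trust", "NIH"),          # no keyword -> registry agency fallback
    ("Xyzzy Trust", "Other"),        # no keyword, no usable agency
]

for name, agency in EXAMPLES:
    cls = classify_sponsor(name, agency)
    print(f"{name:32s} agency={agency:9s} -> {cls.value}")

# "University Hospital Basel" lands in hos, not edu: facility keywords have
# higher priority, so a university hospital is counted with hospitals.
# Keyword-free names inherit a class from the registry's own label where
# that label is informative (Industry, NIH, U.S. Fed), else stay
# unclassified.
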