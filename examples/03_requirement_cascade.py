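"""Evaluate the results-deposition requirement cascade on a synthetic corpus.

Mandatory deposition of summary results applies to trials that are
completed, FDA regulated, covered by Section 801, in an explicit phase 2–4,
published, and interventional. This script generates a calibrated corpus
and prints how many trials survive each single requirement and all of them
together.
"""

from trialmeta import compute_corpus_flags, generate_records, paper_calibrated_config

corpus = generate_records(paper_calibrated_config(n_trials=10_000, seed=7))
flags = compute_corpus_flags(corpus.records)

names = (
    "completed_by_cutoff", "fda_regulated", "section_801",
    "phase_2_to_4", "has_publication", "interventional",
)
print(f"corpus size: {len(corpus.records)}")
for name in names:
    count = sum(1 for f in flags.values() if getattr(f, name))
    print(f"  {name:20s} {count:6d}")
count_all = sum(1 for f in flags.values() if f.all_requirements)
print(f"  {'all requirements':20s} {count_all:6d}")

# The conjunction is far smaller than any single requirement: only a small
# sliver of the registry is simultaneously completed, regulated, phased,
# published and interventional — the pool on which mandatory deposition
# can actually be judged.
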