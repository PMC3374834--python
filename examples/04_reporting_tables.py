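"""Build the reporting-efficiency summary tables for a synthetic corpus.

Generates a calibrated corpus, classifies sponsors, computes requirement
flags, and prints the per-class deposition table (under all requirements)
and the outcome-reporting table.
"""

from trialmeta import (
    class_restrained_table,
    classify_corpus,
    compute_corpus_flags,
    generate_records,
    outcome_table,
    paper_calibrated_config,
)

corpus = generate_records(paper_calibrated_config(n_trials=20_000, seed=1))
assignments, class_sizes = classify_corpus(corpus.records)
flags = compute_corpus_flags(corpus.records)

print("class sizes:")
print(class_sizes.to_string(index=False))

print("\nresults deposition among trials meeting every requirement:")
print(class_restrained_table(corpus.records, assignments, flags).to_string(index=False))

print("\noutcome reporting over the full corpus:")
print(outcome_table(corpus.records, assignments).to_string(index=False))

# Companies deposit results far more often than the non-profit classes in
# the restrained pool (46% vs 2% for government sponsors in this draw; the
# per-class pools are small, so single-corpus rates are noisy), while
# outcome listing is high (~3/4) everywhere except the government class.
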