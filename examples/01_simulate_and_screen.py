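"""Generate the two synthetic corpora and apply the expert keyword screen.

The filtered corpus emulates a development set built by keyword screening
(every section contains a cognitive-function keyword; ~29.4% positive);
the unfiltered corpus emulates a random test sample (~3.5% positive).
"""

from notesift import (
    expert_patterns,
    filtered_spec,
    generate_corpus,
    screen_sections,
    split_corpus,
    unfiltered_spec,
)

dev = generate_corpus(filtered_spec(n_sections=1000, prevalence=0.294, seed=1))
test = generate_corpus(unfiltered_spec(n_sections=500, prevalence=0.035, seed=2))

for name, corpus in [("filtered", dev), ("unfiltered", test)]:
    lengths = [s.n_chars for s in corpus]
    print(
        f"{name}: {len(corpus)} sections, "
        f"{corpus.realized_prevalence:.1%} positive, "
        f"mean length {sum(lengths) / len(lengths):.0f} chars "
        f"(range {min(lengths)}-{max(lengths)})"
    )

patterns = expert_patterns()
print(f"expert screen: {len(patterns)} keyword patterns")
print(f"filtered corpus retained by screen: {len(screen_sections(dev, patterns))}/{len(dev)}")
kept = screen_sections(test, patterns)
print(
    f"unfiltered corpus retained: {len(kept)}/{len(test)} — the screen is a "
    "high-recall pre-filter, so it keeps benign keyword mentions too"
)

pool, holdout = split_corpus(dev, [900, 100], seed=3)
print(f"split: {len(pool)} example-pool sections + {len(holdout)} holdout, disjoint ids")

sample = next(s for s in dev if s.label == 1)
print("\nexample positive section:")
print(" ", sample.text[:160], "...")
print("  planted cues:", sample.meta["cues"])
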