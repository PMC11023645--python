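"""Sectioned prompts, reply triage and the four example-selection strategies.

Hard prompting picks five examples once (randomly, from prior errors, or
as k-means cluster medoids); soft/dynamic prompting re-picks each query's
five nearest neighbors in embedding space.
"""

from notesift import (
    HashingEmbedder,
    default_template,
    filtered_spec,
    generate_corpus,
    render_prompt,
    select_dynamic,
    select_kmeans,
    select_random,
    select_targeted,
    triage_reply,
)

pool = generate_corpus(filtered_spec(60, 0.4, seed=21))
query = generate_corpus(filtered_spec(1, 0.9, seed=22)).sections[0]
embedder = HashingEmbedder(dim=256)

template = default_template().with_examples(select_random(pool, 5, seed=0))
prompt = render_prompt(template, query)
print(f"rendered prompt: {len(prompt)} chars, query appears "
      f"{prompt.count(query.text)} time(s)\n")

strategies = {
    "random": select_random(pool, 5, seed=0),
    "targeted (prior errors)": select_targeted(pool, set(pool.ids[:7]), 5, seed=0),
    "k-means medoids": select_kmeans(pool, embedder, 5, seed=0),
    "dynamic (per-query kNN)": select_dynamic(query, pool, embedder, 5),
}
for name, picked in strategies.items():
    print(f"{name}: {[s.section_id for s in picked]}")
print("each strategy returns 5 distinct pool members; only the dynamic one "
      "depends on the query\n")

for raw in [
    '{"cognitive_decline": true, "keywords": ["memory loss", "MoCA"]}',
    "Yes — evidence found. Keywords: memory loss, MoCA.",
    "I cannot determine that.",
]:
    reply = triage_reply(raw)
    print(f"{reply.category:<22} verdict={reply.verdict} keywords={reply.keywords}")
print("triage is total: JSON replies parse strictly, free text falls back to "
      "a pattern scan, anything else is not effective")
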