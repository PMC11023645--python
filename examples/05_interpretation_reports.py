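"""Mean + 2*SD keyword reports from all three model families.

A keyword (or token, or tree feature) is flagged when its statistic
strictly exceeds the population mean plus two standard deviations —
frequency for LLM output, within-section weight for attention, total split
gain for the boosted trees.
"""

from notesift import (
    AttentionDnnClassifier,
    BackendConfig,
    GbtClassifier,
    MockBackend,
    attention_keyword_report,
    filtered_spec,
    gain_keyword_report,
    generate_corpus,
    llm_keyword_report,
    load_keywords,
    merged_report,
)

train = generate_corpus(filtered_spec(1200, 0.294, seed=41))
gbt = GbtClassifier(seed=0).fit(train)
dnn = AttentionDnnClassifier(
    embed_dim=16, n_filters=16, hidden_size=16, attn_size=16,
    max_len=128, epochs=10, word_dropout=0.2, weight_decay=1e-3, seed=0,
).fit(train)
backend = MockBackend(BackendConfig(seed=5, mock_error_rate=0.05))
replies = [backend.classify(s) for s in train]

llm_rep = llm_keyword_report(replies)
attn_rep = attention_keyword_report(dnn.attention_maps(train))
gain_rep = gain_keyword_report(gbt)

for rep in (llm_rep, attn_rep, gain_rep):
    print(f"{rep.source}: {len(rep.stats)} candidates, threshold "
          f"{rep.threshold:.2f}, selected {rep.selected[:8]}")

table = merged_report([llm_rep, attn_rep, gain_rep], load_keywords())
uniques = table[table["unique_to"] != ""]
print(f"\nmerged table: {len(table)} keywords across 4 sources; "
      f"{len(uniques)} appear in a single source only")
print("keywords unique to the LLM output:",
      uniques[uniques['unique_to'] == 'llm_output']['keyword'].tolist()[:6])
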