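"""Majority-vote ensembling of three noisy models and the Venn error profile.

Three independent models that each err with probability e = 0.2 yield a
2-of-3 majority vote erring at 3e^2 - 2e^3 = 10.4% — error diversity is
what the ensemble converts into accuracy.
"""

from notesift import (
    BackendConfig,
    MockBackend,
    ensemble_run,
    filtered_spec,
    generate_corpus,
)

corpus = generate_corpus(filtered_spec(2000, 0.3, seed=31))
gold = dict(zip(corpus.ids, corpus.labels))

tables = []
for m in range(3):
    backend = MockBackend(BackendConfig(seed=100 + m, mock_error_rate=0.2))
    tables.append({s.section_id: backend.classify(s).verdict for s in corpus})

result = ensemble_run(tables, gold)
for i, mm in enumerate(result.per_model_metrics):
    print(f"model {i}: accuracy {mm.accuracy:.3f}")
ens_err = sum(p.label != gold[p.section_id] for p in result.predictions) / len(corpus)
print(f"ensemble error rate {ens_err:.3f} vs closed form 3e^2-2e^3 = 0.104")

profile = result.profile
print(f"error union {profile.union_size}, regions {profile.region_counts()}")
print(f"mutual errors (all three wrong): {profile.abc} "
      f"({100 * profile.mutual_error_share:.1f}% of the union) — small because "
      "the error profiles are independent")
assert profile.inclusion_exclusion_union == profile.union_size
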