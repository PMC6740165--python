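"""Benchmark the three similarity measures on a labeled synthetic corpus.

Generates a seeded corpus with known ground truth (single-edit typos on 20%
of records, concentration prefixes on 20%, 2% junk), standardizes it with
each measure, and reports accuracy at the two validation granularities:
value-level (over distinct raw values) and data-level (over records).
"""

from saltc import NoiseSpec, generate_corpus, load_registry, map_corpus, score_mapping

registry = load_registry()
spec = NoiseSpec(n_records=2000, seed=42, typo_rate=0.2, prefix_rate=0.2,
                 junk_rate=0.02, case_noise_rate=0.1)
corpus = generate_corpus(spec, registry)
print(f"corpus: {spec.n_records} records, "
      f"{len({(r.test_id, r.raw_value) for r in corpus})} distinct values\n")

print(f"{'measure':<12} {'value-level':>12} {'data-level':>12} {'to review':>10}")
for measure in ("cosine", "euclidean", "hybrid"):
    result = map_corpus(corpus, registry, measure)
    report = score_mapping(corpus, result.records)
    print(f"{measure:<12} {report.value_level:>12.4f} {report.data_level:>12.4f} "
          f"{report.n_review_values:>10}")

print("\nValue-level treats each distinct notation once; data-level weights")
print("frequent notations by their record counts. 'to review' counts distinct")
print("values the mapper abstained on (zero vector, or fully tied after the")
print("hybrid tie-break); cosine alone loses the collinear dipstick grades,")
print("which the hybrid measure recovers through its Euclidean tie-break.")
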