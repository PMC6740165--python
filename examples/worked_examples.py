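"""Map single worked inputs: the graded-tie case, dipstick reformatting, junk.

Shows why the hybrid measure exists: a concentration-prefixed grade like
"+++ 6" has a count vector collinear with every grade's vector, so cosine
similarity ties at 1.0 and only the Euclidean distance can separate them.
"""

from saltc import (
    Category,
    clean_pipeline,
    cosine_similarity,
    euclidean_distance,
    load_registry,
    match_value,
    vectorize,
)

registry = load_registry()

print("input '+++ 6' against the urine-dipstick value set:")
u = vectorize(clean_pipeline("+++ 6"))
for grade in ("+", "++", "+++", "++++"):
    v = vectorize(registry.get(Category.URINE_DIPSTICK, grade).comparison_string)
    print(f"  {grade:<5} cosine={cosine_similarity(u, v):.4f}  "
          f"euclidean={euclidean_distance(u, v):.4f}")
best = match_value(clean_pipeline("+++ 6"), Category.URINE_DIPSTICK, registry, "hybrid")
print(f"  hybrid pick: {best.best.label}  (cosine ties at 1.0; distance decides)\n")

clean = clean_pipeline("4+")
mapped = match_value(clean, Category.URINE_DIPSTICK, registry)
print(f"input '4+': reformatted to '{clean.text}', mapped to "
      f"'{mapped.best.label}' with SNOMED CT concept {mapped.best.snomed_id}\n")

junk = match_value(clean_pipeline("****"), Category.URINE_DIPSTICK, registry)
print(f"input '****': unmapped ({junk.reason})")
print("  junk carries no scheme character, so no similarity is defined and")
print("  the value is routed to manual review instead of guessed.")
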