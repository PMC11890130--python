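"""Assemble the three-level boolean PubMed query for one category's text.

MeSH descriptors found in the text are grouped by the leading letter of
their tree numbers; each group is OR-ed internally, the groups are AND-ed
into the MeSH subquery, extracted keyphrases are AND-ed into a second
subquery, and the final query OR-s the two.
"""

import healthfact as hf

TEXT = ("Hypertension means persistently raised blood pressure. "
        "Blood pressure checks during screening detect hypertension early. "
        "Untreated hypertension raises cardiovascular risk.")

vocab = hf.MeshVocabulary.load()  # packaged mini-vocabulary
mesh_terms = hf.extract_mesh_terms(TEXT, vocab)
print("MeSH terms:")
for t in mesh_terms:
    print(f"  {t.descriptor}  trees={list(t.tree_numbers)}  score={t.score:.2f}")

groups = hf.group_terms_by_category(mesh_terms)
print("tree-category groups:", {k: [t.descriptor for t in v] for k, v in groups.items()})

phrases = hf.extract_keyphrases(TEXT, top_n=3,
                                exclude=[t.descriptor.lower() for t in mesh_terms])
print("keyphrases:", [p.phrase for p in phrases])

query = hf.build_final_query([
    hf.build_mesh_subquery(groups),
    hf.build_keyphrase_subquery(phrases),
])
print("\nfinal PubMed query:\n ", query)

# the emitted string re-parses into an isomorphic tree (grammar conformance)
tree = hf.parse_query(query)
ops = hf.count_operators(tree)
print(f"re-parsed: {ops['AND']} ANDs, {ops['OR']} ORs, "
      f"{len(hf.query_terms(tree))} terms")
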