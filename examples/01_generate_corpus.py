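"""Generate a small synthetic clinical corpus and look at one sentence.

The generator fills bilingual narrative templates with surface variants of
canonical chemotherapy regimens ("EC ×4-TH ×4", "EC 序贯 TH", "CEF ×3-P ×3")
and emits aligned character-level gold labels plus a gold span table.
"""

from pascal import GeneratorConfig, extract_entities, generate_corpus

cfg = GeneratorConfig(n_sentences=500, n_patients=50, seed=7)
train, valid, test, spans = generate_corpus(cfg)
print(f"train/valid/test sentences: {len(train)}/{len(valid)}/{len(test)}")
print(f"gold mentions total: {len(spans)}")

sent = next(s for s in train if any(l != "O" for l in s.ten_labels))
print(f"\nsentence {sent.sentence_id} (patient {sent.patient_id}):")
print(" ", sent.text)
for span in extract_entities(sent.ten_labels, sent.ter_tags, sent.sentence_id):
    surface = sent.text[span.start : span.end]
    print(f"  characters [{span.start}, {span.end}) {surface!r} -> canonical {span.label}")
# Every character inside a mention carries the canonical regimen name;
# every other character is labeled "O".
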