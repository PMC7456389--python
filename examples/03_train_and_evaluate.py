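"""Train the full cascade on a small synthetic corpus and evaluate it.

Runs in a couple of minutes on one CPU.  For the larger scaled experiment
(2000/200/500 sentences) see scripts/acceptance.py at the repository root.
"""

import logging
from dataclasses import replace

from pascal import DESK_PRESET, GeneratorConfig, evaluate_model, generate_corpus, train

logging.basicConfig(level=logging.INFO, format="%(message)s")

cfg = GeneratorConfig(counts=(600, 60, 150), n_patients=50, seed=7)
train_c, valid_c, test_c, _ = generate_corpus(cfg)

result = train(train_c, valid_c, cfg.regimens, replace(DESK_PRESET, seed=1))
print(f"\nbest validation F1 {result.best_f1:.4f} at epoch {result.best_epoch}")

report = evaluate_model(result.model, test_c, result.char_vocab, cfg.regimens)
print(f"held-out entity exact match: P={report.precision:.4f} R={report.recall:.4f} F1={report.f1:.4f}")
# A mention counts as correct only when its canonical label, start and end
# character indices all match the gold span.
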