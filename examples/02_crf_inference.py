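"""Exact CRF inference on a tiny hand-built instance.

The CRF scores a labeling as the sum of per-position emissions plus
adjacent-label transition scores; the forward algorithm gives the exact
log-partition, and Viterbi the best path.  On a tiny instance both can be
cross-checked against brute-force enumeration.
"""

import numpy as np

from pascal import CrfParams, crf_log_partition, crf_score_sequence, viterbi_decode
from pascal.crf import enumerate_best_path, enumerate_log_partition

rng = np.random.default_rng(0)
N, L, d = 5, 3, 4  # 5 characters, 3 labels, 4-dim fused vectors
H_c = rng.normal(size=(N, d))
params = CrfParams(W=rng.normal(size=(d, L)), T=rng.normal(size=(L, L)))

logZ = crf_log_partition(H_c, params)
print(f"log-partition (forward algorithm): {logZ:.6f}")
print(f"log-partition (enumeration of {L}**{N} paths): {enumerate_log_partition(H_c, params):.6f}")

labels, score = viterbi_decode(H_c, params)
ref_labels, _ = enumerate_best_path(H_c, params)
print(f"Viterbi path {labels.tolist()}, score {score:.6f} (enumeration agrees: {(labels == ref_labels).all()})")
print(f"probability of the best path: {np.exp(score - logZ):.4f}")
# The gold-path negative log-likelihood used in training is logZ - score.
print(f"NLL if the best path were gold: {logZ - crf_score_sequence(H_c, labels, params):.6f}")
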