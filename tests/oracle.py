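"""Independent brute-force reference for recall.

Implements the output equation literally, neuron by neuron, with plain
Python loops, and resolves ties by the documented contract: first tied
set in schema order, uniformly random tied feature clamped (draw via
``rng.integers(n_candidates)``), clamps persist, outputs recomputed from
scratch.  Shares no code with the package's recall path.
"""

from __future__ import annotations

import numpy as np

NONE = -1
TIE_RTOL = 1e-12


def oracle_recall(state, memory, input_sets, rng):
    """Return ``(y, hit)`` for a recall trial, brute force."""
    schema = state.schema
    n = schema.n
    n_neurons = schema.neuron_count
    offsets = [int(v) for v in schema.offsets]
    weights = state.weights

    target = list(memory.feature_indices)
    e = [0.0] * n_neurons
    for s in sorted(set(input_sets)):
        e[offsets[s] + target[s]] = state.e_mag

    while True:
        # one synchronous pass: f_q = E_q + sum_p f*_p w_pq, f* = E
        f = []
        for q in range(n_neurons):
            total = e[q]
            for p in range(n_neurons):
                total += e[p] * weights[p, q]
            f.append(total)

        y = []
        tie_set = None
        tie_candidates = None
        for s in range(n):
            lo, hi = offsets[s], offsets[s + 1]
            seg = f[lo:hi]
            mx = max(seg)
            if mx <= 0.0:
                y.append(NONE)
                continue
            near = [j for j, v in enumerate(seg) if v >= mx - TIE_RTOL * mx]
            if len(near) == 1:
                y.append(near[0])
            else:
                y.append(None)
                if tie_set is None:
                    tie_set = s
                    tie_candidates = [lo + j for j in near if e[lo + j] == 0.0]
        if tie_set is None:
            hit = y == target
            return np.array(y, dtype=np.int64), hit
        pick = tie_candidates[int(rng.integers(len(tie_candidates)))]
        e[pick] = state.e_mag
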