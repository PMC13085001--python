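"""Deterministic random-stream management.

Every source of randomness in the package flows from one integer seed.
Independent stages draw from child streams derived with
:class:`numpy.random.SeedSequence` using a fixed per-stage integer code, so
two stages never share a stream and any stage can be re-run in isolation
and reproduce its output byte-for-byte.
"""

from __future__ import annotations

import numpy as np

# Fixed stage codes; changing these changes every simulated dataset.
STREAMS = {
    "universe": 11,
    "effects": 23,
    "counts": 37,
    "gene_sets": 53,
    "gsea": 71,
    "study": 89,
}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return the dedicated generator for *stage* under the global *seed*."""
    try:
        code = STREAMS[stage]
    except KeyError:
        raise ValueError(f"unknown random stream {stage!r}; known: {sorted(STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), code]))
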