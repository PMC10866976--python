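"""Seeded sub-stream derivation shared across modules.

Every stochastic operation draws from ``rng_stream(seed, *labels)``, where
the labels name the module and stage (e.g. ``("synthcohort", "phenotypes")``).
Streams are independent child streams of a :class:`numpy.random.SeedSequence`
keyed on the master seed plus a stable 32-bit hash of each label, so partial
reruns of one stage reproduce bit-identical draws regardless of what other
stages ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_stream(seed: int, *labels: str) -> np.random.Generator:
    keys = [int(seed)] + [zlib.crc32(lab.encode("utf-8")) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(keys))
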