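"""Small shared helpers: deterministic seed derivation and path handling."""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def derive_seed(base: int, *labels) -> int:
    """Derive an independent child seed from ``base`` and a sequence of labels.

    Labels (strings or ints) are hashed with CRC32 so the derivation is stable
    across processes and platforms. The result is always in ``[0, 2^31)``.
    """
    ints = [int(base) % _MOD]
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            ints.append(int(lab) % _MOD)
        else:
            ints.append(zlib.crc32(str(lab).encode("utf-8")) % _MOD)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % _MOD)


def rng_for(base: int, *labels) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded via :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(base, *labels))
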