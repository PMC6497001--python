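"""Deterministic seed derivation for nested experiments.

Every stochastic component in a sweep (graph topology, weight draw, input
mask, data stream) receives its own seed derived from a single master seed
plus a tuple of labels identifying the component's position in the
experiment (e.g. ``("mc", mu_index, rsig_index, sample_index)``).  The
derivation is a cryptographic hash, so it is stable across processes,
Python versions and worker counts, and collisions are negligible for any
practical label set.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *labels: int | str | float) -> int:
    """Derive a child seed in ``[0, 2**31)`` from a master seed and labels.

    Parameters
    ----------
    master
        The experiment's master seed.
    *labels
        Any mixture of ints, floats and strings identifying the component.
        At least one label is required.

    Returns
    -------
    int
        A non-negative 31-bit integer, suitable for ``numpy.random.default_rng``.
    """
    if not labels:
        raise ValueError("derive_seed requires at least one label")
    canonical = repr((int(master), tuple(labels)))
    digest = hashlib.sha256(canonical.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
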