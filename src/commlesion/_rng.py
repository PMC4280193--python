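"""Labelled random-number streams.

Every stochastic routine in the package draws from a stream derived from a
root seed and a tuple of string labels.  The derivation is a plain
``SeedSequence`` over ``(root_seed, crc32(label_1), crc32(label_2), ...)``,
so a (seed, label) pair always yields the same generator regardless of call
order — the property the experiment logs rely on for exact replay.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "stream_label"]


def stream_label(*labels: str | int) -> str:
    """Human-readable name of a derived stream, used in logs."""
    return "/".join(str(l) for l in labels)


def stream(root_seed: int, *labels: str | int) -> np.random.Generator:
    """Return the generator for the stream named by ``labels``.

    Parameters
    ----------
    root_seed
        Root seed of the experiment (a small non-negative integer).
    labels
        Path of string or integer labels naming the stream, e.g.
        ``("subject", "s03", "rep", 4)``.
    """
    entropy = [int(root_seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            entropy.append(int(lab) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(lab).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))
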