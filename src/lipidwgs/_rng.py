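"""Seed plumbing: one master seed, named per-module substreams."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of a master seed.

    Derivation is via ``SeedSequence(seed, spawn_key=(crc32(name),))`` so
    each (seed, name) pair yields an independent, reproducible stream and
    adding a new substream never perturbs existing ones.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
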