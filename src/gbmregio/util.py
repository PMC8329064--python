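"""Shared plumbing: logging and the seed-splitting scheme.

Every stage of the pipeline derives its randomness from one master integer
seed via a stable per-stage hash, so any stage can be regenerated in
isolation and two runs with the same master seed are bit-identical.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np

PACKAGE_LOGGER = "gbmregio"


def get_logger(name: str = "") -> logging.Logger:
    if name:
        return logging.getLogger(f"{PACKAGE_LOGGER}.{name}")
    return logging.getLogger(PACKAGE_LOGGER)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def child_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from a master seed.

    The stage name is hashed with CRC32 (stable across processes and
    Python versions, unlike ``hash``) and combined with the master seed
    through a ``SeedSequence``.
    """
    h = zlib.crc32(stage.encode("utf8"))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Stage-scoped ``numpy`` generator (see :func:`child_seed`)."""
    return np.random.default_rng(child_seed(seed, stage))
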