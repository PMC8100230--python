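"""Deterministic micro-fixtures for tests, docs and quick experimentation."""

from __future__ import annotations

import numpy as np

from .emotion import EmotionState
from .information import InformationPoint, InformationSchedule
from .network import SocialNetwork

__all__ = ["make_fixture"]


def make_fixture(kind: str, seed: int = 0):
    """Small deterministic objects: ``micro_net``, ``schedule`` or ``population``.

    * ``micro_net``: a 5-node star (hub 0), 4 edges.
    * ``schedule``: fully negative information flipping to fully positive at
      step 3.
    * ``population``: a 5-agent :class:`EmotionState` with reproducible
      panic/conformity values drawn from ``seed``.
    """
    if kind == "micro_net":
        edges = np.array([[0, 1], [0, 2], [0, 3], [0, 4]])
        return SocialNetwork(5, 1, edges)
    if kind == "schedule":
        return InformationSchedule(
            (
                (0, InformationPoint(im_neg=1.0, is_neg=1.0)),
                (3, InformationPoint(im_pos=1.0, is_pos=1.0)),
            )
        )
    if kind == "population":
        rng = np.random.default_rng(seed)
        return EmotionState(panic=rng.random(5), conformity=rng.random(5))
    raise ValueError(f"unknown fixture kind {kind!r}")
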