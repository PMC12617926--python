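"""Negative-sample selection.

The guilt-by-association sampler rests on the premise that sites dissimilar
to a disease's validated sites rarely share that disease's pathways: for each
positive (s_i, d_j) it picks the candidate pairs (s_k, d_j) whose site
similarity C_SS[s_i, s_k] is lowest.  A uniform-random sampler is provided
for ablation comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_io import ValidationError
from .multiview import AffinityMatrix


class SamplerMethod(str, Enum):
    GBA = "gba"
    RANDOM = "random"


class PoolExhaustedError(RuntimeError):
    pass


@dataclass
class SamplerConfig:
    method: SamplerMethod = SamplerMethod.GBA
    ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.method = SamplerMethod(self.method)
        if self.ratio <= 0:
            raise ValidationError("ratio must be positive")


def sample_negatives_gba(
    positives: set[tuple[str, str]],
    C_ss: AffinityMatrix,
    ratio: float,
    seed: int = 0,
    exclude: set[tuple[str, str]] | None = None,
    strict: bool = True,
) -> set[tuple[str, str]]:
    """Least-similar-site negatives, ceil(ratio) per positive, globally trimmed.

    Deterministic: positives are processed in sorted order; for each, same-
    disease candidates are ranked by ascending similarity to the positive's
    site with ties broken by ascending site index; a pair is never selected
    twice.  The final selection is trimmed to ratio*|positives| pairs in
    selection order.  The seed is accepted for interface symmetry with the
    random sampler but the procedure is fully deterministic.

    With ``strict`` (the default) a positive whose disease column cannot
    supply its quota raises :class:`PoolExhaustedError`.  ``strict=False``
    instead makes up the global budget by continuing round-robin down the
    other positives' candidate lists (still least-similar, same-disease
    pairs); only an empty global pool raises.  The cross-validation driver
    uses the non-strict mode because a heavily annotated disease can
    legitimately run out of same-column candidates at high ratios.
    """
    if not positives:
        raise ValidationError("no positives to anchor negative sampling")
    exclude = exclude or set()
    site_pos = {s: i for i, s in enumerate(C_ss.entity_ids)}
    per_pos = math.ceil(ratio)
    budget = int(round(ratio * len(positives)))
    taken: set[tuple[str, str]] = set()

    ranked: list[list[tuple[str, str]]] = []
    for s_i, d_j in sorted(positives):
        if s_i not in site_pos:
            raise ValidationError(f"site {s_i!r} missing from the affinity matrix")
        sims = C_ss.values[site_pos[s_i]]
        order = sorted(range(len(C_ss.entity_ids)), key=lambda k: (sims[k], k))
        ranked.append(
            [
                (C_ss.entity_ids[k], d_j)
                for k in order
                if (C_ss.entity_ids[k], d_j) not in positives
                and (C_ss.entity_ids[k], d_j) not in exclude
            ]
        )

    selected: list[tuple[str, str]] = []
    cursors = [0] * len(ranked)

    def advance(i: int) -> bool:
        cands = ranked[i]
        while cursors[i] < len(cands):
            pair = cands[cursors[i]]
            cursors[i] += 1
            if pair not in taken:
                selected.append(pair)
                taken.add(pair)
                return True
        return False

    for i, (s_i, d_j) in enumerate(sorted(positives)):
        got = sum(advance(i) for _ in range(per_pos))
        if got < per_pos and strict:
            raise PoolExhaustedError(
                f"candidate pool exhausted for positive ({s_i}, {d_j}): "
                f"needed {per_pos}, found {got}"
            )
    if not strict:
        # round-robin compensation for columns that ran dry
        progress = True
        while len(selected) < budget and progress:
            progress = False
            for i in range(len(ranked)):
                if len(selected) >= budget:
                    break
                progress = advance(i) or progress
        if len(selected) < budget:
            raise PoolExhaustedError(
                f"global candidate pool exhausted: {len(selected)} of {budget}"
            )
    return set(selected[:budget])


def sample_negatives_random(
    positives: set[tuple[str, str]],
    universe: list[tuple[str, str]],
    ratio: float,
    seed: int = 0,
    exclude: set[tuple[str, str]] | None = None,
) -> set[tuple[str, str]]:
    """Uniform sample without replacement from universe minus positives/exclude."""
    if not positives:
        raise ValidationError("no positives to size the negative sample")
    exclude = exclude or set()
    pool = sorted(set(universe) - positives - exclude)
    size = int(round(ratio * len(positives)))
    if len(pool) < size:
        raise PoolExhaustedError(
            f"candidate pool has {len(pool)} pairs, need {size}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=size, replace=False)
    return {pool[i] for i in idx}


def sample_negatives(
    config: SamplerConfig,
    positives: set[tuple[str, str]],
    C_ss: AffinityMatrix,
    universe: list[tuple[str, str]],
    exclude: set[tuple[str, str]] | None = None,
    strict: bool = True,
) -> set[tuple[str, str]]:
    if config.method is SamplerMethod.GBA:
        return sample_negatives_gba(
            positives, C_ss, config.ratio, config.seed, exclude, strict=strict
        )
    return sample_negatives_random(positives, universe, config.ratio, config.seed, exclude)
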