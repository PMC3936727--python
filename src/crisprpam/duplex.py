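"""Repeat:anti-repeat hybridization scoring.

A base-pair-weighted, antiparallel, inter-strand alignment by dynamic
programming: GC pairs score 3, AU 2, the GU wobble 1, an opposed
non-complementary pair costs 1 and each unpaired (bulged) position inside
the duplex costs 2.  The alignment is local — the empty duplex scores 0 —
so the score is never negative.  This is an explicitly non-thermodynamic
score: it ranks and compares the extent of repeat:anti-repeat pairing
across loci, it does not estimate folding free energies, and intra-strand
structure is ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping

log = logging.getLogger(__name__)

DEFAULT_WEIGHTS = {"GC": 3, "AU": 2, "GU": 1}
DEFAULT_GAP_PENALTY = -2
DEFAULT_MISMATCH_PENALTY = -1
_RNA = set("ACGU")


class DuplexUsageError(ValueError):
    """Bad arguments to the hybridization routine."""


@dataclass(frozen=True)
class DuplexAlignment:
    """An antiparallel pairing between two RNA strands.

    ``pairs`` holds (i, j) 0-based positions, i ascending on strand 1 and j
    descending on strand 2 (non-crossing, antiparallel).  ``structure`` is a
    dot-bracket-style annotation: '(' on strand 1 and ')' on strand 2 at
    paired positions.
    """

    pairs: tuple[tuple[int, int], ...]
    score: int
    structure: tuple[str, str]

    def __post_init__(self) -> None:
        last_i, last_j = -1, None
        for i, j in self.pairs:
            if i <= last_i or (last_j is not None and j >= last_j):
                raise DuplexUsageError("pairs must be increasing in i, decreasing in j")
            last_i, last_j = i, j

    def to_json(self) -> str:
        return json.dumps(
            {
                "score": self.score,
                "pairs": [list(p) for p in self.pairs],
                "strand1": self.structure[0],
                "strand2": self.structure[1],
            },
            indent=2,
        )


def _pair_weight(x: str, y: str, weights: Mapping[str, int]) -> int | None:
    key = "".join(sorted((x, y)))
    table = {"CG": weights["GC"], "AU": weights["AU"], "GU": weights["GU"]}
    return table.get(key)


def _clean(seq: str, name: str) -> str:
    s = seq.upper()
    if "T" in s:
        log.warning("%s looks like DNA; converting T -> U", name)
        s = s.replace("T", "U")
    bad = set(s) - _RNA
    if bad:
        raise DuplexUsageError(f"{name}: non-RNA letters {sorted(bad)}")
    return s


def hybridize(
    repeat: str,
    antirepeat_region: str,
    weights: Mapping[str, int] = DEFAULT_WEIGHTS,
    gap_penalty: int = DEFAULT_GAP_PENALTY,
    mismatch_penalty: int = DEFAULT_MISMATCH_PENALTY,
) -> DuplexAlignment:
    """Maximum-scoring antiparallel duplex between two strands.

    Implemented as a local alignment of strand 1 against the reverse of
    strand 2: aligned complementary columns become base pairs at their
    weight, aligned non-complementary columns pay the mismatch penalty, and
    bulged positions inside the duplex pay the gap penalty.
    """
    s1 = _clean(repeat, "strand 1")
    s2 = _clean(antirepeat_region, "strand 2")
    if not (1 <= len(s1) <= 200 and 1 <= len(s2) <= 200):
        raise DuplexUsageError("strand lengths must be 1-200 nt")

    r2 = s2[::-1]  # index a on r2 is position len(s2)-1-a on strand 2
    n, m = len(s1), len(r2)

    # Smith–Waterman-style local DP with linear gaps
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for a in range(1, m + 1):
            w = _pair_weight(s1[i - 1], r2[a - 1], weights)
            col = w if w is not None else mismatch_penalty
            H[i][a] = max(
                0,
                H[i - 1][a - 1] + col,
                H[i - 1][a] + gap_penalty,
                H[i][a - 1] + gap_penalty,
            )

    best, bi, ba = 0, 0, 0
    for i in range(n + 1):
        for a in range(m + 1):
            if H[i][a] > best:
                best, bi, ba = H[i][a], i, a

    # traceback (deterministic preference: diagonal, up, left)
    pairs: list[tuple[int, int]] = []
    i, a = bi, ba
    while i > 0 and a > 0 and H[i][a] > 0:
        w = _pair_weight(s1[i - 1], r2[a - 1], weights)
        col = w if w is not None else mismatch_penalty
        if H[i][a] == H[i - 1][a - 1] + col:
            if w is not None:
                pairs.append((i - 1, len(s2) - 1 - (a - 1)))
            i, a = i - 1, a - 1
        elif H[i][a] == H[i - 1][a] + gap_penalty:
            i -= 1
        else:
            a -= 1
    pairs.reverse()

    ann1 = ["."] * n
    ann2 = ["."] * len(s2)
    for pi, pj in pairs:
        ann1[pi] = "("
        ann2[pj] = ")"
    return DuplexAlignment(
        pairs=tuple(pairs),
        score=best,
        structure=("".join(ann1), "".join(ann2)),
    )
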