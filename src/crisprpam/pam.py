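"""PAM evidence from protospacer hits.

The PAM of a type II system sits immediately 3' of the protospacer on the
non-target strand.  Given hits, this module extracts the fixed-width flank
(10 nt by default), stacks flanks into a position frequency matrix, scores
per-position information content (2 - Shannon entropy, bits) and calls a
degenerate IUPAC consensus with a cumulative-coverage rule: at each position
bases are included in descending frequency, ties included together, until
the included fraction reaches the coverage threshold (0.8 by default).  A
balanced A/C position therefore surfaces as 'M' rather than being silently
resolved — the kind of ambiguity that, in real data, only a cleavage assay
can settle.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .search import ProtospacerHit
from .seqio import IUPAC_FOR_SET, SequenceRecord, revcomp

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_FLANK_LEN = 10
DEFAULT_COVERAGE = 0.8
DEFAULT_MIN_SUPPORT = 3


class PamUsageError(ValueError):
    """Bad arguments to the PAM routines."""


class NoFlanksError(PamUsageError):
    """No usable flanks; the field fallback is to pool closely related strains."""


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position A/C/G/T counts over ``n`` stacked fixed-width flanks."""

    counts: np.ndarray          # (width, 4) ints
    skipped: np.ndarray         # (width,) ambiguous bases excluded per position
    n: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        skipped = np.asarray(self.skipped, dtype=int)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "skipped", skipped)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise PamUsageError("counts must be (width, 4)")
        if (counts < 0).any() or (skipped < 0).any():
            raise PamUsageError("negative counts")
        if not np.array_equal(counts.sum(axis=1) + skipped, np.full(counts.shape[0], self.n)):
            raise PamUsageError("per-position counts + skipped must equal n")

    @property
    def width(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class PamProfile:
    """Consensus + logo data for one group/source of flanks."""

    consensus: str
    ic: np.ndarray              # (width,) bits in [0, 2]
    freqs: np.ndarray           # (width, 4) base fractions of usable counts
    n: int
    pfm: PositionFrequencyMatrix
    partition_label: str | None = None

    def to_dict(self) -> dict:
        return {
            "consensus": self.consensus,
            "ic": [round(float(x), 6) for x in self.ic],
            "freqs": [[round(float(x), 6) for x in row] for row in self.freqs],
            "n": self.n,
            "partition_label": self.partition_label,
        }


def extract_flank(
    hit: ProtospacerHit, target: SequenceRecord, flank_len: int = DEFAULT_FLANK_LEN
) -> str | None:
    """The ``flank_len`` bases immediately 3' of the matched span.

    Read 5'->3' on the matched strand (the strand carrying the spacer
    sequence, i.e. the non-target strand).  Returns None with a warning when
    the contig ends before ``flank_len`` bases — short flanks are dropped,
    not padded, to avoid biasing terminal positions.
    """
    if hit.target_id != target.id:
        raise PamUsageError(f"hit targets {hit.target_id!r}, record is {target.id!r}")
    seq = target.residues
    if hit.strand == "+":
        lo, hi = hit.end, hit.end + flank_len
        if hi > len(seq):
            log.warning("hit %s@%s:%d: only %d nt downstream; flank dropped",
                        hit.spacer_id, target.id, hit.start, len(seq) - hit.end)
            return None
        return seq[lo:hi]
    lo, hi = hit.start - flank_len, hit.start
    if lo < 0:
        log.warning("hit %s@%s:%d: only %d nt downstream (reverse strand); flank dropped",
                    hit.spacer_id, target.id, hit.start, hit.start)
        return None
    return revcomp(seq[lo:hi])


def build_pfm(flanks: Sequence[str], width: int = DEFAULT_FLANK_LEN) -> PositionFrequencyMatrix:
    """Stack fixed-width flanks into per-position base counts.

    Ambiguous (non-ACGT) bases are tallied in ``skipped`` rather than
    counted.  Flanks are positionally aligned — fixed width makes the
    'alignment' plain stacking.
    """
    if not flanks:
        raise NoFlanksError(
            "no flanks to stack (no protospacers found); consider pooling spacers "
            "from closely related strains of the same species"
        )
    counts = np.zeros((width, 4), dtype=int)
    skipped = np.zeros(width, dtype=int)
    for f in flanks:
        if len(f) != width:
            raise PamUsageError(f"flank {f!r} has length {len(f)}, expected {width}")
        for pos, base in enumerate(f.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                skipped[pos] += 1
            else:
                counts[pos, idx] += 1
    return PositionFrequencyMatrix(counts=counts, skipped=skipped, n=len(flanks))


def base_frequencies(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-position base fractions over usable (unambiguous) counts."""
    usable = pfm.counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(usable > 0, pfm.counts / np.maximum(usable, 1), 0.0)
    return freqs


def information_content(
    pfm: PositionFrequencyMatrix, small_sample_correction: bool = False
) -> np.ndarray:
    """IC(pos) = 2 - H(pos) bits, H the base-2 Shannon entropy of the column.

    With ``small_sample_correction`` the Schneider e(n) = 3 / (2 ln2 n) term
    is subtracted (floored at 0).  A column with zero usable counts gets IC
    0 with a warning.
    """
    if pfm.n < 1:
        raise PamUsageError("empty matrix")
    freqs = base_frequencies(pfm)
    usable = pfm.counts.sum(axis=1)
    ic = np.zeros(pfm.width)
    for pos in range(pfm.width):
        if usable[pos] == 0:
            log.warning("position %d has no usable counts; IC set to 0", pos + 1)
            continue
        p = freqs[pos][freqs[pos] > 0]
        h = float(-(p * np.log2(p)).sum())
        val = 2.0 - h
        if small_sample_correction:
            val -= 3.0 / (2.0 * math.log(2.0) * usable[pos])
        ic[pos] = min(2.0, max(0.0, val))
    return ic


DEFAULT_MIN_IC = 0.25


def call_consensus(
    pfm: PositionFrequencyMatrix,
    coverage: float = DEFAULT_COVERAGE,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_ic: float = DEFAULT_MIN_IC,
) -> str:
    """Degenerate IUPAC consensus under the cumulative-coverage rule.

    Per position, bases are added in descending frequency (frequency ties
    added together) until the cumulative fraction reaches ``coverage``; the
    IUPAC letter of the included set is emitted (all four -> 'N').  A
    position whose information content falls below ``min_ic`` bits is
    written 'N' outright — that is how a logo is read in practice: positions
    where no base rises above sampling noise are uninformative, whatever
    three-letter code the coverage rule would produce.  The 0.25-bit
    default sits far above the ~3/(2 n ln2) bits a uniform column shows
    from sampling alone at n around 50, and below the 2 - log2(3) = 0.415
    bits of a genuinely three-base position.  Refuses to run below
    ``min_support`` flanks, mirroring the field practice of pooling spacers
    from closely related strains when evidence is thin.
    """
    if not (0.0 < coverage <= 1.0):
        raise PamUsageError(f"coverage {coverage} outside (0, 1]")
    if pfm.n < min_support:
        raise PamUsageError(
            f"only {pfm.n} flank(s); a consensus needs >= {min_support} "
            "(pool closely related strains or lower min_support)"
        )
    freqs = base_frequencies(pfm)
    ic = information_content(pfm)
    usable = pfm.counts.sum(axis=1)
    letters = []
    for pos in range(pfm.width):
        if ic[pos] < min_ic:
            letters.append("N")
            continue
        if usable[pos] == 0:
            log.warning("position %d has no usable counts; consensus 'N'", pos + 1)
            letters.append("N")
            continue
        order = sorted(range(4), key=lambda i: (-freqs[pos, i], BASES[i]))
        included: set[str] = set()
        cum = 0.0
        i = 0
        while i < 4 and (cum < coverage - 1e-12 or not included):
            f = freqs[pos, order[i]]
            # include the whole frequency tie at once
            tie = [k for k in order[i:] if abs(freqs[pos, k] - f) < 1e-12]
            for k in tie:
                if freqs[pos, k] > 0 or not included:
                    included.add(BASES[k])
                    cum += freqs[pos, k]
            i += len(tie)
        letters.append(IUPAC_FOR_SET[frozenset(included)])
    return "".join(letters)


def profile_from_flanks(
    flanks: Sequence[str],
    width: int = DEFAULT_FLANK_LEN,
    coverage: float = DEFAULT_COVERAGE,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_ic: float = DEFAULT_MIN_IC,
    small_sample_correction: bool = False,
    partition_label: str | None = None,
) -> PamProfile:
    pfm = build_pfm(flanks, width=width)
    return PamProfile(
        consensus=call_consensus(pfm, coverage=coverage, min_support=min_support, min_ic=min_ic),
        ic=information_content(pfm, small_sample_correction=small_sample_correction),
        freqs=base_frequencies(pfm),
        n=pfm.n,
        pfm=pfm,
        partition_label=partition_label,
    )


def partition_by_source(
    hits: Sequence[ProtospacerHit],
    targets: Sequence[SequenceRecord],
    flank_len: int = DEFAULT_FLANK_LEN,
    coverage: float = DEFAULT_COVERAGE,
    min_support: int = 1,
) -> dict[str, PamProfile]:
    """One profile per source class with at least one usable flank.

    Comparing the phage/plasmid partition with the genome partition is how a
    self-tolerant chromosomal PAM variant (e.g. a C where the functional PAM
    has A) becomes visible.
    """
    by_id = {t.id: t for t in targets}
    flanks_by_class: dict[str, list[str]] = {}
    for h in hits:
        target = by_id.get(h.target_id)
        if target is None:
            raise PamUsageError(f"hit references unknown target {h.target_id!r}")
        flank = extract_flank(h, target, flank_len)
        if flank is not None:
            flanks_by_class.setdefault(h.source_class, []).append(flank)
    return {
        cls: profile_from_flanks(
            fl, width=flank_len, coverage=coverage, min_support=min_support, partition_label=cls
        )
        for cls, fl in sorted(flanks_by_class.items())
    }


def export_logo_data(pfm: PositionFrequencyMatrix) -> pd.DataFrame:
    """Long table (position, base, height) with height = freq x IC.

    Heights at each position sum to that position's information content —
    the standard stacked-letter logo parameterisation, consumable by any
    logo renderer.
    """
    freqs = base_frequencies(pfm)
    ic = information_content(pfm)
    rows = [
        {"position": pos + 1, "base": BASES[i], "height": float(freqs[pos, i] * ic[pos])}
        for pos in range(pfm.width)
        for i in range(4)
    ]
    return pd.DataFrame(rows)


def write_pfm_tsv(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    df = pd.DataFrame(pfm.counts, columns=list(BASES))
    df.insert(0, "position", np.arange(1, pfm.width + 1))
    df["skipped"] = pfm.skipped
    df.to_csv(path, sep="\t", index=False)


def write_profile_json(profiles: Mapping[str, PamProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: p.to_dict() for k, p in profiles.items()}, fh, indent=2)
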