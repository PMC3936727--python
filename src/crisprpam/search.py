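"""Protospacer candidate search: spacers matched against targets at >=90% identity.

An in-package replacement for a BLAST-style search at desk scale.  A spacer
matches a target window under a semi-global alignment (spacer fully aligned,
window overhangs free) with unit match/mismatch and affine gaps; identity is
anchored to the spacer length, ``matches / len(spacer)``, which makes the
90% retention threshold unambiguous.  Candidate windows come from a
pigeonhole seed filter (split the spacer into e+1 exact chunks for edit
budget e; any hit within budget preserves one chunk verbatim), each verified
by full dynamic programming, so no true hit above threshold is missed at the
configured divergence and gap budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio import CrisprLocus, SequenceRecord, revcomp

log = logging.getLogger(__name__)

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = 5        # cost of opening a gap run
GAP_EXTEND = 2      # cost per gapped column
DEFAULT_MAX_GAPS = 2

# lexicographic (score, matches, -gaps) packed into one integer per DP cell
_GAP_SLOT = 2048          # gaps < 2047
_MATCH_SLOT = 1024        # matches < 1024 (spacer <= 60 nt in practice)
_K2 = _GAP_SLOT
_K1 = _MATCH_SLOT * _GAP_SLOT
_BASE = _GAP_SLOT - 1     # start offset so that (value % slot) == slot-1-gaps
_NEG = -(1 << 60)


class SearchUsageError(ValueError):
    """Bad arguments to the search routines."""


@dataclass(frozen=True)
class SpacerAlignment:
    """Best semi-global placement of a spacer inside one window."""

    score: int
    matches: int
    gaps: int
    identity: float
    window_start: int
    window_end: int


@dataclass(frozen=True)
class ProtospacerHit:
    """A spacer match on a target, on the target's forward-strand coordinates.

    ``protospacer_seq`` reads 5'->3' on the matched strand — the strand on
    which the spacer sequence itself occurs (the non-target strand), which
    is also the strand carrying the PAM immediately 3' of the match.
    """

    spacer_id: str
    locus_id: str
    target_id: str
    start: int
    end: int
    strand: str
    identity: float
    matches: int
    gaps: int
    score: int
    protospacer_seq: str
    source_class: str = "unknown"


def _column_value(match: bool) -> int:
    if match:
        return MATCH_SCORE * _K1 + _K2
    return MISMATCH_SCORE * _K1


_GAP_EXT_V = -GAP_EXTEND * _K1 - 1
_GAP_OPEN_V = -GAP_OPEN * _K1


def align_spacer(spacer: str, window: str) -> SpacerAlignment:
    """Best semi-global alignment of ``spacer`` inside ``window``.

    The spacer is aligned end to end; window overhangs are free.  Scoring is
    match +1 / mismatch -2, and a gap run of length g costs 5 + 2g.  Among
    co-optimal alignments the one with most matches, then fewest gaps, then
    the leftmost window span is returned; identity = matches / len(spacer).
    """
    m, n = len(spacer), len(window)
    if m == 0:
        raise SearchUsageError("empty spacer")
    if m > n:
        raise SearchUsageError(f"spacer ({m} nt) longer than window ({n} nt)")
    if n > 2000:
        raise SearchUsageError("window too long for the packed DP encoding")

    # three-state affine DP; each cell carries (packed value, window start)
    # with ties resolved toward the smaller start.
    open_ext = _GAP_OPEN_V + _GAP_EXT_V

    prevM = [_NEG] * (n + 1)
    prevD = [_NEG] * (n + 1)
    prevI = [_NEG] * (n + 1)
    prevMs = [0] * (n + 1)
    prevDs = [0] * (n + 1)
    prevIs = [0] * (n + 1)

    for i in range(1, m + 1):
        si = spacer[i - 1]
        curM = [_NEG] * (n + 1)
        curD = [_NEG] * (n + 1)
        curI = [_NEG] * (n + 1)
        curMs = [0] * (n + 1)
        curDs = [0] * (n + 1)
        curIs = [0] * (n + 1)
        first = i == 1
        for j in range(0, n + 1):
            # D: gap in window (consume spacer char i without a window char)
            best, bs = _NEG, 0
            v = prevM[j] + open_ext
            if v > best or (v == best and prevMs[j] < bs):
                best, bs = v, prevMs[j]
            v = prevD[j] + _GAP_EXT_V
            if v > best or (v == best and prevDs[j] < bs):
                best, bs = v, prevDs[j]
            v = prevI[j] + open_ext
            if v > best or (v == best and prevIs[j] < bs):
                best, bs = v, prevIs[j]
            if first:
                v = _BASE + open_ext
                if v > best or (v == best and j < bs):
                    best, bs = v, j
            curD[j], curDs[j] = best, bs

            if j == 0:
                continue

            # M: spacer char i aligned to window char j
            col = _column_value(si == window[j - 1])
            best, bs = _NEG, 0
            v = prevM[j - 1]
            if v > best or (v == best and prevMs[j - 1] < bs):
                best, bs = v, prevMs[j - 1]
            v = prevD[j - 1]
            if v > best or (v == best and prevDs[j - 1] < bs):
                best, bs = v, prevDs[j - 1]
            v = prevI[j - 1]
            if v > best or (v == best and prevIs[j - 1] < bs):
                best, bs = v, prevIs[j - 1]
            if first and _BASE > best:
                best, bs = _BASE, j - 1
            elif first and _BASE == best and j - 1 < bs:
                bs = j - 1
            if best > _NEG:
                curM[j], curMs[j] = best + col, bs

            # I: gap in spacer (consume window char j inside the alignment)
            best, bs = _NEG, 0
            v = curM[j - 1] + open_ext
            if v > best or (v == best and curMs[j - 1] < bs):
                best, bs = v, curMs[j - 1]
            v = curI[j - 1] + _GAP_EXT_V
            if v > best or (v == best and curIs[j - 1] < bs):
                best, bs = v, curIs[j - 1]
            v = curD[j - 1] + open_ext
            if v > best or (v == best and curDs[j - 1] < bs):
                best, bs = v, curDs[j - 1]
            curI[j], curIs[j] = best, bs

        prevM, prevD, prevI = curM, curD, curI
        prevMs, prevDs, prevIs = curMs, curDs, curIs

    # free trailing window: best over all end columns, ending in M or D
    best, bstart, bend = _NEG, 0, 0
    for j in range(0, n + 1):
        for arr, starts in ((prevM, prevMs), (prevD, prevDs)):
            v = arr[j]
            if v > best or (v == best and (starts[j], j) < (bstart, bend)):
                best, bstart, bend = v, starts[j], j
    if best <= _NEG:
        raise SearchUsageError("alignment failed")  # pragma: no cover

    gaps = _BASE - (best % _GAP_SLOT)
    rem = best // _GAP_SLOT
    matches = rem % _MATCH_SLOT
    score = rem // _MATCH_SLOT
    return SpacerAlignment(
        score=score,
        matches=matches,
        gaps=gaps,
        identity=matches / m,
        window_start=bstart,
        window_end=bend,
    )


def _candidate_windows(spacer: str, target: str, max_edits: int) -> list[tuple[int, int]]:
    """Pigeonhole seed filter: window starts where a hit could lie."""
    L = len(spacer)
    n_chunks = max_edits + 1
    bounds = [round(k * L / n_chunks) for k in range(n_chunks + 1)]
    pad = max_edits + 1
    windows: set[tuple[int, int]] = set()
    for k in range(n_chunks):
        off, nxt = bounds[k], bounds[k + 1]
        chunk = spacer[off:nxt]
        if not chunk:
            continue
        pos = target.find(chunk)
        while pos != -1:
            ws = max(0, pos - off - pad)
            we = min(len(target), pos - off + L + pad)
            if we - ws >= L:
                windows.add((ws, we))
            pos = target.find(chunk, pos + 1)
    return sorted(windows)


def _scan_strand(
    spacer_id: str,
    locus_id: str,
    spacer: str,
    target: SequenceRecord,
    strand: str,
    min_identity: float,
    max_gaps: int,
) -> list[ProtospacerHit]:
    seq = target.residues
    L = len(spacer)
    query = spacer if strand == "+" else revcomp(spacer)
    max_mismatch = int((1.0 - min_identity) * L)
    max_edits = max_mismatch + max_gaps
    hits = []
    for ws, we in _candidate_windows(query, seq, max_edits):
        aln = align_spacer(query, seq[ws:we])
        if aln.identity < min_identity or aln.gaps > max_gaps:
            continue
        start, end = ws + aln.window_start, ws + aln.window_end
        span = seq[start:end]
        hits.append(
            ProtospacerHit(
                spacer_id=spacer_id,
                locus_id=locus_id,
                target_id=target.id,
                start=start,
                end=end,
                strand=strand,
                identity=aln.identity,
                matches=aln.matches,
                gaps=aln.gaps,
                score=aln.score,
                protospacer_seq=span if strand == "+" else revcomp(span),
            )
        )
    return hits


def _dedup_overlapping(hits: list[ProtospacerHit]) -> list[ProtospacerHit]:
    """Keep the best hit among overlapping same-spacer spans (ties: leftmost)."""

    def better(a: ProtospacerHit, b: ProtospacerHit) -> ProtospacerHit:
        ka = (a.score, a.matches, -a.gaps, -a.start, a.strand == "+")
        kb = (b.score, b.matches, -b.gaps, -b.start, b.strand == "+")
        return a if ka >= kb else b

    out: list[ProtospacerHit] = []
    for key in sorted({(h.target_id, h.spacer_id) for h in hits}):
        group = sorted(
            (h for h in hits if (h.target_id, h.spacer_id) == key),
            key=lambda h: (h.start, h.end),
        )
        kept: list[ProtospacerHit] = []
        for h in group:
            merged = False
            for i, k in enumerate(kept):
                if h.start < k.end and k.start < h.end:
                    kept[i] = better(k, h)
                    merged = True
                    break
            if not merged:
                kept.append(h)
        out.extend(kept)
    return out


def find_protospacers(
    loci: Sequence[CrisprLocus],
    targets: Sequence[SequenceRecord],
    min_identity: float = 0.90,
    both_strands: bool = True,
    max_gaps: int = DEFAULT_MAX_GAPS,
    mask: Iterable[tuple[str, int, int]] | None = None,
) -> list[ProtospacerHit]:
    """All spacer matches at >= ``min_identity`` across all targets.

    Both strands are scanned by default; overlapping hits of the same spacer
    on a target are deduplicated to the best-scoring span; results are
    sorted by (target_id, start).  ``mask`` intervals (target_id, start,
    end) exclude self-array matches.
    """
    spacers = [(locus.locus_id, sid, seq) for locus in loci for sid, seq in locus.spacers]
    if not spacers:
        raise SearchUsageError("no spacers supplied")
    if not targets:
        log.warning("no targets supplied; returning no hits")
        return []
    if not (0.0 < min_identity <= 1.0):
        raise SearchUsageError(f"min_identity {min_identity} outside (0, 1]")

    strands = ("+", "-") if both_strands else ("+",)
    hits: list[ProtospacerHit] = []
    for target in targets:
        for locus_id, sid, spacer in spacers:
            if len(spacer) > len(target.residues):
                continue
            for strand in strands:
                hits.extend(
                    _scan_strand(sid, locus_id, spacer, target, strand, min_identity, max_gaps)
                )

    if mask is not None:
        masked = list(mask)
        kept = []
        for h in hits:
            if any(t == h.target_id and h.start < e and s < h.end for t, s, e in masked):
                log.info("hit %s@%s:%d dropped: inside masked array region", h.spacer_id, h.target_id, h.start)
                continue
            kept.append(h)
        hits = kept

    hits = _dedup_overlapping(hits)
    hits.sort(key=lambda h: (h.target_id, h.start, h.end, h.spacer_id, h.strand))
    return hits


def classify_source(hit: ProtospacerHit, target_metadata: Mapping[str, str]) -> ProtospacerHit:
    """Label a hit phage/plasmid/genome from declared target metadata.

    Unmapped targets fall back to ``unknown``.  Genome-class hits are kept
    (a chromosomal protospacer can carry a mutated, self-tolerant PAM and is
    informative precisely because its flank consensus may differ).
    """
    cls = target_metadata.get(hit.target_id, "unknown")
    if cls not in ("phage", "plasmid", "genome", "unknown"):
        raise SearchUsageError(f"bad source class {cls!r} for target {hit.target_id!r}")
    if cls == "genome":
        log.info("hit %s@%s classified genome: possible self-derived protospacer", hit.spacer_id, hit.target_id)
    return replace(hit, source_class=cls)


def classify_sources(
    hits: Sequence[ProtospacerHit], target_metadata: Mapping[str, str]
) -> list[ProtospacerHit]:
    return [classify_source(h, target_metadata) for h in hits]


def read_target_metadata(path: str | Path) -> dict[str, str]:
    """TSV with columns target_id, class."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["target_id"], df["class"]))


def write_bed(hits: Sequence[ProtospacerHit], path: str | Path) -> None:
    """BED6: name = spacer_id, score = round(identity * 1000)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.target_id}\t{h.start}\t{h.end}\t{h.spacer_id}\t{round(h.identity * 1000)}\t{h.strand}\n"
            )


def write_gff3(hits: Sequence[ProtospacerHit], path: str | Path) -> None:
    """GFF3 (1-based, inclusive) with identity/source attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            attrs = (
                f"ID={h.spacer_id}_{h.target_id}_{h.start};spacer_id={h.spacer_id};"
                f"identity={h.identity:.4f};source_class={h.source_class}"
            )
            fh.write(
                f"{h.target_id}\tcrisprpam\tprotospacer\t{h.start + 1}\t{h.end}\t"
                f"{round(h.identity * 1000)}\t{h.strand}\t.\t{attrs}\n"
            )
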