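"""Ortholog clustering under coverage thresholds.

The procedure: discard proteins shorter than 800 aa (complete Cas9s run
~1000–1650 aa; shorter entries are fragments), align all pairs locally
(BLOSUM62, affine gaps), and connect two proteins when the alignment covers
at least 0.8 of BOTH lengths and its score coverage — bit score divided by
alignment length — is at least 0.8.  Clusters are the connected components
(single linkage) of that graph.

Bit scores use the gapped Karlin–Altschul transform with the standard
protein-search constants lambda = 0.267, K = 0.041 (declared, not fitted):
bits = (lambda * raw - ln K) / ln 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from math import log as _ln
from pathlib import Path
from typing import Sequence

import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import AlphabetError, SequenceRecord

log = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 800
DEFAULT_LENGTH_COV = 0.8
DEFAULT_SCORE_COV = 0.8
GAP_OPEN = -11
GAP_EXTEND = -1
KA_LAMBDA = 0.267
KA_K = 0.041


class ClusterUsageError(ValueError):
    """Bad arguments to the clustering routines."""


@dataclass(frozen=True)
class PairwiseAlignmentStats:
    id_a: str
    id_b: str
    raw_score: float
    bit_score: float
    align_len: int
    cov_a: float
    cov_b: float
    identity: float

    @property
    def score_coverage(self) -> float:
        return self.bit_score / self.align_len


@dataclass(frozen=True)
class ClusterSet:
    """A partition of the retained protein ids."""

    clusters: tuple[tuple[str, ...], ...]
    parameters: dict

    def __post_init__(self) -> None:
        members = [m for c in self.clusters for m in c]
        if len(members) != len(set(members)):
            raise ClusterUsageError("clusters are not disjoint")
        if any(not c for c in self.clusters):
            raise ClusterUsageError("empty cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, int]:
        return {m: i for i, c in enumerate(self.clusters) for m in c}


@lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    matrix = substitution_matrices.load("BLOSUM62").copy()
    # X tolerated but uninformative: contribute nothing to the raw score
    for letter in matrix.alphabet:
        matrix["X", letter] = 0.0
        matrix[letter, "X"] = 0.0
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def filter_by_length(
    records: Sequence[SequenceRecord], min_len: int = DEFAULT_MIN_LEN
) -> list[SequenceRecord]:
    """Drop proteins shorter than ``min_len`` residues, preserving order."""
    kept = []
    for r in records:
        if len(r) >= min_len:
            kept.append(r)
        else:
            log.info("discarding %s: %d aa < %d", r.id, len(r), min_len)
    return kept


def align_pair(a: SequenceRecord, b: SequenceRecord) -> PairwiseAlignmentStats:
    """Local alignment stats (score, coverages, identity) for one pair."""
    if not a.residues or not b.residues:
        raise ClusterUsageError("empty sequence")
    aligner = _aligner()
    try:
        alignments = aligner.align(a.residues, b.residues)
    except ValueError as exc:
        raise AlphabetError(f"{a.id} vs {b.id}: {exc}") from exc
    aln = alignments[0]
    counts = aln.counts()
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        # no positive-scoring local alignment at all
        return PairwiseAlignmentStats(a.id, b.id, 0.0, _bits(0.0), 1, 0.0, 0.0, 0.0)
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    align_len = int(aln.length)
    return PairwiseAlignmentStats(
        id_a=a.id,
        id_b=b.id,
        raw_score=float(aln.score),
        bit_score=_bits(float(aln.score)),
        align_len=align_len,
        cov_a=span_a / len(a),
        cov_b=span_b / len(b),
        identity=counts.identities / align_len,
    )


def _bits(raw: float) -> float:
    return (KA_LAMBDA * raw - _ln(KA_K)) / _ln(2.0)


def edge_ok(
    stats: PairwiseAlignmentStats,
    length_cov: float = DEFAULT_LENGTH_COV,
    score_cov: float = DEFAULT_SCORE_COV,
) -> bool:
    """The clustering edge criterion: symmetric length coverage AND score coverage."""
    return min(stats.cov_a, stats.cov_b) >= length_cov and stats.score_coverage >= score_cov


def all_pair_stats(records: Sequence[SequenceRecord]) -> list[PairwiseAlignmentStats]:
    stats = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            stats.append(align_pair(records[i], records[j]))
    return stats


def greedy_cluster(
    records: Sequence[SequenceRecord],
    length_cov: float = DEFAULT_LENGTH_COV,
    score_cov: float = DEFAULT_SCORE_COV,
    stats: Sequence[PairwiseAlignmentStats] | None = None,
) -> ClusterSet:
    """Single-linkage clusters under the coverage edge criterion.

    All-vs-all is O(n^2) alignments — fine at the intended scale of a few
    hundred proteins.  Pass precomputed ``stats`` to re-threshold cheaply.
    Members within a cluster are sorted; clusters sort by size (desc) then
    lexicographically, so output is deterministic.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ClusterUsageError("duplicate record ids")
    if stats is None:
        stats = all_pair_stats(records)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for s in stats:
        if edge_ok(s, length_cov, score_cov):
            graph.add_edge(s.id_a, s.id_b)
    clusters = [tuple(sorted(c)) for c in nx.connected_components(graph)]
    clusters.sort(key=lambda c: (-len(c), c))
    return ClusterSet(
        clusters=tuple(clusters),
        parameters={"length_cov": length_cov, "score_cov": score_cov},
    )


def write_cluster_tsv(clusters: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember_id\n")
        for i, members in enumerate(clusters.clusters):
            for m in members:
                fh.write(f"cluster_{i + 1}\t{m}\n")


def write_edge_tsv(stats: Sequence[PairwiseAlignmentStats], path: str | Path) -> None:
    """Audit table of every pairwise comparison, thresholded or not."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\traw_score\tbit_score\talign_len\tcov_a\tcov_b\tidentity\tscore_coverage\n")
        for s in stats:
            fh.write(
                f"{s.id_a}\t{s.id_b}\t{s.raw_score:.1f}\t{s.bit_score:.2f}\t{s.align_len}\t"
                f"{s.cov_a:.4f}\t{s.cov_b:.4f}\t{s.identity:.4f}\t{s.score_coverage:.4f}\n"
            )
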