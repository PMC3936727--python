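"""Synthetic corpora with known ground truth.

Emulates the statistical structure of a public-database protospacer search:
random i.i.d. background genomes with spacer copies planted at controlled
per-base divergence, each followed 3' (strand-aware) by a concrete flank
drawn from a ground-truth IUPAC PAM; CRISPR loci with random repeats and
spacers; and protein families whose within-family divergence is far below
the between-family divergence, so cluster memberships are known by
construction.  A manifest records every planted fact, making parameter
recovery a measurable quantity rather than an impression.

Each operation draws from its own independently seeded stream, so e.g.
adding placements never perturbs the background genome bases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import (
    IUPAC_DNA_SETS,
    CrisprLocus,
    SequenceRecord,
    revcomp,
)

log = logging.getLogger(__name__)

_DNA = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_FLANK_LEN = 10


class SynthUsageError(ValueError):
    """Bad generator parameters."""


@dataclass(frozen=True)
class Placement:
    target_id: str
    start: int              # protospacer start, forward-strand coordinates
    end: int
    strand: str
    spacer_id: str
    n_mutations: int        # Hamming distance planted spacer vs reference
    realized_flank: str     # the concrete flank written into the genome
    flank_mutations: int


@dataclass(frozen=True)
class SyntheticManifest:
    seed: int
    true_pam: str
    mutation_rate: float
    genome_length: int
    gc: float
    placements: tuple[Placement, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "true_pam": self.true_pam,
                "mutation_rate": self.mutation_rate,
                "genome_length": self.genome_length,
                "gc": self.gc,
                "placements": [asdict(p) for p in self.placements],
            },
            indent=2,
        )


def _stream(seed: int, purpose: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (str hash is salted)
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(purpose.encode()) % (2**31)])
    return np.random.default_rng(ss)


def generate_genome(length: int, gc: float = 0.5, seed: int = 0, target_id: str = "genome") -> SequenceRecord:
    """I.i.d. background sequence with the requested GC fraction."""
    if length < 1:
        raise SynthUsageError("length must be >= 1")
    if not (0.0 < gc < 1.0):
        raise SynthUsageError("gc must be in (0, 1)")
    rng = _stream(seed, "genome")
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(list(_DNA), size=length, p=probs)
    return SequenceRecord(id=target_id, residues="".join(bases))


def _mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    out = list(seq)
    muts = 0
    for i, base in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in _DNA if b != base])
            muts += 1
    return "".join(out), muts


def _sample_pam(true_pam: str, rng: np.random.Generator) -> str:
    bases = []
    for letter in true_pam.upper():
        choices = sorted(IUPAC_DNA_SETS[letter])
        bases.append(choices[rng.integers(0, len(choices))])
    return "".join(bases)


def embed_protospacers(
    genome: SequenceRecord,
    spacers: Sequence[tuple[str, str]],
    true_pam: str,
    n: int,
    mutation_rate: float = 0.0,
    seed: int = 0,
    flank_len: int = DEFAULT_FLANK_LEN,
    gc: float = 0.5,
) -> tuple[SequenceRecord, SyntheticManifest]:
    """Plant ``n`` spacer copies, each 3'-flanked by a PAM realisation.

    Strands are chosen uniformly; placements never overlap.  On the minus
    strand the written block is the reverse complement of spacer+flank, so
    that reading the minus strand 5'->3' gives spacer then flank — exactly
    the convention flank extraction uses.
    """
    bad = set(true_pam.upper()) - set(IUPAC_DNA_SETS)
    if bad:
        raise SynthUsageError(f"true_pam has non-IUPAC letters {sorted(bad)}")
    if not spacers:
        raise SynthUsageError("no spacers supplied")
    if len(true_pam) > flank_len:
        raise SynthUsageError("true_pam longer than the flank")

    rng = _stream(seed, "placements")
    seq = list(genome.residues)
    G = len(seq)
    max_block = max(len(s) for _, s in spacers) + flank_len
    if n * (max_block + 1) > G:
        raise SynthUsageError(
            f"genome of {G} nt cannot hold {n} placements; needs >= {n * (max_block + 1)} nt"
        )

    occupied: list[tuple[int, int]] = []
    placements: list[Placement] = []
    for k in range(n):
        spacer_id, spacer = spacers[k % len(spacers)]
        L = len(spacer)
        block_len = L + flank_len
        placed = False
        for _ in range(2000):
            p = int(rng.integers(0, G - block_len + 1))
            if any(p < e + 1 and s < p + block_len + 1 for s, e in occupied):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            mut_spacer, n_mut = _mutate_dna(spacer, mutation_rate, rng)
            pam = _sample_pam(true_pam, rng)
            flank = pam + "".join(rng.choice(list(_DNA), size=flank_len - len(pam)))
            flank, flank_mut = _mutate_dna(flank, mutation_rate, rng)
            block = mut_spacer + flank
            if strand == "-":
                block = revcomp(block)
                start, end = p + flank_len, p + block_len
            else:
                start, end = p, p + L
            seq[p:p + block_len] = block
            occupied.append((p, p + block_len))
            placements.append(
                Placement(
                    target_id=genome.id,
                    start=start,
                    end=end,
                    strand=strand,
                    spacer_id=spacer_id,
                    n_mutations=n_mut,
                    realized_flank=flank,
                    flank_mutations=flank_mut,
                )
            )
            placed = True
            break
        if not placed:
            raise SynthUsageError(f"could not place protospacer {k + 1}/{n} without overlap")

    placements.sort(key=lambda p: p.start)
    genome_out = SequenceRecord(id=genome.id, residues="".join(seq), description=genome.description)
    manifest = SyntheticManifest(
        seed=seed,
        true_pam=true_pam.upper(),
        mutation_rate=mutation_rate,
        genome_length=G,
        gc=gc,
        placements=tuple(placements),
    )
    return genome_out, manifest


def generate_locus(
    repeat_len: int = 36,
    n_spacers: int = 4,
    spacer_len: int = 30,
    seed: int = 0,
    locus_id: str = "locus1",
    species: str = "synthetic species",
) -> CrisprLocus:
    """Random repeat plus pairwise-distinct random spacers (forward array)."""
    if not (20 <= repeat_len <= 50):
        raise SynthUsageError("repeat_len should be 20-50")
    if not (20 <= spacer_len <= 40):
        raise SynthUsageError("spacer_len should be 20-40")
    rng = _stream(seed, "locus")
    repeat = "".join(rng.choice(list(_DNA), size=repeat_len))
    spacers: list[tuple[str, str]] = []
    seen: set[str] = set()
    while len(spacers) < n_spacers:
        s = "".join(rng.choice(list(_DNA), size=spacer_len))
        if s in seen:
            continue
        seen.add(s)
        spacers.append((f"{locus_id}_sp{len(spacers) + 1}", s))
    return CrisprLocus(
        locus_id=locus_id,
        species=species,
        repeat=repeat,
        spacers=tuple(spacers),
        orientation="forward",
    )


def generate_protein_family(
    k_families: int = 3,
    members_per_family: int = 5,
    length: int = 900,
    within_divergence: float = 0.05,
    between_divergence: float = 0.7,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Protein families with known memberships.

    Ancestors are random sequences kept pairwise at least
    ``between_divergence`` apart (by rejection); members substitute each
    site independently at ``within_divergence``.  Returns records and a
    member-id -> family-index labelling.
    """
    if not (0 <= within_divergence < between_divergence <= 1):
        raise SynthUsageError("need 0 <= within_divergence < between_divergence <= 1")
    rng = _stream(seed, "proteins")
    aa = list(_AA)

    ancestors: list[str] = []
    attempts = 0
    while len(ancestors) < k_families:
        attempts += 1
        if attempts > 200 * k_families:
            raise SynthUsageError("could not generate sufficiently diverged ancestors")
        cand = "".join(rng.choice(aa, size=length))
        ok = True
        for anc in ancestors:
            diff = sum(1 for x, y in zip(anc, cand) if x != y) / length
            if diff < between_divergence:
                ok = False
                break
        if ok:
            ancestors.append(cand)

    records: list[SequenceRecord] = []
    labels: dict[str, int] = {}
    for fam, anc in enumerate(ancestors):
        for m in range(members_per_family):
            seq = list(anc)
            for i in range(length):
                if rng.random() < within_divergence:
                    seq[i] = rng.choice([x for x in aa if x != seq[i]])
            rid = f"fam{fam + 1}_m{m + 1}"
            records.append(SequenceRecord(id=rid, residues="".join(seq), moltype="protein"))
            labels[rid] = fam
    return records, labels


def generate_corpus(
    seed: int,
    true_pam: str = "NGG",
    n_placements: int = 50,
    mutation_rate: float = 0.02,
    genome_length: int = 9000,
    n_spacers: int = 5,
    spacer_len: int = 30,
    gc: float = 0.5,
) -> tuple[CrisprLocus, SequenceRecord, SyntheticManifest]:
    """One complete PAM-recovery corpus: locus, target genome, manifest."""
    locus = generate_locus(n_spacers=n_spacers, spacer_len=spacer_len, seed=seed)
    genome = generate_genome(genome_length, gc=gc, seed=seed, target_id="target1")
    genome, manifest = embed_protospacers(
        genome, list(locus.spacers), true_pam, n_placements, mutation_rate, seed=seed, gc=gc
    )
    return locus, genome, manifest
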