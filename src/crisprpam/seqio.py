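"""Sequence and CRISPR-locus I/O plus nucleotide-alphabet utilities.

Everything downstream (protospacer search, flank extraction, consensus
calling) shares the alphabet conventions defined here: residues are stored
uppercase, DNA may carry IUPAC ambiguity codes, spacers may not (so that
identity arithmetic stays unambiguous), and 'U' is normalised to 'T' for
DNA molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

log = logging.getLogger(__name__)

IUPAC_DNA_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
#: reverse lookup: base set -> IUPAC letter
IUPAC_FOR_SET = {v: k for k, v in IUPAC_DNA_SETS.items()}

_DNA_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_RNA_LETTERS = frozenset("ACGUN")
_PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU*-")  # '-' admits aligned rows


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input, naming the offending line."""


class LocusTableError(ValueError):
    """Raised for malformed CRISPR-locus tables."""


class AlphabetError(ValueError):
    """Raised when a sequence contains letters outside its alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence (DNA, RNA or protein), uppercase residues."""

    id: str
    residues: str
    description: str = ""
    moltype: str = "dna"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id {self.id!r} must be a non-empty token")
        if self.moltype not in ("dna", "rna", "protein"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        residues = self.residues.upper()
        if self.moltype == "dna":
            residues = residues.replace("U", "T")
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        alphabet = {
            "dna": frozenset(IUPAC_DNA_SETS),
            "rna": _RNA_LETTERS,
            "protein": _PROTEIN_LETTERS,
        }[self.moltype]
        bad = set(residues) - alphabet
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: letters {sorted(bad)} not in {self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CrisprLocus:
    """One CRISPR array: repeat, ordered spacers and transcription orientation.

    Orientation is an experimental input (RNA-seq / northern blot evidence),
    never inferred here; ``unknown`` is tolerated but flagged with a warning
    because the non-target-strand flank is meaningless without it.
    Spacers must be plain ACGT so that match identity is unambiguous.
    """

    locus_id: str
    species: str
    repeat: str
    spacers: tuple[tuple[str, str], ...]
    orientation: str = "forward"
    subtype: str | None = None

    def __post_init__(self) -> None:
        if not self.spacers:
            raise ValueError(f"locus {self.locus_id!r} has no spacers")
        object.__setattr__(self, "spacers", tuple((i, s.upper().replace("U", "T")) for i, s in self.spacers))
        ids = [sid for sid, _ in self.spacers]
        if len(set(ids)) != len(ids):
            raise LocusTableError(f"locus {self.locus_id!r} has duplicate spacer ids")
        for sid, seq in self.spacers:
            if not seq or set(seq) - set("ACGT"):
                raise AlphabetError(
                    f"spacer {sid!r} in locus {self.locus_id!r} must be non-empty plain ACGT"
                )
        if self.orientation not in ("forward", "reverse", "unknown"):
            raise ValueError(f"locus {self.locus_id!r}: bad orientation {self.orientation!r}")
        if self.orientation == "unknown":
            log.warning("locus %s has unknown array orientation; flank strand is unreliable", self.locus_id)
        if self.subtype is not None and self.subtype not in ("II-A", "II-B", "II-C"):
            raise ValueError(f"locus {self.locus_id!r}: bad subtype {self.subtype!r}")

    @property
    def orientation_known(self) -> bool:
        return self.orientation != "unknown"

    def spacer_sequences(self) -> dict[str, str]:
        return dict(self.spacers)


def revcomp(dna: str) -> str:
    """IUPAC-aware reverse complement (W<->W, R<->Y, ...)."""
    seq = dna.upper()
    bad = set(seq) - set(IUPAC_DNA_SETS)
    if bad:
        raise AlphabetError(f"non-IUPAC DNA letters {sorted(bad)}")
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff every base of ``seq`` lies in the corresponding pattern set.

    ``pattern`` is an IUPAC degenerate string (e.g. a PAM like ``NGG``);
    ``seq`` must be concrete ACGT of the same length.
    """
    if len(pattern) != len(seq):
        raise ValueError(f"pattern length {len(pattern)} != sequence length {len(seq)}")
    pattern, seq = pattern.upper(), seq.upper()
    for p, s in zip(pattern, seq):
        sets = IUPAC_DNA_SETS.get(p)
        if sets is None:
            raise AlphabetError(f"non-IUPAC pattern letter {p!r}")
        if s not in "ACGT":
            raise AlphabetError(f"ambiguous sequence letter {s!r}; seq must be concrete ACGT")
        if s not in sets:
            return False
    return True


def _validate_fasta_lines(path: Path) -> None:
    """Pre-scan for structural errors so messages can name the line."""
    current_header_line: int | None = None
    seen_sequence = False
    any_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                any_header = True
                if current_header_line is not None and not seen_sequence:
                    raise FastaFormatError(
                        f"{path}: record at line {current_header_line} has an empty sequence"
                    )
                if not line[1:].strip():
                    raise FastaFormatError(f"{path}: malformed header at line {lineno} (no id)")
                current_header_line = lineno
                seen_sequence = False
            else:
                if not any_header:
                    raise FastaFormatError(
                        f"{path}: sequence data before any '>' header at line {lineno}"
                    )
                seen_sequence = True
    if current_header_line is not None and not seen_sequence:
        raise FastaFormatError(
            f"{path}: record at line {current_header_line} has an empty sequence"
        )


def read_fasta(path: str | Path, moltype: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and, for DNA, U is normalised to T.  An empty
    file yields an empty list; malformed records raise
    :class:`FastaFormatError` naming the line.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc, moltype=moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with lines wrapped at ``width`` columns."""
    bio = []
    for r in records:
        bio.append(_BioRecord(Seq(r.residues), id=r.id, description=r.description))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(bio)


LOCUS_COLUMNS = ["locus_id", "species", "repeat", "orientation", "spacer_id", "spacer_seq"]


def read_locus_table(path: str | Path) -> list[CrisprLocus]:
    """Read the package's TSV locus table (one spacer per row).

    Columns: locus_id, species, repeat, orientation, spacer_id, spacer_seq
    and optionally subtype.  Spacers keep file order within each locus.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise LocusTableError(f"{path}: missing columns {missing}")
    loci = []
    for locus_id, grp in df.groupby("locus_id", sort=False):
        spacer_ids = list(grp["spacer_id"])
        if len(set(spacer_ids)) != len(spacer_ids):
            raise LocusTableError(f"{path}: duplicate spacer_id within locus {locus_id!r}")
        first = grp.iloc[0]
        subtype = first["subtype"] if "subtype" in grp.columns and first.get("subtype") else None
        loci.append(
            CrisprLocus(
                locus_id=locus_id,
                species=first["species"],
                repeat=first["repeat"],
                spacers=tuple(zip(grp["spacer_id"], grp["spacer_seq"])),
                orientation=first["orientation"],
                subtype=subtype,
            )
        )
    return loci


def write_locus_table(loci: Sequence[CrisprLocus], path: str | Path) -> None:
    rows = []
    for locus in loci:
        for sid, seq in locus.spacers:
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "species": locus.species,
                    "repeat": locus.repeat,
                    "orientation": locus.orientation,
                    "spacer_id": sid,
                    "spacer_seq": seq,
                    "subtype": locus.subtype or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
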