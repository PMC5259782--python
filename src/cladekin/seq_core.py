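"""Protein alignment data model, FASTA I/O and coordinate mapping.

Residue positions are 1-based on the ungapped sequence, counted from the
initiator methionine; alignment columns are 1-based as well.  The mapping
between the two is what lets a site found in an alignment column be
reported as, say, "position 954 of the reference" and transferred to the
equivalent position of a homolog.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHAR = "-"
_VALID = set(AMINO_ACIDS) | {"X", GAP_CHAR}


class _GapMarker:
    """Singleton returned when a coordinate query lands on a gap."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "GAP"

    def __bool__(self) -> bool:
        return False


#: Sentinel for "this sequence has a gap at that column".
GAP = _GapMarker()


def normalize_residues(raw: str, on_unknown: str = "raise") -> str:
    """Uppercase, map '.' to '-', and handle unknown characters.

    on_unknown: "raise" rejects the record, "mask" maps the character to X.
    """
    s = raw.upper().replace(".", GAP_CHAR)
    bad = sorted(set(s) - _VALID)
    if bad:
        if on_unknown == "mask":
            table = str.maketrans({c: "X" for c in bad})
            s = s.translate(table)
        else:
            raise DataError(f"unknown residue character(s) {bad!r} in sequence")
    return s


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise DataError("sequence id must be non-empty")
        if not self.residues:
            raise DataError(f"sequence {self.id!r} has no residues")
        norm = normalize_residues(self.residues)
        object.__setattr__(self, "residues", norm)

    def ungapped(self) -> str:
        return self.residues.replace(GAP_CHAR, "")

    @property
    def ungapped_length(self) -> int:
        return len(self.ungapped())

    def __len__(self) -> int:
        return len(self.residues)


class CoordinateMap:
    """Bijection between non-gap alignment columns and residue positions
    of one gapped sequence (both 1-based)."""

    def __init__(self, residues: str):
        self._is_residue = np.frombuffer(residues.encode(), dtype=np.uint8) != ord(GAP_CHAR)
        # cumulative residue count up to and including each column
        self._counts = np.cumsum(self._is_residue)
        self._cols_of_pos = np.nonzero(self._is_residue)[0] + 1  # 1-based columns

    @property
    def n_columns(self) -> int:
        return len(self._is_residue)

    @property
    def ungapped_length(self) -> int:
        return int(self._counts[-1]) if len(self._counts) else 0

    def column_to_position(self, column: int):
        if not 1 <= column <= self.n_columns:
            raise DataError(f"column {column} out of range 1..{self.n_columns}")
        if not self._is_residue[column - 1]:
            return GAP
        return int(self._counts[column - 1])

    def position_to_column(self, position: int) -> int:
        if not 1 <= position <= self.ungapped_length:
            raise DataError(
                f"position {position} out of range 1..{self.ungapped_length}"
            )
        return int(self._cols_of_pos[position - 1])


@dataclass
class Alignment:
    """Equal-length gapped protein sequences with optional clade labels."""

    sequences: list[ProteinSequence]
    clade_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sequences:
            raise DataError("alignment must contain at least one sequence")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise DataError(f"ragged alignment: lengths {sorted(lengths)}")
        for col in range(self.n_columns):
            if all(s.residues[col] == GAP_CHAR for s in self.sequences):
                raise DataError(f"column {col + 1} is entirely gaps")
        unknown = set(self.clade_map) - set(ids)
        if unknown:
            raise DataError(f"clade_map refers to unknown ids: {sorted(unknown)}")
        self._by_id = {s.id: s for s in self.sequences}
        self._coord_maps: dict[str, CoordinateMap] = {}

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def sequence(self, seq_id: str) -> ProteinSequence:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise DataError(f"unknown sequence id {seq_id!r}") from None

    def coordinate_map(self, seq_id: str) -> CoordinateMap:
        if seq_id not in self._coord_maps:
            self._coord_maps[seq_id] = CoordinateMap(self.sequence(seq_id).residues)
        return self._coord_maps[seq_id]

    def column_residues(self, column: int) -> dict[str, str]:
        if not 1 <= column <= self.n_columns:
            raise DataError(f"column {column} out of range 1..{self.n_columns}")
        return {s.id: s.residues[column - 1] for s in self.sequences}

    def clades(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.sequences:
            clade = self.clade_map.get(s.id)
            if clade is not None:
                out.setdefault(clade, []).append(s.id)
        return out


def read_fasta(path, expect_aligned: bool = False, on_unknown: str = "raise") -> list[ProteinSequence]:
    """Read protein FASTA, preserving record order and gaps."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    seqs = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise DataError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(
            ProteinSequence(
                id=rec.id,
                residues=normalize_residues(str(rec.seq), on_unknown=on_unknown),
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if expect_aligned and len({len(s) for s in seqs}) != 1:
        raise DataError(f"ragged alignment in {path}: sequence lengths differ")
    return seqs


def write_fasta(sequences: list[ProteinSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def read_clade_table(path) -> dict[str, str]:
    """Two-column TSV: sequence_id<TAB>clade. '#' lines are comments."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise DataError(f"{path}:{lineno}: expected 'id<TAB>clade'")
            if parts[0] in out:
                raise DataError(f"{path}:{lineno}: duplicate id {parts[0]!r}")
            out[parts[0]] = parts[1]
    if not out:
        raise DataError(f"empty clade table {path}")
    return out


def column_to_position(alignment: Alignment, seq_id: str, column: int):
    """Residue position at `column` for `seq_id`, or GAP."""
    return alignment.coordinate_map(seq_id).column_to_position(column)


def position_to_column(alignment: Alignment, seq_id: str, position: int) -> int:
    return alignment.coordinate_map(seq_id).position_to_column(position)


def equivalent_position(alignment: Alignment, seq_id_a: str, pos_a: int, seq_id_b: str):
    """Transfer a residue position from one sequence to its homolog via
    the shared alignment column; GAP if the homolog is gapped there."""
    col = position_to_column(alignment, seq_id_a, pos_a)
    return column_to_position(alignment, seq_id_b, col)


def conserved_columns(alignment: Alignment, max_gap_fraction: float = 0.0) -> list[int]:
    """Columns whose gap fraction is <= max_gap_fraction (0.0 = gap-free),
    in ascending order."""
    if not 0.0 <= max_gap_fraction < 1.0:
        raise DataError("max_gap_fraction must be in [0, 1)")
    n = len(alignment.sequences)
    out = []
    for col in range(1, alignment.n_columns + 1):
        gaps = sum(
            1 for s in alignment.sequences if s.residues[col - 1] == GAP_CHAR
        )
        if gaps / n <= max_gap_fraction:
            out.append(col)
    return out
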