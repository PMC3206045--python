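"""Readers and writers for the external formats the toolkit touches.

Formats: FASTA and Clustal for sequences/alignments (via Biopython), Newick
for phylogenies (via DendroPy), NCBI matrix text format for scoring matrices,
and a tab-separated transmembrane-segment annotation format::

    protein_id <TAB> strand_index <TAB> start <TAB> end <TAB> facing

with 0-based half-open ``[start, end)`` coordinates on the ungapped template
sequence and ``facing`` a string over ``{I, O}`` of length ``end - start``
(barrel-interior vs. lipid-facing side of each strand position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
from Bio import AlignIO, SeqIO

from bbtm.alphabet import ALIGNMENT_CHARS, AMINO_ACIDS, SEQUENCE_CHARS
from bbtm.errors import AlignmentError, ParseError

if TYPE_CHECKING:  # pragma: no cover
    from bbtm.ctmc_model import PhylogeneticTree
    from bbtm.tm_dataset import LabeledAlignment, TMAnnotation


@dataclass(frozen=True)
class SequenceRecord:
    """One named amino-acid sequence, possibly gapped.

    Residues are upper-case one-letter codes; ``-`` marks an alignment gap and
    ``X`` an unknown residue (treated as missing data downstream).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - ALIGNMENT_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MatrixFile:
    """In-memory image of an NCBI-format scoring-matrix file."""

    alphabet_order: str
    scores: np.ndarray  # 20x20 integers
    comment_lines: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if sorted(self.alphabet_order) != sorted(AMINO_ACIDS):
            raise ValueError("alphabet must contain the 20 canonical residues")
        if self.scores.shape != (20, 20):
            raise ValueError("score table must be 20x20")
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.all(self.scores == np.round(self.scores)):
                raise ValueError("scoring-matrix entries must be integers")
            self.scores = self.scores.astype(int)


def _validate_characters(path: Path, allowed: frozenset[str]) -> None:
    """Scan a FASTA file for out-of-alphabet characters, reporting line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            bad = set(line.upper()) - allowed
            if bad:
                raise ParseError(
                    f"illegal sequence character(s) {sorted(bad)}", line=lineno
                )


def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are upper-cased; any character outside the 20 canonical amino
    acids (plus ``X``, and ``-`` when *allow_gaps*) is a parse error naming the
    offending line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first and not first.startswith(">"):
        raise ParseError("FASTA file must start with a '>' header", line=1)
    allowed = ALIGNMENT_CHARS if allow_gaps else SEQUENCE_CHARS
    _validate_characters(path, allowed)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"empty FASTA header in {path}")
        if not len(rec.seq):
            raise ParseError(f"record {rec.id!r} has no residues in {path}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), description=desc)
        )
    if not records:
        raise ParseError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, dialect: str = "fasta") -> "LabeledAlignment":
    """Read a multiple alignment in FASTA or Clustal dialect.

    All sequences must have equal (gapped) length; ragged input raises
    :class:`AlignmentError` listing the offending ids.
    """
    from bbtm.tm_dataset import LabeledAlignment

    if dialect not in ("fasta", "clustal"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    path = Path(path)
    if dialect == "fasta":
        records = read_fasta(path, allow_gaps=True)
    else:
        aln = AlignIO.read(str(path), "clustal")
        records = [
            SequenceRecord(id=rec.id, residues=str(rec.seq).upper()) for rec in aln
        ]
    lengths = {len(r.residues) for r in records}
    if len(lengths) > 1:
        common = max(lengths, key=lambda L: sum(len(r) == L for r in records))
        bad = [r.id for r in records if len(r) != common]
        raise AlignmentError(
            f"unequal sequence lengths in {path}: offending ids {bad}"
        )
    return LabeledAlignment(records)


def write_alignment(aln: "LabeledAlignment", path: str | Path, dialect: str = "fasta") -> None:
    if dialect == "fasta":
        write_fasta(aln.records, path)
    elif dialect == "clustal":
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord as BioSeqRecord

        msa = MultipleSeqAlignment(
            [BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in aln.records]
        )
        AlignIO.write(msa, str(path), "clustal")
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


def read_newick(source: str | Path) -> "PhylogeneticTree":
    """Read a Newick tree (file path or literal string).

    Branch lengths must be non-negative; a missing branch length defaults to
    0.0 with a warning. Duplicate leaf names are an error.
    """
    from bbtm.ctmc_model import PhylogeneticTree

    text = None
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        text = Path(source).read_text()
    return PhylogeneticTree.from_newick(text)


def write_newick(tree: "PhylogeneticTree", path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# --- NCBI matrix text format -------------------------------------------------

def write_matrix_file(mf: MatrixFile, path: str | Path) -> None:
    """Write an NCBI-format scoring-matrix file (symmetric integer table)."""
    scores = np.asarray(mf.scores)
    if not np.array_equal(scores, scores.T):
        raise ValueError("scoring matrix must be symmetric")
    letters = list(mf.alphabet_order)
    with open(path, "w") as fh:
        for line in mf.comment_lines:
            fh.write(f"# {line}\n" if not line.startswith("#") else line + "\n")
        width = max(3, max(len(str(int(v))) for v in scores.ravel()) + 1)
        fh.write(" " + "".join(f"{c:>{width}}" for c in letters) + "\n")
        for i, c in enumerate(letters):
            row = "".join(f"{int(v):>{width}}" for v in scores[i])
            fh.write(f"{c}{row}\n")


def read_matrix_file(path: str | Path) -> MatrixFile:
    """Read an NCBI-format scoring-matrix file."""
    comments: list[str] = []
    header: list[str] | None = None
    rows: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                comments.append(line.lstrip()[1:].strip())
                continue
            fields = line.split()
            if header is None:
                header = fields
                if sorted(header) != sorted(AMINO_ACIDS):
                    # tolerate extra columns (B, Z, X, *) by keeping canonical ones
                    keep = [c for c in header if c in AMINO_ACIDS]
                    if sorted(keep) != sorted(AMINO_ACIDS):
                        raise ParseError(
                            "matrix header must contain the 20 canonical residues",
                            line=lineno,
                        )
                    header = keep
                continue
            letter, *values = fields
            if letter not in AMINO_ACIDS:
                continue
            try:
                rows[letter] = [int(v) for v in values[: len(header)]]
            except ValueError as exc:
                raise ParseError(f"non-integer matrix entry: {exc}", line=lineno)
    if header is None or len(rows) != 20:
        raise ParseError(f"incomplete scoring matrix in {path}")
    scores = np.zeros((20, 20), dtype=int)
    for i, ci in enumerate(header):
        for j, cj in enumerate(header):
            scores[i, j] = rows[ci][j]
    # reorder to canonical alphabet order
    order = [header.index(c) for c in AMINO_ACIDS]
    scores = scores[np.ix_(order, order)]
    return MatrixFile(alphabet_order=AMINO_ACIDS, scores=scores, comment_lines=comments)


# --- TM annotation TSV -------------------------------------------------------

def read_tm_annotation(path: str | Path) -> "TMAnnotation":
    """Read a transmembrane-segment annotation table for a single protein."""
    from bbtm.tm_dataset import TMAnnotation

    protein_id = None
    segments: list[tuple[int, int, int]] = []
    facing: dict[int, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"expected 5 tab-separated fields, got {len(fields)}", line=lineno
                )
            pid, strand_s, start_s, end_s, face = fields
            if protein_id is None:
                protein_id = pid
            elif pid != protein_id:
                raise ParseError(
                    f"annotation file mixes proteins {protein_id!r} and {pid!r}",
                    line=lineno,
                )
            try:
                strand, start, end = int(strand_s), int(start_s), int(end_s)
            except ValueError:
                raise ParseError("strand/start/end must be integers", line=lineno)
            if end <= start:
                raise ParseError(f"empty segment [{start},{end})", line=lineno)
            if len(face) != end - start:
                raise ParseError(
                    f"facing string length {len(face)} != segment length {end - start}",
                    line=lineno,
                )
            if set(face) - {"I", "O"}:
                raise ParseError("facing string must be over {I,O}", line=lineno)
            segments.append((strand, start, end))
            for offset, ch in enumerate(face):
                facing[start + offset] = ch
    if protein_id is None:
        raise ParseError(f"no annotation rows in {path}")
    return TMAnnotation(protein_id=protein_id, segments=segments, facing=facing)


def write_tm_annotation(ann: "TMAnnotation", path: str | Path) -> None:
    with open(path, "w") as fh:
        for strand, start, end in ann.segments:
            face = "".join(ann.facing[p] for p in range(start, end))
            fh.write(f"{ann.protein_id}\t{strand}\t{start}\t{end}\t{face}\n")
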