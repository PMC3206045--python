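"""Transmembrane datasets: column extraction, composition, hydrophobicity, homolog selection.

A template beta-barrel membrane protein contributes three column sets to rate
estimation: TM_all (every membrane-embedded strand position), and its
partition into TM_in (positions facing the barrel lumen) and TM_out
(positions facing the lipid). Annotations are given on the ungapped template
sequence; alignment columns where the template carries a gap are never TM
columns.

Hydrophobicity uses the GES (Goldman-Engelman-Steitz) water-to-membrane
transfer free-energy scale, in kcal/mol with the sign convention that
positive values are hydrophobic and negative values polar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from bbtm.alphabet import AA_INDEX, GAP, UNKNOWN
from bbtm.errors import AnnotationError
from bbtm.io_formats import SequenceRecord

#: GES transfer free energies (kcal/mol); positive = hydrophobic.
GES_SCALE: dict[str, float] = {
    "F": 3.7, "M": 3.4, "I": 3.1, "L": 2.8, "V": 2.6,
    "C": 2.0, "W": 1.9, "A": 1.6, "T": 1.2, "G": 1.0,
    "S": 0.6, "P": -0.2, "Y": -0.7, "H": -3.0, "Q": -4.1,
    "N": -4.8, "E": -8.2, "K": -8.8, "D": -9.2, "R": -12.3,
}


class LabeledAlignment:
    """A gapped multiple sequence alignment with named rows.

    Rows keep their input order; the first row is the structural template when
    the alignment backs a TM dataset.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment needs at least one sequence")
        widths = {len(r.residues) for r in records}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(widths)}")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        self.records = records
        self.width = widths.pop()
        self.ids = ids

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def take_columns(self, indices: Iterable[int]) -> "LabeledAlignment":
        idx = list(indices)
        return LabeledAlignment(
            [
                SequenceRecord(
                    id=r.id,
                    residues="".join(r.residues[j] for j in idx),
                    description=r.description,
                )
                for r in self.records
            ]
        )

    def to_indices(self) -> np.ndarray:
        """(n_sequences, width) int array; gaps and 'X' are -1 (missing)."""
        out = np.full((self.n_sequences, self.width), -1, dtype=np.int8)
        for i, rec in enumerate(self.records):
            for j, ch in enumerate(rec.residues):
                out[i, j] = AA_INDEX.get(ch, -1)
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, LabeledAlignment) and [
            (r.id, r.residues) for r in self.records
        ] == [(r.id, r.residues) for r in other.records]

    def __repr__(self) -> str:
        return f"LabeledAlignment({self.n_sequences} sequences x {self.width} columns)"


@dataclass
class TMAnnotation:
    """Strand segments of one template protein with per-position facing labels.

    Segments are 0-based half-open intervals on the ungapped template
    sequence; ``facing`` maps each TM position to ``'I'`` (barrel interior) or
    ``'O'`` (lipid-facing).
    """

    protein_id: str
    segments: list[tuple[int, int, int]]  # (strand_index, start, end)
    facing: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.segments = sorted(self.segments, key=lambda s: s[1])
        prev_end = None
        for _, start, end in self.segments:
            if end <= start:
                raise AnnotationError(f"empty segment [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"overlapping segments near position {start} in {self.protein_id}"
                )
            prev_end = end
        positions = self.tm_positions()
        if set(self.facing) != set(positions):
            raise AnnotationError(
                f"facing labels must cover exactly the TM positions of {self.protein_id}"
            )
        bad = set(self.facing.values()) - {"I", "O"}
        if bad:
            raise AnnotationError(f"facing labels must be 'I' or 'O', got {bad}")

    def tm_positions(self, facing: str = "ALL") -> list[int]:
        """TM positions on the ungapped template, optionally filtered by facing."""
        pos = [p for _, start, end in self.segments for p in range(start, end)]
        if facing == "ALL":
            return pos
        want = {"IN": "I", "OUT": "O"}[facing]
        return [p for p in pos if self.facing[p] == want]

    @property
    def n_tm_residues(self) -> int:
        return sum(end - start for _, start, end in self.segments)

    @property
    def n_strands(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class DatasetStats:
    """Per-protein (or aggregated) dataset statistics."""

    protein_id: str
    n_tm_residues: int
    n_total_residues: int
    n_strands: int
    n_in: int
    n_out: int
    hydro_all: float
    hydro_in: float
    hydro_out: float

    def __post_init__(self):
        # equality holds for stats computed here; published reference rows
        # occasionally leave one TM position unassigned to either face
        if self.n_in + self.n_out > self.n_tm_residues:
            raise ValueError("n_in + n_out cannot exceed n_tm_residues")


def extract_tm_columns(
    aln: LabeledAlignment, ann: TMAnnotation, facing: str = "ALL"
) -> LabeledAlignment:
    """Sub-alignment of the columns whose template position is TM (and matches facing).

    Annotation positions refer to the ungapped coordinates of the first
    (template) row; columns are returned in template order.
    """
    if facing not in ("ALL", "IN", "OUT"):
        raise ValueError(f"facing must be ALL/IN/OUT, got {facing!r}")
    template = aln.records[0].residues
    ungapped_len = sum(1 for ch in template if ch != GAP)
    wanted = set(ann.tm_positions(facing))
    too_far = [p for p in ann.tm_positions() if p >= ungapped_len]
    if too_far:
        raise AnnotationError(
            f"annotation position {min(too_far)} beyond template length {ungapped_len}"
        )
    cols = []
    upos = 0
    for j, ch in enumerate(template):
        if ch == GAP:
            continue
        if upos in wanted:
            cols.append(j)
        upos += 1
    return aln.take_columns(cols)


def composition(aln: LabeledAlignment, pseudocount: float = 0.0) -> np.ndarray:
    """Relative amino-acid frequencies over the alignment; gaps and 'X' ignored."""
    counts = np.full(20, pseudocount, dtype=float)
    for rec in aln.records:
        for ch in rec.residues:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no amino-acid residues")
    return counts / total


def ges_hydrophobicity(residues: str | Iterable[str], scale: dict[str, float] | None = None) -> float:
    """Mean GES transfer free energy of the given residues (gaps/'X' skipped)."""
    scale = scale or GES_SCALE
    if not isinstance(residues, str):
        residues = "".join(residues)
    values = [scale[ch] for ch in residues.upper() if ch in scale]
    if not values:
        raise ValueError("no scorable residues")
    return float(np.mean(values))


def _alignment_residues(aln: LabeledAlignment) -> str:
    return "".join(
        ch for rec in aln.records for ch in rec.residues if ch not in (GAP, UNKNOWN)
    )


def dataset_stats(
    aln: LabeledAlignment, ann: TMAnnotation, total_length: int | None = None
) -> DatasetStats:
    """Compute the per-protein dataset statistics row.

    Hydrophobicity is averaged over all aligned residues of the extracted
    column sets, one value per facing class.
    """
    sub = {f: extract_tm_columns(aln, ann, f) for f in ("ALL", "IN", "OUT")}
    n_in = len(ann.tm_positions("IN"))
    n_out = len(ann.tm_positions("OUT"))
    if total_length is None:
        total_length = len(aln.records[0].ungapped)
    return DatasetStats(
        protein_id=ann.protein_id,
        n_tm_residues=ann.n_tm_residues,
        n_total_residues=total_length,
        n_strands=ann.n_strands,
        n_in=n_in,
        n_out=n_out,
        hydro_all=ges_hydrophobicity(_alignment_residues(sub["ALL"])),
        hydro_in=ges_hydrophobicity(_alignment_residues(sub["IN"])),
        hydro_out=ges_hydrophobicity(_alignment_residues(sub["OUT"])),
    )


def aggregate_stats(rows: Sequence[DatasetStats]) -> DatasetStats:
    """Arithmetic-mean aggregation across proteins (counts rounded to nearest int)."""
    if not rows:
        raise ValueError("no rows to aggregate")

    def imean(values):
        return int(round(float(np.mean(values))))

    return DatasetStats(
        protein_id="Mean",
        n_tm_residues=imean([r.n_tm_residues for r in rows]),
        n_total_residues=imean([r.n_total_residues for r in rows]),
        n_strands=imean([r.n_strands for r in rows]),
        n_in=imean([r.n_in for r in rows]),
        n_out=imean([r.n_out for r in rows]),
        hydro_all=float(np.mean([r.hydro_all for r in rows])),
        hydro_in=float(np.mean([r.hydro_in for r in rows])),
        hydro_out=float(np.mean([r.hydro_out for r in rows])),
    )


def load_template_stats() -> list[DatasetStats]:
    """Published per-protein statistics for the 11 template beta-barrel proteins.

    These are reference values (TM residue counts, totals, strand counts,
    in/out partition sizes and GES hydrophobicity per facing class) shipped
    with the package for aggregation checks and worked examples.
    """
    with resources.files("bbtm.data").joinpath("template_stats.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            DatasetStats(
                protein_id=row["pdb"],
                n_tm_residues=int(row["n_tm"]),
                n_total_residues=int(row["n_total"]),
                n_strands=int(row["n_strands"]),
                n_in=int(row["n_in"]),
                n_out=int(row["n_out"]),
                hydro_all=float(row["hydro_all"]),
                hydro_in=float(row["hydro_in"]),
                hydro_out=float(row["hydro_out"]),
            )
        )
    return out


def percent_identity(seq_a: str, seq_b: str, aligned: bool = True) -> float:
    """Percent identity between two sequences.

    For *aligned* sequences, identity is counted over columns where at least
    one sequence has a residue (double-gap columns are skipped).
    """
    if not aligned:
        raise NotImplementedError("only pre-aligned comparison is supported")
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    comparable = ident = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == GAP and b == GAP:
            continue
        comparable += 1
        if a == b and a != GAP:
            ident += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    return 100.0 * ident / comparable


def select_homologs(
    hits: Sequence[tuple[str, float, Sequence[int]]],
    max_per_bin: int = 2,
    max_gaps_per_segment: int = 2,
    bins: Sequence[tuple[float, float]] = tuple(
        (lo, lo + 10.0) for lo in (30.0, 40.0, 50.0, 60.0, 70.0, 80.0)
    ),
) -> list[str]:
    """Select homologs by identity bin, mirroring the template-database protocol.

    *hits* are ``(id, percent_identity, gaps_per_segment)`` triples. Hits with
    any TM segment containing more than *max_gaps_per_segment* gaps are
    excluded; within each half-open identity bin at most *max_per_bin* hits
    are kept (highest identity first, ties by input order). Hits outside all
    bins are dropped.
    """
    selected: list[str] = []
    for lo, hi in bins:
        eligible = [
            (idx, hid, ident)
            for idx, (hid, ident, gaps) in enumerate(hits)
            if lo <= ident < hi and all(g <= max_gaps_per_segment for g in gaps)
        ]
        eligible.sort(key=lambda t: (-t[2], t[0]))
        selected.extend(hid for _, hid, _ in eligible[:max_per_bin])
    return selected
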