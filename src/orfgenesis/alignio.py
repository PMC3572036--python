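"""Reference-anchored multiple alignments of a focal CDS.

Genome-wide MULTIZ alignments arrive as MAF blocks in reference-genome
coordinates.  To reason about a single-exon CDS we cut those blocks down to
the reference interval, stitch them into one gapped matrix anchored on the
reference row, and keep a map from every reference CDS position (1-based,
position 1 = first coding base) to its alignment column.  Per-species
"alignability" — the fraction of reference CDS positions at which a species
contributes an aligned base — is computed on that matrix.

Coordinates are 1-based inclusive throughout the public API; column indices
are 0-based and internal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import AlignIO
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

GAP = "-"


class MafParseError(ValueError):
    """Raised when a MAF file violates the format's row-length invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def parse(cls, text: str, strand: str = "+") -> "GenomicInterval":
        """Parse ``chrom:start-end`` (thousands separators tolerated)."""
        chrom, _, span = text.partition(":")
        lo, _, hi = span.partition("-")
        clean = lambda s: int(s.replace(",", "").replace("′", "").replace("'", ""))
        return cls(chrom, clean(lo), clean(hi), strand)


@dataclass
class MafRow:
    """One 's' line of a MAF block: a gapped slice of one species' genome."""

    species: str
    chrom: str
    start: int  # 0-based, on `strand`, as in the MAF
    size: int  # ungapped length
    strand: str
    src_size: int
    text: str


@dataclass
class MafBlock:
    rows: list[MafRow]

    def row_for(self, species: str) -> MafRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.rows]

    def n_aligned_rows(self) -> int:
        """Rows contributing at least one real base (used for overlap ties)."""
        return sum(1 for r in self.rows if any(c != GAP for c in r.text))


@dataclass
class CdsAlignment:
    """A multi-species alignment anchored on the reference CDS.

    ``rows`` maps species name to a gapped sequence; all rows have equal
    length.  ``colmap[p]`` gives the 0-based column of reference CDS position
    ``p + 1`` — it is total over 1..ref_cds_length_nt and strictly increasing.
    Columns not covered by colmap are insertions relative to the reference.
    """

    ref_species: str
    ref_cds_length_nt: int
    rows: dict[str, str]
    colmap: list[int]
    absent_species: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows differ in length: {sorted(lengths)}")
        ref = self.rows.get(self.ref_species)
        if ref is None:
            raise ValueError(f"reference species {self.ref_species!r} missing")
        n_ref = sum(1 for c in ref if c != GAP)
        if n_ref != self.ref_cds_length_nt:
            raise ValueError(
                f"reference row has {n_ref} bases, expected {self.ref_cds_length_nt}"
            )
        if len(self.colmap) != self.ref_cds_length_nt:
            raise ValueError("colmap must cover every reference CDS position")
        if any(b <= a for a, b in zip(self.colmap, self.colmap[1:])):
            raise ValueError("colmap must be strictly increasing")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def ref_base(self, pos: int) -> str:
        """Reference base at 1-based CDS position `pos`."""
        return self.rows[self.ref_species][self.colmap[pos - 1]]

    def ungapped_ref(self) -> str:
        return self.rows[self.ref_species].replace(GAP, "")


def _species_of(src: str) -> str:
    """MAF 'src' fields are assembly.chrom; the assembly names the species."""
    return src.split(".", 1)[0]


def _chrom_of(src: str) -> str:
    return src.split(".", 1)[1] if "." in src else src


def read_maf(path, ref_species: str | None = None) -> list[MafBlock]:
    """Read MAF alignment blocks (UCSC dialect, 's' lines).

    Blocks missing the designated reference species are skipped with a
    warning.  Malformed blocks (rows of unequal gapped length) raise
    :class:`MafParseError`.
    """
    blocks: list[MafBlock] = []
    try:
        parsed = list(AlignIO.parse(path, "maf"))
    except ValueError as exc:
        raise MafParseError(f"malformed MAF {path}: {exc}") from exc
    for msa in parsed:
        widths = {len(rec.seq) for rec in msa}
        if len(widths) > 1:
            raise MafParseError(f"block rows differ in length in {path}")
        rows = [
            MafRow(
                species=_species_of(rec.id),
                chrom=_chrom_of(rec.id),
                start=rec.annotations["start"],
                size=rec.annotations["size"],
                strand="+" if rec.annotations["strand"] in (1, "+") else "-",
                src_size=rec.annotations["srcSize"],
                text=str(rec.seq).upper(),
            )
            for rec in msa
        ]
        block = MafBlock(rows)
        if ref_species is not None and block.row_for(ref_species) is None:
            warnings.warn(f"MAF block without reference row {ref_species!r} skipped")
            continue
        blocks.append(block)
    return blocks


def read_fasta_alignment(path, ref_species: str, ref_cds_length_nt: int | None = None) -> CdsAlignment:
    """Read an aligned FASTA (equal gapped lengths, reference row present)."""
    msa = AlignIO.read(path, "fasta")
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    if ref_species not in rows:
        raise ValueError(f"reference species {ref_species!r} not in {sorted(rows)}")
    ref = rows[ref_species]
    colmap = [i for i, c in enumerate(ref) if c != GAP]
    n = len(colmap)
    if ref_cds_length_nt is not None and n != ref_cds_length_nt:
        raise ValueError(f"reference row has {n} bases, expected {ref_cds_length_nt}")
    return CdsAlignment(ref_species, n, rows, colmap)


def _ref_positions_of_block(row: MafRow, interval: GenomicInterval) -> list[int | None]:
    """Map each block column to a 1-based CDS position, or None.

    None marks columns that are reference gaps (insertions) or fall outside
    the interval.  Works in plus-strand genomic space; minus-strand CDSs are
    handled by flipping the stitched matrix afterwards.
    """
    out: list[int | None] = []
    gpos = row.start  # 0-based genomic cursor on + strand
    if row.strand != "+":
        # UCSC reference rows are + strand; reverse-strand ref rows are not
        # produced by MULTIZ for the reference genome.
        raise ValueError("reference MAF row must be on the + strand")
    for c in row.text:
        if c == GAP:
            out.append(None)
            continue
        pos1 = gpos + 1  # genomic, 1-based
        if interval.start <= pos1 <= interval.end:
            out.append(pos1 - interval.start + 1)  # plus-strand CDS position
        else:
            out.append(None)
        gpos += 1
    return out


def stitch_cds(
    blocks: list[MafBlock],
    ref_interval: GenomicInterval,
    ref_species: str,
    expected_species: list[str] | None = None,
) -> CdsAlignment:
    """Stitch MAF blocks into a reference-anchored CDS alignment.

    Columns outside ``ref_interval`` are dropped; reference positions covered
    by no block appear as all-gap columns in the non-reference rows.  When
    blocks overlap on a reference position the block with more non-gap rows
    wins (tie: first encountered; the conflict is logged).  Minus-strand
    intervals are reverse-complemented so CDS position 1 is the first coding
    base.
    """
    L = len(ref_interval)
    # For each plus-strand CDS position: (block index, column) of the winner.
    owner: dict[int, tuple[int, int]] = {}
    block_cols: list[list[int | None]] = []
    for bi, block in enumerate(blocks):
        ref_row = block.row_for(ref_species)
        if ref_row is None:
            block_cols.append([])
            continue
        cols = _ref_positions_of_block(ref_row, ref_interval)
        block_cols.append(cols)
        for col, pos in enumerate(cols):
            if pos is None:
                continue
            if pos in owner:
                prev_bi = owner[pos][0]
                if block.n_aligned_rows() > blocks[prev_bi].n_aligned_rows():
                    log.warning(
                        "overlapping blocks at CDS position %d: block %d replaces %d",
                        pos, bi, prev_bi,
                    )
                    owner[pos] = (bi, col)
                else:
                    log.warning(
                        "overlapping blocks at CDS position %d: keeping block %d",
                        pos, prev_bi,
                    )
            else:
                owner[pos] = (bi, col)
    if not owner:
        raise ValueError("CDS absent from alignment: no block covers the interval")

    all_species: list[str] = []
    for block in blocks:
        for sp in block.species:
            if sp not in all_species:
                all_species.append(sp)
    if expected_species:
        for sp in expected_species:
            if sp not in all_species:
                all_species.append(sp)

    out_cols: list[dict[str, str]] = []  # one dict per emitted column
    colmap: list[int] = []

    def emit(column: dict[str, str], ref_pos: int | None) -> None:
        if ref_pos is not None:
            colmap.append(len(out_cols))
        out_cols.append(column)

    def block_column(bi: int, col: int) -> dict[str, str]:
        block = blocks[bi]
        return {r.species: r.text[col] for r in block.rows}

    prev: tuple[int, int] | None = None
    for pos in range(1, L + 1):
        if pos not in owner:
            # Uncovered reference position: reference base is unknown from the
            # alignment; an N placeholder keeps the matrix rectangular.
            emit({ref_species: "N"}, pos)
            prev = None
            continue
        bi, col = owner[pos]
        # Insertion columns (reference gaps) between consecutive positions of
        # the same block are retained: they carry species-relative insertions.
        if prev is not None and prev[0] == bi:
            for c in range(prev[1] + 1, col):
                if block_cols[bi][c] is None:
                    emit(block_column(bi, c), None)
        emit(block_column(bi, col), pos)
        prev = (bi, col)

    rows = {
        sp: "".join(col.get(sp, GAP) for col in out_cols) for sp in all_species
    }
    absent = {
        sp for sp in all_species
        if all(c == GAP for c in rows[sp]) and sp != ref_species
    }
    if ref_interval.strand == "-":
        rows = {sp: reverse_complement(seq) for sp, seq in rows.items()}
        n = len(out_cols)
        colmap = [n - 1 - c for c in reversed(colmap)]
    return CdsAlignment(ref_species, L, rows, colmap, absent_species=absent)


def alignable_fraction(aln: CdsAlignment, species: str) -> float:
    """Fraction of reference CDS positions where `species` has an aligned base.

    IUPAC ambiguity codes count as aligned; N does not (MULTIZ uses N for
    low-quality fill), nor do gaps.
    """
    if species not in aln.rows:
        raise KeyError(
            f"unknown species {species!r}; available: {sorted(aln.rows)}"
        )
    row = aln.rows[species]
    n = sum(1 for c in aln.colmap if row[c] not in (GAP, "N", "n"))
    return n / aln.ref_cds_length_nt


def write_fasta(aln: CdsAlignment, path) -> None:
    """Write the alignment as aligned FASTA, reference row first."""
    order = [aln.ref_species] + [s for s in aln.rows if s != aln.ref_species]
    with open(path, "w") as fh:
        for sp in order:
            fh.write(f">{sp}\n{aln.rows[sp]}\n")
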