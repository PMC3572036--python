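"""Per-species ORF-disruption tracing over a reference-anchored alignment.

A de novo protein-coding gene leaves a characteristic trail in orthologous
loci: start-codon losses, frameshifting indels, premature in-frame stops, or
the absence of any in-frame stop (a non-stop transcript, which is degraded
rather than translated).  This module walks the aligned ortholog of a focal
CDS left to right, records every such disruption in reference coordinates,
and converts the first one into a protein-homology fraction — the share of
the reference protein N-terminal to the first disruption.

The homology denominator is the coding length in nucleotides excluding the
stop codon; the numerator is the count of reference bases strictly before
the first event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .alignio import GAP, CdsAlignment

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


class DisruptionKind(str, Enum):
    START_LOSS = "start_loss"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    PREMATURE_STOP = "premature_stop"
    NONSTOP = "nonstop"


@dataclass(frozen=True)
class OrfDisruption:
    """One ORF-disrupting event in reference CDS coordinates.

    ``ref_pos_nt`` is the 1-based reference position where the event begins:
    0 for loss of the initiator codon, ``ref_cds_length + 1`` for a missing
    in-frame stop.  ``indel_len_nt`` is nonzero only for frameshifts.
    """

    kind: DisruptionKind
    ref_pos_nt: int
    indel_len_nt: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind in (DisruptionKind.FRAMESHIFT_INSERTION,
                         DisruptionKind.FRAMESHIFT_DELETION):
            if self.indel_len_nt % 3 == 0:
                raise ValueError(
                    f"frameshift with indel length {self.indel_len_nt} "
                    "(multiple of 3 is not a frameshift)"
                )

    def key(self) -> tuple:
        """Identity used to match the same event across species."""
        return (self.kind, self.ref_pos_nt, self.indel_len_nt)


@dataclass
class SpeciesOrfReport:
    species: str
    alignable_fraction: float
    protein_homology_fraction: float
    disruptions: list[OrfDisruption] = field(default_factory=list)
    has_start: bool = True
    absent: bool = False


def orf_length_aa(cds_start_nt: int, cds_end_nt: int) -> int:
    """Protein length encoded by a 1-based inclusive ORF span (stop included).

    >>> orf_length_aa(96, 503)
    135
    """
    span = cds_end_nt - cds_start_nt + 1
    if span % 3 != 0:
        raise ValueError(f"ORF span {span} nt is not a multiple of 3")
    return span // 3 - 1


def homology_fraction(first_event_pos_nt: int, coding_len_nt: int) -> float:
    """Fraction of the reference protein upstream of the first disruption.

    ``coding_len_nt`` excludes the stop codon.  Position 0 (start loss)
    yields 0.0; ``coding_len_nt + 1`` (no event before the stop) yields 1.0.
    The result is clamped to [0, 1].
    """
    if first_event_pos_nt < 0:
        raise ValueError(f"negative event position {first_event_pos_nt}")
    if coding_len_nt <= 0:
        raise ValueError("coding length must be positive")
    frac = (first_event_pos_nt - 1) / coding_len_nt
    return min(1.0, max(0.0, frac))


def _validate_ref_orf(ref_seq: str) -> None:
    if len(ref_seq) % 3 != 0 or len(ref_seq) < 6:
        raise ValueError("reference ORF invalid: length not a codon multiple")
    if not ref_seq.startswith(START_CODON):
        raise ValueError("reference ORF invalid: no ATG at position 1")
    if ref_seq[-3:] not in STOP_CODONS:
        raise ValueError("reference ORF invalid: no terminal stop codon")
    internal = {ref_seq[i:i + 3] for i in range(0, len(ref_seq) - 3, 3)}
    if internal & STOP_CODONS:
        raise ValueError("reference ORF invalid: internal stop codon")


def scan_species_orf(
    aln: CdsAlignment,
    species: str,
    *,
    from_alignable: float | None = None,
) -> SpeciesOrfReport:
    """Trace ORF disruptions for one species against the reference CDS.

    The scan walks alignment columns spanning the reference CDS in order,
    treating runs of gaps in the species row as deletions and runs of
    species bases opposite reference gaps as insertions; any run whose
    length is not a multiple of 3 is a frameshift.  The species sequence is
    then read in the frame set by the start codon, shifted by the cumulative
    indel offset, and the first in-frame stop upstream of the reference stop
    is a premature stop.  If no in-frame stop exists anywhere in the aligned
    span, the transcript is non-stop.

    Homology is set by the first disruption; a non-stop first disruption
    yields homology 0.0 (no stable protein survives non-stop decay).
    """
    from .alignio import alignable_fraction as _af

    L = aln.ref_cds_length_nt
    coding_len = L - 3
    ref_row = aln.rows[aln.ref_species]
    _validate_ref_orf(aln.ungapped_ref())
    if species not in aln.rows:
        raise KeyError(f"unknown species {species!r}; available: {sorted(aln.rows)}")
    sp_row = aln.rows[species]
    af = _af(aln, species) if from_alignable is None else from_alignable

    if af == 0.0:
        return SpeciesOrfReport(
            species=species, alignable_fraction=0.0,
            protein_homology_fraction=0.0,
            disruptions=[OrfDisruption(DisruptionKind.START_LOSS, 0, note="absent")],
            has_start=False, absent=True,
        )

    # Columns from the first to the last reference CDS column, inclusive of
    # interior insertion columns.  Each entry: (ref_pos or None, ref_c, sp_c).
    lo, hi = aln.colmap[0], aln.colmap[-1]
    pos_at_col = {c: p + 1 for p, c in enumerate(aln.colmap)}
    walk: list[tuple[int | None, str, str]] = []
    for c in range(lo, hi + 1):
        walk.append((pos_at_col.get(c), ref_row[c], sp_row[c]))

    disruptions: list[OrfDisruption] = []

    # --- start codon ---
    start_bases = [sp for pos, _r, sp in walk if pos is not None and pos <= 3]
    has_start = (
        all(b != GAP for b in start_bases)
        and "".join(start_bases).upper() == START_CODON
    )
    if not has_start:
        note = "unaligned" if all(b == GAP for b in start_bases) else ""
        disruptions.append(OrfDisruption(DisruptionKind.START_LOSS, 0, note=note))

    # --- indel runs ---
    # Deletion: species gap at a reference position.  Insertion: species base
    # at an insertion column.  Runs are maximal over the walk.
    i = 0
    n = len(walk)
    while i < n:
        pos, ref_c, sp_c = walk[i]
        if pos is not None and sp_c == GAP:
            j = i
            while j < n and walk[j][0] is not None and walk[j][2] == GAP:
                j += 1
            run_len = sum(1 for k in range(i, j) if walk[k][0] is not None)
            if run_len % 3 != 0:
                disruptions.append(OrfDisruption(
                    DisruptionKind.FRAMESHIFT_DELETION, walk[i][0], run_len))
            i = j
        elif pos is None and sp_c != GAP:
            j = i
            while j < n and walk[j][0] is None and walk[j][2] != GAP:
                j += 1
            run_len = j - i
            # event anchored at the next reference base
            nxt = next((walk[k][0] for k in range(j, n) if walk[k][0] is not None),
                       L + 1)
            if run_len % 3 != 0:
                disruptions.append(OrfDisruption(
                    DisruptionKind.FRAMESHIFT_INSERTION, nxt, run_len))
            i = j
        else:
            i += 1

    # --- translation in the indel-shifted frame ---
    # Stream of species bases in column order, each tagged with the reference
    # position it reads through (insertions borrow the next reference base).
    stream: list[tuple[str, int]] = []
    pending_ins: list[str] = []
    for pos, _r, sp_c in walk:
        if sp_c == GAP:
            continue
        if pos is None:
            pending_ins.append(sp_c)
        else:
            for b in pending_ins:
                stream.append((b, pos))
            pending_ins = []
            stream.append((sp_c, pos))
    for b in pending_ins:
        stream.append((b, L + 1))

    ref_stop_start = L - 2
    saw_stop = False
    for k in range(0, len(stream) - 2, 3):
        codon = (stream[k][0] + stream[k + 1][0] + stream[k + 2][0]).upper()
        if codon in STOP_CODONS:
            stop_pos = stream[k][1]
            saw_stop = True
            if stop_pos < ref_stop_start:
                disruptions.append(OrfDisruption(
                    DisruptionKind.PREMATURE_STOP, stop_pos))
            break
    if not saw_stop:
        disruptions.append(OrfDisruption(DisruptionKind.NONSTOP, L + 1))

    disruptions.sort(key=lambda d: d.ref_pos_nt)

    if not disruptions:
        homology = 1.0
    elif disruptions[0].kind is DisruptionKind.NONSTOP:
        homology = 0.0  # non-stop decay: no stable protein product
    else:
        homology = homology_fraction(disruptions[0].ref_pos_nt, coding_len)
    if not has_start:
        homology = 0.0

    return SpeciesOrfReport(
        species=species,
        alignable_fraction=af,
        protein_homology_fraction=homology,
        disruptions=disruptions,
        has_start=has_start,
    )


def scan_all_species(aln: CdsAlignment) -> list[SpeciesOrfReport]:
    """Reports for every species in the alignment, reference included.

    The reference's own report is the identity (no disruptions); keeping it
    in the list lets downstream event placement treat the reference lineage
    as an informative non-carrier.
    """
    reports = []
    for sp in aln.species:
        rep = scan_species_orf(aln, sp)
        if sp in aln.absent_species:
            rep.absent = True
        reports.append(rep)
    return reports
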