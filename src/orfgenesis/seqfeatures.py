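"""Promoter architecture, in-silico PCR, and conservation-track summaries.

Core-promoter classes differ in regulatory logic: GC-poor promoters with a
TATA box and initiator position the transcription start site (TSS) precisely
and answer to transcription factors and histone acetylation, while GC-rich
CpG-island promoters respond chiefly to DNA methylation.  This module
measures GC content around a TSS, classifies the promoter, and scans for
IUPAC consensus motifs in TSS-relative windows.  TSS-relative coordinates
follow promoter convention: the TSS base is +1, the base before it is -1,
and there is no position 0.

Also here: exact-match in-silico PCR (expected amplicon sizes from a
reference template) and mean/sd summaries of per-base conservation tracks
such as phyloP.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass

from Bio.Seq import reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDef:
    """An IUPAC consensus motif with a TSS-relative search window.

    ``window`` bounds the TSS-relative start position of a hit (inclusive,
    promoter coordinates: no 0).
    """

    name: str
    consensus: str
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty consensus")
        bad = [c for c in self.consensus.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"non-IUPAC symbol {bad[0]!r} in consensus")
        if self.window[0] > self.window[1]:
            raise ValueError("window min > max")

    def regex(self) -> re.Pattern:
        return re.compile("".join(f"[{IUPAC[c]}]" for c in self.consensus.upper()))

    def expansions(self) -> list[str]:
        """All concrete sequences matching the consensus (small motifs only)."""
        return ["".join(p) for p in itertools.product(
            *[IUPAC[c] for c in self.consensus.upper()])]


@dataclass
class MotifHit:
    name: str
    matched: str
    tss_relative_start: int


@dataclass
class PromoterAnnotation:
    gc_content: float
    promoter_class: str
    hits: list[MotifHit]
    gc_threshold: float


def index_to_tss_relative(i: int, tss_index: int) -> int:
    """0-based sequence index -> promoter coordinate (+1 at the TSS, no 0)."""
    return i - tss_index + 1 if i >= tss_index else i - tss_index


def tss_relative_to_index(pos: int, tss_index: int) -> int:
    if pos == 0:
        raise ValueError("promoter coordinates have no position 0")
    return tss_index + pos - 1 if pos > 0 else tss_index + pos


def gc_window(seq: str, tss_index: int, halfwidth: int = 100) -> float:
    """GC fraction of the (2*halfwidth + 1)-base window centered on the TSS."""
    lo, hi = tss_index - halfwidth, tss_index + halfwidth
    if lo < 0 or hi >= len(seq):
        raise ValueError(
            f"window [{lo}, {hi}] exceeds sequence of length {len(seq)}"
        )
    window = seq[lo:hi + 1].upper()
    return sum(1 for c in window if c in "GC") / len(window)


def classify_promoter(gc: float, threshold: float = 0.45) -> str:
    """GC-poor (TATA-type) vs GC-rich (CpG-island-type) promoter class."""
    if not 0 <= gc <= 1:
        raise ValueError(f"GC fraction {gc} outside [0, 1]")
    return "GC-poor" if gc < threshold else "GC-rich"


def scan_motifs(seq: str, tss_index: int, motifs: list[MotifDef]) -> list[MotifHit]:
    """Exact IUPAC-consensus scan, hits restricted to each motif's window.

    Positions are TSS-relative starts of the match on the given strand.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    for motif in motifs:
        pat = motif.regex()
        for m in pat.finditer(seq):
            rel = index_to_tss_relative(m.start(), tss_index)
            if motif.window[0] <= rel <= motif.window[1]:
                hits.append(MotifHit(motif.name, m.group(0), rel))
    hits.sort(key=lambda h: h.tss_relative_start)
    return hits


def annotate_promoter(
    seq: str,
    tss_index: int,
    motifs: list[MotifDef],
    *,
    halfwidth: int = 100,
    gc_threshold: float = 0.45,
) -> PromoterAnnotation:
    gc = gc_window(seq, tss_index, halfwidth)
    return PromoterAnnotation(
        gc_content=gc,
        promoter_class=classify_promoter(gc, gc_threshold),
        hits=scan_motifs(seq, tss_index, motifs),
        gc_threshold=gc_threshold,
    )


def insilico_pcr(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    max_product: int = 5000,
) -> list[int]:
    """Exact-match PCR product lengths on a template's given strand.

    The forward primer anneals to the template as written; the reverse
    primer anneals to the opposite strand, i.e. its reverse complement must
    occur downstream.  Product length spans the outer primer ends.
    """
    if len(fwd_primer) < 10 or len(rev_primer) < 10:
        raise ValueError("primers must be at least 10 nt")
    template = template.upper()
    fwd = fwd_primer.upper()
    rev_site = reverse_complement(rev_primer.upper())
    fwd_starts = [m.start() for m in re.finditer(re.escape(fwd), template)]
    rev_ends = [m.end() - 1 for m in re.finditer(re.escape(rev_site), template)]
    products = []
    for fs in fwd_starts:
        for re_ in rev_ends:
            rev_start = re_ - len(rev_site) + 1
            if rev_start < fs + len(fwd):
                continue  # reverse site must lie downstream of the forward primer
            length = re_ - fs + 1
            if length <= max_product:
                products.append(length)
    return sorted(products)


def summarize_track(values) -> tuple[float, float, int]:
    """Mean and population sd of a per-base score track.

    Missing bases (None or NaN) are skipped; the count of skipped bases is
    returned as the third element.
    """
    values = list(values)
    clean = [
        v for v in values
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    skipped = len(values) - len(clean)
    if not clean:
        raise ValueError("no values after skipping missing bases")
    n = len(clean)
    mean = sum(clean) / n
    var = sum((v - mean) ** 2 for v in clean) / n
    return mean, math.sqrt(var), skipped


def read_bedgraph(path, interval=None) -> list[float]:
    """Per-base values from a bedGraph file (0-based half-open lines).

    If ``interval`` (a :class:`~orfgenesis.alignio.GenomicInterval`) is
    given, only bases inside it are returned, in genomic order, with NaN for
    uncovered bases.
    """
    import numpy as np

    if interval is None:
        out = []
        with open(path) as fh:
            for line in fh:
                if line.startswith(("track", "#")) or not line.strip():
                    continue
                _chrom, start, end, val = line.split()[:4]
                out.extend([float(val)] * (int(end) - int(start)))
        return out
    vals = np.full(len(interval), np.nan)
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, val = line.split()[:4]
            if chrom != interval.chrom:
                continue
            for g in range(max(int(start) + 1, interval.start),
                           min(int(end), interval.end) + 1):
                vals[g - interval.start] = float(val)
    return list(vals)
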