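"""Ka/Ks (dN/dS) estimation by synonymous/nonsynonymous site counting.

The estimator is the classical counting approach: each codon contributes
synonymous and nonsynonymous *sites* according to the fraction of possible
single-base changes at each position that preserve the amino acid, observed
codon differences are decomposed into single-step mutational pathways
(averaged with equal weight over all orderings that avoid intermediate stop
codons), proportions are corrected for multiple hits with the Jukes-Cantor
formula, and Ka/Ks is the ratio of the corrected rates.  Mutations that
create a stop codon count as nonsynonymous opportunities so that synonymous
and nonsynonymous sites always sum to three per codon.

Confidence intervals come from a parametric Monte-Carlo resampling of the
difference counts at the estimated per-site rates.  A ratio near 1 is the
neutral expectation; values well below 1 indicate purifying selection on the
protein.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .orftrace import STOP_CODONS

_BASES = "TCAG"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _translate(codon: str) -> str:
    """One-letter amino acid, or '*' for stop."""
    return "*" if codon in STOP_CODONS else _STANDARD.forward_table[codon]


def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one codon (sum to 3).

    At each position the synonymous fraction is the share of the three
    possible base changes that leave the amino acid unchanged; changes to a
    stop codon are nonsynonymous opportunities.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no sites")
    aa = _translate(codon)
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if mut not in STOP_CODONS and _translate(mut) == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def _pathways(c1: str, c2: str) -> list[list[tuple[str, str]]]:
    """All orderings of single-base steps from c1 to c2.

    Each pathway is a list of (from_codon, to_codon) steps.  Pathways passing
    through an intermediate stop codon are excluded unless every pathway
    does.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        ok = True
        for k, i in enumerate(order):
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in STOP_CODONS and k < len(order) - 1:
                ok = False
            steps.append((cur, nxt))
            cur = nxt
        paths.append((ok, steps))
    clean = [s for ok, s in paths if ok]
    return clean if clean else [s for _ok, s in paths]


def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences of a codon pair."""
    if c1 == c2:
        return 0.0, 0.0
    paths = _pathways(c1, c2)
    syn = nonsyn = 0.0
    for steps in paths:
        for a, b in steps:
            if b in STOP_CODONS or a in STOP_CODONS:
                nonsyn += 1  # stop-bound step: nonsynonymous by convention
            elif _translate(a) == _translate(b):
                syn += 1
            else:
                nonsyn += 1
    n = len(paths)
    return syn / n, nonsyn / n


def ng86_counts(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """Synonymous/nonsynonymous sites and differences between two CDSs.

    Returns (syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs).  Sites are
    the average of the two sequences' per-codon opportunities; codons
    containing a stop in either sequence are skipped.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError(f"length mismatch: {len(seq1)} vs {len(seq2)}")
    if len(seq1) % 3 != 0:
        raise ValueError("sequence length not a multiple of 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        s1, n1 = syn_nonsyn_sites(c1)
        s2, n2 = syn_nonsyn_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _pair_diffs(c1, c2)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a difference proportion."""
    if not 0 <= p < 0.75:
        raise ValueError(f"proportion {p} outside [0, 0.75): JC saturated")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None
    ci_low: float | None
    ci_high: float | None
    n_sim: int
    seed: int
    per_pair: dict | None = None


def _drop_gapped_columns(seqs: dict[str, str]) -> dict[str, str]:
    """Remove codon columns containing a gap in any retained species."""
    n = min(len(s) for s in seqs.values())
    n -= n % 3
    keep = []
    for i in range(0, n, 3):
        if all("-" not in s[i:i + 3] and "N" not in s[i:i + 3].upper()
               for s in seqs.values()):
            keep.append(i)
    return {sp: "".join(s[i:i + 3] for i in keep) for sp, s in seqs.items()}


def kaks_with_ci(
    aln: dict[str, str],
    ref_species: str,
    n_sim: int = 1000,
    seed: int = 0,
    *,
    alpha: float = 0.05,
) -> KaKsResult:
    """Pooled Ka/Ks of a reference against every other species, with CI.

    Counts are summed over reference-vs-other pairs (per-pair results are
    reported alongside); Ka = JC(Nd/N), Ks = JC(Sd/S).  The confidence
    interval is a parametric Monte Carlo: difference counts are resampled
    binomially at the estimated per-site proportions — the sampling
    distribution of the estimator over simulated sequence pairs — and the
    ratio is re-estimated for each replicate.
    """
    if ref_species not in aln:
        raise KeyError(f"reference {ref_species!r} not in alignment")
    others = [sp for sp in aln if sp != ref_species]
    if not others:
        raise ValueError("need at least two species")
    clean = _drop_gapped_columns(aln)

    S = N = Sd = Nd = 0.0
    per_pair = {}
    for sp in others:
        s, n, sd, nd = ng86_counts(clean[ref_species], clean[sp])
        per_pair[sp] = _pair_result(s, n, sd, nd)
        S += s
        N += n
        Sd += sd
        Nd += nd

    if S == 0 or N == 0:
        raise ValueError("no codons survive column filtering")
    ps, pn = Sd / S, Nd / N
    ks, ka = jc_correct(ps), jc_correct(pn)
    if ks == 0:
        return KaKsResult(ka=ka, ks=0.0, ratio=None, ci_low=None, ci_high=None,
                          n_sim=0, seed=seed, per_pair=per_pair)

    rng = np.random.default_rng(seed)
    nS, nN = int(round(S)), int(round(N))
    ratios = []
    for _ in range(n_sim):
        sd_sim = rng.binomial(nS, ps)
        nd_sim = rng.binomial(nN, pn)
        ps_sim, pn_sim = sd_sim / nS, nd_sim / nN
        if ps_sim == 0 or ps_sim >= 0.75 or pn_sim >= 0.75:
            continue
        ratios.append(jc_correct(pn_sim) / jc_correct(ps_sim))
    if ratios:
        lo, hi = np.percentile(ratios, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        lo = hi = None
    return KaKsResult(ka=ka, ks=ks, ratio=ka / ks, ci_low=lo, ci_high=hi,
                      n_sim=n_sim, seed=seed, per_pair=per_pair)


def _pair_result(s, n, sd, nd):
    out = {"syn_sites": s, "nonsyn_sites": n, "syn_diffs": sd, "nonsyn_diffs": nd}
    try:
        ks = jc_correct(sd / s) if s else None
        ka = jc_correct(nd / n) if n else None
        out["ka"], out["ks"] = ka, ks
        out["ratio"] = ka / ks if ks else None
    except ValueError:
        out["ka"] = out["ks"] = out["ratio"] = None
    return out
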