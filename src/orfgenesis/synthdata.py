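"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the data the analysis consumes:

* :func:`simulate_cds_evolution` evolves a root CDS down a phylogeny with
  per-branch substitution and indel rates plus deterministically scripted
  ORF-disrupting events (start loss, frameshifting indels, stop gain/loss),
  and emits the true alignment — known by construction, no realignment — and
  the true branch placement of every scripted event.
* :func:`simulate_expression` builds a genes x samples matrix in which
  chosen partner genes correlate with a focal gene at specified r and sample
  groups carry additive effects.
* :func:`make_promoter` writes concrete motif texts at TSS-relative
  positions into a background sequence drawn to a target GC content.

All generators are deterministic given their seed.  Indel lengths are
geometric with mean 2, so single-base frameshifts — the most consequential
events in de novo gene history — are the most common.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignio import GAP, CdsAlignment
from .exprassoc import ExpressionMatrix
from .orftrace import STOP_CODONS, DisruptionKind, OrfDisruption
from .phyloevents import EventPlacement, PhyloTree

_BASES = np.array(list("ACGT"))
# HKY-flavoured replacement: transitions twice as likely as each transversion.
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class ScriptedEvent:
    """An ORF disruption to apply deterministically on a named branch."""

    branch: str  # node id (tip label or internal node id)
    kind: DisruptionKind
    ref_pos_nt: int = 0
    indel_len_nt: int = 0

    def to_disruption(self, ref_len: int | None = None) -> OrfDisruption:
        if self.kind is DisruptionKind.NONSTOP and ref_len is not None:
            # A lost stop is detected downstream of the whole reference CDS.
            return OrfDisruption(self.kind, ref_len + 1, 0)
        return OrfDisruption(self.kind, self.ref_pos_nt, self.indel_len_nt)


@dataclass
class EvolSpec:
    """Everything needed to evolve a CDS down a tree reproducibly."""

    tree: PhyloTree
    root_cds: str
    ref_species: str
    seed: int = 0
    sub_rate: float = 0.0  # substitutions/site/branch, uniform default
    indel_rate: float = 0.0  # indel events/site/branch
    branch_sub_rates: dict[str, float] = field(default_factory=dict)
    branch_indel_rates: dict[str, float] = field(default_factory=dict)
    scripted_events: list[ScriptedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        cds = self.root_cds.upper()
        if len(cds) % 3 != 0 or not cds.startswith("ATG") \
                or cds[-3:] not in STOP_CODONS:
            raise ValueError("root_cds must be a valid ORF (ATG...stop)")
        internal = {cds[i:i + 3] for i in range(0, len(cds) - 3, 3)}
        if internal & STOP_CODONS:
            raise ValueError("root_cds has an internal stop codon")


def random_orf(n_codons: int, seed: int = 0) -> str:
    """A random ORF of ``n_codons`` sense codons plus a terminal stop."""
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, 3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


class _Lineage:
    """A sequence as a dict column-id -> base; absence of an id = deletion."""

    def __init__(self, bases: dict[int, str]):
        self.bases = bases

    def copy(self) -> "_Lineage":
        return _Lineage(dict(self.bases))


def _apply_scripted(lineage: _Lineage, ev: ScriptedEvent, columns: list[int],
                    next_id: list[int], col_order: dict[int, float],
                    root_len: int = 0) -> None:
    """Mutate a lineage in place according to a scripted event template."""
    k = ev.kind
    if k is DisruptionKind.START_LOSS:
        col = ev.ref_pos_nt if ev.ref_pos_nt >= 1 else 1
        cid = col - 1  # root column ids are 0-based ref positions
        if cid not in lineage.bases:
            raise ValueError("scripted start loss at an already-deleted position")
        lineage.bases[cid] = "G" if lineage.bases[cid] != "G" else "C"
    elif k is DisruptionKind.FRAMESHIFT_DELETION:
        for p in range(ev.ref_pos_nt, ev.ref_pos_nt + ev.indel_len_nt):
            cid = p - 1
            if cid not in lineage.bases:
                raise ValueError(
                    f"scripted deletion at ref {p}: position already absent"
                )
            del lineage.bases[cid]
    elif k is DisruptionKind.FRAMESHIFT_INSERTION:
        anchor = ev.ref_pos_nt - 1
        base_order = col_order[anchor]
        prev_order = max(
            (o for c, o in col_order.items() if o < base_order),
            default=base_order - 1,
        )
        for j in range(ev.indel_len_nt):
            cid = next_id[0]
            next_id[0] += 1
            frac = (j + 1) / (ev.indel_len_nt + 1)
            col_order[cid] = prev_order + frac * (base_order - prev_order)
            columns.append(cid)
            lineage.bases[cid] = "A"
    elif k is DisruptionKind.PREMATURE_STOP:
        stop = "TGA"
        for j, b in enumerate(stop):
            cid = ev.ref_pos_nt - 1 + j
            if cid not in lineage.bases:
                raise ValueError("scripted stop overlaps a deleted position")
            lineage.bases[cid] = b
    elif k is DisruptionKind.NONSTOP:
        # Mutate the first base of the reference stop codon to a sense base;
        # ref_pos_nt may name it explicitly, else it is the terminal codon.
        cid = (ev.ref_pos_nt - 1) if ev.ref_pos_nt >= 1 else root_len - 3
        if cid not in lineage.bases:
            raise ValueError("scripted stop-loss at a deleted position")
        lineage.bases[cid] = "C"
    else:  # pragma: no cover
        raise ValueError(f"unknown scripted kind {k}")


def simulate_cds_evolution(spec: EvolSpec) -> tuple[CdsAlignment, list[EventPlacement]]:
    """Evolve the root CDS down the tree; return (alignment, truth placements).

    Substitutions are HKY-like (transition:transversion weight 2:1) at the
    branch's substitution rate; indels arrive at the indel rate with
    geometric lengths (mean 2) and are equally likely insertions or
    deletions.  Scripted events are applied after the stochastic process on
    their branch and are inherited by all descendants.  The emitted
    alignment is the true one (column identity tracked through the
    simulation), with the reference species' row anchoring the column map.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(spec.root_cds)
    columns = list(range(L))  # all column ids ever created
    col_order: dict[int, float] = {i: float(i) for i in range(L)}
    next_id = [L]

    root = _Lineage({i: b for i, b in enumerate(spec.root_cds.upper())})
    truth: list[EventPlacement] = []
    tip_seqs: dict[str, _Lineage] = {}

    def descend(node, lineage: _Lineage) -> None:
        nid = node.node_id
        if node is not spec.tree.tree.seed_node:
            sub_rate = spec.branch_sub_rates.get(nid, spec.sub_rate)
            indel_rate = spec.branch_indel_rates.get(nid, spec.indel_rate)
            present = sorted(lineage.bases, key=col_order.__getitem__)
            if sub_rate > 0 and present:
                n_subs = rng.binomial(len(present), min(sub_rate, 1.0))
                for cid in rng.choice(present, size=n_subs, replace=False):
                    cur = lineage.bases[cid]
                    ti = _TRANSITION.get(cur, "A")
                    tv = [b for b in "ACGT" if b not in (cur, ti)]
                    pick = rng.random()
                    lineage.bases[cid] = ti if pick < 0.5 else tv[pick < 0.75]
            if indel_rate > 0 and present:
                n_indels = rng.binomial(len(present), min(indel_rate, 1.0))
                for _ in range(n_indels):
                    length = rng.geometric(0.5)
                    present_now = sorted(lineage.bases, key=col_order.__getitem__)
                    if not present_now:
                        break
                    at = rng.integers(len(present_now))
                    if rng.random() < 0.5:  # deletion
                        for cid in present_now[at:at + length]:
                            del lineage.bases[cid]
                    else:  # insertion after present_now[at]
                        lo = col_order[present_now[at]]
                        hi = min(
                            (col_order[c] for c in lineage.bases
                             if col_order[c] > lo),
                            default=lo + 1,
                        )
                        for j in range(length):
                            cid = next_id[0]
                            next_id[0] += 1
                            col_order[cid] = lo + (j + 1) / (length + 1) * (hi - lo)
                            columns.append(cid)
                            lineage.bases[cid] = str(rng.choice(_BASES))
            for ev in spec.scripted_events:
                if ev.branch == nid:
                    _apply_scripted(lineage, ev, columns, next_id, col_order, L)
                    truth.append(EventPlacement(
                        event=ev.to_disruption(L), branch=nid,
                        supporting_tips=spec.tree.tips_below(node),
                    ))
        if node.is_leaf():
            tip_seqs[node.taxon.label] = lineage
        else:
            for child in node.child_nodes():
                descend(child, lineage.copy())

    descend(spec.tree.tree.seed_node, root)

    if spec.ref_species not in tip_seqs:
        raise ValueError(f"reference {spec.ref_species!r} is not a tip of the tree")
    ordered = sorted(columns, key=col_order.__getitem__)
    # Drop columns no tip retains (all-gap columns carry no information).
    kept = [c for c in ordered if any(c in lin.bases for lin in tip_seqs.values())]
    rows = {
        sp: "".join(lin.bases.get(c, GAP) for c in kept)
        for sp, lin in tip_seqs.items()
    }
    ref_row = rows[spec.ref_species]
    colmap = [i for i, ch in enumerate(ref_row) if ch != GAP]
    aln = CdsAlignment(
        ref_species=spec.ref_species,
        ref_cds_length_nt=len(colmap),
        rows=rows,
        colmap=colmap,
    )
    truth.sort(key=lambda t: (t.event.ref_pos_nt, t.branch))
    return aln, truth


def simulate_expression(
    n_genes: int,
    n_samples: int,
    planted: list[tuple[str, float]] | None = None,
    group_effects: dict | None = None,
    seed: int = 0,
    focal_gene: str = "FOCAL",
) -> tuple[ExpressionMatrix, dict]:
    """Expression matrix with planted focal-gene correlations and group shifts.

    The focal gene is standard normal across samples; each planted partner
    is r*focal + sqrt(1-r^2)*noise, so its population correlation with the
    focal gene is exactly r.  Remaining genes are independent noise.
    ``group_effects`` maps factor name -> (labels per sample, effect dict
    gene -> {label: shift}); shifts are added after correlation planting.
    """
    planted = planted or []
    for gene, r in planted:
        if not -1 < r < 1:
            raise ValueError(f"planted r for {gene!r} must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    samples = [f"s{i+1}" for i in range(n_samples)]
    focal = rng.standard_normal(n_samples)
    data = {focal_gene: focal}
    truth: dict = {"planted_r": dict(planted), "focal_gene": focal_gene}
    for gene, r in planted:
        noise = rng.standard_normal(n_samples)
        data[gene] = r * focal + np.sqrt(1 - r * r) * noise
    n_null = n_genes - len(data)
    for i in range(n_null):
        data[f"null{i+1}"] = rng.standard_normal(n_samples)
    values = pd.DataFrame(data).T
    values.columns = samples

    ann = pd.DataFrame(index=samples)
    if group_effects:
        truth["group_effects"] = {}
        for factor, (labels, effects) in group_effects.items():
            if len(labels) != n_samples:
                raise ValueError(f"factor {factor!r} labels != n_samples")
            ann[factor] = list(labels)
            for gene, shift_by_label in effects.items():
                shifts = np.array([shift_by_label.get(l, 0.0) for l in labels])
                values.loc[gene] = values.loc[gene] + shifts
            truth["group_effects"][factor] = effects
    return ExpressionMatrix(values, ann), truth


def make_promoter(
    length: int,
    plants: list[tuple[str, int]] | None = None,
    gc_target: float = 0.5,
    tss_index: int | None = None,
    seed: int = 0,
) -> tuple[str, dict]:
    """Background sequence at a target GC with motif texts planted at
    TSS-relative positions.

    Each background base is G or C with probability ``gc_target`` (split
    evenly), A or T otherwise.  Plants are concrete sequences written at
    their TSS-relative start; overlaps are rejected.
    """
    from .seqfeatures import tss_relative_to_index

    plants = plants or []
    if tss_index is None:
        tss_index = length // 2
    rng = np.random.default_rng(seed)
    probs = [
        (1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2
    ]
    seq = list(rng.choice(_BASES, size=length, p=probs))

    occupied: set[int] = set()
    truth = {"plants": [], "tss_index": tss_index, "gc_target": gc_target}
    for text, rel_pos in plants:
        start = tss_relative_to_index(rel_pos, tss_index)
        span = range(start, start + len(text))
        if start < 0 or start + len(text) > length:
            raise ValueError(f"plant {text!r} at {rel_pos} falls outside sequence")
        if occupied & set(span):
            raise ValueError(f"plant {text!r} at {rel_pos} overlaps another plant")
        occupied.update(span)
        for j, b in enumerate(text.upper()):
            seq[start + j] = b
        truth["plants"].append({"text": text.upper(), "tss_relative": rel_pos})
    return "".join(seq), truth
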