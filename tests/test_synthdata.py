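import numpy as np
import pytest

from orfgenesis.alignio import alignable_fraction
from orfgenesis.exprassoc import one_tailed_ttest, pearson_with_p
from orfgenesis.orftrace import DisruptionKind, scan_all_species, scan_species_orf
from orfgenesis.phyloevents import PhyloTree, place_events
from orfgenesis.seqfeatures import gc_window
from orfgenesis.synthdata import (
    EvolSpec,
    ScriptedEvent,
    make_promoter,
    random_orf,
    simulate_cds_evolution,
    simulate_expression,
)

from conftest import random_binary_newick


class TestSimulateCdsEvolution:
    def test_zero_rates_give_identical_tips(self, primate_tree):
        spec = EvolSpec(tree=primate_tree, root_cds=random_orf(135, 1),
                        ref_species="human", seed=3)
        aln, truth = simulate_cds_evolution(spec)
        assert truth == []
        for sp in aln.species:
            rep = scan_species_orf(aln, sp)
            assert rep.protein_homology_fraction == 1.0
            assert alignable_fraction(aln, sp) == 1.0

    def test_scripted_deletion_at_12_gives_3pct_homology(self, primate_tree):
        spec = EvolSpec(
            tree=primate_tree, root_cds=random_orf(135, 2),
            ref_species="human", seed=4,
            scripted_events=[ScriptedEvent(
                "dog", DisruptionKind.FRAMESHIFT_DELETION, 12, 1)],
        )
        aln, truth = simulate_cds_evolution(spec)
        rep = scan_species_orf(aln, "dog")
        first = rep.disruptions[0]
        assert first.kind is DisruptionKind.FRAMESHIFT_DELETION
        assert first.ref_pos_nt == 12
        assert round(100 * rep.protein_homology_fraction) == 3
        assert truth[0].branch == "dog"

    def test_internal_branch_event_reaches_all_descendants(self, primate_tree):
        stem = primate_tree.clade_node("Hominidae").node_id
        spec = EvolSpec(
            tree=primate_tree, root_cds=random_orf(135, 5),
            ref_species="rhesus", seed=6,
            scripted_events=[ScriptedEvent(
                stem, DisruptionKind.PREMATURE_STOP, 88)],
        )
        aln, truth = simulate_cds_evolution(spec)
        reports = scan_all_species(aln)
        placements = place_events(primate_tree, reports)
        match = [p for p in placements
                 if p.event.kind is DisruptionKind.PREMATURE_STOP
                 and p.event.ref_pos_nt == 88]
        assert len(match) == 1
        assert match[0].branch == stem and not match[0].ambiguous
        assert truth[0].branch == stem

    def test_deterministic_given_seed(self, primate_tree):
        spec = lambda: EvolSpec(
            tree=primate_tree, root_cds=random_orf(135, 7),
            ref_species="human", seed=11, sub_rate=0.05, indel_rate=0.01)
        a1, _ = simulate_cds_evolution(spec())
        a2, _ = simulate_cds_evolution(spec())
        assert a1.rows == a2.rows

    def test_substitution_rate_scales_divergence(self, primate_tree):
        spec = EvolSpec(tree=primate_tree, root_cds=random_orf(135, 8),
                        ref_species="human", seed=13, sub_rate=0.05)
        aln, _ = simulate_cds_evolution(spec)
        ref = aln.rows["human"]
        dog = aln.rows["dog"]
        mismatches = sum(1 for a, b in zip(ref, dog) if a != b)
        # several branches at 5% per site separate human and dog
        assert 0 < mismatches < len(ref) * 0.5

    def test_invalid_root_rejected(self, primate_tree):
        with pytest.raises(ValueError, match="valid ORF"):
            EvolSpec(tree=primate_tree, root_cds="AAATTT",
                     ref_species="human")


def candidate_branches(tree: PhyloTree, ref: str) -> list[str]:
    """Branches usable for scripted events: exclude the reference lineage and
    any node whose informative clade is everything-but-the-reference."""
    all_tips = set(tree.tips)
    out = []
    for node in tree.tree.preorder_node_iter():
        below = tree.tips_below(node)
        if ref in below:
            continue
        if below == all_tips - {ref}:
            continue
        out.append((node.node_id, below))
    return out


KINDS = [DisruptionKind.START_LOSS, DisruptionKind.FRAMESHIFT_DELETION,
         DisruptionKind.FRAMESHIFT_INSERTION, DisruptionKind.PREMATURE_STOP,
         DisruptionKind.NONSTOP]


def random_scenario(rng: np.random.Generator):
    """A random tree plus scripted events on disjoint non-reference clades."""
    n_tips = int(rng.integers(6, 11))
    tree = PhyloTree(random_binary_newick(n_tips, rng))
    ref = "t1"
    n_codons = 135
    cands = candidate_branches(tree, ref)
    rng.shuffle(cands)
    events, used_tips, used_kinds = [], set(), set()
    for node_id, below in cands:
        if len(events) == 3:
            break
        if below & used_tips:
            continue  # keep scripted clades disjoint: one event per lineage
        kind = KINDS[rng.integers(len(KINDS))]
        codon = int(rng.integers(3, n_codons - 2))  # interior codon
        pos = 3 * (codon - 1) + 1
        # identical events on two clades are convergence, which placement
        # rightly reports as ambiguous — keep scripted event keys unique
        if kind in (DisruptionKind.START_LOSS, DisruptionKind.NONSTOP):
            if kind in used_kinds:
                continue
            used_kinds.add(kind)
            pos = 0
        elif (kind, pos) in used_kinds:
            continue
        used_kinds.add((kind, pos))
        used_tips |= below
        if kind in (DisruptionKind.FRAMESHIFT_DELETION,
                    DisruptionKind.FRAMESHIFT_INSERTION):
            length = int(rng.choice([1, 2, 4]))
            events.append(ScriptedEvent(node_id, kind, pos, length))
        else:
            events.append(ScriptedEvent(node_id, kind, pos))
    spec = EvolSpec(tree=tree, root_cds=random_orf(n_codons, int(rng.integers(2**31))),
                    ref_species=ref, seed=int(rng.integers(2**31)),
                    scripted_events=events)
    return tree, spec


class TestClosedLoopRecovery:
    def test_scripted_events_recovered_over_50_random_scenarios(self):
        """orftrace + phyloevents recover every scripted event exactly when
        its realized carrier clade is monophyletic.

        A scripted frameshift can secondarily unmask the same nonstop state
        as a nonstop scripted on another clade; such convergent carrier sets
        are not monophyletic and must surface as ambiguous placements, not as
        a wrong branch.
        """
        rng = np.random.default_rng(2023)
        n_clean = 0
        for _ in range(50):
            tree, spec = random_scenario(rng)
            aln, truth = simulate_cds_evolution(spec)
            reports = scan_all_species(aln)
            placements = place_events(tree, reports)
            recovered = {
                (p.event.kind, p.event.ref_pos_nt, p.event.indel_len_nt, p.branch)
                for p in placements if not p.ambiguous
            }
            flagged = {
                (p.event.kind, p.event.ref_pos_nt, p.event.indel_len_nt)
                for p in placements if p.ambiguous
            }
            for t in truth:
                ekey = (t.event.kind, t.event.ref_pos_nt, t.event.indel_len_nt)
                carriers = {
                    r.species for r in reports
                    if any(d.key() == t.event.key() for d in r.disruptions)
                }
                if carriers == t.supporting_tips:  # monophyletic by construction
                    assert ekey + (t.branch,) in recovered, \
                        f"lost {ekey} on {t.branch}; got {recovered}"
                    n_clean += 1
                else:
                    assert ekey in flagged
        assert n_clean >= 80  # the overwhelming majority of events are clean


class TestSimulateExpression:
    def test_unplanted_gene_uncorrelated(self):
        em, _ = simulate_expression(n_genes=50, n_samples=400, seed=21)
        r, _ = pearson_with_p(em.gene("FOCAL"), em.gene("null1"))
        assert abs(r) < 2 / np.sqrt(400)

    def test_planted_correlation_recovered(self):
        em, truth = simulate_expression(
            n_genes=20, n_samples=200, planted=[("SHH", 0.9)], seed=22)
        r, _ = pearson_with_p(em.gene("FOCAL"), em.gene("SHH"))
        assert 0.85 <= r <= 0.95
        assert truth["planted_r"]["SHH"] == 0.9

    def test_planted_correlation_within_tenth_at_gds_scale(self):
        # at 60 samples (the breast-cancer set's size) recovery is within 0.1
        em, _ = simulate_expression(
            n_genes=100, n_samples=60, planted=[("CEBPA", 0.48)], seed=23)
        r, _ = pearson_with_p(em.gene("FOCAL"), em.gene("CEBPA"))
        assert abs(r - 0.48) < 0.1

    def test_group_effect_detected_by_one_tailed_test(self):
        labels = ["treated"] * 20 + ["control"] * 20
        em, _ = simulate_expression(
            n_genes=10, n_samples=40, seed=24,
            group_effects={"arm": (labels, {"FOCAL": {"treated": 2.0}})})
        x = em.gene("FOCAL")
        treated, control = x[:20], x[20:]
        _, p = one_tailed_ttest(treated, control, "a>b")
        assert p < 0.01

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError, match="in \\(-1, 1\\)"):
            simulate_expression(10, 10, planted=[("X", 1.0)])

    def test_deterministic_given_seed(self):
        e1, _ = simulate_expression(20, 30, planted=[("A", 0.5)], seed=9)
        e2, _ = simulate_expression(20, 30, planted=[("A", 0.5)], seed=9)
        assert e1.values.equals(e2.values)


class TestMakePromoter:
    def test_planted_motif_is_written_verbatim(self):
        seq, truth = make_promoter(
            400, plants=[("GCCAAT", -53)], gc_target=0.35, tss_index=200, seed=1)
        start = 200 - 53
        assert seq[start:start + 6] == "GCCAAT"
        assert truth["plants"][0]["tss_relative"] == -53

    def test_background_gc_near_target(self):
        seq, _ = make_promoter(10000, gc_target=0.35, seed=2)
        assert gc_window(seq, 5000, halfwidth=4999) == pytest.approx(0.35, abs=0.02)

    def test_no_plants_background_hit_rate(self):
        # specific 9-mers appear at ~ the composition-implied background rate
        seq, _ = make_promoter(200_000, gc_target=0.5, seed=3)
        count = seq.count("GATATATTT")
        expected = (200_000 - 8) * 0.25**9
        assert count <= expected * 5 + 3  # loose Poisson envelope

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_promoter(400, plants=[("GCCAAT", -53), ("TTTTTT", -50)],
                          tss_index=200, seed=1)

    def test_plant_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_promoter(100, plants=[("GCCAAT", -90)], tss_index=10, seed=1)

    def test_deterministic_given_seed(self):
        s1, _ = make_promoter(500, gc_target=0.4, seed=8)
        s2, _ = make_promoter(500, gc_target=0.4, seed=8)
        assert s1 == s2
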