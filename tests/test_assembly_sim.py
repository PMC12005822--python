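"""Overlap-directed assembly, hybrids, ORF verification, screening tallies."""

from itertools import permutations, product

import numpy as np
import pytest

from scrca.assembly_sim import (
    Recombinant,
    ScreeningTally,
    colony_pcr_length,
    form_hybrids,
    infusion_assemble,
    positivity_rate,
    verify_orf,
)
from scrca.construct_design import DesignConfig, design_block_primers, design_ring
from scrca.rca_sim import Amplicon, AmpliconPool, simulate_rca, size_select
from scrca.seqcore import revcomp


def _one_amplicon(design, n, seed=0):
    pool = simulate_rca(design, 50, repeat_dist={n: 1.0}, p_ss_end=0.0, seed=seed)
    return pool.members[0][0]


class TestInfusionAssemble:
    def test_single_fragment_assembles_in_frame(self, e_design, vector):
        frag = _one_amplicon(e_design, 6)
        result = infusion_assemble([frag], vector)
        assert len(result) == 1
        rec = result.recombinants[0]
        assert rec.reading_frame_ok
        assert rec.n_repeats == 6

    def test_orientation_forced_by_homology(self, e_design, vector):
        """The same dsDNA handed in minus-strand representation yields the
        identical single product (never a reverse-inserted one); a fragment
        without the designed terminal homology yields nothing."""
        frag = _one_amplicon(e_design, 3)
        flipped = Amplicon(
            n_repeats=frag.n_repeats,
            unit_variants=tuple(str(revcomp(u)) for u in reversed(frag.unit_variants)),
            fwd_overlap=str(revcomp(frag.rev_overlap)),
            rev_overlap=str(revcomp(frag.fwd_overlap)),
        )
        assert flipped.sequence == str(revcomp(frag.sequence))
        plus = infusion_assemble([frag], vector)
        minus = infusion_assemble([flipped], vector)
        assert len(plus) == len(minus) == 1
        assert plus.recombinants[0].insert == minus.recombinants[0].insert
        assert plus.recombinants[0].reading_frame_ok
        broken = Amplicon(1, (frag.unit_variants[0],), "A" * 15, "G" * 15)
        failed = infusion_assemble([broken], vector)
        assert len(failed) == 0
        assert failed.diagnostics

    def test_two_fragment_order_forced_by_junction(self, rlp, elp, vector):
        a_design = design_ring(rlp, DesignConfig(), vector)
        b_design = design_ring(elp, DesignConfig(), vector)
        block = design_block_primers(a_design, b_design, vector)
        frag_a = _one_amplicon(block.block_a, 3, seed=1)
        frag_b = _one_amplicon(block.block_b, 3, seed=2)
        res_ab = infusion_assemble([frag_a, frag_b], vector)
        res_ba = infusion_assemble([frag_b, frag_a], vector)
        assert len(res_ab) == len(res_ba) == 1
        assert res_ab.recombinants[0].insert == res_ba.recombinants[0].insert
        rec = res_ab.recombinants[0]
        assert rec.reading_frame_ok
        assert rec.unit_variants[:3] == frag_a.unit_variants
        assert rec.n_repeats == 6

    def test_three_fragments_rejected(self, e_design, vector):
        frag = _one_amplicon(e_design, 1)
        with pytest.raises(ValueError):
            infusion_assemble([frag, frag, frag], vector)

    def test_matches_brute_force_chain_oracle(self, e_design, vector):
        """Assembly succeeds iff some orientation/order chain has full homology."""
        rng = np.random.default_rng(9)
        good = _one_amplicon(e_design, 2)
        bases = "ACGT"
        for trial in range(20):
            # randomly corrupt one terminus (or none)
            fo, ro = good.fwd_overlap, good.rev_overlap
            mode = trial % 4
            if mode == 1:
                fo = "".join(rng.choice(list(bases), len(fo)))
            elif mode == 2:
                ro = "".join(rng.choice(list(bases), len(ro)))
            elif mode == 3:
                fo = str(revcomp(ro))
            frag = Amplicon(good.n_repeats, good.unit_variants, fo, ro)

            def chain_exists(fragments, ov=15):
                up, down = str(vector.upstream_end), str(vector.downstream_end)
                for order in permutations(range(len(fragments))):
                    for flips in product((False, True), repeat=len(fragments)):
                        seqs = [
                            str(revcomp(fragments[i].sequence)) if f else fragments[i].sequence
                            for i, f in zip(order, flips)
                        ]
                        parts = [up, *seqs, down]
                        if all(
                            x[-ov:] == y[:ov] for x, y in zip(parts, parts[1:])
                        ):
                            return True
                return False

            got = bool(infusion_assemble([frag], vector))
            assert got == chain_exists([frag])


class TestVerifyOrf:
    def test_designed_construct_has_both_tags(self, e_design, vector):
        rec = infusion_assemble([_one_amplicon(e_design, 6)], vector).recombinants[0]
        assert rec.tags_found == ("MK", "WPTHHHHHH")
        assert rec.peptide.startswith("MK" + "VGVPG")
        assert rec.peptide.endswith("WPTHHHHHH")

    def test_single_nt_deletion_breaks_frame(self, e_design, vector):
        rec = infusion_assemble([_one_amplicon(e_design, 2)], vector).recombinants[0]
        damaged = Recombinant(
            insert=rec.insert[:10] + rec.insert[11:],
            n_repeats=rec.n_repeats,
            unit_variants=rec.unit_variants,
        )
        assert verify_orf(damaged, vector).reading_frame_ok is False

    def test_empty_insert_vector_self_translation(self, vector):
        rec = verify_orf(Recombinant("", 0, ()), vector)
        assert rec.reading_frame_ok
        assert rec.peptide == "MKWPTHHHHHH"

    def test_colony_pcr_length(self, e_design, vector):
        rec = infusion_assemble([_one_amplicon(e_design, 6)], vector).recombinants[0]
        assert colony_pcr_length(rec, vector) == len(vector.upstream_end) + 540 + len(
            vector.downstream_end
        )


class TestHybrids:
    def test_p_anneal_zero_leaves_pool_unchanged(self, ndt_design):
        pool = simulate_rca(ndt_design, 500, p_ss_end=0.5, seed=1)
        hyb = form_hybrids(pool, p_anneal=0.0, seed=2)
        assert hyb.repeat_histogram() == pool.repeat_histogram()
        assert hyb.total_repeats == pool.total_repeats

    def test_two_parents_give_two_distinct_blocks(self):
        a = Amplicon(2, ("AAATTTGGGCCCAAATTT",) * 2, "G" * 15, "C" * 15,
                     end_state="ss3prime", ss_len=10)
        b = Amplicon(3, ("AAATTTGGGCCCAAATTT",) * 3, "G" * 15, "C" * 15,
                     end_state="ss5prime", ss_len=10)
        # give b a variant differing within mismatch budget
        vb = "AAATTTGGGCCCAATTTT"
        b = Amplicon(3, (vb,) * 3, "G" * 15, "C" * 15, end_state="ss5prime", ss_len=10)
        pool = AmpliconPool(((a, 1), (b, 1)), params={})
        hyb = form_hybrids(pool, p_anneal=1.0, seed=0)
        (child, mult), = hyb.members
        assert child.n_repeats == 5
        assert len(set(child.unit_variants)) == 2
        assert child.end_state == "blunt"

    def test_repeat_count_conserved(self, ndt_design):
        pool = simulate_rca(ndt_design, 2000, p_ss_end=0.6, seed=3)
        hyb = form_hybrids(pool, p_anneal=0.7, seed=4)
        assert hyb.total_repeats == pool.total_repeats

    def test_hybrid_fraction_matches_pairing_oracle(self, ndt_design):
        """Joined-pair count equals a brute-force recount over the same draws."""
        pool = simulate_rca(ndt_design, 1000, p_ss_end=0.5, seed=5)
        n3 = sum(m for a, m in pool if a.end_state == "ss3prime")
        n5 = sum(m for a, m in pool if a.end_state == "ss5prime")
        hyb = form_hybrids(pool, p_anneal=0.5, seed=6)
        n_joined = sum(
            m for a, m in hyb if a.end_state == "blunt"
        ) - sum(m for a, m in pool if a.end_state == "blunt")
        # every join consumes one ss3 + one ss5 molecule
        n3_left = sum(m for a, m in hyb if a.end_state == "ss3prime")
        n5_left = sum(m for a, m in hyb if a.end_state == "ss5prime")
        assert n3 - n3_left == n_joined
        assert n5 - n5_left == n_joined
        assert 0 < n_joined <= min(n3, n5)

    def test_hybrids_enable_assembly_of_incomplete_molecules(self, ndt_design, vector):
        pool = simulate_rca(ndt_design, 400, repeat_dist={3: 1.0}, p_ss_end=1.0, seed=7)
        # incomplete molecules alone never assemble
        some = next(iter(pool.molecules()))
        assert len(infusion_assemble([some], vector)) == 0
        hyb = form_hybrids(pool, p_anneal=1.0, seed=8)
        blunt = [a for a in hyb.molecules() if a.end_state == "blunt"]
        assert blunt
        rec = infusion_assemble([blunt[0]], vector).recombinants[0]
        assert rec.reading_frame_ok
        assert rec.n_repeats == 6


class TestPositivityRate:
    def test_printed_formula_arithmetic(self):
        assert positivity_rate(ScreeningTally((8, 10), (5, 8))) == pytest.approx(50.0)

    def test_all_positive_and_zero(self):
        assert positivity_rate(ScreeningTally((4, 4), (4, 4))) == 100.0
        assert positivity_rate(ScreeningTally((0, 10), (5, 8))) == 0.0

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            ScreeningTally((0, 0), (1, 1))
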