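"""Terminal-unit extraction, counting, classification, concordance, PFMs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scrca.fixtures import FixtureSpec, make_read_records
from scrca.library_stats import LibraryDesign, enumerate_library
from scrca.repeat_reads import (
    ExtractConfig,
    Flanks,
    ReadRecord,
    classify_unit,
    count_units,
    end_concordance,
    extract_all,
    extract_terminal_units,
    frequency_matrix,
)
from scrca.seqcore import expand_degenerate, revcomp


@pytest.fixture(scope="module")
def lib(ndt_design):
    return LibraryDesign.from_ring(ndt_design)


@pytest.fixture(scope="module")
def flanks(ndt_design):
    return Flanks(str(ndt_design.fwd_overlap), str(ndt_design.rev_overlap))


def _read(lib, flanks, variant, n_units=5):
    return flanks.five_prime + variant * n_units + flanks.three_prime


class TestExtraction:
    def test_planted_variant_recovered_at_both_ends(self, lib, flanks):
        v = enumerate_library(lib)["dna"].iloc[100]
        u5, u3 = extract_terminal_units(_read(lib, flanks, v), lib, flanks)
        assert u5 == v and u3 == v

    def test_reverse_complemented_read_gives_same_result(self, lib, flanks):
        v = enumerate_library(lib)["dna"].iloc[7]
        read = _read(lib, flanks, v)
        assert extract_terminal_units(read, lib, flanks) == extract_terminal_units(
            str(revcomp(read)), lib, flanks
        )

    def test_one_flank_mismatch_tolerated_two_rejected(self, lib, flanks):
        v = enumerate_library(lib)["dna"].iloc[3]
        read = _read(lib, flanks, v)
        one = "T" + read[1:]
        assert read[0] != "T"
        assert extract_terminal_units(one, lib, flanks)[0] == v
        corrupted = list(read)
        corrupted[0] = "T" if read[0] != "T" else "A"
        corrupted[2] = "G" if read[2] != "G" else "A"
        # both ends' flanks broken beyond budget -> unanchored
        tail = len(read) - len(flanks.three_prime)
        corrupted[tail] = "A" if read[tail] != "A" else "C"
        corrupted[tail + 2] = "C" if read[tail + 2] != "C" else "G"
        assert extract_terminal_units("".join(corrupted), lib, flanks) == (None, None)

    def test_truncated_side_reported_none(self, lib, flanks):
        v = enumerate_library(lib)["dna"].iloc[9]
        read = flanks.five_prime + v  # no 3' flank at all
        u5, u3 = extract_terminal_units(read, lib, flanks)
        assert u5 == v and u3 is None


class TestCounting:
    def test_single_variant_tally(self, lib):
        v = enumerate_library(lib)["dna"].iloc[0]
        t = count_units([(v, v)] * 10, lib, min_count=6)
        assert len(t.table) == 1
        row = t.table.iloc[0]
        assert (row["count5"], row["count3"]) == (10, 10)
        assert row["class"] == "mutant"

    def test_low_count_variant_dropped_and_reported(self, lib):
        vs = enumerate_library(lib)["dna"].head(2).tolist()
        pairs = [(vs[0], vs[0])] * 10 + [(vs[1], vs[1])] * 5
        t = count_units(pairs, lib, min_count=6)
        assert len(t.table) == 1
        assert len(t.dropped) == 1
        assert t.dropped.iloc[0]["variant"] == vs[1]

    def test_order_invariant(self, lib):
        rng = np.random.default_rng(0)
        vs = enumerate_library(lib)["dna"].head(5).tolist()
        pairs = [(v, v) for v in vs for _ in range(8)]
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        a = count_units(pairs, lib, min_count=6).table
        b = count_units(shuffled, lib, min_count=6).table
        pd.testing.assert_frame_equal(a, b)


class TestClassification:
    def test_every_library_member_is_mutant(self, lib):
        for v in expand_degenerate(lib.dna, cap=2000)[::97]:
            assert classify_unit(v, lib) == "mutant"

    def test_backbone_substitution_is_error(self, lib):
        v = enumerate_library(lib)["dna"].iloc[0]
        fixed = [i for i in range(len(v)) if i not in lib.degenerate_nt_positions]
        i = fixed[5]
        bad = v[:i] + ("A" if v[i] != "A" else "G") + v[i + 1 :]
        assert classify_unit(bad, lib) == "error"

    def test_base_outside_iupac_set_at_degenerate_position_is_error(self, lib):
        v = enumerate_library(lib)["dna"].iloc[0]
        # find a D site (allows A/G/T, not C)
        d_sites = [i for i in lib.degenerate_nt_positions if str(lib.dna)[i] == "D"]
        i = d_sites[0]
        bad = v[:i] + "C" + v[i + 1 :]
        assert classify_unit(bad, lib) == "error"

    def test_length_variant_is_error(self, lib):
        v = enumerate_library(lib)["dna"].iloc[0]
        assert classify_unit(v[:-1], lib) == "error"


class TestConcordance:
    def test_identical_vectors_give_one(self, lib):
        vs = enumerate_library(lib)["dna"].head(4).tolist()
        t = count_units([(v, v) for v in vs for _ in range(10 + 2 * vs.index(v))], lib, 6)
        assert end_concordance(t) == pytest.approx(1.0)

    def test_error_free_processive_pool_gives_one(self, lib, flanks):
        rng = np.random.default_rng(1)
        vs = enumerate_library(lib)["dna"].sample(8, random_state=2).tolist()
        spec = FixtureSpec(
            variants=tuple(vs),
            abundances=tuple([1 / 8] * 8),
            flank5=flanks.five_prime,
            flank3=flanks.three_prime,
            n_reads=2000,
            sub_rate=0.0,
            seed=3,
        )
        reads, _, _ = make_read_records(spec)
        t = count_units(extract_all(reads, lib, flanks), lib, min_count=6)
        assert end_concordance(t) == pytest.approx(1.0)

    def test_anti_ordered_counts_match_pearson_oracle(self, lib):
        vs = enumerate_library(lib)["dna"].head(4).tolist()
        rows = list(zip(vs, [10, 20, 30, 40], [40, 30, 20, 10]))
        pairs = []
        for v, c5, c3 in rows:
            pairs += [(v, None)] * c5 + [(None, v)] * c3
        t = count_units(pairs, lib, min_count=6)
        r = end_concordance(t)
        x = t.table["count5"].to_numpy(float)
        y = t.table["count3"].to_numpy(float)
        oracle = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert r == pytest.approx(oracle)
        assert r < 0

    def test_zero_variance_undefined(self, lib):
        vs = enumerate_library(lib)["dna"].head(3).tolist()
        t = count_units([(v, v) for v in vs for _ in range(7)], lib, 6)
        with pytest.warns(UserWarning):
            assert np.isnan(end_concordance(t))


class TestFrequencyMatrix:
    def test_identical_units_one_hot(self):
        pfm = frequency_matrix(["ACGT", "ACGT"], "dna")
        assert (pfm.freqs.max(axis=1) == 1.0).all()
        assert pfm.freqs.loc[0, "A"] == 1.0

    def test_rows_sum_to_one(self, lib):
        seqs = enumerate_library(lib)["dna"].head(50).tolist()
        pfm = frequency_matrix(seqs, "dna", design=lib)
        assert np.allclose(pfm.freqs.sum(axis=1), 1.0)
        assert pfm.flagged == lib.degenerate_nt_positions

    def test_uniform_ndt_draw_approaches_expected_columns(self):
        rng = np.random.default_rng(5)
        codons = expand_degenerate("NDT")
        draws = [str(codons[i]) for i in rng.integers(0, 12, size=6000)]
        pfm = frequency_matrix(draws, "dna")
        np.testing.assert_allclose(
            pfm.freqs.loc[0].to_numpy(), [0.25] * 4, atol=0.03
        )
        assert pfm.freqs.loc[1, "C"] == 0.0
        np.testing.assert_allclose(
            pfm.freqs.loc[1, ["A", "G", "T"]].to_numpy(), [1 / 3] * 3, atol=0.03
        )
        assert pfm.freqs.loc[2, "T"] == 1.0

    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValueError):
            frequency_matrix(["ACG", "ACGT"], "dna")


class TestStrandSymmetry:
    def test_reverse_complementing_all_reads_preserves_outputs(self, lib, flanks):
        vs = enumerate_library(lib)["dna"].sample(6, random_state=7).tolist()
        spec = FixtureSpec(
            variants=tuple(vs),
            abundances=tuple([1 / 6] * 6),
            flank5=flanks.five_prime,
            flank3=flanks.three_prime,
            n_reads=1500,
            sub_rate=0.003,
            seed=8,
        )
        reads, _, _ = make_read_records(spec)
        flipped = [ReadRecord(r.id, str(revcomp(r.bases))) for r in reads]
        t1 = count_units(extract_all(reads, lib, flanks), lib, 6)
        t2 = count_units(extract_all(flipped, lib, flanks), lib, 6)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        assert end_concordance(t1) == pytest.approx(end_concordance(t2))


class TestErrorRateRecovery:
    def test_planted_substitution_rate_recovered(self, lib, flanks):
        """Error-class fraction among extracted units matches the closed-form
        per-unit error probability within 20% relative."""
        rate = 0.005
        vs = enumerate_library(lib)["dna"].sample(4, random_state=9).tolist()
        spec = FixtureSpec(
            variants=tuple(vs),
            abundances=(0.4, 0.3, 0.2, 0.1),
            flank5=flanks.five_prime,
            flank3=flanks.three_prime,
            n_reads=12_000,
            sub_rate=rate,
            seed=10,
        )
        reads, _, _ = make_read_records(spec)
        ext = extract_all(reads, lib, flanks)
        units = [u for col in ("unit5", "unit3") for u in ext[col] if u]
        classes = np.array([classify_unit(u, lib) for u in units])
        recovered = (classes == "error").mean()
        # oracle: a unit misclassifies unless every fixed position is intact
        # and every degenerate-site substitution stays inside its IUPAC set.
        template = str(lib.dna)
        p_ok = 1.0
        for c in template:
            if c in "ACGT":
                p_ok *= 1 - rate
            elif c == "N":
                p_ok *= 1.0
            elif c == "D":
                p_ok *= 1 - rate / 3
        expected = 1 - p_ok
        assert recovered == pytest.approx(expected, rel=0.2)
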