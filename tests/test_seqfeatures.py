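"""Sequence I/O, composition, net charge / pI, and redundancy removal."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virionnet.seqfeatures import (
    AMINO_ACIDS,
    BJELLQVIST_PKA,
    EMBOSS_PKA,
    FeatureVector,
    SequenceError,
    SequenceRecord,
    aa_composition,
    clean_sequence,
    dedup_90,
    featurize,
    featurize_records,
    isoelectric_point,
    net_charge,
    pairwise_identity,
    read_fasta,
    read_feature_tsv,
    write_fasta,
    write_feature_tsv,
)

protein = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


# ---------------------------------------------------------------------------
# FASTA

class TestFasta:
    def test_parse_header_and_residues(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1 major capsid protein\nMKV\n")
        (rec,) = read_fasta(p)
        assert rec == SequenceRecord(id="p1", description="major capsid protein", residues="MKV")

    def test_two_entries_preserve_order(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a first\nMK\n>b second\nVV\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]

    def test_round_trip_is_lossless(self, tmp_path):
        recs = [
            SequenceRecord("x1", "tail fiber", "MKVLA" * 20),
            SequenceRecord("x2", "", "ACDEFGHIKLMNPQRSTVWY"),
        ]
        p = tmp_path / "rt.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in recs]

    def test_headerless_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("MKVLA\nMKVLA\n")
        with pytest.raises(SequenceError, match="line 1"):
            read_fasta(p)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.warns(UserWarning):
            assert read_fasta(p) == []


# ---------------------------------------------------------------------------
# Cleaning

class TestCleanSequence:
    @pytest.mark.parametrize(
        "raw,expected",
        [("MK*V", "MKV"), ("MXK", "MK"), ("mkv", "MKV"), ("M-K.V", "MKV")],
    )
    def test_drop_policy(self, raw, expected):
        assert clean_sequence(raw, "drop-residue") == expected

    def test_reject_names_position(self):
        with pytest.raises(SequenceError, match="position 2"):
            clean_sequence("MXK", "reject")

    @pytest.mark.parametrize("raw", ["", "***", "XXX"])
    def test_empty_results_are_errors(self, raw):
        with pytest.raises(SequenceError):
            clean_sequence(raw)


# ---------------------------------------------------------------------------
# Composition

class TestComposition:
    def test_single_residue_sequence(self):
        comp = aa_composition("AAAA")
        assert comp[0] == 100.0 and comp[1:].sum() == 0.0

    def test_uniform_sequence(self):
        assert np.allclose(aa_composition(AMINO_ACIDS), 5.0)

    def test_counts_match_brute_force(self):
        comp = aa_composition("MKKLV")
        expected = {aa: 100.0 * "MKKLV".count(aa) / 5 for aa in AMINO_ACIDS}
        assert comp == pytest.approx([expected[aa] for aa in AMINO_ACIDS])

    @settings(max_examples=50, derandomize=True)
    @given(protein)
    def test_sums_to_100_and_order_invariant(self, seq):
        comp = aa_composition(seq)
        assert abs(comp.sum() - 100.0) < 1e-9
        assert np.allclose(comp, aa_composition(seq[::-1]))

    def test_empty_is_an_error(self):
        with pytest.raises(SequenceError):
            aa_composition("")


# ---------------------------------------------------------------------------
# Net charge and pI

class TestNetCharge:
    def test_low_ph_limit_is_plus_one(self):
        assert net_charge("GG", 0.0) == pytest.approx(1.0, abs=5e-3)

    def test_high_ph_limit_is_minus_one(self):
        assert net_charge("GG", 14.0) == pytest.approx(-1.0, abs=5e-3)

    @settings(max_examples=30, derandomize=True)
    @given(protein)
    def test_matches_per_group_summation_oracle(self, seq):
        for ph in (2.0, 7.0, 11.5):
            expected = 0.0
            for aa, pka in [("K", 10.8), ("R", 12.5), ("H", 6.5)]:
                expected += seq.count(aa) / (1 + 10 ** (ph - pka))
            expected += 1 / (1 + 10 ** (ph - 8.6))
            for aa, pka in [("D", 3.9), ("E", 4.1), ("C", 8.5), ("Y", 10.1)]:
                expected -= seq.count(aa) / (1 + 10 ** (pka - ph))
            expected -= 1 / (1 + 10 ** (3.6 - ph))
            assert net_charge(seq, ph, EMBOSS_PKA) == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=30, derandomize=True)
    @given(protein)
    def test_strictly_decreasing_in_ph(self, seq):
        grid = np.linspace(0, 14, 30)
        charges = [net_charge(seq, ph) for ph in grid]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_ph_out_of_range(self):
        with pytest.raises(ValueError):
            net_charge("GG", -0.1)


def grid_scan_pi(seq, table, step=5e-4):
    """Independent oracle: first pH (on a fine grid) where charge <= 0."""
    grid = np.arange(0.0, 14.0 + step, step)
    basic = [(seq.count(aa), table.side[aa]) for aa in ("K", "R", "H")] + [(1, table.nterm)]
    acidic = [(seq.count(aa), table.side[aa]) for aa in ("D", "E", "C", "Y")] + [(1, table.cterm)]
    charge = np.zeros_like(grid)
    for n, pka in basic:
        charge += n / (1 + 10 ** (grid - pka))
    for n, pka in acidic:
        charge -= n / (1 + 10 ** (pka - grid))
    crossing = np.argmax(charge <= 0)
    return grid[crossing]


class TestIsoelectricPoint:
    @pytest.mark.parametrize("table", [EMBOSS_PKA, BJELLQVIST_PKA], ids=lambda t: t.name)
    def test_gg_is_midpoint_of_terminal_pkas(self, table):
        expected = (table.nterm + table.cterm) / 2
        assert isoelectric_point("GG", table) == pytest.approx(expected, abs=2e-3)

    def test_monotone_in_basic_and_acidic_content(self):
        assert isoelectric_point("KKKKK") > isoelectric_point("GGGGG") > isoelectric_point("DDDDD")

    def test_adding_lysine_never_lowers_adding_aspartate_never_raises(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=30))
            base = isoelectric_point(seq)
            assert isoelectric_point(seq + "K") >= base - 2e-3
            assert isoelectric_point(seq + "D") <= base + 2e-3

    def test_bisection_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(42)
        tol = 1e-3
        for _ in range(200):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(5, 80)))
            assert isoelectric_point(seq, EMBOSS_PKA, tol) == pytest.approx(
                grid_scan_pi(seq, EMBOSS_PKA), abs=2 * tol
            )


# ---------------------------------------------------------------------------
# Featurization

class TestFeaturize:
    def test_composition_only_is_20_dim(self):
        v = featurize(SequenceRecord("s", residues="AAAA"))
        assert v.values.shape == (20,) and v.composition[0] == 100.0

    def test_pi_appended_as_21st_feature(self):
        v = featurize(SequenceRecord("s", residues="AAAA"), include_pi=True)
        assert v.values.shape == (21,)
        assert v.values[-1] == pytest.approx(isoelectric_point("AAAA"))

    def test_batch_preserves_order(self):
        recs = [SequenceRecord(f"s{i}", residues="MKV" * (i + 1)) for i in range(5)]
        vecs = featurize_records(recs)
        assert [v.id for v in vecs] == [r.id for r in recs]

    def test_feature_tsv_round_trip(self, tmp_path):
        recs = [SequenceRecord(f"s{i}", residues="MKVLADE" * 3) for i in range(3)]
        vecs = featurize_records(recs, include_pi=True, label=1)
        p = tmp_path / "feat.tsv"
        write_feature_tsv(vecs, p)
        back = read_feature_tsv(p)
        for a, b in zip(vecs, back):
            assert a.id == b.id and a.label == b.label
            assert np.allclose(a.values, b.values)

    def test_invalid_vectors_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(composition=np.full(20, 1.0))  # sums to 20, not 100
        comp = np.zeros(20)
        comp[0] = 100.0
        with pytest.raises(ValueError):
            FeatureVector(composition=comp, label=0)


# ---------------------------------------------------------------------------
# Redundancy removal

def lcs_length(a: str, b: str) -> int:
    """Independent dynamic-programming oracle for maximal match count."""
    dp = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
    for i, ca in enumerate(a, 1):
        for j, cb in enumerate(b, 1):
            dp[i, j] = max(dp[i - 1, j], dp[i, j - 1], dp[i - 1, j - 1] + (ca == cb))
    return int(dp[len(a), len(b)])


class TestDedup:
    def test_identical_sequences_collapse(self):
        recs = [SequenceRecord("a", residues="MKVLA" * 10), SequenceRecord("b", residues="MKVLA" * 10)]
        assert [r.id for r in dedup_90(recs)] == ["a"]

    def test_disjoint_sequences_both_retained(self):
        recs = [SequenceRecord("a", residues="MKMKMKMKMK"), SequenceRecord("b", residues="WCWCWCWCWC")]
        assert len(dedup_90(recs)) == 2

    def test_exact_90_percent_pair_is_grouped(self):
        # 9 matching columns out of 10: identity exactly 0.9, inclusive
        a = SequenceRecord("a", residues="ACDEFGHIKL")
        b = SequenceRecord("b", residues="ACDEFGHIKW")
        assert pairwise_identity(a.residues, b.residues) == pytest.approx(0.9)
        assert len(dedup_90([a, b])) == 1

    def test_below_threshold_pair_is_kept(self):
        a = SequenceRecord("a", residues="ACDEFGHIKL")
        b = SequenceRecord("b", residues="ACDEFGHWYW")  # 7/10
        assert len(dedup_90([a, b])) == 2

    def test_alignment_match_count_equals_dp_oracle(self):
        rng = np.random.default_rng(7)
        from virionnet.seqfeatures import _make_aligner

        aligner = _make_aligner()
        for _ in range(30):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 15)))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 15)))
            alignment = aligner.align(a, b)[0]
            assert alignment.counts().identities == lcs_length(a, b)

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        recs = [
            SequenceRecord(f"s{i}", residues="".join(rng.choice(list(AMINO_ACIDS), size=30)))
            for i in range(12)
        ]
        recs += [SequenceRecord(f"d{i}", residues=recs[i].residues) for i in range(4)]
        once = dedup_90(recs)
        assert [r.id for r in dedup_90(once)] == [r.id for r in once]
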