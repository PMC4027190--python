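import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polymirts import (
    ConfigurationError,
    EnergyParams,
    MiRNARecord,
    ScoringParams,
    ValidationError,
    align,
    duplex_energy,
    scan_window,
    snp_in_seed,
)
from polymirts.duplex_engine import Column, DuplexAlignment, recompute_score

from oracle import oracle_best_score, oracle_best_snp_paired

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU")) for _ in range(n))


# ---------------------------------------------------------------------------
# align
# ---------------------------------------------------------------------------


class TestAlign:
    def test_perfect_seven_mer_scores_125(self, sparams):
        """7 WC pairs: position 1 at weight 1, positions 2-7 at seed weight 4."""
        m = MiRNARecord("m", "ACGUACG")
        a = align(m, "AA" + rc("ACGUACG") + "AA", sparams)
        assert a.score == 5 * 1 + 5 * 4 * 6 == 125
        assert len(a.pairs) == 7
        assert all(cls == "WC" for _, _, cls in a.pairs)

    def test_no_pairable_bases_gives_empty_alignment(self, sparams):
        a = align(MiRNARecord("m", "AAAAAAA"), "AAAAAAAAAA", sparams)
        assert a.is_empty and a.score == 0

    def test_antiparallel_pair_ordering(self, sparams):
        a = align(MiRNARecord("m", "ACGUACGUAC"), "GG" + rc("ACGUACGUAC") + "GG", sparams)
        mirna_positions = [p for p, _, _ in a.pairs]
        target_positions = [t for _, t, _ in a.pairs]
        assert mirna_positions == sorted(mirna_positions)
        assert target_positions == sorted(target_positions, reverse=True)

    def test_score_matches_column_recomputation(self, sparams):
        rng = np.random.default_rng(3)
        for _ in range(40):
            m = MiRNARecord("m", random_rna(rng, int(rng.integers(8, 16))))
            w = random_rna(rng, int(rng.integers(12, 30)))
            a = align(m, w, sparams)
            if not a.is_empty:
                assert recompute_score(a, sparams) == pytest.approx(a.score)

    def test_deterministic(self, sparams, eparams):
        m = MiRNARecord("m", "ACGUACGUACGUACG")
        w = "GGCAUGCGUACGUACGUACGGCAU"
        a1 = align(m, w, sparams, eparams)
        a2 = align(m, w, sparams, eparams)
        assert a1 == a2

    def test_non_rna_rejected(self, sparams):
        with pytest.raises(ValidationError):
            align(MiRNARecord("m", "ACGU"), "ACGTN", sparams)

    def test_oracle_equivalence_seeded(self, sparams):
        """align() equals brute-force enumeration on random small instances."""
        rng = np.random.default_rng(12345)
        for _ in range(60):
            m = random_rna(rng, int(rng.integers(4, 11)))
            w = random_rna(rng, int(rng.integers(6, 15)))
            got = align(MiRNARecord("m", m), w, sparams).score
            assert got == pytest.approx(oracle_best_score(m, w, sparams)), (m, w)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        m=st.text(alphabet="ACGU", min_size=3, max_size=8),
        w=st.text(alphabet="ACGU", min_size=4, max_size=10),
    )
    def test_oracle_equivalence_property(self, m, w):
        p = ScoringParams()
        assert align(MiRNARecord("m", m), w, p).score == pytest.approx(
            oracle_best_score(m, w, p)
        )

    def test_wc_extension_never_decreases_score(self, sparams):
        """Growing a perfect complement by one WC pair adds a non-negative term."""
        rng = np.random.default_rng(7)
        core = random_rna(rng, 6)
        prev = align(MiRNARecord("m", core), rc(core), sparams).score
        seq = core
        for _ in range(8):
            seq = seq + random_rna(rng, 1)
            score = align(MiRNARecord("m", seq), rc(seq), sparams).score
            assert score >= prev
            prev = score


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------


def _helix_alignment(mirna_seq: str) -> DuplexAlignment:
    """Perfect WC helix alignment for a miRNA against its reverse complement."""
    window = rc(mirna_seq)
    cols = tuple(
        Column(i, len(window) - 1 - i, mirna_seq[i], window[len(window) - 1 - i], "WC")
        for i in range(len(mirna_seq))
    )
    return DuplexAlignment(score=0.0, mfe=math.nan, columns=cols)


class TestEnergy:
    def test_single_pair_is_initiation_only(self, eparams):
        a = DuplexAlignment(score=5.0, mfe=math.nan, columns=(Column(0, 0, "G", "C", "WC"),))
        assert duplex_energy(a, eparams) == pytest.approx(4.09)

    def test_empty_alignment_is_plus_infinity(self, eparams):
        a = DuplexAlignment(score=0.0, mfe=math.nan, columns=())
        assert duplex_energy(a, eparams) == math.inf

    def test_gc_helix_more_stable_than_au_helix(self, eparams):
        gc = duplex_energy(_helix_alignment("GCGCGCGC"), eparams)
        au = duplex_energy(_helix_alignment("AUAUAUAU"), eparams)
        assert gc < au

    def test_seven_mer_helix_matches_hand_sum(self, eparams):
        """Energy equals the manually summed stack entries + initiation."""
        import yaml
        from importlib import resources

        mseq = "GACUGCA"
        a = _helix_alignment(mseq)
        ref = resources.files("polymirts.data").joinpath("stack_energies.yaml")
        with resources.as_file(ref) as path:
            raw = yaml.safe_load(path.read_text())
        stacks = raw["stacks"]

        def lookup(key):
            top, bottom = key.split("/")
            alt = bottom[::-1] + "/" + top[::-1]
            return stacks.get(key, stacks.get(alt))

        expected = raw["duplex_init"]
        wrc = rc(mseq)[::-1]  # partner bases in miRNA order
        for i in range(len(mseq) - 1):
            expected += lookup(f"{mseq[i]}{mseq[i+1]}/{wrc[i]}{wrc[i+1]}")
        assert duplex_energy(a, eparams) == pytest.approx(expected)

    def test_appending_wc_stack_never_raises_energy(self, eparams):
        rng = np.random.default_rng(11)
        seq = random_rna(rng, 3)
        prev = duplex_energy(_helix_alignment(seq), eparams)
        for _ in range(10):
            seq = seq + random_rna(rng, 1)
            e = duplex_energy(_helix_alignment(seq), eparams)
            assert e <= prev
            prev = e

    def test_internal_loop_penalized(self, eparams):
        helix = _helix_alignment("GCGCGC")
        # split the helix with a central mismatch column
        cols = list(helix.columns)
        mm = Column(2, helix.columns[2].tj, "A", "A", "MM")
        split = DuplexAlignment(
            score=0.0, mfe=math.nan,
            columns=tuple(cols[:2] + [mm] + cols[3:]),
        )
        assert duplex_energy(split, eparams) > duplex_energy(helix, eparams)

    def test_missing_stack_entry_raises(self):
        ep = EnergyParams(stacks={"GC/CG": -3.42})
        with pytest.raises(ConfigurationError, match="dinucleotide step"):
            duplex_energy(_helix_alignment("GACUGCA"), ep)


# ---------------------------------------------------------------------------
# scan + seed classification
# ---------------------------------------------------------------------------


class TestScan:
    def _planted(self, seed_pos=5, k=13, mlen=21, rng_seed=5):
        """Window with a planted site; SNP opposite miRNA position seed_pos."""
        rng = np.random.default_rng(rng_seed)
        site = random_rna(rng, k)
        mir = rc(site) + random_rna(rng, mlen - k)
        flank = random_rna(rng, 20)
        flank2 = random_rna(rng, 20)
        window = flank + site + flank2
        offset = len(flank) + k - seed_pos  # target base opposite miRNA seed_pos
        return MiRNARecord("p", mir), window, offset

    def test_planted_site_covers_snp(self, sparams, eparams):
        mir, window, offset = self._planted()
        a = scan_window(mir, window, offset, sparams, eparams)
        assert a is not None and a.covers(offset)
        col = a.column_at_target(offset)
        assert col.kind in ("WC", "GU")

    def test_site_away_from_snp_gives_none_or_weak(self, sparams):
        """A miRNA complementary only to a sub-window far from the SNP cannot
        produce a strong SNP-anchored alignment."""
        rng = np.random.default_rng(9)
        site = random_rna(rng, 10)
        mir = MiRNARecord("m", rc(site))
        window = site + "A" * 30
        offset = len(window) - 1  # SNP far outside the complementary region
        a = scan_window(mir, window, offset, sparams)
        full = align(mir, window, sparams)
        if a is not None:
            assert a.score < full.score
            assert a.covers(offset)

    def test_matches_filtered_oracle(self, sparams):
        """Forced-pair scan equals the brute-force oracle restricted to
        alignments pairing the SNP base."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(60):
            m = random_rna(rng, int(rng.integers(4, 9)))
            w = random_rna(rng, int(rng.integers(6, 13)))
            offset = int(rng.integers(0, len(w)))
            got = scan_window(MiRNARecord("m", m), w, offset, sparams)
            want = oracle_best_snp_paired(m, w, offset, sparams)
            if got is None:
                assert want <= 0, (m, w, offset, want)
            else:
                assert got.score == pytest.approx(want), (m, w, offset)
                checked += 1
        assert checked > 10

    @pytest.mark.parametrize("seed_pos,expected", [(5, True), (12, False)])
    def test_snp_in_seed_classification(self, sparams, eparams, seed_pos, expected):
        mir, window, offset = self._planted(seed_pos=seed_pos)
        a = scan_window(mir, window, offset, sparams, eparams)
        assert a is not None
        assert snp_in_seed(a, offset, sparams) is expected

    def test_snp_opposite_position_1_is_not_seed(self, sparams, eparams):
        mir, window, offset = self._planted(seed_pos=1)
        a = scan_window(mir, window, offset, sparams, eparams)
        assert a is not None
        assert snp_in_seed(a, offset, sparams) is False

    def test_snp_in_seed_outside_span_raises(self, sparams, eparams):
        mir, window, offset = self._planted()
        a = scan_window(mir, window, offset, sparams, eparams)
        with pytest.raises(ValidationError):
            snp_in_seed(a, len(window) - 1, sparams)
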