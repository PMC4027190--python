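import math

import numpy as np
import pytest

from polymirts import (
    DifferentialHit,
    PassThresholds,
    Region,
    ScoredPair,
    StringencyThresholds,
    ValidationError,
    first_pass,
    high_stringency_filter,
    run_pipeline,
    second_pass,
)
from polymirts.duplex_engine import EMPTY_ALIGNMENT


def make_pair(score_a=0.0, mfe_a=0.0, score_b=0.0, mfe_b=0.0, rs="rsX", mirna="m"):
    """A ScoredPair with sentinel context/miRNA stand-ins for threshold tests."""

    class _Ctx:
        rs_id = rs
        transcript_id = "T"
        region = Region.CDS
        allele_a_mrna = "A"
        allele_b_mrna = "G"

        def allele_base(self, allele):
            return "A" if allele.upper() == "A" else "G"

    class _Mir:
        name = mirna

    pair = ScoredPair(ctx=_Ctx(), mirna=_Mir())
    if score_a or mfe_a:
        pair.score_a, pair.mfe_a, pair.aln_a = score_a, mfe_a, EMPTY_ALIGNMENT
    if score_b or mfe_b:
        pair.score_b, pair.mfe_b, pair.aln_b = score_b, mfe_b, EMPTY_ALIGNMENT
    return pair


# ---------------------------------------------------------------------------
# first pass
# ---------------------------------------------------------------------------


class TestFirstPass:
    def test_fixed_thresholds(self):
        kept = make_pair(score_a=130, mfe_a=-18)
        dropped = make_pair(score_a=130, mfe_a=-10)
        out = first_pass([kept, dropped], "A", PassThresholds())
        assert out == [kept]

    def test_boundary_inclusive(self):
        boundary = make_pair(score_a=125, mfe_a=-16)
        assert first_pass([boundary], "A") == [boundary]

    def test_all_zero_scores_empty(self):
        pairs = [make_pair() for _ in range(5)]
        assert first_pass(pairs, "A") == []

    def test_empty_input_ok(self):
        assert first_pass([], "A") == []

    def test_percentile_mode_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        pairs = [
            make_pair(score_a=float(rng.integers(0, 250)), mfe_a=float(-rng.uniform(0, 35)))
            for _ in range(100)
        ]
        th = PassThresholds(mode="percentile", percentile=0.2)
        kept = set(map(id, first_pass(pairs, "A", th)))
        # independent recomputation via explicit sorting
        scores = sorted(p.score_a for p in pairs)
        mfes = sorted(p.mfe_a for p in pairs)
        n = len(pairs)
        score_cut = scores[math.ceil((n - 1) * 0.8)]
        mfe_cut = mfes[math.floor((n - 1) * 0.2)]
        want = {
            id(p) for p in pairs if p.score_a >= score_cut and p.mfe_a <= mfe_cut
        }
        assert kept == want


# ---------------------------------------------------------------------------
# second pass
# ---------------------------------------------------------------------------


class TestSecondPass:
    def test_deltas_per_definition(self):
        pair = make_pair(score_a=200, mfe_a=-20, score_b=10, mfe_b=-1)
        (hit,) = second_pass([pair], "B")
        assert hit.delta_score == 190
        assert hit.delta_mfe == -19
        assert hit.targeted_allele_label == "A"

    def test_weak_score_bound_excludes(self):
        pair = make_pair(score_a=200, mfe_a=-20, score_b=80, mfe_b=-1)
        assert second_pass([pair], "B") == []

    def test_weak_boundary_inclusive(self):
        pair = make_pair(score_a=200, mfe_a=-20, score_b=60, mfe_b=-4)
        assert len(second_pass([pair], "B")) == 1

    def test_b_preferred_direction_gain_of_regulation(self):
        """When the variant allele binds tighter the hit is a gain-of-regulation."""
        pair = make_pair(score_a=10, mfe_a=-1, score_b=200, mfe_b=-20)
        survivors = first_pass([pair], "B")
        (hit,) = second_pass(survivors, "A")
        assert hit.targeted_allele_label == "B"
        assert not hit.targeted_is_reference
        assert hit.regulation_class == "gain_of_regulation"
        assert hit.targeted_allele == "G (SNP)"

    def test_allele_swap_antisymmetry(self):
        """Swapping the per-allele scores flips the A/B label but preserves
        |ΔScore| and |ΔMFE|."""
        pair = make_pair(score_a=180, mfe_a=-22, score_b=15, mfe_b=-2)
        swapped = make_pair(score_a=15, mfe_a=-2, score_b=180, mfe_b=-22)
        (h1,) = second_pass(first_pass([pair], "A"), "B")
        (h2,) = second_pass(first_pass([swapped], "B"), "A")
        assert h1.targeted_allele_label == "A" and h2.targeted_allele_label == "B"
        assert abs(h1.delta_score) == abs(h2.delta_score)
        assert abs(h1.delta_mfe) == abs(h2.delta_mfe)
        assert h1.regulation_class != h2.regulation_class


# ---------------------------------------------------------------------------
# high-stringency filter
# ---------------------------------------------------------------------------


def hit_with_deltas(ds, dmfe):
    return DifferentialHit(
        rs_id="rsX", transcript_id="T", region=Region.CDS, mirna="m",
        targeted_allele_label="A", targeted_allele_base="A",
        targeted_is_reference=True, score_pref=0, mfe_pref=0,
        score_other=0, mfe_other=0, delta_score=ds, delta_mfe=dmfe,
    )


class TestHighStringency:
    @pytest.mark.parametrize(
        "ds,dmfe,expected",
        [
            (199, -26.6, True),   # reference worked example: passes both arms
            (141, -22.1, False),  # reference excluded example: passes neither
            (165, -0.5, True),    # inclusive ΔScore boundary
            (100, -25.0, True),   # inclusive ΔMFE boundary
            (164.99, -24.99, False),
        ],
    )
    def test_worked_examples_and_boundaries(self, ds, dmfe, expected):
        assert high_stringency_filter(hit_with_deltas(ds, dmfe)) is expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            StringencyThresholds(delta_score_min=-1)
        with pytest.raises(ValidationError):
            PassThresholds(strong_score_min=50)  # below weak_score_max


# ---------------------------------------------------------------------------
# full pipeline invariants (on the default synthetic scenario)
# ---------------------------------------------------------------------------


class TestPipeline:
    def test_subset_chain(self, default_dataset, default_result):
        """high-stringency hits <= differential candidates <= first-pass survivors."""
        res = default_result
        scored = res.scored_pairs
        for pref, other in (("A", "B"), ("B", "A")):
            survivors = first_pass(scored, pref)
            candidates = second_pass(survivors, other)
            surv_keys = {(p.ctx.rs_id, p.mirna.name) for p in survivors}
            cand_keys = {(h.rs_id, h.mirna) for h in candidates}
            assert cand_keys <= surv_keys
            hs_keys = {
                (h.rs_id, h.mirna) for h in candidates if high_stringency_filter(h)
            }
            assert hs_keys <= cand_keys

    def test_hit_invariants(self, default_result):
        for h in default_result.hits:
            assert h.delta_score >= 0
            assert h.delta_mfe <= 0
            assert (h.regulation_class == "gain_of_regulation") == (
                not h.targeted_is_reference
            )
            if h.high_stringency:
                assert h.delta_score >= 165 or h.delta_mfe <= -25

    def test_deterministic_ordering(self, default_dataset):
        ds = default_dataset
        r1 = run_pipeline(ds.mirnas, ds.transcripts, ds.genome, ds.snps)
        keys = [(h.rs_id, h.mirna) for h in r1.hits]
        assert keys == sorted(keys)

    def test_zero_snps_gives_empty_result(self, default_dataset):
        ds = default_dataset
        res = run_pipeline(ds.mirnas, ds.transcripts, ds.genome, [])
        assert res.hits == []
        assert res.summary["n_hits"] == 0
        assert all(v == 0 for v in res.summary["by_region"].values())
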