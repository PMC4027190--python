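"""Two-pass allele-differential selection and high-stringency filtering.

For every (SNP context, miRNA) pair both allele windows are scanned with the
SNP-anchored duplex alignment.  The first pass keeps pairs whose *preferred*
allele binds strongly (Score >= 125 and MFE <= -16 kcal/mol by default); the
second pass keeps, among those, pairs whose *other* allele binds weakly
(Score <= 60 and MFE >= -4 kcal/mol).  Both directions are evaluated, so
either the reference or the variant allele can be the preferred one — a
variant-targeted pair is a gain-of-regulation, a reference-targeted one a
loss-of-regulation.  Candidates are finally marked high-stringency when
ΔScore >= 165 or ΔMFE <= -25 kcal/mol (inclusive), with
ΔScore = Score_preferred - Score_other >= 0 and
ΔMFE = MFE_preferred - MFE_other <= 0.

Thresholds can alternatively be applied in percentile mode (top 20% of the
observed preferred-allele distribution / bottom 20% of the other-allele
distribution), which reproduces the same selection on arbitrarily scaled
score distributions.

An allele with no SNP-encompassing alignment contributes Score 0 and
MFE 0.0 kcal/mol (no duplex formed), keeping the deltas finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .duplex_engine import (
    DuplexAlignment,
    EnergyParams,
    ScoringParams,
    scan_snp,
    snp_in_seed,
)
from .errors import PolymirtsError, ValidationError
from .io_annotations import (
    MiRNARecord,
    Region,
    SNPContext,
    SNPRecord,
    TranscriptAnnotation,
    annotate_consequence,
    build_snp_context,
)

# ---------------------------------------------------------------------------
# Threshold types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PassThresholds:
    """First/second miRanda-pass selection bounds (fixed or percentile mode)."""

    strong_score_min: float = 125.0
    strong_mfe_max: float = -16.0
    weak_score_max: float = 60.0
    weak_mfe_min: float = -4.0
    mode: str = "fixed"
    percentile: float = 0.20

    def __post_init__(self):
        if not self.strong_score_min > self.weak_score_max:
            raise ValidationError("strong_score_min must exceed weak_score_max")
        if not self.strong_mfe_max < self.weak_mfe_min:
            raise ValidationError("strong_mfe_max must be below weak_mfe_min")
        if self.mode not in ("fixed", "percentile"):
            raise ValidationError(f"unknown threshold mode {self.mode!r}")
        if not 0 < self.percentile < 1:
            raise ValidationError("percentile must be in (0, 1)")


@dataclass(frozen=True)
class StringencyThresholds:
    """High-stringency ΔScore/ΔMFE bounds (inclusive, OR-combined)."""

    delta_score_min: float = 165.0
    delta_mfe_max: float = -25.0

    def __post_init__(self):
        if self.delta_score_min <= 0:
            raise ValidationError("delta_score_min must be positive")
        if self.delta_mfe_max >= 0:
            raise ValidationError("delta_mfe_max must be negative")


# ---------------------------------------------------------------------------
# Scored pairs and hits
# ---------------------------------------------------------------------------


@dataclass
class ScoredPair:
    """One (SNP context, miRNA) pair with per-allele scan results.

    A missing alignment (no SNP-encompassing duplex) is recorded as
    score 0 / MFE 0.0 with ``aln`` None.
    """

    ctx: SNPContext
    mirna: MiRNARecord
    score_a: float = 0.0
    mfe_a: float = 0.0
    aln_a: Optional[DuplexAlignment] = None
    score_b: float = 0.0
    mfe_b: float = 0.0
    aln_b: Optional[DuplexAlignment] = None

    def score(self, allele: str) -> float:
        return self.score_a if allele.upper() == "A" else self.score_b

    def mfe(self, allele: str) -> float:
        return self.mfe_a if allele.upper() == "A" else self.mfe_b

    def aln(self, allele: str) -> Optional[DuplexAlignment]:
        return self.aln_a if allele.upper() == "A" else self.aln_b


@dataclass
class DifferentialHit:
    """One allele-differential (SNP, miRNA) candidate with deltas and labels."""

    rs_id: str
    transcript_id: str
    region: Region
    mirna: str
    targeted_allele_label: str  # "A" or "B"
    targeted_allele_base: str  # mRNA-sense base (or "-")
    targeted_is_reference: bool
    score_pref: float
    mfe_pref: float
    score_other: float
    mfe_other: float
    delta_score: float
    delta_mfe: float
    snp_in_seed: Optional[bool] = None
    high_stringency: bool = False
    consequence_label: Optional[str] = None
    consequence_id: Optional[str] = None
    alignment_pref: Optional[DuplexAlignment] = None

    @property
    def regulation_class(self) -> str:
        """gain_of_regulation when the variant (non-reference) allele is targeted."""
        return "loss_of_regulation" if self.targeted_is_reference else "gain_of_regulation"

    @property
    def targeted_allele(self) -> str:
        """Table-style label, e.g. ``G (SNP)`` or ``T (WT)`` (mRNA sense)."""
        tag = "WT" if self.targeted_is_reference else "SNP"
        return f"{self.targeted_allele_base} ({tag})"


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def score_pairs(
    ctxs: Sequence[SNPContext],
    mirnas: Sequence[MiRNARecord],
    sparams: Optional[ScoringParams] = None,
    eparams: Optional[EnergyParams] = None,
    require_paired: bool = True,
) -> list[ScoredPair]:
    """Scan every (context, miRNA) pair on both alleles."""
    sparams = sparams or ScoringParams()
    eparams = eparams or EnergyParams.default()
    out = []
    for ctx in ctxs:
        for mir in mirnas:
            pair = ScoredPair(ctx, mir)
            for allele in "AB":
                aln = scan_snp(mir, ctx, allele, sparams, eparams, require_paired)
                if aln is not None:
                    if allele == "A":
                        pair.score_a, pair.mfe_a, pair.aln_a = aln.score, aln.mfe, aln
                    else:
                        pair.score_b, pair.mfe_b, pair.aln_b = aln.score, aln.mfe, aln
            out.append(pair)
    return out


# ---------------------------------------------------------------------------
# Passes
# ---------------------------------------------------------------------------


def _strong_cutoffs(pairs, allele, th):
    if th.mode == "fixed":
        return th.strong_score_min, th.strong_mfe_max
    scores = [p.score(allele) for p in pairs if p.aln(allele) is not None]
    mfes = [p.mfe(allele) for p in pairs if p.aln(allele) is not None]
    if not scores:
        return np.inf, -np.inf
    score_cut = float(np.quantile(scores, 1 - th.percentile, method="higher"))
    mfe_cut = float(np.quantile(mfes, th.percentile, method="lower"))
    return score_cut, mfe_cut


def _weak_cutoffs(pairs, allele, th):
    if th.mode == "fixed":
        return th.weak_score_max, th.weak_mfe_min
    scores = [p.score(allele) for p in pairs]
    mfes = [p.mfe(allele) for p in pairs]
    if not scores:
        return -np.inf, np.inf
    score_cut = float(np.quantile(scores, th.percentile, method="lower"))
    mfe_cut = float(np.quantile(mfes, 1 - th.percentile, method="higher"))
    return score_cut, mfe_cut


def first_pass(
    pairs: Sequence[ScoredPair],
    allele: str = "A",
    thresholds: Optional[PassThresholds] = None,
) -> list[ScoredPair]:
    """Keep pairs whose ``allele`` binding is strong; drop pairs with no
    SNP-encompassing alignment for that allele."""
    th = thresholds or PassThresholds()
    with_aln = [p for p in pairs if p.aln(allele) is not None]
    score_cut, mfe_cut = _strong_cutoffs(pairs, allele, th)
    return [
        p for p in with_aln if p.score(allele) >= score_cut and p.mfe(allele) <= mfe_cut
    ]


def second_pass(
    survivors: Sequence[ScoredPair],
    allele: str = "B",
    thresholds: Optional[PassThresholds] = None,
) -> list[DifferentialHit]:
    """Among first-pass survivors, keep pairs whose ``allele`` (the other
    allele) binds weakly, and emit DifferentialHit candidates."""
    th = thresholds or PassThresholds()
    pref = "A" if allele.upper() == "B" else "B"
    score_cut, mfe_cut = _weak_cutoffs(survivors, allele, th)
    hits = []
    for p in survivors:
        if p.score(allele) <= score_cut and p.mfe(allele) >= mfe_cut:
            hits.append(_make_hit(p, pref))
    return hits


def _make_hit(pair: ScoredPair, pref: str) -> DifferentialHit:
    other = "B" if pref == "A" else "A"
    ctx = pair.ctx
    return DifferentialHit(
        rs_id=ctx.rs_id,
        transcript_id=ctx.transcript_id,
        region=ctx.region,
        mirna=pair.mirna.name,
        targeted_allele_label=pref,
        targeted_allele_base=ctx.allele_base(pref),
        targeted_is_reference=(pref == "A"),
        score_pref=pair.score(pref),
        mfe_pref=pair.mfe(pref),
        score_other=pair.score(other),
        mfe_other=pair.mfe(other),
        delta_score=pair.score(pref) - pair.score(other),
        delta_mfe=pair.mfe(pref) - pair.mfe(other),
        alignment_pref=pair.aln(pref),
    )


def high_stringency_filter(
    hit: DifferentialHit, st: Optional[StringencyThresholds] = None
) -> bool:
    """True iff ΔScore >= 165 OR ΔMFE <= -25 kcal/mol (inclusive)."""
    st = st or StringencyThresholds()
    return hit.delta_score >= st.delta_score_min or hit.delta_mfe <= st.delta_mfe_max


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    scoring: ScoringParams = field(default_factory=ScoringParams)
    energy: EnergyParams = field(default_factory=EnergyParams.default)
    passes: PassThresholds = field(default_factory=PassThresholds)
    stringency: StringencyThresholds = field(default_factory=StringencyThresholds)
    flank: int = 30
    require_paired: bool = True
    high_stringency_only: bool = False


@dataclass
class PipelineResult:
    hits: list[DifferentialHit]
    summary: dict
    scored_pairs: list[ScoredPair] = field(default_factory=list)


def build_contexts(
    snps: Sequence[SNPRecord],
    transcripts: Sequence[TranscriptAnnotation],
    genome: Mapping[str, str],
    flank: int = 30,
) -> list[SNPContext]:
    """One context per exonic (SNP, transcript) combination."""
    out = []
    for snp in snps:
        for tx in transcripts:
            try:
                ctx = build_snp_context(snp, tx, genome, flank)
            except PolymirtsError as exc:
                raise type(exc)(f"[{snp.rs_id} x {tx.transcript_id}] {exc}") from exc
            if ctx is not None:
                out.append(ctx)
    return out


def run_pipeline(
    mirnas: Sequence[MiRNARecord],
    transcripts: Sequence[TranscriptAnnotation],
    genome: Mapping[str, str],
    snps: Sequence[SNPRecord],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Full scan: contexts -> per-allele duplex scans -> two passes in both
    allele directions -> stringency, seed-overlap and consequence annotation.

    Output ordering is deterministic: (rs_id, miRNA name, targeted allele).
    """
    cfg = config or PipelineConfig()
    ctxs = build_contexts(snps, transcripts, genome, cfg.flank)
    scored = score_pairs(ctxs, mirnas, cfg.scoring, cfg.energy, cfg.require_paired)

    # transcript CDS sequences for consequence annotation
    cds_cache: dict[str, str] = {}
    for tx in transcripts:
        span = tx.cds_span_transcript()
        if span is not None:
            seq = tx.transcript_sequence(genome)
            cds_cache[tx.transcript_id] = seq[span[0] : span[1]]

    hits: list[DifferentialHit] = []
    funnel = {}
    for pref, other in (("A", "B"), ("B", "A")):
        survivors = first_pass(scored, pref, cfg.passes)
        candidates = second_pass(survivors, other, cfg.passes)
        funnel[f"first_pass_{pref}_preferred"] = len(survivors)
        funnel[f"candidates_{pref}_preferred"] = len(candidates)
        hits.extend(candidates)

    for hit in hits:
        hit.high_stringency = high_stringency_filter(hit, cfg.stringency)
        ctx = next(
            c for c in ctxs if c.rs_id == hit.rs_id and c.transcript_id == hit.transcript_id
        )
        if hit.alignment_pref is not None:
            hit.snp_in_seed = snp_in_seed(
                hit.alignment_pref,
                ctx.snp_offset(hit.targeted_allele_label),
                cfg.scoring,
            )
        cds = cds_cache.get(hit.transcript_id)
        if cds is not None or ctx.region is not Region.CDS:
            cons = annotate_consequence(ctx, cds or "")
            hit.consequence_label = cons.label
            hit.consequence_id = cons.ident

    if cfg.high_stringency_only:
        hits = [h for h in hits if h.high_stringency]
    hits.sort(key=lambda h: (h.rs_id, h.mirna, h.targeted_allele_label))

    summary = summarize(hits)
    summary["funnel"] = {
        "snps": len(snps),
        "contexts": len(ctxs),
        "mirnas": len(mirnas),
        "scored_pairs": len(scored),
        **funnel,
        "differential_candidates": len(hits),
        "high_stringency": sum(1 for h in hits if h.high_stringency),
    }
    return PipelineResult(hits=hits, summary=summary, scored_pairs=scored)


def summarize(hits: Sequence[DifferentialHit]) -> dict:
    """Per-region / per-regulation-class tallies and per-SNP miRNA multiplicity."""
    by_region = {r.value: 0 for r in Region}
    by_class = {"gain_of_regulation": 0, "loss_of_regulation": 0}
    multiplicity: dict[str, int] = {}
    seed_hits = 0
    for h in hits:
        by_region[h.region.value] += 1
        by_class[h.regulation_class] += 1
        multiplicity[h.rs_id] = multiplicity.get(h.rs_id, 0) + 1
        if h.snp_in_seed:
            seed_hits += 1
    total = len(hits)
    fractions = {
        k: (v / total if total else 0.0) for k, v in by_region.items()
    }
    return {
        "n_hits": total,
        "by_region": by_region,
        "region_fractions": fractions,
        "by_regulation_class": by_class,
        "snp_in_seed_hits": seed_hits,
        "mirnas_per_snp": dict(sorted(multiplicity.items())),
    }
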