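"""Synthetic genomes, transcripts, SNPs and miRNA populations with ground truth.

The generator emulates the shape of the genome-scale inputs (genome FASTA,
refFlat transcript annotation, SNP table, mature-miRNA FASTA) at desk scale:
random multi-exon transcripts on both strands with annotated 5'UTR/CDS/3'UTR
structure, SNPs placed in every region, and a miRNA population consisting of
*planted* allele-specific binders plus non-binding decoys.

A planted miRNA is the reverse complement of a site centred on one allele of
its SNP (miRNA positions 1..k complementary, k=15 by default), so the targeted
allele carries a perfect seed while the other allele breaks the duplex at the
chosen miRNA position (position 5, inside the seed, by default; position 12
with ``planted_outside_seed``).  Each planted pair is verified against the
actual scan-and-threshold machinery at generation time and re-drawn until the
targeted allele passes the strong criteria, the other allele the weak
criteria, and the high-stringency delta is met; generation fails after a
bounded number of retries.  Decoys are random sequences with no >= 6-nt
Watson-Crick complementary run to any SNP window, which keeps them below any
seed-anchored selection threshold.

Everything is driven by one seeded RNG: the same config yields byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .differential_pipeline import PassThresholds, StringencyThresholds
from .duplex_engine import EnergyParams, ScoringParams, pair_class, scan_window
from .errors import GenerationError, ValidationError
from .io_annotations import (
    MiRNARecord,
    Region,
    SNPRecord,
    TranscriptAnnotation,
    revcomp_dna,
    write_genome,
    write_mirnas,
    write_refflat,
    write_snps,
)

_RNA = "ACGU"
_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}

# weak-allele choices that can neither WC- nor wobble-pair the miRNA base
# opposite the SNP (keyed by the strong target base)
_SAFE_WEAK = {"A": "CU", "C": "AG", "G": "AU", "U": "ACG"}

# site alphabet keyed by the weak base: bases whose complementary miRNA
# position cannot pair the weak allele.  Drawing the whole site (and the
# miRNA tail) from this alphabet leaves the weak allele with no pairable
# partner anywhere in the planted miRNA, so no bulged "bridge" alignment can
# rescue its score: the site is specific to exactly one allele.
_SITE_ALPHABET = {"A": "CGU", "C": "AGU", "G": "CU", "U": "AG"}


def _rc_rna(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_transcripts: int = 3
    utr5_len: int = 60
    cds_len: int = 300
    utr3_len: int = 90
    n_snps_per_region: int = 2
    n_planted_targets: int = 1
    n_decoy_mirnas: int = 50
    planted_seed_position: int = 5
    planted_outside_seed: bool = False
    planted_complement_len: int = 15
    planted_synonymous: bool = False
    mirna_len: int = 21
    gc_content: float = 0.5
    flank: int = 30
    intron_len: int = 50
    pad_len: int = 25
    rng_seed: int = 42
    max_retries: int = 80

    def __post_init__(self):
        if self.cds_len % 3:
            raise ValidationError("cds_len must be a multiple of 3")
        if not 1 <= self.planted_complement_len <= self.mirna_len:
            raise ValidationError("planted_complement_len out of range")
        seed_pos = 12 if self.planted_outside_seed else self.planted_seed_position
        if not 1 <= seed_pos <= self.planted_complement_len:
            raise ValidationError("planted seed position outside the complementary run")
        if not 0 < self.gc_content < 1:
            raise ValidationError("gc_content must be in (0, 1)")
        for name in ("n_transcripts", "n_snps_per_region", "n_planted_targets",
                     "n_decoy_mirnas"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_transcripts == 0 and self.n_planted_targets > 0:
            raise ValidationError("planted targets require at least one transcript")

    @property
    def effective_seed_position(self) -> int:
        return 12 if self.planted_outside_seed else self.planted_seed_position


@dataclass(frozen=True)
class PlantedTarget:
    rs_id: str
    mirna_name: str
    targeted_allele_base: str  # mRNA sense
    targeted_is_reference: bool
    snp_in_seed: bool


@dataclass(frozen=True)
class GroundTruth:
    entries: tuple[PlantedTarget, ...]

    def to_json(self) -> str:
        return json.dumps(
            {"entries": [asdict(e) for e in self.entries]}, indent=2, sort_keys=True
        )


@dataclass
class SyntheticDataset:
    genome: dict
    transcripts: list[TranscriptAnnotation]
    snps: list[SNPRecord]
    mirnas: list[MiRNARecord]
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, outdir) -> dict:
        """Write the five standard outputs; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "refflat": outdir / "refflat.txt",
            "snps": outdir / "snps.tsv",
            "mirnas": outdir / "mirnas.fa",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_genome(self.genome, paths["genome"])
        write_refflat(self.transcripts, paths["refflat"])
        write_snps(self.snps, paths["snps"])
        write_mirnas(self.mirnas, paths["mirnas"])
        paths["ground_truth"].write_text(self.truth.to_json() + "\n")
        return paths


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _random_rna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return "".join(rng.choice(list("ACGU"), size=n, p=p))


class _TranscriptPlan:
    """Mutable mRNA being assembled, with SNP bookkeeping."""

    def __init__(self, idx: int, cfg: SyntheticConfig, rng: np.random.Generator):
        self.idx = idx
        self.cfg = cfg
        self.strand = "+" if idx % 2 == 0 else "-"
        n = cfg.utr5_len + cfg.cds_len + cfg.utr3_len
        self.mrna = list(_random_rna(rng, n, cfg.gc_content))
        # canonical start/stop codons for realism
        self.mrna[cfg.utr5_len : cfg.utr5_len + 3] = "AUG"
        self.mrna[cfg.utr5_len + cfg.cds_len - 3 : cfg.utr5_len + cfg.cds_len] = "UAA"
        self.snp_positions: list[int] = []
        self.exclusions: list[tuple[int, int]] = []  # closed intervals, no new SNPs

    @property
    def length(self) -> int:
        return len(self.mrna)

    def region_bounds(self, region: Region) -> tuple[int, int]:
        c = self.cfg
        if region is Region.FIVE_UTR:
            return 0, c.utr5_len
        if region is Region.CDS:
            return c.utr5_len, c.utr5_len + c.cds_len
        return c.utr5_len + c.cds_len, self.length

    def position_free(self, pos: int) -> bool:
        if pos in self.snp_positions:
            return False
        return not any(lo <= pos <= hi for lo, hi in self.exclusions)


def _plant_target(
    plan: _TranscriptPlan,
    target_idx: int,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    sparams: ScoringParams,
    eparams: EnergyParams,
    passes: PassThresholds,
    stringency: StringencyThresholds,
):
    """Engineer one allele-specific site into the transcript; returns
    (tpos, ref_base, alt_base, mirna, targeted_is_reference)."""
    s = cfg.effective_seed_position
    k = cfg.planted_complement_len
    region = Region.CDS  # the screen's dominant compartment
    lo, hi = plan.region_bounds(region)
    targeted_is_reference = target_idx % 2 == 1

    for _ in range(cfg.max_retries):
        # choose the SNP position so the complementary run fits inside the CDS
        # (site spans transcript positions [tpos+s-k, tpos+s-1])
        tlo = max(lo + 3, lo + k - s)  # keep off the start codon
        thi = hi - 3 - s  # keep off the stop codon
        if thi <= tlo:
            raise GenerationError("CDS too short for the planted site")
        tpos = int(rng.integers(tlo, thi))
        if cfg.planted_synonymous:
            # third codon position of a four-fold degenerate glycine codon
            tpos = cfg.utr5_len + ((tpos - cfg.utr5_len) // 3) * 3 + 2
            if not tlo <= tpos < thi:
                continue
        p_end = tpos + s - 1
        p_start = p_end - k + 1
        if plan.snp_positions and any(
            not plan.position_free(q) for q in range(p_start, p_end + 1)
        ):
            continue

        if cfg.planted_synonymous:
            strong, weak = "C", "A"  # GGC -> GGA, both glycine
        else:
            strong = str(rng.choice(list("ACGU")))
            weak = str(rng.choice(list(_SAFE_WEAK[strong])))

        # site drawn from the weak-allele-incompatible alphabet, SNP codon
        # imposed afterwards ('G' is in the alphabet for weak 'A')
        alpha = list(_SITE_ALPHABET[weak])
        site = [str(b) for b in rng.choice(alpha, size=k)]
        plan.mrna[p_start : p_end + 1] = site
        if cfg.planted_synonymous:
            plan.mrna[tpos - 2 : tpos] = "GG"
        plan.mrna[tpos] = strong if targeted_is_reference else weak
        ref_base = plan.mrna[tpos]
        alt_base = weak if targeted_is_reference else strong

        # strong-allele site sequence and the complementary miRNA; the tail is
        # likewise unable to pair the weak allele, and its first base must not
        # extend the helix past the site
        window_site = plan.mrna[p_start : p_end + 1]
        window_site[tpos - p_start] = strong
        tail_alpha = [y for y in "ACGU" if pair_class(y, weak) is None]

        def draw_tail() -> str:
            return "".join(str(b) for b in rng.choice(tail_alpha, size=cfg.mirna_len - k))

        tail = draw_tail()
        if p_start > 0 and tail:
            upstream = plan.mrna[p_start - 1]
            if any(pair_class(y, upstream) is None for y in tail_alpha):
                for _ in range(20):
                    if pair_class(tail[0], upstream) is None:
                        break
                    tail = draw_tail()
        mir_seq = _rc_rna("".join(window_site)) + tail
        mirna = MiRNARecord(f"syn-miR-planted-{target_idx + 1}", mir_seq)

        # verify against the real scan + thresholds
        wlo = max(0, tpos - cfg.flank)
        whi = min(plan.length, tpos + cfg.flank + 1)
        offset = tpos - wlo
        mrna_str = "".join(plan.mrna)
        win_ref = mrna_str[wlo:whi]
        win_alt = win_ref[:offset] + alt_base + win_ref[offset + 1 :]
        win_strong = win_ref if targeted_is_reference else win_alt
        win_weak = win_alt if targeted_is_reference else win_ref
        a_strong = scan_window(mirna, win_strong, offset, sparams, eparams)
        a_weak = scan_window(mirna, win_weak, offset, sparams, eparams)
        if a_strong is None:
            continue
        if not (
            a_strong.score >= passes.strong_score_min
            and a_strong.mfe <= passes.strong_mfe_max
        ):
            continue
        weak_score = 0.0 if a_weak is None else a_weak.score
        weak_mfe = 0.0 if a_weak is None else a_weak.mfe
        if not (weak_score <= passes.weak_score_max and weak_mfe >= passes.weak_mfe_min):
            continue
        if not (
            a_strong.score - weak_score >= stringency.delta_score_min
            or a_strong.mfe - weak_mfe <= stringency.delta_mfe_max
        ):
            continue
        in_seed = sparams.seed_start <= s <= sparams.seed_end
        snp_col = a_strong.column_at_target(offset)
        if snp_col is None or snp_col.mi is None or snp_col.mi + 1 != s:
            continue  # site found in an unintended register; re-draw

        plan.snp_positions.append(tpos)
        # keep other SNPs away from the site and the tail's reach
        plan.exclusions.append(
            (p_start - (cfg.mirna_len - k) - 6, p_end + 2)
        )
        return tpos, ref_base, alt_base, mirna, targeted_is_reference, in_seed

    raise GenerationError(
        f"could not engineer planted target {target_idx + 1} after "
        f"{cfg.max_retries} retries"
    )


def _place_snp(
    plan: _TranscriptPlan, region: Region, rng: np.random.Generator
) -> tuple[int, str, str]:
    lo, hi = plan.region_bounds(region)
    for _ in range(200):
        pos = int(rng.integers(lo, hi))
        if not plan.position_free(pos):
            continue
        ref = plan.mrna[pos]
        alt = str(rng.choice([b for b in _RNA if b != ref]))
        plan.snp_positions.append(pos)
        return pos, ref, alt
    raise GenerationError(f"no free SNP position in {region.value}")


def _assemble_genome(plan: _TranscriptPlan, cfg: SyntheticConfig, rng: np.random.Generator):
    """Embed the mRNA into a two-exon gene on its chromosome; returns
    (chrom_name, chrom_seq, TranscriptAnnotation, plus_to_genomic mapper)."""
    mrna_dna = "".join(plan.mrna).replace("U", "T")
    sp = cfg.utr5_len + cfg.cds_len // 2  # arbitrary exon split point
    d1, d2 = mrna_dna[:sp], mrna_dna[sp:]
    intron = _random_rna(rng, cfg.intron_len, cfg.gc_content).replace("U", "T")
    pad1 = _random_rna(rng, cfg.pad_len, cfg.gc_content).replace("U", "T")
    pad2 = _random_rna(rng, cfg.pad_len, cfg.gc_content).replace("U", "T")
    p = cfg.pad_len
    chrom = f"chrS{plan.idx + 1}"
    if plan.strand == "+":
        seq = pad1 + d1 + intron + d2 + pad2
        exons = [(p, p + len(d1)), (p + len(d1) + cfg.intron_len,
                                    p + len(d1) + cfg.intron_len + len(d2))]
    else:
        r2, r1 = revcomp_dna(d2), revcomp_dna(d1)
        seq = pad1 + r2 + intron + r1 + pad2
        exons = [(p, p + len(r2)), (p + len(r2) + cfg.intron_len,
                                    p + len(r2) + cfg.intron_len + len(r1))]

    exon_lens = [e - s for s, e in exons]

    def plus_to_genomic(plus_pos: int) -> int:
        off = 0
        for (s, e), ln in zip(exons, exon_lens):
            if plus_pos < off + ln:
                return s + (plus_pos - off)
            off += ln
        raise ValueError(plus_pos)

    n = plan.length
    # CDS bounds in plus-transcript coordinates
    if plan.strand == "+":
        cds_plus = (cfg.utr5_len, cfg.utr5_len + cfg.cds_len)
    else:
        cds_plus = (n - cfg.utr5_len - cfg.cds_len, n - cfg.utr5_len)
    cds_start = plus_to_genomic(cds_plus[0])
    cds_end = plus_to_genomic(cds_plus[1] - 1) + 1

    tx = TranscriptAnnotation(
        gene=f"SYNG{plan.idx + 1}",
        transcript_id=f"SYNT{plan.idx + 1}",
        chrom=chrom,
        strand=plan.strand,
        tx_start=exons[0][0],
        tx_end=exons[-1][1],
        cds_start=cds_start,
        cds_end=cds_end,
        exon_starts=tuple(s for s, _ in exons),
        exon_ends=tuple(e for _, e in exons),
    )
    return chrom, seq, tx, plus_to_genomic


def generate(config: Optional[SyntheticConfig] = None) -> SyntheticDataset:
    """Generate a complete synthetic dataset with ground truth."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    sparams, eparams = ScoringParams(), EnergyParams.default()
    passes, stringency = PassThresholds(), StringencyThresholds()

    plans = [_TranscriptPlan(i, cfg, rng) for i in range(cfg.n_transcripts)]

    planted: list[dict] = []
    for t_idx in range(cfg.n_planted_targets):
        plan = plans[t_idx % len(plans)]
        tpos, ref, alt, mirna, tgt_ref, in_seed = _plant_target(
            plan, t_idx, cfg, rng, sparams, eparams, passes, stringency
        )
        planted.append(
            dict(plan=plan, tpos=tpos, ref=ref, alt=alt, mirna=mirna,
                 targeted_is_reference=tgt_ref, snp_in_seed=in_seed)
        )

    # background SNPs, filling each region's quota
    background: list[tuple[_TranscriptPlan, int, str, str]] = []
    for plan in plans:
        planted_here = {p["tpos"] for p in planted if p["plan"] is plan}
        for region in (Region.FIVE_UTR, Region.CDS, Region.THREE_UTR):
            lo, hi = plan.region_bounds(region)
            have = sum(1 for q in planted_here if lo <= q < hi)
            for _ in range(max(0, cfg.n_snps_per_region - have)):
                pos, ref, alt = _place_snp(plan, region, rng)
                background.append((plan, pos, ref, alt))

    # genome assembly
    genome: dict[str, str] = {}
    transcripts: list[TranscriptAnnotation] = []
    mappers = {}
    for plan in plans:
        chrom, seq, tx, mapper = _assemble_genome(plan, cfg, rng)
        genome[chrom] = seq
        transcripts.append(tx)
        mappers[plan.idx] = (tx, mapper)

    # SNP records (genomic sense)
    def to_record(plan, tpos, ref, alt, rs_num) -> SNPRecord:
        tx, mapper = mappers[plan.idx]
        plus_pos = tpos if plan.strand == "+" else plan.length - 1 - tpos
        gpos = mapper(plus_pos)
        def g(base):
            if base == "-":
                return "-"
            dna = base.replace("U", "T")
            return dna if plan.strand == "+" else revcomp_dna(dna)
        return SNPRecord(f"rsSYN{rs_num:06d}", tx.chrom, gpos, g(ref), g(alt))

    snps: list[SNPRecord] = []
    truth_entries: list[PlantedTarget] = []
    rs_num = 1
    for p in planted:
        rec = to_record(p["plan"], p["tpos"], p["ref"], p["alt"], rs_num)
        snps.append(rec)
        base = p["ref"] if p["targeted_is_reference"] else p["alt"]
        truth_entries.append(
            PlantedTarget(
                rs_id=rec.rs_id,
                mirna_name=p["mirna"].name,
                targeted_allele_base=base,
                targeted_is_reference=p["targeted_is_reference"],
                snp_in_seed=p["snp_in_seed"],
            )
        )
        rs_num += 1
    for plan, pos, ref, alt in background:
        snps.append(to_record(plan, pos, ref, alt, rs_num))
        rs_num += 1

    # decoy miRNAs: no >=6-nt WC-complementary run to any SNP window
    # (both allele variants of every window)
    all_snp_sites = [(p["plan"], p["tpos"], p["alt"]) for p in planted]
    all_snp_sites += [(plan, pos, alt) for plan, pos, _, alt in background]
    windows = []
    for plan, tpos, alt in all_snp_sites:
        wlo = max(0, tpos - cfg.flank)
        whi = min(plan.length, tpos + cfg.flank + 1)
        ref_win = "".join(plan.mrna[wlo:whi])
        windows.append(ref_win)
        off = tpos - wlo
        if alt == "-":
            windows.append(ref_win[:off] + ref_win[off + 1 :])
        else:
            windows.append(ref_win[:off] + alt + ref_win[off + 1 :])
    forbidden = set()
    for w in windows:
        rc = _rc_rna(w)
        for i in range(len(rc) - 5):
            forbidden.add(rc[i : i + 6])

    mirnas: list[MiRNARecord] = [p["mirna"] for p in planted]
    for d in range(cfg.n_decoy_mirnas):
        for _ in range(2000):
            seq = _random_rna(rng, cfg.mirna_len, cfg.gc_content)
            kmers = {seq[i : i + 6] for i in range(len(seq) - 5)}
            if not (kmers & forbidden):
                mirnas.append(MiRNARecord(f"syn-miR-{d + 1:04d}", seq))
                break
        else:
            raise GenerationError(
                f"could not draw decoy {d + 1} satisfying the complementarity "
                "exclusion (gc_content too extreme?)"
            )

    return SyntheticDataset(
        genome=genome,
        transcripts=transcripts,
        snps=snps,
        mirnas=mirnas,
        truth=GroundTruth(tuple(truth_entries)),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Curated reference hit set (MMP-9 screen)
# ---------------------------------------------------------------------------

#: published tallies accompanying the curated MMP-9 / chromosome-20 screen
REFERENCE_SCREEN = {
    "chr20_total_snps": 961_931,
    "chr20_transcript_snps": 36_315,
    "mmp9_first_pass_by_region": {"5'UTR": 0, "CDS": 312, "3'UTR": 9},
    "chr20_first_pass_pairs": 28_494,
    "chr20_high_stringency_pairs": 15_359,
}


def table1_fixture():
    """The curated 41-row set of allele-differential miRNA:MMP-9 pairs
    (ID, rs#, miRNA, targeted allele, ΔScore, ΔMFE), schema-validated.

    Returns a pandas DataFrame with columns id, rs_id, mirna, targeted_allele,
    allele_class, delta_score, delta_mfe, region.
    """
    import pandas as pd
    from importlib import resources

    ref = resources.files("polymirts.data").joinpath("mmp9_reference_hits.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"targeted_allele": str})

    required = ["id", "rs_id", "mirna", "targeted_allele", "allele_class",
                "delta_score", "delta_mfe"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"reference hit set missing columns: {missing}")
    if df["id"].isna().any() or (df["id"] == "").any():
        raise ValidationError("reference hit set: empty ID")
    if not df["rs_id"].str.fullmatch(r"rs\d+").all():
        raise ValidationError("reference hit set: malformed rs identifier")
    if not df["allele_class"].isin(["WT", "SNP"]).all():
        raise ValidationError("reference hit set: allele class must be WT or SNP")
    if not (df["delta_score"] > 0).all():
        raise ValidationError("reference hit set: ΔScore must be positive")
    if not (df["delta_mfe"] < 0).all():
        raise ValidationError("reference hit set: ΔMFE must be negative")

    def region_of(ident: str) -> str:
        if ident.startswith("5'UTR"):
            return Region.FIVE_UTR.value
        if ident.startswith("3'UTR"):
            return Region.THREE_UTR.value
        return Region.CDS.value

    df = df.assign(region=df["id"].map(region_of))
    return df


def fixture_stringency_flags(df=None, st: Optional[StringencyThresholds] = None):
    """Boolean Series: which fixture rows satisfy the stated high-stringency
    criteria as printed (rows that do not are flagged, not dropped)."""
    if df is None:
        df = table1_fixture()
    st = st or StringencyThresholds()
    return (df["delta_score"] >= st.delta_score_min) | (df["delta_mfe"] <= st.delta_mfe_max)
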