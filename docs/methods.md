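# Methods

## Problem and model

A biallelic SNP inside an mRNA changes one base of every miRNA binding site
that overlaps it. Because miRNA target recognition is dominated by
Watson–Crick pairing of the miRNA seed (positions 2–8 from the 5' end), a
single base change at the paired position can switch a transcript between
"targeted" and "not targeted". `polymirts` quantifies this with two
per-allele measures computed from one duplex model:

* **Score** — a seed-weighted local complementarity alignment score
  (dimensionless), and
* **MFE** — an estimated duplex hybridization free energy (kcal/mol, more
  negative = more stable),

and then selects (SNP, miRNA) pairs whose Score/MFE differ strongly between
alleles.

## Duplex alignment

The miRNA (5'→3') is aligned against the *reverse* of the mRNA window so the
strands run antiparallel. It is a Smith–Waterman local alignment over a
complementarity "match" relation: Watson–Crick pairs score `match_wc = +5`,
G:U wobbles `match_gu = +1`, other juxtapositions `mismatch = -3`. Gaps are
affine: a run of length L costs `gap_open + gap_extend·(L−1)` with
`gap_open = −9`, `gap_extend = −4`. Every per-column contribution — match,
mismatch or gap — at a miRNA position inside the seed range (2–8, clipped to
the miRNA length) is multiplied by `seed_scale = 4`; a gap column consuming
only a target base takes the weight of the last consumed miRNA position. A
perfect 7-mer complement therefore scores 5·1 + 5·4·6 = 125 (position 1 at
weight 1, positions 2–7 at weight 4).

Local alignments start and end on substitution columns (an optimal local
alignment never gains from terminal gaps or mismatches). Ties are broken
deterministically: prefer the alignment ending 5'-most on the window, and
within a path prefer pair columns over miRNA-consuming gaps over
target-consuming gaps (fewer gaps, shorter span). Identical inputs yield
bitwise-identical outputs.

The implementation is a three-matrix (match / gap-in-target / gap-in-miRNA)
dynamic program. The test suite checks it against an independent brute-force
oracle — a top-down maximization over all gapped antiparallel local
alignments with the affine state carried explicitly — on hundreds of seeded
random instances.

## SNP-anchored scan

For allele-differential work the relevant duplex is the best alignment whose
hybridized region *encompasses the polymorphism*. We interpret this as the
polymorphic base itself being engaged in a base pair (WC or G:U): the scan
(`scan_snp`) returns the best such alignment, computed exactly by forcing a
pair at each candidate miRNA position and combining optimal prefix and suffix
alignments from forward and backward matrices. A weaker, span-containment
interpretation is available via `require_paired=False`.

The pairing requirement is what makes allele discrimination expressible.
Under any additive scoring, the best alignment that merely *covers* the SNP
changes by at most `(match_wc − mismatch)·seed_scale = 32` points when one
base flips — so a strong/weak split of ≥ 65 Score points between alleles
(125 vs 60) could never occur. Requiring the SNP base to pair means the
disfavored allele legitimately scores ~0 when no register can pair its base,
which is exactly the behavior of site-reporting scanners that simply emit no
hit for the broken allele.

When the scan returns no alignment for an allele, the pipeline records
Score 0 and MFE 0.0 kcal/mol (no duplex formed) so that ΔScore/ΔMFE remain
finite; `duplex_energy` itself returns +∞ for an empty alignment.

`snp_in_seed` reports whether the window position of the SNP sits opposite a
miRNA position in 2–8 (paired or mismatched); a SNP consumed by a gap is
classified as outside the seed.

## Duplex energy

The energy model is a deliberately simple nearest-neighbor sum: duplex
initiation (+4.09 kcal/mol) plus stacking terms over consecutive base pairs,
one flat bulge penalty (+3.8) per gap run and one internal-loop penalty
(+2.8) per mismatch run between pairs. The stack table (shipped as
`data/stack_energies.yaml`, documented key scheme, closed under 180°
rotation at load time) uses the standard unified Watson–Crick RNA parameters
and representative wobble values; wobble–wobble stacks are floored at
−0.1 kcal/mol so that appending any stack never destabilizes a duplex, which
keeps the energy ordering monotone. This is not a secondary-structure folder:
no multi-loops, no dangling ends, no target-site accessibility. Absolute
kcal/mol values are therefore not comparable to full folding engines, and all
energy-based guarantees in the tests are ordinal/property-based (GC-rich
helices below AU-rich, monotone growth, hand-summed table agreement).
Alternative published tables can be dropped in via `EnergyParams.from_file`.

## Two-pass differential selection

Defaults are the operative published thresholds: first pass keeps pairs with
preferred-allele Score ≥ 125 **and** MFE ≤ −16 kcal/mol; second pass keeps,
among those, pairs with other-allele Score ≤ 60 **and** MFE ≥ −4 kcal/mol.
Both directions (reference-preferred and variant-preferred) are evaluated, so
either allele can be the targeted one: a variant-targeted hit is a
*gain-of-regulation*, a reference-targeted one a *loss-of-regulation*.
Candidates are marked high-stringency when ΔScore ≥ 165 **or**
ΔMFE ≤ −25 kcal/mol; all comparisons are inclusive, and ΔMFE is preferred
minus disfavored (negative for real hits). The two strong criteria are
required jointly (a conjunction), matching the fixed-threshold statement of
the selection.

Percentile mode replaces the fixed cutoffs with quantiles of the observed
distribution (top `p` of preferred-allele Score and MFE, bottom `p` of
other-allele, default p = 0.20). Quantiles use `numpy.quantile` with
`method="higher"` for the strong-score / weak-MFE side and `method="lower"`
for the strong-MFE / weak-score side, so that a distribution constructed with
its 80th score percentile exactly 125 and 20th MFE percentile exactly −16
selects exactly the same set as the fixed thresholds.

## Coordinates, strands, consequences

Internal coordinates are 0-based half-open; report output is 1-based. All
windows and alleles are mRNA-sense: for minus-strand transcripts the stored
alleles are complements of the genomic alleles, and the targeted-allele
column is reported in transcript sense. A SNP hitting several overlapping
transcripts produces one context (and potentially one hit) per transcript,
with the transcript id carried in the output. The flank defaults to 30 nt per
side (≥ the longest mature miRNA − 1), so any duplex encompassing the
polymorphism fits in the window; windows truncate at transcript ends.

Coding consequences are computed from the codon frame with the standard
genetic code: missense (`Asn38Ser`), synonymous (`Gly344=`), stop gained
(`Cys302Ter`), stop lost (`Ter7Gln`), start lost (`Met1Lys`) and, for a
deletion allele in the CDS, frameshift (`Ala608fs`). UTR SNPs get
`5'UTR-`/`3'UTR-<ref><pos><alt>` identifiers. A deletion allele's window is
one base shorter and is scanned as-is, with the SNP offset at the junction
base.

## Synthetic data generator

The generator emulates the shape of the genome-scale inputs with known
ground truth. Default study conditions: 3 transcripts (alternating strands,
two exons, 50 nt intron, 25 nt pads) with 60 nt 5'UTR / 300 nt CDS / 90 nt
3'UTR; 2 SNPs per region per transcript; 1 planted allele-specific site; 50
decoy miRNAs of 21 nt; GC content 0.5; all driven by one seeded RNG
(byte-identical outputs per seed).

A planted miRNA is the reverse complement of a 15-nt site centred on one
allele, with a random 6-nt tail; the SNP sits opposite miRNA position 5
(inside the seed) by default, or position 12 with `planted_outside_seed`.
Site and tail are drawn from the alphabet of bases whose complements cannot
pair the weak allele (neither WC nor wobble), so the disfavored allele has no
pairable partner anywhere in the planted miRNA — the site is specific to
exactly one allele by construction, which is the defining property being
modeled. The complement length 15 makes the strong-allele Score 180 and its
MFE comfortably below −16 at default GC. Each planted pair is verified at
generation time against the actual scan and thresholds (strong pass, weak
pass, stringency, intended register); failing draws are re-engineered, with a
generation error after a bounded number of retries. Non-planted SNPs are
kept out of the planted site's reach, and synonymous planting uses a
four-fold degenerate glycine codon with the SNP at its third position.

Decoys are random sequences with no ≥ 6-nt Watson–Crick complementary run to
any SNP window (both alleles), which keeps them below any seed-anchored
selection threshold.

What the generator does **not** emulate: real genome composition beyond GC
content, repeat structure, linkage between SNPs, miRNA expression levels, or
target-site accessibility. Passing the planted-recovery tests therefore shows
that the pipeline's selection logic is correct and discriminating under
controlled conditions; it does not certify sensitivity or specificity on real
genomes.

## Reference hit set

`data/mmp9_reference_hits.tsv` is a curated 41-row table of published
allele-differential miRNA:MMP-9 pairs (ID, rs#, miRNA, targeted allele,
ΔScore, ΔMFE) used by the validation tooling and the acceptance script, with
schema validation on load. One printed row (rs3918252 / hsa-miR-4684-3p,
ΔScore 164, ΔMFE −16.55) does not satisfy the stated stringency criteria —
likely rounding in the source table; `validate-fixture` flags such rows
rather than dropping them or guessing intent. The accompanying
`REFERENCE_SCREEN` constants carry the screen's printed tallies (961,931
chromosome-20 SNPs, 36,315 within gene transcripts; per-region first-pass
counts 0/312/9), from which the report module recomputes the derived
fractions and totals. No attempt is made to numerically reproduce the
per-pair Score/MFE values of the reference screen: those depend on the exact
scanner build and archival genome/dbSNP/miRBase snapshots.

## Problem sizes and determinism

The default test and acceptance workloads are desk-scale by design: 18 SNP
contexts × 51 miRNAs (918 scored pairs, ~5 s), 200-instance oracle
comparisons at miRNA ≤ 10 nt / window ≤ 14 nt, and 100-pair threshold-mode
distributions. Every stochastic component takes an explicit seed;
re-running any command from its written `manifest.json` reproduces outputs
byte-for-byte.

## Known limitations

* The energy model is ordinal, not calibrated; use a full folding engine if
  absolute ΔG matters.
* Fixed Score thresholds presuppose the default substitution magnitudes
  (+5/+1/−3); if you change those, re-derive thresholds or use percentile
  mode, which is scale-free.
* Noncanonical (bulged/mismatched seed) sites, which real miRNAs do use, are
  penalized by design; the pipeline models the canonical seed-dominated
  regime.
* VCF input is not supported (a converter to the 5-column SNP table is a
  plausible extension); no download clients for reference resources.
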