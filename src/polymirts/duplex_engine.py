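"""Seed-weighted complementarity alignment and duplex free-energy estimation.

The alignment is a Smith-Waterman-style local alignment of a miRNA (read
5'->3') against the reverse of an mRNA target window, so that the two strands
run antiparallel as in a physical duplex.  "Match" means the two bases can
pair: Watson-Crick pairs score ``match_wc``, G:U wobbles ``match_gu``,
anything else ``mismatch``.  Gaps are affine: a run of length L costs
``gap_open + gap_extend*(L-1)``.  Every per-column contribution (match,
mismatch or gap) at a miRNA position inside the seed range (positions 2-8 from
the miRNA 5' end, 1-based, clipped to the miRNA length) is multiplied by
``seed_scale`` — this is how seed pairing dominates the Score.  A gap column
that consumes only a target base is weighted by the last consumed miRNA
position (weight 1 before the first).

The hybridization energy is a deliberately simple nearest-neighbor model:
duplex initiation plus stacking terms over consecutive base pairs, with flat
per-event penalties for bulges and internal loops.  It is not a
secondary-structure folder; it provides a physically ordered, deterministic
MFE axis (more negative = more stable) on the same alignment the Score is
computed from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import NamedTuple, Optional

import yaml

from .errors import ConfigurationError, ValidationError
from .io_annotations import RNA_ALPHABET, MiRNARecord, SNPContext

NEG_INF = float("-inf")

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}


def pair_class(mbase: str, tbase: str) -> Optional[str]:
    """'WC', 'GU' or None (cannot pair)."""
    if (mbase, tbase) in _WC:
        return "WC"
    if (mbase, tbase) in _GU:
        return "GU"
    return None


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoringParams:
    """miRanda-style scoring: +5 WC / +1 G:U / -3 mismatch, affine gaps
    -9/-4, and a 4x multiplicative weight on seed positions 2-8."""

    match_wc: float = 5.0
    match_gu: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0
    seed_start: int = 2
    seed_end: int = 8

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValidationError("require gap_open <= gap_extend <= 0")
        if self.seed_scale < 1:
            raise ValidationError("seed_scale must be >= 1")
        if not (1 <= self.seed_start <= self.seed_end):
            raise ValidationError("invalid seed range")

    def weight(self, mirna_pos: int) -> float:
        """Positional weight for a 1-based miRNA position (0 = before the first base)."""
        if self.seed_start <= mirna_pos <= self.seed_end:
            return self.seed_scale
        return 1.0

    def seed_positions(self, mirna_len: int) -> frozenset[int]:
        """Effective seed positions, clipped to the miRNA length."""
        return frozenset(range(self.seed_start, min(self.seed_end, mirna_len) + 1))

    def column_score(self, mbase: str, tbase: str) -> float:
        cls = pair_class(mbase, tbase)
        if cls == "WC":
            return self.match_wc
        if cls == "GU":
            return self.match_gu
        return self.mismatch


@dataclass(frozen=True)
class EnergyParams:
    """Nearest-neighbor stack table plus initiation and loop penalties (kcal/mol)."""

    stacks: dict
    duplex_init: float = 4.09
    bulge_penalty: float = 3.8
    internal_loop_penalty: float = 2.8

    def __post_init__(self):
        if self.bulge_penalty <= 0 or self.internal_loop_penalty <= 0:
            raise ValidationError("loop penalties must be positive")

    @staticmethod
    def _rotate(key: str) -> str:
        top, bottom = key.split("/")
        return bottom[::-1] + "/" + top[::-1]

    def stack_energy(self, key: str) -> float:
        """Energy of a dinucleotide step, closed under 180-degree rotation."""
        if key in self.stacks:
            return self.stacks[key]
        rot = self._rotate(key)
        if rot in self.stacks:
            return self.stacks[rot]
        raise ConfigurationError(f"no stacking energy for dinucleotide step {key!r}")

    @classmethod
    def from_file(cls, path) -> "EnergyParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                stacks={str(k): float(v) for k, v in raw["stacks"].items()},
                duplex_init=float(raw["duplex_init"]),
                bulge_penalty=float(raw["bulge_penalty"]),
                internal_loop_penalty=float(raw["internal_loop_penalty"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad energy parameter file {path}: {exc}") from exc

    @classmethod
    def default(cls) -> "EnergyParams":
        return _default_energy_params()


@lru_cache(maxsize=1)
def _default_energy_params() -> EnergyParams:
    ref = resources.files("polymirts.data").joinpath("stack_energies.yaml")
    with resources.as_file(ref) as path:
        return EnergyParams.from_file(path)


# ---------------------------------------------------------------------------
# Alignment result
# ---------------------------------------------------------------------------


class Column(NamedTuple):
    """One alignment column.  ``mi``/``tj`` are 0-based miRNA / original-window
    indices (None for a gap on that side); kind in {WC, GU, MM, gap_t, gap_m}
    where gap_t consumes a miRNA base and gap_m a target base."""

    mi: Optional[int]
    tj: Optional[int]
    mbase: Optional[str]
    tbase: Optional[str]
    kind: str


@dataclass(frozen=True)
class DuplexAlignment:
    """One miRNA:target duplex alignment with Score, MFE and pairing map.

    ``pairs`` holds (miRNA position 1-based, window position 0-based, WC|GU),
    strictly increasing in miRNA position and strictly decreasing in window
    position (antiparallel).  ``target_span`` is half-open on the window.
    The empty alignment has score 0, no columns and mfe +inf.
    """

    score: float
    mfe: float
    columns: tuple[Column, ...]
    seed_positions_paired: frozenset[int] = frozenset()

    @property
    def is_empty(self) -> bool:
        return not self.columns

    @property
    def pairs(self) -> tuple[tuple[int, int, str], ...]:
        return tuple(
            (c.mi + 1, c.tj, c.kind) for c in self.columns if c.kind in ("WC", "GU")
        )

    @property
    def target_span(self) -> tuple[int, int]:
        tjs = [c.tj for c in self.columns if c.tj is not None]
        if not tjs:
            return (0, 0)
        return (min(tjs), max(tjs) + 1)

    @property
    def mirna_span(self) -> tuple[int, int]:
        mis = [c.mi for c in self.columns if c.mi is not None]
        if not mis:
            return (0, 0)
        return (min(mis), max(mis) + 1)

    def covers(self, window_offset: int) -> bool:
        s, e = self.target_span
        return s <= window_offset < e

    def column_at_target(self, window_offset: int) -> Optional[Column]:
        for c in self.columns:
            if c.tj == window_offset:
                return c
        return None


EMPTY_ALIGNMENT = DuplexAlignment(score=0.0, mfe=math.inf, columns=())


def _validate_rna(seq: str, what: str) -> None:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValidationError(f"{what} contains non-RNA characters: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Core DP
# ---------------------------------------------------------------------------


def _dp_matrices(m: str, r: str, p: ScoringParams, wcons=None, wgap=None):
    """Smith-Waterman matrices over miRNA ``m`` and reversed window ``r``.

    M[i][j]: best alignment ending with a column pairing m[i-1] and r[j-1]
    (pair or mismatch).  X[i][j]: ending with a gap column consuming m[i-1].
    Y[i][j]: ending with a gap column consuming r[j-1].  Fresh starts only via
    M (a local alignment never starts with a gap).

    ``wcons(i)`` weights a column consuming miRNA base i, ``wgap(i)`` a
    target-consuming gap column after i miRNA bases; both default to the seed
    weights of ScoringParams.  The scan's backward pass supplies remapped
    weights so that seed positions refer to the original miRNA orientation.
    """
    wcons = wcons or p.weight
    wgap = wgap or p.weight
    n1, n2 = len(m), len(r)
    M = [[NEG_INF] * (n2 + 1) for _ in range(n1 + 1)]
    X = [[NEG_INF] * (n2 + 1) for _ in range(n1 + 1)]
    Y = [[NEG_INF] * (n2 + 1) for _ in range(n1 + 1)]
    for i in range(1, n1 + 1):
        wi = wcons(i)
        wg = wgap(i)
        mi = m[i - 1]
        for j in range(1, n2 + 1):
            sub = wi * p.column_score(mi, r[j - 1])
            prev = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = sub + prev
            X[i][j] = max(
                M[i - 1][j] + wi * p.gap_open,
                X[i - 1][j] + wi * p.gap_extend,
                Y[i - 1][j] + wi * p.gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + wg * p.gap_open,
                Y[i][j - 1] + wg * p.gap_extend,
                X[i][j - 1] + wg * p.gap_open,
            )
    # Y in row 0 (no miRNA base consumed yet): gaps cannot start a local
    # alignment (fresh starts only via M), so row 0 stays -inf.
    return M, X, Y


def _traceback(m: str, r: str, p: ScoringParams, M, X, Y, i: int, j: int, mat: str,
               wcons=None, wgap=None):
    """Columns (reversed-window coords) of the alignment ending at (i, j, mat)."""
    wcons = wcons or p.weight
    wgap = wgap or p.weight
    cols = []
    while i > 0 and j > 0:
        if mat == "M":
            cols.append(("both", i - 1, j - 1))
            prev_vals = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            prev = max(0.0, *prev_vals)
            i, j = i - 1, j - 1
            if prev == 0.0 and max(prev_vals) <= 0.0:
                break  # fresh start (preferred on ties: shortest span)
            # deterministic preference: pair column, then miRNA-consuming gap,
            # then target-consuming gap (fewer gaps first)
            if M[i][j] == prev:
                mat = "M"
            elif X[i][j] == prev:
                mat = "X"
            else:
                mat = "Y"
        elif mat == "X":
            wi = wcons(i)
            cols.append(("gap_t", i - 1, None))
            val = X[i][j]
            if M[i - 1][j] + wi * p.gap_open == val:
                mat = "M"
            elif X[i - 1][j] + wi * p.gap_extend == val:
                mat = "X"
            else:
                mat = "Y"
            i -= 1
        else:  # Y
            wg = wgap(i)
            cols.append(("gap_m", None, j - 1))
            val = Y[i][j]
            if M[i][j - 1] + wg * p.gap_open == val:
                mat = "M"
            elif Y[i][j - 1] + wg * p.gap_extend == val:
                mat = "Y"
            else:
                mat = "X"
            j -= 1
    return cols[::-1]


def _columns_from_trace(trace, m: str, window: str) -> tuple[Column, ...]:
    L = len(window)
    out = []
    for kind0, mi, jr in trace:
        if kind0 == "both":
            tj = L - 1 - jr
            cls = pair_class(m[mi], window[tj]) or "MM"
            out.append(Column(mi, tj, m[mi], window[tj], cls))
        elif kind0 == "gap_t":
            out.append(Column(mi, None, m[mi], None, "gap_t"))
        else:
            tj = L - 1 - jr
            out.append(Column(None, tj, None, window[tj], "gap_m"))
    return tuple(out)


def _finish_alignment(
    score: float,
    trace,
    mirna_seq: str,
    window: str,
    sparams: ScoringParams,
    eparams: Optional[EnergyParams],
) -> DuplexAlignment:
    columns = _columns_from_trace(trace, mirna_seq, window)
    seed = sparams.seed_positions(len(mirna_seq))
    paired = frozenset(
        c.mi + 1 for c in columns if c.kind in ("WC", "GU") and c.mi + 1 in seed
    )
    aln = DuplexAlignment(score=score, mfe=math.nan, columns=columns,
                          seed_positions_paired=paired)
    mfe = duplex_energy(aln, eparams) if eparams is not None else math.nan
    return DuplexAlignment(score=score, mfe=mfe, columns=columns,
                           seed_positions_paired=paired)


def align(
    mirna: MiRNARecord,
    window: str,
    params: Optional[ScoringParams] = None,
    energy: Optional[EnergyParams] = None,
) -> DuplexAlignment:
    """Best local duplex alignment of a miRNA against a target window.

    Ties are broken deterministically: prefer the alignment ending 5'-most on
    the window, and within a path prefer pair columns over gaps (fewer gaps,
    shorter span).
    """
    params = params or ScoringParams()
    m = mirna.sequence
    _validate_rna(window, "target window")
    if not window:
        raise ValidationError("empty target window")
    r = window[::-1]
    M, X, Y = _dp_matrices(m, r, params)
    best, bi, bj = 0.0, 0, 0
    n1, n2 = len(m), len(r)
    for i in range(1, n1 + 1):
        row = M[i]
        for j in range(1, n2 + 1):
            v = row[j]
            # tie-break: larger j = 5'-most start on the original window
            if v > best or (v == best and v > 0 and (j > bj or (j == bj and i < bi))):
                best, bi, bj = v, i, j
    if best <= 0:
        return EMPTY_ALIGNMENT
    trace = _traceback(m, r, params, M, X, Y, bi, bj, "M")
    return _finish_alignment(best, trace, m, window, params, energy)


def recompute_score(alignment: DuplexAlignment, params: ScoringParams) -> float:
    """Recompute the Score from the stored columns (invariant check)."""
    total = 0.0
    prev_kind = None
    last_mi = 0
    for c in alignment.columns:
        if c.kind in ("WC", "GU", "MM"):
            last_mi = c.mi + 1
            total += params.weight(last_mi) * params.column_score(c.mbase, c.tbase)
        elif c.kind == "gap_t":
            last_mi = c.mi + 1
            g = params.gap_extend if prev_kind == "gap_t" else params.gap_open
            total += params.weight(last_mi) * g
        else:  # gap_m
            g = params.gap_extend if prev_kind == "gap_m" else params.gap_open
            total += params.weight(last_mi) * g
        prev_kind = c.kind
    return total


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------


def duplex_energy(alignment: DuplexAlignment, params: Optional[EnergyParams] = None) -> float:
    """Estimated duplex free energy (kcal/mol); +inf for the empty alignment.

    Initiation + stacking over consecutive paired columns, one bulge penalty
    per gap run and one internal-loop penalty per mismatch run between paired
    columns.
    """
    params = params or EnergyParams.default()
    paired = [c for c in alignment.columns if c.kind in ("WC", "GU")]
    if not paired:
        return math.inf
    energy = params.duplex_init
    cols = list(alignment.columns)
    first = cols.index(paired[0])
    last = cols.index(paired[-1])
    interior = cols[first : last + 1]
    prev_pair = None
    i = 0
    while i < len(interior):
        c = interior[i]
        if c.kind in ("WC", "GU"):
            if prev_pair is not None:
                if prev_pair.mi + 1 == c.mi and prev_pair.tj - 1 == c.tj:
                    key = f"{prev_pair.mbase}{c.mbase}/{prev_pair.tbase}{c.tbase}"
                    energy += params.stack_energy(key)
                # non-adjacent consecutive pairs were interrupted by a loop
                # event, charged when the interrupting run was consumed below
            prev_pair = c
            i += 1
        else:
            kind = "bulge" if c.kind in ("gap_t", "gap_m") else "loop"
            run_kinds = {c.kind}
            while i < len(interior) and interior[i].kind not in ("WC", "GU"):
                run_kinds.add(interior[i].kind)
                i += 1
            if run_kinds <= {"gap_t"} or run_kinds <= {"gap_m"}:
                energy += params.bulge_penalty
            else:
                energy += params.internal_loop_penalty
    return energy


# ---------------------------------------------------------------------------
# SNP-anchored scan
# ---------------------------------------------------------------------------


def scan_snp(
    mirna: MiRNARecord,
    ctx: SNPContext,
    allele: str,
    sparams: Optional[ScoringParams] = None,
    eparams: Optional[EnergyParams] = None,
    require_paired: bool = True,
) -> Optional[DuplexAlignment]:
    """Best alignment whose hybridized region encompasses the polymorphism.

    With ``require_paired`` (default) the polymorphic base itself must be
    engaged in a base pair (WC or G:U) — the allele-discriminating notion of a
    site.  With ``require_paired=False`` the SNP may instead sit opposite a
    mismatch or inside a gap, i.e. mere span containment.  Returns None when
    no such alignment has positive score.
    """
    sparams = sparams or ScoringParams()
    window = ctx.window(allele)
    offset = ctx.snp_offset(allele)
    if not window:
        return None
    return scan_window(mirna, window, offset, sparams, eparams, require_paired)


def scan_window(
    mirna: MiRNARecord,
    window: str,
    offset: int,
    sparams: Optional[ScoringParams] = None,
    eparams: Optional[EnergyParams] = None,
    require_paired: bool = True,
) -> Optional[DuplexAlignment]:
    """scan_snp on a raw window/offset (used by the generator's verification)."""
    sparams = sparams or ScoringParams()
    m = mirna.sequence
    _validate_rna(window, "target window")
    L = len(window)
    if not 0 <= offset < L:
        raise ValidationError(f"SNP offset {offset} outside window of length {L}")
    r = window[::-1]
    j0 = L - 1 - offset  # reversed-window index of the SNP base
    n1, n2 = len(m), len(r)

    Mf, Xf, Yf = _dp_matrices(m, r, sparams)
    mb, rb = m[::-1], r[::-1]
    # backward weights: backward row i consumes original miRNA position n1-i+1;
    # a target-gap column at backward row i sits 5'-ward of original position
    # n1-i+1, i.e. its forward last-consumed position is n1-i.
    wcons_b = lambda i: sparams.weight(n1 - i + 1)
    wgap_b = lambda i: sparams.weight(n1 - i) if i < n1 else 1.0
    Mb, Xb, Yb = _dp_matrices(mb, rb, sparams, wcons_b, wgap_b)

    def best_end(Mx, Xx, Yx, i, j):
        vals = [(0.0, None), (Mx[i][j], "M"), (Xx[i][j], "X"), (Yx[i][j], "Y")]
        return max(vals, key=lambda kv: kv[0])

    best_total = 0.0
    best_choice = None  # (i_forced, pre_mat, suf_mat, kind)
    for i in range(1, n1 + 1):
        cls = pair_class(m[i - 1], r[j0])
        if cls is None and require_paired:
            continue
        sub = sparams.weight(i) * sparams.column_score(m[i - 1], r[j0])
        pre_v, pre_m = best_end(Mf, Xf, Yf, i - 1, j0)
        suf_v, suf_m = best_end(Mb, Xb, Yb, n1 - i, n2 - j0 - 1)
        total = pre_v + sub + suf_v
        if total > best_total:
            best_total = total
            best_choice = (i, pre_m, suf_m, cls or "MM", pre_v, suf_v)
    if best_choice is None or best_total <= 0:
        return None

    i, pre_m, suf_m, cls, pre_v, suf_v = best_choice
    trace = []
    if pre_m is not None:
        trace.extend(_traceback(m, r, sparams, Mf, Xf, Yf, i - 1, j0, pre_m))
    trace.append(("both", i - 1, j0))
    if suf_m is not None:
        suf_trace = _traceback(
            mb, rb, sparams, Mb, Xb, Yb, n1 - i, n2 - j0 - 1, suf_m, wcons_b, wgap_b
        )
        # map backward-problem coordinates to forward ones and reverse order
        for kind0, pmi, pjr in reversed(suf_trace):
            fmi = None if pmi is None else n1 - 1 - pmi
            fjr = None if pjr is None else n2 - 1 - pjr
            trace.append((kind0, fmi, fjr))
    return _finish_alignment(best_total, trace, m, window, sparams, eparams)


def snp_in_seed(
    alignment: DuplexAlignment, snp_offset: int, params: Optional[ScoringParams] = None
) -> bool:
    """True iff the polymorphic window position sits opposite a seed-range
    miRNA position (paired or mismatched); False when it is consumed by a gap.

    Raises ValidationError when the alignment does not cover the offset.
    """
    params = params or ScoringParams()
    if not alignment.covers(snp_offset):
        raise ValidationError(
            f"alignment span {alignment.target_span} does not cover offset {snp_offset}"
        )
    col = alignment.column_at_target(snp_offset)
    if col is None or col.mi is None:
        return False
    return params.seed_start <= col.mi + 1 <= params.seed_end
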