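"""Independent brute-force oracle for the duplex alignment score.

Top-down enumeration over alignment column choices (pair/mismatch, gap
consuming a miRNA base, gap consuming a target base) with the affine gap
state carried explicitly.  Memoization makes it polynomial but the
formulation stays a direct maximization over all gapped antiparallel local
alignments, independent of the production bottom-up matrices.
"""

from functools import lru_cache

from polymirts.duplex_engine import ScoringParams, pair_class


def _column_score(p: ScoringParams, mbase: str, tbase: str) -> float:
    cls = pair_class(mbase, tbase)
    if cls == "WC":
        return p.match_wc
    if cls == "GU":
        return p.match_gu
    return p.mismatch


def oracle_best_score(mirna_seq: str, window: str, p: ScoringParams) -> float:
    """Best local-alignment score over all gapped antiparallel alignments."""
    return _oracle(mirna_seq, window, p, None)


def oracle_best_snp_paired(
    mirna_seq: str, window: str, snp_offset: int, p: ScoringParams
) -> float:
    """Best score among alignments in which the window base at ``snp_offset``
    is engaged in a WC or G:U pair; 0 when none is positive."""
    j_req = len(window) - 1 - snp_offset  # reversed-window index
    return _oracle(mirna_seq, window, p, j_req)


def _oracle(m: str, t: str, p: ScoringParams, j_req) -> float:
    r = t[::-1]
    n1, n2 = len(m), len(r)
    w = [1.0] + [p.weight(i) for i in range(1, n1 + 1)]

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, gap_state: str, covered: bool) -> float:
        # best additional score continuing at boundary (i, j); may stop here
        best = 0.0 if (j_req is None or covered) else float("-inf")
        if i < n1 and j < n2:
            cls = pair_class(m[i], r[j])
            cov = covered or (j == j_req and cls is not None)
            best = max(best, w[i + 1] * _column_score(p, m[i], r[j]) + ext(i + 1, j + 1, "", cov))
        if i < n1:  # gap consuming a miRNA base
            g = p.gap_extend if gap_state == "gt" else p.gap_open
            best = max(best, w[i + 1] * g + ext(i + 1, j, "gt", covered))
        if j < n2:  # gap consuming a target base (weighted by last miRNA pos)
            g = p.gap_extend if gap_state == "gm" else p.gap_open
            best = max(best, w[i] * g + ext(i, j + 1, "gm", covered))
        return best

    best = 0.0
    for i in range(n1):
        for j in range(n2):
            # local alignments start with a substitution column, never a gap
            cls = pair_class(m[i], r[j])
            cov = j_req is not None and j == j_req and cls is not None
            v = w[i + 1] * _column_score(p, m[i], r[j]) + ext(
                i + 1, j + 1, "", cov if j_req is not None else True
            )
            best = max(best, v)
    ext.cache_clear()
    return max(best, 0.0)
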