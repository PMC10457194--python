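"""Independent brute-force reimplementations used as test oracles.

These deliberately avoid the package's vectorized code paths: windows are
enumerated one by one, counts come from linear scans, and BH adjustment is
re-derived from its definition.
"""

import math
from bisect import bisect_left


def bh_adjust(pvals):
    """Benjamini-Hochberg q-values from first principles."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[idx] * m / rank)
        q[idx] = val
        prev = val
    return q


def poisson_sf(k_minus_1, lam):
    """P(X >= k) for X ~ Poisson(lam), via the cumulative sum."""
    if lam <= 0:
        return 0.0 if k_minus_1 >= 0 else 1.0
    cdf = 0.0
    term = math.exp(-lam)
    for i in range(0, k_minus_1 + 1):
        if i > 0:
            term *= lam / i
        cdf += term
    return max(0.0, 1.0 - cdf)


def _count(sorted_pos, lo, hi):
    return bisect_left(sorted_pos, hi) - bisect_left(sorted_pos, lo)


def oracle_call_peaks(lib, input_lib, params):
    """Literal window-enumeration peak caller; returns list of peak tuples.

    Output rows: (chrom, start, end, summit, tag_count, input_scaled) with
    float fields rounded for comparison by the caller.
    """
    genome_len = sum(lib.chrom_lengths.values())
    total = lib.total_tags
    if total == 0:
        return []
    lam_floor = total / genome_len * params.window_bp
    scale = total / input_lib.total_tags if input_lib is not None else None

    windows = []  # (chrom, start, end, count, input_scaled, p, is_candidate)
    for chrom in sorted(lib.chrom_lengths):
        L = lib.chrom_lengths[chrom]
        plus = list(lib.positions.get(chrom, {}).get("+", []))
        minus = list(lib.positions.get(chrom, {}).get("-", []))
        ip = list(input_lib.positions.get(chrom, {}).get("+", [])) if input_lib else []
        im = list(input_lib.positions.get(chrom, {}).get("-", [])) if input_lib else []
        s = 0
        while s + params.window_bp <= L:
            e = s + params.window_bp
            np_ = _count(plus, s, e)
            nm = _count(minus, s, e)
            n = np_ + nm
            ok = n >= params.min_reads
            if lib.assay != "atac":
                ok = ok and np_ >= params.min_reads_per_strand and nm >= params.min_reads_per_strand
            if input_lib is not None:
                in_scaled = (_count(ip, s, e) + _count(im, s, e)) * scale
            else:
                in_scaled = lam_floor
            lam = max(lam_floor, in_scaled)
            windows.append([chrom, s, e, n, in_scaled, poisson_sf(n - 1, lam), ok])
            s += params.step_bp
    if not windows:
        return []
    qs = bh_adjust([w[5] for w in windows])
    kept = [w[:6] + [q] for w, q in zip(windows, qs)
            if w[6] and q <= params.fdr_max
            and (w[3] + 1) / (w[4] + 1) >= params.min_fold_vs_input]
    if not kept:
        return []

    peaks = []
    kept.sort(key=lambda c: (c[0], c[1]))
    run = [kept[0]]
    run_end = kept[0][2]
    for c in kept[1:]:
        if c[0] == run[-1][0] and c[1] - run_end < params.merge_gap_bp:
            run.append(c)
            run_end = max(run_end, c[2])
        else:
            peaks.append(_finish_run(run, params))
            run = [c]
            run_end = c[2]
    peaks.append(_finish_run(run, params))
    if params.factor_fold_filter is not None:
        peaks = [p for p in peaks
                 if (p[4] + 1) / (p[5] + 1) >= params.factor_fold_filter]
    return peaks


def _finish_run(run, params):
    best = run[0]
    for c in run[1:]:
        if c[3] > best[3]:
            best = c
    return (
        run[0][0],                      # chrom
        min(c[1] for c in run),         # start
        max(c[2] for c in run),         # end
        best[1] + params.window_bp // 2,  # summit (leftmost max window)
        best[3],                        # tag_count
        best[4],                        # input_scaled
        min(c[5] for c in run),         # p
        min(c[6] for c in run),         # q
    )


def hypergeom_sf_enum(fg_hits, M, K, N):
    """P(X >= fg_hits) for hypergeometric(M, K, N) by direct summation."""
    total = 0.0
    denom = math.comb(M, N)
    for k in range(fg_hits, min(K, N) + 1):
        if N - k <= M - K:
            total += math.comb(K, k) * math.comb(M - K, N - k) / denom
    return total
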