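"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the definitions, deliberately avoiding the
package's vectorised code paths: per-site loops, all-pairs scans and direct
transcriptions of the published estimator formulas.
"""

from __future__ import annotations

import numpy as np


def brute_site_stats(genotypes: np.ndarray) -> tuple[int, float, int]:
    """(alt count j, per-site pi, called alleles n) for one site's
    (samples, 2) genotype array with -1 as missing."""
    alleles = [a for pair in genotypes for a in pair if a >= 0]
    n = len(alleles)
    j = sum(1 for a in alleles if a > 0)
    if n < 2:
        return j, float("nan"), n
    pi = 2.0 * j * (n - j) / (n * (n - 1))
    return j, pi, n


def brute_window_pi(genotypes: np.ndarray, length: float) -> float:
    """Sum of per-site pi over all sites divided by the window length."""
    total = 0.0
    seen = 0
    for site in genotypes:
        _, pi, n = brute_site_stats(site)
        if n >= 2 and not np.isnan(pi):
            total += pi
            seen += 1
    return total / length if seen else float("nan")


def brute_tajima(genotypes: np.ndarray, n: int) -> float:
    """Tajima's D from first principles for complete-call genotypes."""
    S = 0
    pi_sum = 0.0
    for site in genotypes:
        j, pi, ncall = brute_site_stats(site)
        if 0 < j < ncall:
            S += 1
        pi_sum += pi
    if S == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def wc_fst_site(n1: int, n2: int, p1: float, p2: float, h1: float, h2: float):
    """Weir & Cockerham (1984) variance components, transcribed directly
    from the published equations for r = 2 populations.

    n_i diploid counts, p_i allele frequencies, h_i observed heterozygote
    proportions.  Returns (a, b, c).
    """
    r = 2
    n_bar = (n1 + n2) / r
    c2_ = ((n1 - n_bar) ** 2 + (n2 - n_bar) ** 2) / r / n_bar**2  # squared CV
    n_c = n_bar * (1 - c2_)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def brute_fst(genotypes: np.ndarray, cols1: list[int], cols2: list[int]) -> float:
    """Ratio-of-sums W&C FST over all usable sites via the site transcription."""
    num = den = 0.0
    for site in genotypes:
        parts = []
        for cols in (cols1, cols2):
            sub = site[cols]
            called = [pair for pair in sub if pair[0] >= 0]
            n = len(called)
            if n == 0:
                parts = None
                break
            alleles = [a for pair in called for a in pair]
            p = sum(1 for a in alleles if a > 0) / (2.0 * n)
            h = sum(1 for pair in called if pair[0] != pair[1]) / n
            parts.append((n, p, h))
        if parts is None or parts[0][0] + parts[1][0] < 2:
            continue
        (n1, p1, h1), (n2, p2, h2) = parts
        p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
        if p_bar in (0.0, 1.0):
            continue
        if n1 + n2 <= 2:
            continue
        a, b, c = wc_fst_site(n1, n2, p1, p2, h1, h2)
        num += a
        den += a + b + c
    return num / den if den else float("nan")


def brute_abba_baba(p1, p2, p3, p4):
    """Site-pattern sums and D / f_d from the closed forms, looped."""
    abba = baba = dnum = dden = 0.0
    for a, b, c, d in zip(p1, p2, p3, p4):
        site_abba = (1 - a) * b * c * (1 - d)
        site_baba = a * (1 - b) * c * (1 - d)
        abba += site_abba
        baba += site_baba
        pd = b if b >= c else c
        dnum += site_abba - site_baba
        dden += (1 - a) * pd * pd * (1 - d) - a * (1 - pd) * pd * (1 - d)
    D = (abba - baba) / (abba + baba) if abba + baba else float("nan")
    fd = dnum / dden if dden else float("nan")
    return abba, baba, D, fd


def brute_jackknife_se(num_blocks: np.ndarray, den_blocks: np.ndarray) -> float:
    """Delete-one jackknife SE of a ratio, evaluated literally."""
    m = len(num_blocks)
    tot_n, tot_d = sum(num_blocks), sum(den_blocks)
    loo = [(tot_n - num_blocks[i]) / (tot_d - den_blocks[i]) for i in range(m)]
    mean = sum(loo) / m
    return float(np.sqrt((m - 1) / m * sum((x - mean) ** 2 for x in loo)))


def brute_ibs(genotypes: np.ndarray, i: int, j: int) -> float:
    """Mean allele-sharing proportion between samples i and j."""
    vals = []
    for site in genotypes:
        a, b = site[i], site[j]
        if a[0] < 0 or b[0] < 0:
            continue
        a, b = sorted(a), list(b)
        shared = 0
        for x in a:
            if x in b:
                b.remove(x)
                shared += 1
        vals.append(shared / 2.0)
    return float(np.mean(vals)) if vals else float("nan")


def brute_vst(values: np.ndarray, idx_a, idx_b) -> float:
    """V_ST evaluated from the variance definitions with denominator N."""
    a = np.asarray([values[i] for i in idx_a], dtype=float)
    b = np.asarray([values[i] for i in idx_b], dtype=float)
    pooled = np.concatenate([a, b])
    vt = np.mean((pooled - pooled.mean()) ** 2)
    if vt == 0:
        return float("nan")
    va = np.mean((a - a.mean()) ** 2)
    vb = np.mean((b - b.mean()) ** 2)
    vs = (va * len(a) + vb * len(b)) / (len(a) + len(b))
    return (vt - vs) / vt


def brute_overlaps(gene_spans, window_spans):
    """All-pairs half-open interval intersection."""
    out = {}
    for gid, gc, gs, ge in gene_spans:
        hits = []
        for w, (wc, ws, we) in enumerate(window_spans):
            if wc == gc and ws < ge and we > gs:
                hits.append(w)
        out[gid] = hits
    return out


def brute_ehh(panel: np.ndarray, core: int, direction: int, truncate=0.05, positions=None):
    """EHH curve via explicit haplotype-string comparison at each extension."""
    n = panel.shape[1]
    pairs = n * (n - 1) // 2
    curve = [(0.0, 1.0)]
    idx = core
    while True:
        nxt = idx + direction
        if nxt < 0 or nxt >= panel.shape[0]:
            break
        lo, hi = (core + direction, nxt) if direction > 0 else (nxt, core + direction)
        seg = panel[lo:hi + 1]
        same = 0
        for i in range(n):
            for j in range(i + 1, n):
                if np.array_equal(seg[:, i], seg[:, j]):
                    same += 1
        ehh = same / pairs
        dist = abs(positions[nxt] - positions[core]) if positions is not None else abs(nxt - core)
        curve.append((dist, ehh))
        if ehh < truncate:
            break
        idx = nxt
    return curve
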