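"""Independent brute-force reference implementations.

Deliberately naive (loops, exhaustive enumeration, closed forms) so they
share no code path with the package; used to cross-check the vectorised
implementations on small instances.
"""

from __future__ import annotations

import math

import numpy as np


def count_reads_naive(bins, reads) -> np.ndarray:
    """O(reads x bins) interval scan; 5' start rule, strand-aware."""
    counts = np.zeros(len(bins), dtype=int)
    bin_rows = list(bins.itertuples())
    for read in reads.itertuples(index=False):
        fp = read.start if read.strand == "+" else read.end - 1
        for i, b in enumerate(bin_rows):
            if b.chrom == read.chrom and b.start <= fp < b.end:
                counts[i] += 1
                break
    return counts


def pearson_naive(x, y) -> float:
    """Covariance over the product of standard deviations, by the sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def classify_bins_naive(bins, genes) -> list[str]:
    """Per-bin precedence oracle built from explicit zone interval lists."""
    precedence = [
        "proximal_promoter",
        "intermediate_promoter",
        "distal_promoter",
        "exon",
        "intron",
        "intergenic",
    ]
    zones: dict[str, list[tuple[str, int, int]]] = {name: [] for name in precedence}
    for g in genes:
        tss = g.start if g.strand == "+" else g.end
        for name, (a, b) in {
            "proximal_promoter": (-200, 500),
            "intermediate_promoter": (-1000, -200),
            "distal_promoter": (-2200, -1000),
        }.items():
            if g.strand == "+":
                zones[name].append((g.chrom, tss + a, tss + b))
            else:
                zones[name].append((g.chrom, tss - b, tss - a))
        for s, e in g.exons:
            zones["exon"].append((g.chrom, s, e))
        zones["intron"].append((g.chrom, g.start, g.end))
    labels = []
    for b in bins.itertuples():
        label = "intergenic"
        for name in precedence:
            if any(c == b.chrom and b.start < hi and b.end > lo for c, lo, hi in zones[name]):
                label = name
                break
        labels.append(label)
    return labels


def cpg_oe_naive(seq: str) -> float:
    seq = seq.upper()
    c = seq.count("C")
    g = seq.count("G")
    cg = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CG")
    return cg * len(seq) / (c * g) if c and g else 0.0


def detect_cgi_naive(seq: str, min_len: int = 200, threshold: float = 0.6):
    """Exhaustive window enumeration + merge of overlapping windows."""
    qual = []
    for i in range(len(seq) - min_len + 1):
        w = seq[i:i + min_len].upper()
        if any(ch not in "ACGT" for ch in w):
            continue
        if cpg_oe_naive(w) > threshold:
            qual.append(i)
    islands = []
    for s in qual:
        if islands and s < islands[-1][1]:
            islands[-1] = (islands[-1][0], s + min_len)
        else:
            islands.append((s, s + min_len))
    return [(s, e) for s, e in islands if cpg_oe_naive(seq[s:e]) > threshold]


def hypergeom_tail_naive(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


def fst_naive(h1, h2) -> float:
    """Two-level AMOVA from the full 0/1 distance matrix, literal loops."""
    groups = [list(h1), list(h2)]
    allh = groups[0] + groups[1]
    N = len(allh)

    def ssd(items):
        n = len(items)
        total = 0.0
        for i in range(n):
            for j in range(n):
                total += 0.0 if items[i] == items[j] else 1.0
        return total / (2 * n)

    ssd_total = ssd(allh)
    ssd_within = ssd(groups[0]) + ssd(groups[1])
    ssd_among = ssd_total - ssd_within
    df_within = N - 2
    sigma_w = ssd_within / df_within
    n1, n2 = len(groups[0]), len(groups[1])
    n_c = (N - (n1 * n1 + n2 * n2) / N) / 1
    sigma_a = (ssd_among / 1 - sigma_w) / n_c
    if sigma_a + sigma_w == 0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)
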