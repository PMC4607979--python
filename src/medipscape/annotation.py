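"""Genomic-element annotation of bins and CpG-island detection.

Element classes follow the promoter-zone convention used throughout the
analysis, all strand-aware relative to the transcription start site (TSS):

* proximal promoter      -200 .. +500
* intermediate promoter  -1000 .. -200
* distal promoter        -2200 .. -1000

Bins falling in none of those zones are classed exon, intron or intergenic.
When a bin overlaps several features the precedence is
proximal > intermediate > distal > exon > intron > intergenic, so element
classes always partition the bin set.

CpG islands are CpG-dense tracts: any 200-bp window whose observed/expected
CpG ratio

    O/E = (#CpG dinucleotides * L) / (#C * #G)

exceeds 0.6 seeds an island; overlapping qualifying windows are merged into
maximal islands (Gardiner-Garden style O/E, no GC% criterion by default).
Detected islands are then classed into four region types relative to gene
models: promoter CGI (-1000..+300 around the TSS), intragenic CGI (TSS+300
to TES-300), 3'-transcript CGI (TES-300 to TES+1000) and intergenic CGI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# element precedence: higher wins
ELEMENT_ORDER = [
    "intergenic",
    "intron",
    "exon",
    "distal_promoter",
    "intermediate_promoter",
    "proximal_promoter",
]
CGI_ORDER = ["intergenic_cgi", "three_prime_cgi", "intragenic_cgi", "promoter_cgi"]

PROMOTER_ZONES = {
    # printed closed bounds relative to the TSS, converted to half-open
    "proximal_promoter": (-200, 500),
    "intermediate_promoter": (-1000, -200),
    "distal_promoter": (-2200, -1000),
}
CGI_PROMOTER_ZONE = (-1000, 300)   # around TSS
CGI_BODY_MARGIN = 300              # intragenic: TSS+300 .. TES-300
CGI_THREE_PRIME = (-300, 1000)     # around TES


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, transcript extent and exon structure.

    ``start``/``end`` are the 0-based half-open transcript span on the
    chromosome; the TSS is ``start`` for + genes and ``end`` for - genes
    (as a half-open anchor), and the TES is the opposite end.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid span {self.start}..{self.end}")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e > self.end or s >= e:
                raise ValueError(f"gene {self.gene_id}: invalid exon ({s},{e})")
            prev = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def zone(self, up: int, down: int, anchor: str = "tss") -> tuple[int, int]:
        """Half-open genomic interval for a strand-aware zone.

        ``up``/``down`` are signed offsets in transcription direction
        (negative = upstream) around the TSS or TES anchor.
        """
        pos = self.tss if anchor == "tss" else self.tes
        if self.strand == "+":
            return pos + up, pos + down
        return pos - down, pos - up


def _overlapping_bins(bins_chrom: tuple[np.ndarray, np.ndarray, np.ndarray], s: int, e: int):
    """Indices (into the global bin index) of bins overlapping [s, e)."""
    starts, ends, idx = bins_chrom
    if e <= s:
        return idx[0:0]
    lo = np.searchsorted(ends, s, side="right")
    hi = np.searchsorted(starts, e, side="left")
    return idx[lo:hi]


def _bins_by_chrom(bins: pd.DataFrame):
    out = {}
    for chrom, sub in bins.groupby("chrom", sort=False):
        out[chrom] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub.index.to_numpy(np.int64),
        )
    return out


def classify_bins(bins: pd.DataFrame, genes: list[GeneModel]) -> pd.Series:
    """Assign one element class to every bin.

    Overlap means any shared base pair; conflicts between zones or genes are
    resolved by the fixed precedence (proximal > intermediate > distal
    promoter > exon > intron > intergenic), so the result is a partition.
    """
    rank = {name: i for i, name in enumerate(ELEMENT_ORDER)}
    level = np.zeros(len(bins), dtype=np.int8)  # intergenic
    pos_of = {b: i for i, b in enumerate(bins.index)}
    by_chrom = _bins_by_chrom(bins)

    def paint(interval: tuple[int, int], chrom: str, cls: str) -> None:
        if chrom not in by_chrom:
            return
        r = rank[cls]
        for b in _overlapping_bins(by_chrom[chrom], *interval):
            i = pos_of[b]
            if level[i] < r:
                level[i] = r

    for gene in genes:
        paint((gene.start, gene.end), gene.chrom, "intron")
        for exon in gene.exons:
            paint(exon, gene.chrom, "exon")
        for cls, (up, down) in PROMOTER_ZONES.items():
            paint(gene.zone(up, down), gene.chrom, cls)
    labels = pd.Series(
        pd.Categorical.from_codes(level, categories=ELEMENT_ORDER), index=bins.index, name="element"
    )
    return labels


def _cpg_oe(seq: np.ndarray) -> tuple[float, float, int]:
    """(O/E, GC fraction, #CpG) of a byte-array sequence; O/E=0 if C or G absent."""
    c = int((seq == ord("C")).sum())
    g = int((seq == ord("G")).sum())
    cg = int(((seq[:-1] == ord("C")) & (seq[1:] == ord("G"))).sum())
    L = len(seq)
    oe = (cg * L) / (c * g) if c and g else 0.0
    return oe, (c + g) / L if L else 0.0, cg


def detect_cgi(
    genome: dict[str, str],
    min_len: int = 200,
    oe_threshold: float = 0.6,
    gc_min: float | None = None,
) -> pd.DataFrame:
    """Scan for CpG islands with a 1-bp-step sliding window.

    Every ``min_len`` window with CpG O/E above ``oe_threshold`` qualifies
    (windows containing N are skipped); overlapping qualifying windows are
    merged into maximal islands and the O/E is recomputed on the merged
    span.  An optional GC-fraction floor can be applied on the merged span.

    Returns a DataFrame ``chrom, start, end, cpg_oe, gc_frac``.
    """
    records = []
    L = min_len
    for chrom, seq in genome.items():
        s = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        n = len(s)
        if n < L:
            continue
        isC = (s == ord("C")).astype(np.int64)
        isG = (s == ord("G")).astype(np.int64)
        isN = (~np.isin(s, np.frombuffer(b"ACGT", dtype=np.uint8))).astype(np.int64)
        isCG = np.zeros(n, dtype=np.int64)
        isCG[:-1] = (s[:-1] == ord("C")) & (s[1:] == ord("G"))
        cC = np.concatenate([[0], np.cumsum(isC)])
        cG = np.concatenate([[0], np.cumsum(isG)])
        cN = np.concatenate([[0], np.cumsum(isN)])
        cCG = np.concatenate([[0], np.cumsum(isCG)])
        starts = np.arange(0, n - L + 1)
        C = cC[starts + L] - cC[starts]
        G = cG[starts + L] - cG[starts]
        N = cN[starts + L] - cN[starts]
        # CpG dinucleotides fully inside the window: starts in [w, w+L-2]
        CG = cCG[starts + L - 1] - cCG[starts]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where((C > 0) & (G > 0), CG * L / np.maximum(C * G, 1), 0.0)
        ok = (oe > oe_threshold) & (N == 0)
        qual = starts[ok]
        if qual.size == 0:
            continue
        # split chains of overlapping windows (gap < L between starts)
        breaks = np.flatnonzero(np.diff(qual) >= L)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [qual.size - 1]])
        for a, b in zip(run_starts, run_ends):
            lo, hi = int(qual[a]), int(qual[b]) + L
            oe_m, gc_m, _ = _cpg_oe(s[lo:hi])
            if oe_m <= oe_threshold:
                continue  # merged span diluted below threshold (rare)
            if gc_min is not None and gc_m < gc_min:
                continue
            records.append(
                {"chrom": chrom, "start": lo, "end": hi, "cpg_oe": oe_m, "gc_frac": gc_m}
            )
    return pd.DataFrame(records, columns=["chrom", "start", "end", "cpg_oe", "gc_frac"])


def classify_cgi_regions(cgis: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Class each island as promoter / intragenic / 3'-transcript / intergenic.

    Zones are strand-aware and islands spanning a boundary take the highest
    class by the precedence promoter > intragenic > 3'-transcript >
    intergenic.  Returns a copy with a ``region_class`` column.
    """
    rank = {name: i for i, name in enumerate(CGI_ORDER)}
    out = cgis.copy()
    level = np.zeros(len(cgis), dtype=np.int8)
    cs = cgis["chrom"].to_numpy()
    ss = cgis["start"].to_numpy(np.int64)
    es = cgis["end"].to_numpy(np.int64)

    def paint(gene: GeneModel, interval: tuple[int, int], cls: str) -> None:
        lo, hi = interval
        if hi <= lo:
            return
        hit = (cs == gene.chrom) & (ss < hi) & (es > lo)
        r = rank[cls]
        level[hit & (level < r)] = r

    for gene in genes:
        paint(gene, gene.zone(*CGI_THREE_PRIME, anchor="tes"), "three_prime_cgi")
        # intragenic: TSS+300 .. TES-300 in transcription direction
        if gene.strand == "+":
            paint(gene, (gene.tss + CGI_BODY_MARGIN, gene.tes - CGI_BODY_MARGIN), "intragenic_cgi")
        else:
            paint(gene, (gene.tes + CGI_BODY_MARGIN, gene.tss - CGI_BODY_MARGIN), "intragenic_cgi")
        paint(gene, gene.zone(*CGI_PROMOTER_ZONE), "promoter_cgi")
    out["region_class"] = pd.Categorical.from_codes(level, categories=CGI_ORDER)
    return out


def annotate_bins(
    bins: pd.DataFrame, genes: list[GeneModel], cgis: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Combine element classification and CGI membership per bin.

    Returns a DataFrame indexed like ``bins`` with columns ``element`` and
    ``cgi`` (the island's region class, or NA when the bin overlaps no
    island; overlaps with several islands take the highest class).
    """
    out = bins.copy()
    out["element"] = classify_bins(bins, genes)
    cgi_codes = np.full(len(bins), -1, dtype=np.int8)
    if cgis is not None and len(cgis):
        if "region_class" not in cgis.columns:
            cgis = classify_cgi_regions(cgis, genes)
        rank = {name: i for i, name in enumerate(CGI_ORDER)}
        pos_of = {b: i for i, b in enumerate(bins.index)}
        by_chrom = _bins_by_chrom(bins)
        for row in cgis.itertuples(index=False):
            if row.chrom not in by_chrom:
                continue
            r = rank[str(row.region_class)]
            for b in _overlapping_bins(by_chrom[row.chrom], row.start, row.end):
                i = pos_of[b]
                if cgi_codes[i] < r:
                    cgi_codes[i] = r
    out["cgi"] = pd.Categorical.from_codes(cgi_codes, categories=CGI_ORDER)
    return out


def element_profiles(scores: pd.DataFrame, annotated: pd.DataFrame) -> pd.DataFrame:
    """Mean enrichment per (class, unit) for element and CGI classes.

    ``scores`` columns are the units (breeds or samples); rows must be a
    subset of ``annotated``.  Classes with no bins get a missing mean, never
    zero.  Output is tidy: ``kind, cls, unit, mean_score, n_bins``.
    """
    ann = annotated.loc[scores.index]
    rows = []
    for kind, labels, categories in (
        ("element", ann["element"], ELEMENT_ORDER),
        ("cgi", ann["cgi"], CGI_ORDER),
    ):
        for cls in categories:
            mask = (labels == cls).to_numpy()
            n = int(mask.sum())
            for unit in scores.columns:
                mean = float(scores.loc[mask, unit].mean()) if n else float("nan")
                rows.append(
                    {"kind": kind, "cls": cls, "unit": unit, "mean_score": mean, "n_bins": n}
                )
    return pd.DataFrame(rows)
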