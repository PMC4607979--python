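"""Genome binning, read counting and MeDIP enrichment scoring.

MeDIP-seq read density is a *relative* methylation signal: the number of
immunoprecipitated fragments mapping to a region scales with its methylated
CpG content but cannot be converted to an absolute 0-100% methylation level.
The analysis therefore works on fixed-width genomic bins (300 bp by default)
and a depth- and length-normalised enrichment score,

    score = count * 1e9 / (width * total_unique_mapped_reads)

an RPKM variant evaluated per bin and per sample.  Bins supported by fewer
than ``min_total`` reads summed over all samples are discarded before any
statistics are computed, to avoid spurious enrichment in near-empty regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 300
DEFAULT_MIN_TOTAL = 10

BIN_COLUMNS = ["chrom", "start", "end"]


def make_bins(chrom_lengths: Mapping[str, int], width: int = DEFAULT_BIN_WIDTH) -> pd.DataFrame:
    """Tile each chromosome with fixed-width bins.

    Coordinates are 0-based half-open.  Each chromosome of length ``L``
    yields ``ceil(L / width)`` bins; the final bin is truncated at the
    chromosome end, so the bins partition the chromosome exactly.

    Returns a DataFrame with columns ``chrom``, ``start``, ``end`` and a
    RangeIndex giving the global bin ordinal.
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    frames = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has nonpositive length {length}")
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=BIN_COLUMNS)
    bins.index.name = "bin"
    return bins


@dataclass
class BinCounts:
    """Read counts per bin per sample plus per-sample library sizes.

    ``counts`` is a bins x samples integer DataFrame sharing its index with
    ``bins``.  ``totals`` holds the total uniquely mapped read count per
    sample (the denominator of the enrichment score) which includes reads
    that fell outside the binned chromosomes.
    """

    bins: pd.DataFrame
    counts: pd.DataFrame
    totals: pd.Series
    breed_of: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def __post_init__(self) -> None:
        if not self.bins.index.equals(self.counts.index):
            raise ValueError("bins and counts must share an index")
        bad = self.counts.sum(axis=0) > self.totals.reindex(self.counts.columns)
        if bad.any():
            raise ValueError(
                f"binned counts exceed total mapped reads for samples: {list(bad[bad].index)}"
            )


def _five_prime(reads: pd.DataFrame) -> np.ndarray:
    """Strand-aware 5' position: start for +, end-1 for -."""
    strand = reads["strand"].to_numpy()
    fp = reads["start"].to_numpy(dtype=np.int64).copy()
    minus = strand == "-"
    fp[minus] = reads["end"].to_numpy(dtype=np.int64)[minus] - 1
    return fp


def count_reads(
    bins: pd.DataFrame,
    reads_by_sample: Mapping[str, pd.DataFrame],
    breed_of: Mapping[str, str] | None = None,
) -> BinCounts:
    """Attribute each read to the single bin containing its 5' start.

    A read is never split or double counted: the strand-aware 5' position
    (start for ``+`` reads, ``end - 1`` for ``-`` reads) determines its bin.
    Reads on chromosomes absent from ``bins`` or beyond the binned extent are
    tallied and logged, not binned; they still count toward the sample's
    total mapped reads.
    """
    # per-chromosome sorted starts/ends for subset-safe lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in bins.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub.index.to_numpy(np.int64),
        )
    nbins = len(bins)
    counts = {}
    totals = {}
    for sample, reads in reads_by_sample.items():
        vec = np.zeros(nbins, dtype=np.int64)
        unbinned = 0
        totals[sample] = len(reads)
        for chrom, sub in reads.groupby("chrom", sort=False):
            if chrom not in by_chrom:
                unbinned += len(sub)
                continue
            starts, ends, idx = by_chrom[chrom]
            fp = _five_prime(sub)
            pos = np.searchsorted(starts, fp, side="right") - 1
            ok = (pos >= 0) & (fp < ends[np.clip(pos, 0, len(ends) - 1)])
            unbinned += int((~ok).sum())
            hit = idx[pos[ok]]
            vec += np.bincount(hit, minlength=nbins)
        if unbinned:
            logger.info("%s: %d reads outside binned regions (not binned)", sample, unbinned)
        counts[sample] = vec
    counts_df = pd.DataFrame(counts, index=bins.index)
    return BinCounts(
        bins=bins,
        counts=counts_df,
        totals=pd.Series(totals, dtype=np.int64),
        breed_of=dict(breed_of or {}),
    )


def filter_bins(
    matrix: BinCounts, min_total: int = DEFAULT_MIN_TOTAL, per_sample: bool = False
) -> BinCounts:
    """Drop low-coverage bins.

    By default a bin is retained when its read count summed over *all*
    samples is at least ``min_total`` (the aggregate reading of a
    "fewer than 10 reads across all individuals" rule).  With
    ``per_sample=True`` every sample individually must reach ``min_total``.
    Bin order is preserved.
    """
    if per_sample:
        keep = (matrix.counts >= min_total).all(axis=1)
    else:
        keep = matrix.counts.sum(axis=1) >= min_total
    return replace(matrix, bins=matrix.bins.loc[keep], counts=matrix.counts.loc[keep])


def enrichment_score(count, total_unique_mapped, width: int = DEFAULT_BIN_WIDTH):
    """Depth- and length-normalised enrichment score.

    score = count * 1e9 / (width * total_unique_mapped).  Accepts scalars or
    arrays (broadcast).  ``total_unique_mapped`` must be positive.
    """
    total = np.asarray(total_unique_mapped, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total_unique_mapped must be positive")
    out = np.asarray(count, dtype=float) * 1e9 / (width * total)
    return out if out.ndim else float(out)


def enrichment_matrix(matrix: BinCounts, width: int = DEFAULT_BIN_WIDTH) -> pd.DataFrame:
    """Per-bin per-sample enrichment scores from a count matrix."""
    totals = matrix.totals.reindex(matrix.counts.columns).to_numpy(dtype=float)
    scores = enrichment_score(matrix.counts.to_numpy(dtype=float), totals[None, :], width)
    return pd.DataFrame(scores, index=matrix.counts.index, columns=matrix.counts.columns)


def windowed_rpkm(
    chrom_lengths: Mapping[str, int],
    reads_by_sample: Mapping[str, pd.DataFrame],
    window: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coarse genome-wide methylation landscape.

    Applies the enrichment-score formula with ``width = window`` (100 kb by
    default), one track per sample.  Returns ``(windows, scores)``.
    """
    wins = make_bins(chrom_lengths, window)
    bc = count_reads(wins, reads_by_sample)
    return wins, enrichment_matrix(bc, width=window)


def replicate_qc_and_average(
    scores: pd.DataFrame, breed_of: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-breed replicate concordance and per-breed averaging.

    For every within-breed replicate pair the Pearson correlation of the two
    score vectors over retained bins is reported; the breed-level score of a
    bin is the arithmetic mean of its replicate scores.  Averaging scores
    (already depth-normalised) rather than raw counts keeps samples of
    unequal depth commensurable.

    Returns ``(breed_scores, qc)`` where ``qc`` has one row per replicate
    pair with columns ``breed, sample_a, sample_b, pearson_r``.
    """
    missing = [s for s in scores.columns if s not in breed_of]
    if missing:
        raise ValueError(f"samples without a breed label: {missing}")
    breeds: dict[str, list[str]] = {}
    for sample in scores.columns:
        breeds.setdefault(breed_of[sample], []).append(sample)
    qc_rows = []
    breed_cols = {}
    for breed, samples in breeds.items():
        if len(samples) < 2:
            logger.warning("breed %s has a single replicate: QC skipped", breed)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a, b = scores[samples[i]], scores[samples[j]]
                qc_rows.append(
                    {
                        "breed": breed,
                        "sample_a": samples[i],
                        "sample_b": samples[j],
                        "pearson_r": float(np.corrcoef(a, b)[0, 1]),
                    }
                )
        breed_cols[breed] = scores[samples].mean(axis=1)
    qc = pd.DataFrame(qc_rows, columns=["breed", "sample_a", "sample_b", "pearson_r"])
    return pd.DataFrame(breed_cols, index=scores.index), qc
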