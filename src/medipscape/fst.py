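"""Haplotype collapsing and AMOVA-based pairwise Fst with permutation tests.

Aligned sequences (e.g. a mitochondrial D-loop amplicon per individual) are
collapsed to haplotypes by exact identity after complete deletion of sites
containing gaps or ambiguous bases.  Population differentiation is then the
fixation index Fst from a two-level analysis of molecular variance on
haplotype identity (0/1) distances,

    Fst = sigma2_among / (sigma2_among + sigma2_within),

which is the haplotype-frequency (distance-free) form of the statistic and
may legitimately be slightly negative when within-population variation
exceeds the between-population component.  Significance is assessed by
permuting individuals between the two populations and recomputing Fst; the
add-one estimator p = (1 + #{Fst_perm >= Fst_obs}) / (n_perm + 1) avoids
exact zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING = set("-Nn.?")


@dataclass
class HaplotypeDataset:
    """Individuals with population labels and collapsed haplotype ids.

    ``haplotype_id`` is an integer per individual; identical (post-deletion,
    uppercased) sequences share an id.  ``n_sites_dropped`` records how many
    alignment columns were removed for gaps/ambiguity.
    """

    individuals: list[str]
    populations: pd.Series  # individual -> population label
    haplotype_id: pd.Series  # individual -> integer id
    n_haplotypes: int
    n_sites_dropped: int = 0

    def pops(self) -> list[str]:
        return sorted(self.populations.unique())

    def hap_array(self, pop: str) -> np.ndarray:
        mask = self.populations == pop
        return self.haplotype_id[mask].to_numpy()


@dataclass
class FstResult:
    """Symmetric pairwise Fst matrix with optional permutation P-values."""

    fst: pd.DataFrame
    p_perm: pd.DataFrame | None = None
    n_permutations: int = 0


def collapse_haplotypes(
    sequences: Mapping[str, str], population_of: Mapping[str, str]
) -> HaplotypeDataset:
    """Collapse aligned sequences to exact-identity haplotypes.

    Sequences are uppercased; any alignment column containing a gap, N or
    other ambiguity in *any* individual is dropped (complete deletion)
    before comparison.  Length mismatches are an error.
    """
    names = list(sequences)
    if not names:
        raise ValueError("no sequences")
    missing = [n for n in names if n not in population_of]
    if missing:
        raise ValueError(f"individuals without a population label: {missing}")
    seqs = [sequences[n].upper() for n in names]
    L = len(seqs[0])
    for n, s in zip(names, seqs):
        if len(s) != L:
            raise ValueError(f"sequence {n!r} has length {len(s)}, expected {L}")
    arr = np.array([list(s) for s in seqs])
    bad = np.zeros(L, dtype=bool)
    for ch in _MISSING:
        bad |= (arr == ch.upper()).any(axis=0)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("dropped %d alignment columns with gaps/ambiguity", n_dropped)
    clean = arr[:, ~bad]
    seen: dict[bytes, int] = {}
    ids = []
    for row in clean:
        key = row.tobytes()
        ids.append(seen.setdefault(key, len(seen)))
    return HaplotypeDataset(
        individuals=names,
        populations=pd.Series({n: population_of[n] for n in names}, name="population"),
        haplotype_id=pd.Series(ids, index=names, name="haplotype_id"),
        n_haplotypes=len(seen),
        n_sites_dropped=n_dropped,
    )


def _fst_two(h1: np.ndarray, h2: np.ndarray) -> float:
    """Two-population AMOVA Fst on haplotype-identity distances.

    With 0/1 distances the sums of squared deviations reduce to haplotype
    counts: for a group of size n with haplotype counts c_k,
    SSD = (n^2 - sum c_k^2) / (2n).  Variance components follow the standard
    two-level AMOVA decomposition.
    """

    def ssd(h: np.ndarray) -> float:
        n = len(h)
        _, counts = np.unique(h, return_counts=True)
        return (n * n - float((counts ** 2).sum())) / (2.0 * n)

    n1, n2 = len(h1), len(h2)
    N = n1 + n2
    ssd_total = ssd(np.concatenate([h1, h2]))
    ssd_within = ssd(h1) + ssd(h2)
    ssd_among = ssd_total - ssd_within
    df_among, df_within = 1, N - 2
    sigma_w = ssd_within / df_within if df_within > 0 else 0.0
    n_c = (N - (n1 * n1 + n2 * n2) / N) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0  # no variation at all
    return float(sigma_a / denom)


def pairwise_fst(dataset: HaplotypeDataset) -> FstResult:
    """Point estimates of Fst for every population pair."""
    pops = dataset.pops()
    for pop in pops:
        if len(dataset.hap_array(pop)) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in combinations(pops, 2):
        value = _fst_two(dataset.hap_array(a), dataset.hap_array(b))
        fst.loc[a, b] = fst.loc[b, a] = value
    return FstResult(fst=fst)


def fst_permutation(
    dataset: HaplotypeDataset, n_perm: int = 1000, seed: int | None = None
) -> FstResult:
    """Pairwise Fst with permutation P-values.

    For each pair, individuals are pooled and reallocated to the two
    populations (sizes preserved) ``n_perm`` times; p is the add-one
    fraction of permuted Fst values at least as large as the observed one.
    Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    point = pairwise_fst(dataset)
    pops = dataset.pops()
    p = pd.DataFrame(1.0, index=pops, columns=pops)
    for a, b in combinations(pops, 2):
        ha, hb = dataset.hap_array(a), dataset.hap_array(b)
        pooled = np.concatenate([ha, hb])
        obs = point.fst.loc[a, b]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _fst_two(perm[: len(ha)], perm[len(ha):]) >= obs:
                hits += 1
        p.loc[a, b] = p.loc[b, a] = (1.0 + hits) / (n_perm + 1.0)
    np.fill_diagonal(p.values, 1.0)
    return FstResult(fst=point.fst, p_perm=p, n_permutations=n_perm)
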