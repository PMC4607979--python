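"""Differentially methylated region (DMR) calling and downstream analyses.

A DMR is a retained bin whose enrichment score differs between at least one
pair of breeds by a two-sample t-test at raw P < 0.05 (with 4 breeds there
are exactly C(4,2) = 6 pairs).  The test is Student's pooled-variance t: with
two replicates per breed the Welch degrees of freedom degenerate, and the
pooled form is exact under equal group variances.  No multiple-testing
correction is applied in DMR calling; Benjamini-Hochberg adjustment is used
only in gene-set enrichment, where many sets are tested jointly.

Breed specificity uses the strictest consistent rule: a bin is specific to
breed B when all three comparisons involving B are significant with B on the
same side each time, and no comparison among the other breeds is
significant.  The rule is deliberately pluggable (``alpha`` and the strict
flag are parameters).

Breed relationships are summarised by average-linkage hierarchical
clustering of intergenic bin profiles under the 1 - Pearson correlation
distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

PSEUDO_SCORE = 0.01  # added to zero breed means so fold changes stay finite


@dataclass
class PairwiseResults:
    """Per-bin t, P and fold change for every unordered breed pair.

    ``t``, ``p`` and ``fold_change`` are bins x pairs DataFrames whose
    columns are ``"A_vs_B"`` strings; ``fold_change`` is mean(A)/mean(B)
    with a pseudo-score guarding zero means.  ``breed_means`` holds the
    per-breed mean score per bin.
    """

    pairs: list[tuple[str, str]]
    t: pd.DataFrame
    p: pd.DataFrame
    fold_change: pd.DataFrame
    breed_means: pd.DataFrame

    @staticmethod
    def pair_label(a: str, b: str) -> str:
        return f"{a}_vs_{b}"


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sample pooled-variance t-test along axis 1.

    Returns (t, p).  Bins where both groups have zero variance are assigned
    t = 0, p = 1 (no usable within-group information).
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, (ma - mb) / np.where(degenerate, 1.0, se))
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, p


def pairwise_tests(
    scores: pd.DataFrame, breed_of: Mapping[str, str]
) -> PairwiseResults:
    """t-test every retained bin across every unordered breed pair.

    ``scores`` is bins x samples; each breed needs at least two samples.
    Fold change is the ratio of breed mean scores (pair order A/B), with a
    pseudo-score of 0.01 substituted for zero means.
    """
    groups: dict[str, list[str]] = {}
    for sample in scores.columns:
        if sample not in breed_of:
            raise ValueError(f"sample {sample!r} has no breed label")
        groups.setdefault(breed_of[sample], []).append(sample)
    for breed, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"breed {breed!r} has fewer than 2 samples")
    breeds = sorted(groups)
    arrays = {b: scores[groups[b]].to_numpy(dtype=float) for b in breeds}
    means = pd.DataFrame({b: arrays[b].mean(axis=1) for b in breeds}, index=scores.index)
    pairs = list(combinations(breeds, 2))
    t_cols, p_cols, fc_cols = {}, {}, {}
    for a, b in pairs:
        label = PairwiseResults.pair_label(a, b)
        t, p = _pooled_t(arrays[a], arrays[b])
        ma = means[a].to_numpy().copy()
        mb = means[b].to_numpy().copy()
        ma[ma == 0] = PSEUDO_SCORE
        mb[mb == 0] = PSEUDO_SCORE
        t_cols[label], p_cols[label], fc_cols[label] = t, p, ma / mb
    idx = scores.index
    return PairwiseResults(
        pairs=pairs,
        t=pd.DataFrame(t_cols, index=idx),
        p=pd.DataFrame(p_cols, index=idx),
        fold_change=pd.DataFrame(fc_cols, index=idx),
        breed_means=means,
    )


def call_dmrs(results: PairwiseResults, alpha: float = 0.05, adjust: bool = False) -> pd.DataFrame:
    """Call a bin a DMR when any pair is significant at ``alpha``.

    Raw per-pair P-values are used by default; ``adjust=True`` applies
    Benjamini-Hochberg across bins within each pair first.  Returns a
    DataFrame indexed like the score matrix with ``is_dmr``, ``n_sig_pairs``,
    ``min_p`` and one boolean ``sig_<pair>`` column per pair.
    """
    p = results.p
    if adjust:
        p = p.apply(lambda col: multipletests(col, method="fdr_bh")[1], axis=0)
    sig = p < alpha
    out = pd.DataFrame(index=p.index)
    out["is_dmr"] = sig.any(axis=1)
    out["n_sig_pairs"] = sig.sum(axis=1)
    out["min_p"] = p.min(axis=1)
    for col in p.columns:
        out[f"sig_{col}"] = sig[col]
    return out


def fold_change_filter(
    dmrs: pd.DataFrame, results: PairwiseResults, low: float = 0.5, high: float = 2.0
) -> pd.DataFrame:
    """Keep DMRs with a strong effect in at least one comparison.

    Strict inequalities: a fold change must exceed ``high`` or fall below
    ``low`` in some pair; a fold change exactly at a bound does not qualify.
    """
    fc = results.fold_change.loc[dmrs.index]
    strong = ((fc > high) | (fc < low)).any(axis=1)
    return dmrs.loc[dmrs["is_dmr"] & strong]


def breed_specific_dmrs(
    results: PairwiseResults, alpha: float = 0.05, exclusive: bool = True
) -> pd.Series:
    """Assign each bin the breed (if any) whose methylation sets it apart.

    A bin is specific to breed B when every comparison involving B is
    significant with consistent direction (B above, or below, all other
    breeds).  With ``exclusive=True`` (default) additionally no comparison
    among the remaining breeds may be significant.  Returns a Series of
    breed labels with NA elsewhere.
    """
    breeds = sorted({b for pair in results.pairs for b in pair})
    sig = (results.p < alpha).to_numpy()
    idx = results.p.index
    labels = {PairwiseResults.pair_label(a, b): k for k, (a, b) in enumerate(results.pairs)}
    means = results.breed_means
    specific = pd.Series(pd.array([pd.NA] * len(idx), dtype="string"), index=idx)
    for breed in breeds:
        involve, direction = [], []
        others = []
        for a, b in results.pairs:
            k = labels[PairwiseResults.pair_label(a, b)]
            if breed == a:
                involve.append(k)
                direction.append(np.sign(means[a].to_numpy() - means[b].to_numpy()))
            elif breed == b:
                involve.append(k)
                direction.append(np.sign(means[b].to_numpy() - means[a].to_numpy()))
            else:
                others.append(k)
        all_sig = sig[:, involve].all(axis=1)
        dirs = np.stack(direction, axis=1)
        consistent = (np.abs(dirs.sum(axis=1)) == dirs.shape[1]) & (dirs != 0).all(axis=1)
        ok = all_sig & consistent
        if exclusive and others:
            ok &= ~sig[:, others].any(axis=1)
        specific[ok] = breed
    return specific.rename("specific_to")


def map_dmrs_to_genes(
    dmr_bins: pd.DataFrame,
    genes: Sequence,
    promoter_upstream: int = 2200,
    promoter_downstream: int = 500,
) -> pd.Series:
    """List, per DMR bin, every gene whose promoter or body it overlaps.

    The gene extent is the transcript span united with the strand-aware
    promoter (up to ``promoter_upstream`` bp upstream and
    ``promoter_downstream`` bp downstream of the TSS).  A bin spanning two
    genes is assigned to both.  Returns a Series of gene-id tuples.
    """
    hits: list[tuple[str, ...]] = []
    cs = dmr_bins["chrom"].to_numpy()
    ss = dmr_bins["start"].to_numpy(np.int64)
    es = dmr_bins["end"].to_numpy(np.int64)
    extents = []
    for gene in genes:
        ps, pe = gene.zone(-promoter_upstream, promoter_downstream)
        extents.append((gene.chrom, min(gene.start, ps), max(gene.end, pe), gene.gene_id))
    for i in range(len(dmr_bins)):
        found = [
            gid
            for chrom, lo, hi, gid in extents
            if chrom == cs[i] and ss[i] < hi and es[i] > lo
        ]
        hits.append(tuple(found))
    return pd.Series(hits, index=dmr_bins.index, name="gene_ids")


def differentially_methylated_genes(
    gene_hits: pd.Series, specific_to: pd.Series | None = None
) -> dict[str, list[str]]:
    """Deduplicated gene lists, overall and (optionally) per breed set."""
    out: dict[str, set[str]] = {"all": set()}
    for bin_id, genes in gene_hits.items():
        out["all"].update(genes)
        if specific_to is not None:
            breed = specific_to.get(bin_id)
            if pd.notna(breed):
                out.setdefault(str(breed), set()).update(genes)
    return {k: sorted(v) for k, v in out.items()}


def gene_set_enrichment(
    dmg: Sequence[str],
    background: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of DMGs in named gene sets.

    For each set the upper-tail hypergeometric probability of drawing at
    least the observed overlap is computed, then Benjamini-Hochberg adjusted
    across sets.  ``dmg`` must be a subset of ``background``; sets are
    intersected with the background.
    """
    bg = set(background)
    fg = set(dmg)
    offenders = sorted(fg - bg)
    if offenders:
        raise ValueError(f"DMG not in background: {offenders}")
    N, n = len(bg), len(fg)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & bg)
        k = len(set(members) & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K, "p_value": p})
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p_value"])
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = []
    return df


def cluster_breeds(scores: pd.DataFrame) -> tuple[np.ndarray, str]:
    """Average-linkage clustering of units under 1 - Pearson distance.

    ``scores`` is bins x units (typically breed-averaged intergenic bins,
    restricted to bins covered in every unit).  Columns are sorted by label
    first so leaf order is deterministic.  Returns ``(linkage, newick)``.
    """
    units = sorted(scores.columns)
    if len(units) < 2:
        raise ValueError("need at least 2 units to cluster")
    X = scores[units].to_numpy(dtype=float).T
    if X.shape[1] < 2:
        raise ValueError("need at least 2 usable bins")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.average(squareform(dist, checks=False))
    tree = hierarchy.to_tree(Z)

    def newick(node, parent_height: float) -> str:
        length = max(parent_height - (node.dist if not node.is_leaf() else 0.0), 0.0)
        if node.is_leaf():
            return f"{units[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return Z, newick(tree, tree.dist) + ";"


def outgroup_unit(Z: np.ndarray, labels: Sequence[str]) -> str | None:
    """The unit that joins last, if the final merge splits off a singleton."""
    n = len(labels)
    last = Z[-1]
    for side in (int(last[0]), int(last[1])):
        if side < n:
            return labels[side]
    return None
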