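"""qPCR relative expression, CpG-site group tests and methylation coupling.

Relative expression follows the E^(-ddCt) convention: per sample, technical
replicate Ct values are averaged per gene, the target Ct is normalised by
the mean of the reference-gene Cts (dCt), then by the mean dCt of a
calibrator group (ddCt), and expression is E**(-ddCt) with amplification
efficiency base E = 2 by default.  Reference aggregation uses the
arithmetic mean of Cts, equivalent to geometric-mean quantity normalisation
at a common efficiency.

Per-CpG-site breed differences use the same pooled-variance t-test as the
bin-level DMR analysis; methylation-expression (or methylation-protein)
association uses the Pearson correlation with the exact t-based P-value
p from t = r * sqrt(n-2) / sqrt(1-r^2).

MBMI (modified body mass index) = body weight / body length squared, in
kg/m^2, with length measured shoulder to ischium.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from medipscape.dmr import _pooled_t

DEFAULT_REFERENCE_GENES = ("ACTB", "RPL19")
DEFAULT_EFFICIENCY = 2.0


def relative_expression(
    records: pd.DataFrame,
    calibrator: Sequence[str],
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
    efficiency: float | Mapping[str, float] = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """E^(-ddCt) relative expression per sample per target gene.

    ``records`` needs columns ``sample, gene, role, ct`` (role is
    ``target`` or ``reference``); repeated wells for the same sample/gene
    are averaged first.  ``calibrator`` lists the samples whose mean dCt
    anchors ddCt = 0 (their mean relative expression is 1 per gene).
    ``efficiency`` may be a scalar or a per-gene mapping.

    Returns a samples x genes DataFrame of relative expression values.
    """
    required = {"sample", "gene", "role", "ct"}
    if not required.issubset(records.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    ct = records.groupby(["sample", "gene"], sort=False)["ct"].mean().unstack("gene")
    roles = records.drop_duplicates("gene").set_index("gene")["role"]
    refs = [g for g in reference_genes if g in ct.columns]
    if len(refs) != len(reference_genes):
        raise ValueError(f"reference genes missing from table: "
                         f"{sorted(set(reference_genes) - set(ct.columns))}")
    bad = ct[refs].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"samples missing a reference-gene Ct: {list(ct.index[bad])}")
    missing_cal = [s for s in calibrator if s not in ct.index]
    if missing_cal:
        raise ValueError(f"calibrator samples absent from table: {missing_cal}")
    targets = [g for g in ct.columns if g not in set(refs) and roles.get(g) != "reference"]
    ref_mean = ct[refs].mean(axis=1)
    dct = ct[targets].sub(ref_mean, axis=0)
    ddct = dct.sub(dct.loc[list(calibrator)].mean(axis=0), axis=1)
    if isinstance(efficiency, Mapping):
        E = pd.Series({g: efficiency.get(g, DEFAULT_EFFICIENCY) for g in targets})
        return pd.DataFrame(
            np.power(E.to_numpy()[None, :], -ddct.to_numpy()),
            index=ddct.index,
            columns=targets,
        )
    return efficiency ** (-ddct)


def site_group_test(methylation: pd.DataFrame, breed_of: Mapping[str, str]) -> pd.DataFrame:
    """Two-sample t-test per CpG site per breed pair.

    ``methylation`` needs columns ``region, site, sample, fraction``.  Each
    breed must contribute at least two samples per site.  Sites where both
    groups are constant get p = 1.  Returns a tidy DataFrame
    ``region, site, breed_a, breed_b, t, p_value``.
    """
    required = {"region", "site", "sample", "fraction"}
    if not required.issubset(methylation.columns):
        raise ValueError(f"methylation table must have columns {sorted(required)}")
    meth = methylation.copy()
    meth["breed"] = meth["sample"].map(dict(breed_of))
    if meth["breed"].isna().any():
        orphans = sorted(meth.loc[meth["breed"].isna(), "sample"].unique())
        raise ValueError(f"samples without a breed label: {orphans}")
    rows = []
    for (region, site), sub in meth.groupby(["region", "site"], sort=False):
        groups = {b: g["fraction"].to_numpy(dtype=float) for b, g in sub.groupby("breed")}
        for a, b in combinations(sorted(groups), 2):
            xa, xb = groups[a], groups[b]
            if len(xa) < 2 or len(xb) < 2:
                raise ValueError(f"site {region}/{site}: breed with <2 samples")
            t, p = _pooled_t(xa[None, :], xb[None, :])
            rows.append(
                {"region": region, "site": site, "breed_a": a, "breed_b": b,
                 "t": float(t[0]), "p_value": float(p[0])}
            )
    return pd.DataFrame(rows, columns=["region", "site", "breed_a", "breed_b", "t", "p_value"])


def methylation_expression_correlation(
    methylation: pd.DataFrame,
    values: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of per-sample CpG methylation with expression.

    ``methylation`` is the tidy site table (``region, site, sample,
    fraction``); ``values`` is samples x genes (relative expression or
    protein level).  ``pairs`` restricts testing to (region, site, gene)
    triples; by default every site is tested against every gene.  Sites or
    genes with zero variance across the shared samples yield missing r/p
    rather than a number.

    Returns ``region, site, gene, n, r, p_value``.
    """
    rows = []
    site_tables = {
        (region, site): sub.set_index("sample")["fraction"]
        for (region, site), sub in methylation.groupby(["region", "site"], sort=False)
    }
    if pairs is None:
        pairs = [(r, s, g) for (r, s) in site_tables for g in values.columns]
    for region, site, gene in pairs:
        m = site_tables.get((region, site))
        if m is None or gene not in values.columns:
            raise KeyError(f"unknown site or gene: {(region, site, gene)}")
        shared = m.index.intersection(values.index)
        x = m.loc[shared].to_numpy(dtype=float)
        y = values.loc[shared, gene].to_numpy(dtype=float)
        n = len(shared)
        if n < 3:
            raise ValueError(f"{region}/{site} vs {gene}: fewer than 3 paired samples")
        if np.std(x) == 0 or np.std(y) == 0:
            r = p = float("nan")
        else:
            r, p = stats.pearsonr(x, y)
        rows.append(
            {"region": region, "site": site, "gene": gene, "n": n,
             "r": float(r), "p_value": float(p)}
        )
    return pd.DataFrame(rows, columns=["region", "site", "gene", "n", "r", "p_value"])


def mbmi(weight: float, length: float) -> float:
    """Modified body mass index: weight / length**2 (kg/m^2)."""
    if weight <= 0 or length <= 0:
        raise ValueError("weight and length must be positive")
    return weight / length ** 2
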