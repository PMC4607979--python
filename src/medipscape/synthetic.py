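"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a four-breed MeDIP-seq study design (two biological
replicates per breed) at desk scale:

* a genome whose background is CpG-free (an idealised extreme of vertebrate
  CpG depletion) with CpG-dense island tracts spliced in, half of them at
  gene promoters;
* per-bin read-sampling propensities with element-dependent baselines
  (exons above introns, promoter-CGI bins strongly suppressed), shared
  lognormal bin-to-bin heterogeneity, and planted breed-specific
  differentially methylated bins at a configurable propensity fold;
* per-sample reads drawn multinomially with per-bin lognormal replicate
  noise, calibrated so default settings reproduce within-breed replicate
  Pearson correlations of ~0.99;
* multi-population haplotype samples drawn from Dirichlet-perturbed
  frequency vectors with a divergence dial (0 = identical frequencies,
  1 = fixed differences);
* qPCR Ct tables in which designated target genes are linearly coupled to
  per-sample CpG-site methylation, plus stable reference genes.

Every output is deterministic under the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from medipscape.annotation import GeneModel, classify_bins
from medipscape.binning import make_bins

ELEMENT_BASELINES = {
    "exon": 2.0,
    "intron": 1.0,
    "intergenic": 0.8,
    "distal_promoter": 0.7,
    "intermediate_promoter": 0.9,
    "proximal_promoter": 1.2,
}
PROMOTER_CGI_FACTOR = 0.25  # promoter islands are rarely methylated


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults model the study design end to end: 4 breeds x 2 replicates of
    MeDIP coverage over 2,000 bins of 300 bp, 120 planted breed-specific
    DMR bins at 4-fold propensity difference, 4 populations x 40 haplotyped
    individuals, and 9 muscle samples (3 breeds x 3) with two
    methylation-coupled target genes of opposite slope sign.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 200_000}
    )
    n_genes: int = 60
    breeds: tuple[str, ...] = ("UQ", "Tan", "StH", "Hu")
    replicates_per_breed: int = 2
    reads_per_sample: int = 600_000
    read_length: int = 50
    bin_width: int = 300
    n_planted_dmrs: int = 120
    dmr_fold: float = 4.0
    replicate_noise_sd: float = 0.05
    propensity_jitter_sd: float = 0.8
    cpg_island_fraction: float = 0.02
    divergent_breed: str | None = None
    divergence_sd: float = 0.0
    # haplotype simulation
    n_populations: int = 4
    individuals_per_population: int = 40
    n_root_haplotypes: int = 12
    haplotype_length: int = 600
    divergence: float = 0.3
    # expression simulation
    expression_breeds: tuple[str, ...] = ("UQ", "Tan", "StH")
    expression_samples_per_breed: int = 3
    expression_coupling: tuple[tuple[str, str, float, float], ...] = (
        ("AKT1", "1CpG", 3.0, 0.17),
        ("TSC1", "6CpG", -3.0, 0.17),
    )
    reference_ct_noise_sd: float = 0.05
    well_noise_sd: float = 0.02
    baseline_ct: float = 26.0
    protein_coupling: tuple[tuple[str, float], ...] = (("TSC1", -1.0),)
    mbmi_means: dict[str, float] = field(
        default_factory=lambda: {"UQ": 84.78, "Tan": 61.54, "StH": 72.78, "Hu": 73.19}
    )

    def __post_init__(self) -> None:
        if self.dmr_fold < 1:
            raise ValueError("dmr_fold must be >= 1")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be nonnegative")
        if not 0 <= self.cpg_island_fraction <= 1:
            raise ValueError("cpg_island_fraction must be in [0, 1]")
        for name in ("replicates_per_breed", "reads_per_sample", "bin_width", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0 or self.n_planted_dmrs < 0:
            raise ValueError("counts must be nonnegative")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be nonempty")

    @property
    def samples(self) -> list[str]:
        return [f"{b}_rep{i + 1}" for b in self.breeds for i in range(self.replicates_per_breed)]

    @property
    def breed_of(self) -> dict[str, str]:
        return {f"{b}_rep{i + 1}": b
                for b in self.breeds for i in range(self.replicates_per_breed)}

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per simulation stage."""
        return np.random.default_rng([self.seed, stream])

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("breeds", "expression_breeds"):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("expression_coupling", "protein_coupling"):
            if key in data:
                data[key] = tuple(tuple(item) for item in data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key in ("breeds", "expression_breeds", "expression_coupling", "protein_coupling"):
            data[key] = [list(v) if isinstance(v, tuple) else v for v in data[key]]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating inputs.

    ``propensity`` is bins x breeds, scaled into (0, 1]; every planted DMR
    bin has a propensity ratio of exactly ``dmr_fold`` (or its reciprocal)
    between its breed and every other breed.
    """

    bins: pd.DataFrame
    propensity: pd.DataFrame
    planted: pd.DataFrame  # columns: bin, breed, direction, fold
    cgi_tracts: pd.DataFrame  # chrom, start, end, at_promoter
    bin_cpg: pd.Series  # CpG dinucleotide count per bin
    haplotype_frequencies: pd.DataFrame | None = None
    expression_slopes: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genome

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _background_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random sequence with every CpG dinucleotide removed.

    The zero-CpG background makes island detection exactly decidable and
    models (in idealised form) the CpG depletion of methylated genomes.
    """
    s = _ACGT[rng.integers(0, 4, length)]
    if length >= 2:
        mask = (s[:-1] == ord("C")) & (s[1:] == ord("G"))
        idx = np.flatnonzero(mask) + 1
        s[idx] = np.frombuffer(b"AT", dtype=np.uint8)[rng.integers(0, 2, idx.size)]
    return s


def _island_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """CpG-dense, GC-rich sequence of exactly ``length`` bases."""
    out = np.empty(length, dtype=np.uint8)
    i = 0
    while i < length:
        if i + 1 < length and rng.random() < 0.22:
            out[i], out[i + 1] = ord("C"), ord("G")
            i += 2
        else:
            out[i] = _ACGT[rng.choice(4, p=[0.2, 0.3, 0.3, 0.2])]
            i += 1
    return out


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return genes
    total = sum(config.chrom_lengths.values())
    remaining = config.n_genes
    chroms = list(config.chrom_lengths.items())
    for ci, (chrom, length) in enumerate(chroms):
        quota = remaining if ci == len(chroms) - 1 else round(config.n_genes * length / total)
        quota = min(quota, remaining)
        cursor = 3000
        placed = 0
        while placed < quota:
            glen = int(rng.integers(2000, 6001))
            start = cursor + int(rng.integers(0, 1000))
            end = start + glen
            if end + 2500 > length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 5))
            cuts = np.sort(rng.choice(np.arange(1, glen // 100), size=2 * (n_exons - 1),
                                      replace=False)) * 100 if n_exons > 1 else np.array([], int)
            bounds = np.concatenate([[0], cuts, [glen]])
            exons = tuple(
                (start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
                for k in range(n_exons)
            )
            gid = f"G{len(genes):04d}"
            genes.append(GeneModel(gid, chrom, start, end, strand, exons))
            cursor = end + 2500
            placed += 1
        remaining -= placed
    if remaining > 0:
        raise ValueError(
            f"could not fit {config.n_genes} genes into the configured chromosomes "
            f"({remaining} left over)"
        )
    return genes


def _place_cgi_tracts(
    config: SimulationConfig, genes: list[GeneModel], rng: np.random.Generator
) -> pd.DataFrame:
    total_bp = int(config.cpg_island_fraction * sum(config.chrom_lengths.values()))
    rows: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_lengths}

    def free(chrom: str, lo: int, hi: int) -> bool:
        return all(hi <= s or lo >= e for s, e in occupied[chrom])

    budget = total_bp
    # half the island budget goes to promoters (strand-aware, around the TSS)
    promoter_genes = list(genes)
    rng.shuffle(promoter_genes)
    for gene in promoter_genes:
        if budget <= total_bp / 2:
            break
        tlen = int(rng.integers(400, 1201))
        lo, hi = gene.zone(-tlen + 300, 300)
        lo = max(lo, 0)
        hi = min(hi, config.chrom_lengths[gene.chrom])
        if hi - lo < 200 or not free(gene.chrom, lo, hi):
            continue
        rows.append({"chrom": gene.chrom, "start": lo, "end": hi, "at_promoter": True})
        occupied[gene.chrom].append((lo, hi))
        budget -= hi - lo
    chroms = list(config.chrom_lengths.items())
    attempts = 0
    while budget > 0 and attempts < 10_000:
        attempts += 1
        chrom, length = chroms[rng.integers(0, len(chroms))]
        tlen = int(rng.integers(400, 1201))
        if length <= tlen:
            continue
        lo = int(rng.integers(0, length - tlen))
        if not free(chrom, lo, lo + tlen):
            continue
        rows.append({"chrom": chrom, "start": lo, "end": lo + tlen, "at_promoter": False})
        occupied[chrom].append((lo, lo + tlen))
        budget -= tlen
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "at_promoter"])


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Generate the genome, gene models and the per-bin ground truth.

    Returns ``(genome, genes, truth)`` where ``truth`` carries the per-bin
    per-breed read-sampling propensities (element-dependent baselines,
    shared lognormal heterogeneity, planted DMR folds, optional breed
    divergence) together with the planted-DMR table and island tracts.
    """
    rng = config.rng(1)
    genes = _place_genes(config, rng)
    tracts = _place_cgi_tracts(config, genes, rng)
    genome: dict[str, str] = {}
    for chrom, length in config.chrom_lengths.items():
        seq = _background_sequence(rng, length)
        for row in tracts[tracts["chrom"] == chrom].itertuples(index=False):
            seq[row.start:row.end] = _island_sequence(rng, row.end - row.start)
        genome[chrom] = seq.tobytes().decode("ascii")

    bins = make_bins(config.chrom_lengths, config.bin_width)
    element = classify_bins(bins, genes)
    base = element.map(ELEMENT_BASELINES).to_numpy(dtype=float)

    # promoter-island suppression
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms_arr = bins["chrom"].to_numpy()
    for row in tracts.itertuples(index=False):
        if not row.at_promoter:
            continue
        hit = (chroms_arr == row.chrom) & (starts < row.end) & (ends > row.start)
        base[hit] *= PROMOTER_CGI_FACTOR

    # CpG dinucleotide count per bin, for MeDIP-like CpG weighting of reads
    cpg = np.zeros(len(bins), dtype=np.int64)
    for chrom, seq in genome.items():
        s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_cg = np.zeros(len(s), dtype=np.int64)
        if len(s) >= 2:
            is_cg[:-1] = (s[:-1] == ord("C")) & (s[1:] == ord("G"))
        cum = np.concatenate([[0], np.cumsum(is_cg)])
        mask = chroms_arr == chrom
        cpg[mask] = cum[ends[mask] - 1] - cum[starts[mask]]
    bin_cpg = pd.Series(cpg, index=bins.index, name="cpg_count")

    jitter = np.exp(rng.normal(0.0, config.propensity_jitter_sd, len(bins)))
    shared = base * jitter
    prop = pd.DataFrame({b: shared.copy() for b in config.breeds}, index=bins.index)

    if config.divergent_breed is not None:
        if config.divergent_breed not in config.breeds:
            raise ValueError(f"divergent breed {config.divergent_breed!r} not in breeds")
        factor = np.exp(rng.normal(0.0, config.divergence_sd, len(bins)))
        prop[config.divergent_breed] *= factor

    planted_rows = []
    if config.n_planted_dmrs > 0:
        chosen = rng.choice(len(bins), size=min(config.n_planted_dmrs, len(bins)), replace=False)
        for j, pos in enumerate(chosen):
            breed = config.breeds[j % len(config.breeds)]
            direction = 1 if (j // len(config.breeds)) % 2 == 0 else -1
            fold = config.dmr_fold if direction > 0 else 1.0 / config.dmr_fold
            prop.iloc[pos, prop.columns.get_loc(breed)] *= fold
            planted_rows.append(
                {"bin": int(bins.index[pos]), "breed": breed,
                 "direction": "up" if direction > 0 else "down", "fold": fold}
            )
    planted = pd.DataFrame(planted_rows, columns=["bin", "breed", "direction", "fold"])
    prop /= prop.to_numpy().max()  # scale into (0, 1]
    truth = SyntheticTruth(
        bins=bins, propensity=prop, planted=planted, cgi_tracts=tracts, bin_cpg=bin_cpg
    )
    return genome, genes, truth


# ---------------------------------------------------------------------------
# reads


def simulate_bin_counts(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample per-bin read counts, without materialising read records.

    Each sample's counts are multinomial over bins with probability
    proportional to the breed propensity times ``1 + CpG count / bin
    width`` times a per-bin lognormal replicate factor
    (sd ``replicate_noise_sd``).  This is exactly the count distribution
    that :func:`simulate_reads` followed by 5'-start binning produces, and
    is the preferred path for count-level experiments at depths where read
    records would be wasteful.
    """
    rng = config.rng(2)
    cpg_weight = 1.0 + truth.bin_cpg.to_numpy() / config.bin_width
    counts: dict[str, np.ndarray] = {}
    for sample in config.samples:
        breed = config.breed_of[sample]
        lam = truth.propensity[breed].to_numpy() * cpg_weight
        if not np.any(lam > 0):
            raise ValueError("all-zero read propensity: nothing to sample")
        lam = lam * np.exp(rng.normal(0.0, config.replicate_noise_sd, len(lam)))
        counts[sample] = rng.multinomial(config.reads_per_sample, lam / lam.sum())
    totals = pd.Series({s: config.reads_per_sample for s in config.samples}, dtype=np.int64)
    return pd.DataFrame(counts, index=truth.bins.index), totals


def simulate_reads(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Per-sample BED6 read tables with MeDIP-like coverage structure.

    Bin counts come from :func:`simulate_bin_counts`; each read's 5' start
    is then placed uniformly within its bin, with random strand.  Exactly
    ``reads_per_sample`` records are emitted per sample.
    """
    rng = config.rng(5)
    bins = truth.bins
    width = (bins["end"] - bins["start"]).to_numpy()
    starts = bins["start"].to_numpy()
    chroms_arr = bins["chrom"].to_numpy()
    chrom_len = {c: config.chrom_lengths[c] for c in config.chrom_lengths}
    all_counts, _ = simulate_bin_counts(config, truth)
    reads: dict[str, pd.DataFrame] = {}
    totals: dict[str, int] = {}
    for sample in config.samples:
        counts = all_counts[sample].to_numpy()
        bin_idx = np.repeat(np.arange(len(bins)), counts)
        offsets = rng.integers(0, width[bin_idx])
        fp = starts[bin_idx] + offsets
        strand = np.where(rng.random(len(fp)) < 0.5, "+", "-")
        read_start = np.where(strand == "+", fp, fp - (config.read_length - 1))
        read_end = np.where(strand == "+", fp + config.read_length, fp + 1)
        chrom_of = chroms_arr[bin_idx]
        limits = np.array([chrom_len[c] for c in chrom_of])
        read_start = np.maximum(read_start, 0)
        read_end = np.minimum(read_end, limits)
        order = rng.permutation(len(fp))
        df = pd.DataFrame(
            {
                "chrom": chrom_of[order],
                "start": read_start[order],
                "end": read_end[order],
                "name": [f"{sample}_r{i}" for i in range(len(fp))],
                "score": 0,
                "strand": strand[order],
            }
        )
        reads[sample] = df
        totals[sample] = len(df)
    return reads, pd.Series(totals, dtype=np.int64)


# ---------------------------------------------------------------------------
# haplotypes


def simulate_haplotypes(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Individual haplotype sequences for a multi-population sample.

    K root haplotypes are derived from a common ancestral sequence by
    disjoint private mutations, so all roots are pairwise distinct.
    Population haplotype frequencies start from a shared Dirichlet base
    vector; ``divergence`` interpolates between identical frequencies in
    every population (0) and fixation for distinct haplotypes (1).

    Returns ``(sequences, population_of, frequencies)``.
    """
    K = config.n_root_haplotypes
    if K < 1:
        raise ValueError("need at least one root haplotype")
    if config.n_populations < 2:
        raise ValueError("need at least 2 populations")
    if config.individuals_per_population < 2:
        raise ValueError("need at least 2 individuals per population")
    rng = config.rng(3)
    L = config.haplotype_length
    ancestor = _ACGT[rng.integers(0, 4, L)]
    # disjoint mutated site sets keep all root haplotypes distinct
    n_sites = min(3 * K, L)
    sites = rng.choice(L, size=n_sites, replace=False)
    roots = []
    per = n_sites // K
    for k in range(K):
        hap = ancestor.copy()
        for site in sites[k * per:(k + 1) * per] if per else sites[k:k + 1]:
            hap[site] = _ACGT[(np.searchsorted(_ACGT, hap[site]) + 1 + rng.integers(0, 3)) % 4]
        roots.append(hap.tobytes().decode("ascii"))
    base = rng.dirichlet(np.full(K, 5.0))
    d = float(np.clip(config.divergence, 0.0, 1.0))
    freqs = np.zeros((config.n_populations, K))
    for i in range(config.n_populations):
        if d == 0.0:
            freqs[i] = base
        elif d >= 1.0:
            freqs[i, i % K] = 1.0
        else:
            freqs[i] = rng.dirichlet(base * K * (1.0 - d) / d)
    pops = [f"pop{i + 1}" for i in range(config.n_populations)]
    sequences: dict[str, str] = {}
    population_of: dict[str, str] = {}
    for i, pop in enumerate(pops):
        draws = rng.choice(K, size=config.individuals_per_population, p=freqs[i])
        for j, k in enumerate(draws):
            name = f"{pop}_ind{j + 1}"
            sequences[name] = roots[k]
            population_of[name] = pop
    freq_df = pd.DataFrame(freqs, index=pops, columns=[f"hap{k + 1}" for k in range(K)])
    return sequences, population_of, freq_df


# ---------------------------------------------------------------------------
# expression / phenotypes


def simulate_expression(
    config: SimulationConfig, truth: SyntheticTruth | None = None
) -> dict[str, pd.DataFrame]:
    """Ct, CpG-methylation, protein and phenotype tables.

    Target-gene Ct = baseline - slope * methylation + noise, so a positive
    coupling slope yields higher expression (lower Ct) at higher
    methylation and hence a positive methylation-expression correlation.
    Reference genes (ACTB, RPL19) are stable across samples up to
    ``reference_ct_noise_sd``.  Three wells per sample/gene exercise
    technical-replicate averaging.  Protein levels are linearly coupled to
    the same methylation values with the configured sign.
    """
    rng = config.rng(4)
    samples = [
        f"{b}_m{i + 1}"
        for b in config.expression_breeds
        for i in range(config.expression_samples_per_breed)
    ]
    ref_ct = {"ACTB": 18.0, "RPL19": 20.0}
    meth_rows, ct_rows, slope_rows = [], [], []
    meth_by_gene: dict[str, np.ndarray] = {}
    for gene, site, slope, noise_sd in config.expression_coupling:
        m = rng.uniform(0.3, 0.7, len(samples))
        meth_by_gene[gene] = m
        for s, mv in zip(samples, m):
            meth_rows.append({"region": gene, "site": site, "sample": s,
                              "fraction": round(float(mv), 6)})
        ct_base = config.baseline_ct - slope * m + rng.normal(0.0, noise_sd, len(samples))
        for si, s in enumerate(samples):
            for well in range(3):
                ct_rows.append(
                    {"sample": s, "gene": gene, "role": "target", "well": well + 1,
                     "ct": float(ct_base[si] + rng.normal(0.0, config.well_noise_sd))}
                )
        slope_rows.append({"gene": gene, "site": site, "slope": slope, "noise_sd": noise_sd})
    for gene, ct0 in ref_ct.items():
        for s in samples:
            base_s = ct0 + rng.normal(0.0, config.reference_ct_noise_sd)
            for well in range(3):
                ct_rows.append(
                    {"sample": s, "gene": gene, "role": "reference", "well": well + 1,
                     "ct": float(base_s + rng.normal(0.0, config.well_noise_sd))}
                )
    protein_cols = {}
    for gene, sign in config.protein_coupling:
        if gene not in meth_by_gene:
            continue
        m = meth_by_gene[gene]
        protein_cols[gene] = 1.0 + sign * 0.8 * (m - 0.5) + rng.normal(0.0, 0.05, len(samples))
    protein = pd.DataFrame(protein_cols, index=pd.Index(samples, name="sample"))

    pheno_rows = []
    for breed, mu in config.mbmi_means.items():
        for i in range(10):
            length = float(np.clip(rng.normal(0.97, 0.05), 0.7, None))
            target = float(np.clip(rng.normal(mu, 8.0), 30.0, None))
            pheno_rows.append(
                {"animal": f"{breed}_a{i + 1}", "breed": breed, "sex": "F",
                 "weight": round(target * length ** 2, 3), "length": round(length, 3)}
            )
    tables = {
        "ct": pd.DataFrame(ct_rows, columns=["sample", "gene", "role", "well", "ct"]),
        "methylation": pd.DataFrame(meth_rows, columns=["region", "site", "sample", "fraction"]),
        "protein": protein,
        "phenotypes": pd.DataFrame(pheno_rows,
                                   columns=["animal", "breed", "sex", "weight", "length"]),
        "breed_of": pd.DataFrame(
            {"sample": samples,
             "breed": [s.rsplit("_m", 1)[0] for s in samples]}
        ),
    }
    if truth is not None:
        truth.expression_slopes = pd.DataFrame(slope_rows)
    return tables
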