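"""End-to-end orchestration of the comparative methylome analysis.

Stages run in dependency order: simulate (optional) -> bin/count -> filter ->
score -> replicate QC/average -> annotate -> DMR calling (+ breed-specific
sets, gene mapping) -> clustering; haplotype Fst and qPCR integration are
independent arms.  Every stage writes plain-text outputs into the run
directory and a JSON manifest records the config hash and per-output
checksums, so deterministic stages are byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from medipscape import annotation, binning, dmr, expression, fst, io
from medipscape.synthetic import (
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_haplotypes,
    simulate_reads,
)

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_simulation(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write every synthetic input file."""
    out = io.ensure_dir(outdir)
    genome, genes, truth = simulate_genome(config)
    reads, totals = simulate_reads(config, truth)
    haps, pops, freqs = simulate_haplotypes(config)
    tables = simulate_expression(config, truth)
    paths: dict[str, Path] = {}

    def save(name: str, fn) -> None:
        paths[name] = out / name
        fn(paths[name])

    save("genome.fa", lambda p: io.write_fasta(p, genome))
    save("genes.bed12", lambda p: io.write_bed12(p, genes))
    for sample, df in reads.items():
        save(f"reads_{sample}.bed", lambda p, df=df: io.write_bed6(p, df))
    save("totals.tsv", lambda p: totals.rename("total_unique_mapped")
         .rename_axis("sample").to_csv(p, sep="\t"))
    save("breeds.tsv", lambda p: io.write_population_map(
        p, {s: b for s, b in config.breed_of.items()}))
    save("haplotypes.fa", lambda p: io.write_fasta(p, haps))
    save("populations.tsv", lambda p: io.write_population_map(p, pops))
    save("ct.tsv", lambda p: tables["ct"].to_csv(p, sep="\t", index=False))
    save("methylation.tsv", lambda p: tables["methylation"].to_csv(p, sep="\t", index=False))
    save("protein.tsv", lambda p: tables["protein"].to_csv(p, sep="\t"))
    save("phenotypes.tsv", lambda p: tables["phenotypes"].to_csv(p, sep="\t", index=False))
    save("truth_planted.tsv", lambda p: truth.planted.to_csv(p, sep="\t", index=False))
    save("truth_propensity.tsv", lambda p: truth.propensity.to_csv(p, sep="\t"))
    save("config.yaml", lambda p: config.to_yaml(p))
    return paths


def run_pipeline(
    config: SimulationConfig,
    outdir,
    min_total: int = 10,
    alpha: float = 0.05,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    n_perm: int = 1000,
    resume: bool = False,
) -> dict:
    """Run the full analysis on freshly simulated inputs.

    Returns a results dictionary; writes one text artefact per stage plus a
    ``manifest.json``.  With ``resume=True`` a stage whose primary output
    file already exists is skipped (its result is reloaded where needed).
    """
    out = io.ensure_dir(outdir)
    t_start = time.time()
    stages: list[str] = []

    def stage(name: str, output: Path, compute):
        if resume and output.exists():
            logger.info("stage %s: reusing %s", name, output)
            stages.append(f"{name} (resumed)")
            return None
        result = compute()
        stages.append(name)
        return result

    genome, genes, truth = simulate_genome(config)
    reads, totals = simulate_reads(config, truth)

    counts = binning.count_reads(truth.bins, reads, config.breed_of)
    retained = binning.filter_bins(counts, min_total=min_total)
    scores = binning.enrichment_matrix(retained, width=config.bin_width)
    breed_scores, qc = binning.replicate_qc_and_average(scores, config.breed_of)
    qc_path = out / "replicate_qc.tsv"
    stage("replicate_qc", qc_path, lambda: qc.to_csv(qc_path, sep="\t", index=False))

    cgis = annotation.detect_cgi(genome)
    cgis = annotation.classify_cgi_regions(cgis, genes)
    annotated = annotation.annotate_bins(retained.bins, genes, cgis)
    profiles = annotation.element_profiles(breed_scores, annotated)
    stage("profiles", out / "element_profiles.tsv",
          lambda: profiles.to_csv(out / "element_profiles.tsv", sep="\t", index=False))
    cgis.to_csv(out / "cgi.tsv", sep="\t", index=False)

    results = dmr.pairwise_tests(scores, config.breed_of)
    dmrs = dmr.call_dmrs(results, alpha=alpha)
    strong = dmr.fold_change_filter(dmrs, results, low=fc_low, high=fc_high)
    specific = dmr.breed_specific_dmrs(results, alpha=alpha)
    gene_hits = dmr.map_dmrs_to_genes(retained.bins.loc[dmrs.index[dmrs["is_dmr"]]], genes)
    dmr_table = retained.bins.join(dmrs).join(specific)
    stage("dmrs", out / "dmrs.tsv",
          lambda: dmr_table.to_csv(out / "dmrs.tsv", sep="\t"))
    strong.to_csv(out / "dmrs_strong_fc.tsv", sep="\t")

    intergenic = annotated.index[annotated["element"] == "intergenic"]
    covered = retained.counts.loc[intergenic]
    usable = covered.index[(covered >= min_total).all(axis=1)]
    Z, newick = dmr.cluster_breeds(breed_scores.loc[usable])
    (out / "breed_tree.nwk").write_text(newick + "\n")
    stages.append("clustering")

    haps, pops, freqs = simulate_haplotypes(config)
    dataset = fst.collapse_haplotypes(haps, pops)
    fst_res = fst.fst_permutation(dataset, n_perm=n_perm, seed=config.seed)
    fst_res.fst.to_csv(out / "fst.tsv", sep="\t")
    fst_res.p_perm.to_csv(out / "fst_pvalues.tsv", sep="\t")
    stages.append("fst")

    tables = simulate_expression(config, truth)
    breed_of_expr = dict(zip(tables["breed_of"]["sample"], tables["breed_of"]["breed"]))
    calibrator = [s for s, b in breed_of_expr.items() if b == config.expression_breeds[0]]
    expr = expression.relative_expression(tables["ct"], calibrator=calibrator)
    pairs = [(g, s, g) for g, s, _, _ in config.expression_coupling]
    corr = expression.methylation_expression_correlation(tables["methylation"], expr, pairs)
    expr.to_csv(out / "expression.tsv", sep="\t")
    corr.to_csv(out / "methylation_expression_correlation.tsv", sep="\t", index=False)
    pheno = tables["phenotypes"].copy()
    pheno["mbmi"] = [
        expression.mbmi(w, l) for w, l in zip(pheno["weight"], pheno["length"])
    ]
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    stages.append("expression")

    config_blob = json.dumps(asdict(config), sort_keys=True, default=list)
    manifest = {
        "tool_version": "0.1.0",
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "stages": stages,
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
        "elapsed_seconds": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "retained": retained,
        "scores": scores,
        "breed_scores": breed_scores,
        "qc": qc,
        "annotated": annotated,
        "profiles": profiles,
        "results": results,
        "dmrs": dmrs,
        "strong": strong,
        "specific": specific,
        "gene_hits": gene_hits,
        "linkage": Z,
        "newick": newick,
        "fst": fst_res,
        "expression": expr,
        "correlation": corr,
        "phenotypes": pheno,
        "truth": truth,
        "manifest": manifest,
    }
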