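"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic coordinates are 0-based half-open (native BED convention) both
in memory and on disk.  Parsing is strict: malformed records raise
:class:`FormatError` carrying the file and line number.  CRLF line endings
and missing trailing newlines are tolerated.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from medipscape.annotation import GeneModel

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    """A malformed record, reported as file:line: message."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _lines(path) -> Iterable[tuple[int, str]]:
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if line and not line.startswith(("#", "track", "browser")):
                yield lineno, line


def _int_field(path, lineno: int, value: str, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(path, lineno, f"{what} is not an integer: {value!r}") from None


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id, as plain uppercase-preserving strings."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed6(path) -> pd.DataFrame:
    """BED6 intervals (chrom, start, end, name, score, strand), validated."""
    rows = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(path, lineno, f"expected >=6 BED fields, got {len(fields)}")
        chrom, start_s, end_s, name, score, strand = fields[:6]
        start = _int_field(path, lineno, start_s, "start")
        end = _int_field(path, lineno, end_s, "end")
        if start < 0 or start >= end:
            raise FormatError(path, lineno, f"invalid interval [{start}, {end})")
        if strand not in {"+", "-", "."}:
            raise FormatError(path, lineno, f"invalid strand {strand!r}")
        try:
            score = int(score)
        except ValueError:
            pass  # BED permits non-integer scores; keep verbatim
        rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed6(path, intervals: pd.DataFrame) -> None:
    intervals.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLUMNS)


def read_bed12(path) -> list[GeneModel]:
    """Gene models from BED12 (blocks become exons)."""
    genes = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 12:
            raise FormatError(path, lineno, f"expected 12 BED fields, got {len(fields)}")
        chrom, start_s, end_s, name, _score, strand = fields[:6]
        start = _int_field(path, lineno, start_s, "start")
        end = _int_field(path, lineno, end_s, "end")
        if start < 0 or start >= end:
            raise FormatError(path, lineno, f"invalid interval [{start}, {end})")
        n_blocks = _int_field(path, lineno, fields[9], "blockCount")
        sizes = [s for s in fields[10].rstrip(",").split(",") if s]
        offsets = [s for s in fields[11].rstrip(",").split(",") if s]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise FormatError(path, lineno, "blockSizes/blockStarts disagree with blockCount")
        exons = []
        for size_s, off_s in zip(sizes, offsets):
            size = _int_field(path, lineno, size_s, "blockSize")
            off = _int_field(path, lineno, off_s, "blockStart")
            exons.append((start + off, start + off + size))
        try:
            genes.append(GeneModel(name, chrom, start, end, strand, tuple(exons)))
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from None
    return genes


def write_bed12(path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offs = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )


def read_tsv(path, required: Sequence[str] | None = None) -> pd.DataFrame:
    """A headered TSV with optional required-column validation."""
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(path, 1, f"missing required columns: {missing}")
    return df


def read_population_map(path) -> dict[str, str]:
    """Two-column TSV (individual, population), header optional."""
    out: dict[str, str] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(path, lineno, "expected 2 columns: individual, population")
        if lineno == 1 and fields[0].lower() in {"individual", "sample", "id"}:
            continue
        out[fields[0]] = fields[1]
    return out


def write_population_map(path, population_of: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\n")
        for ind, pop in population_of.items():
            fh.write(f"{ind}\t{pop}\n")


def read_genome_sizes(path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length in bp."""
    out: dict[str, int] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(path, lineno, "expected 2 columns: chrom, length")
        out[fields[0]] = _int_field(path, lineno, fields[1], "length")
    return out


def write_gene_sets_gmt(path, gene_sets: Mapping[str, Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "."] + list(members)) + "\n")


def read_gene_sets_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name, description, members..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(path, lineno, "GMT line needs name, description, >=1 gene")
        sets[fields[0]] = fields[2:]
    return sets


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
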