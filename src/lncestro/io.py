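"""Readers and writers for the flat-file formats the pipeline exchanges.

FASTA goes through Biopython SeqIO, multiple alignments through the
Bio.AlignIO MAF dialect (MultiZ-style ``a``/``s`` blocks, ``src`` spelled as
``assembly.chrom``). BED12/BED6 are read and written directly: the BED12
block columns are expanded into exon intervals of :class:`TranscriptModel`,
with the score column carrying the isoform's cDNA/EST support count.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CatalogueFormatError, MissingInputError
from .features import TranscriptModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed12",
    "write_bed12",
    "read_bed6",
    "write_bed6",
    "read_maf",
    "write_maf",
    "read_tsv",
    "write_tsv",
    "write_json",
    "read_json",
]

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _require(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise MissingInputError(str(p))
    return p


# -- FASTA -------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(_require(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# -- BED ---------------------------------------------------------------------

def read_bed12(path) -> list[TranscriptModel]:
    models = []
    for line_no, line in enumerate(_require(path).read_text().splitlines(), 1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise CatalogueFormatError(f"{path}:{line_no}: expected 12 BED columns")
        chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != int(f[9]) or len(offsets) != int(f[9]):
            raise CatalogueFormatError(f"{path}:{line_no}: blockCount mismatch")
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        gene_id, _, tx = name.partition("|")
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tx or gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
                support_count=max(1, int(float(f[4]))),
            )
        )
    return models


def write_bed12(models: Iterable[TranscriptModel], path) -> None:
    lines = []
    for m in models:
        start, end = m.start, m.end
        sizes = ",".join(str(e - s) for s, e in m.exons)
        offsets = ",".join(str(s - start) for s, e in m.exons)
        name = m.gene_id if m.transcript_id == m.gene_id else f"{m.gene_id}|{m.transcript_id}"
        lines.append(
            "\t".join(
                [
                    m.chrom,
                    str(start),
                    str(end),
                    name,
                    str(m.support_count),
                    m.strand,
                    str(start),
                    str(end),
                    "0",
                    str(len(m.exons)),
                    sizes,
                    offsets,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed6(path) -> pd.DataFrame:
    rows = []
    for line_no, line in enumerate(_require(path).read_text().splitlines(), 1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise CatalogueFormatError(f"{path}:{line_no}: expected 6 BED columns")
        rows.append((f[0], int(f[1]), int(f[2]), f[3], float(f[4]), f[5]))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def write_bed6(peaks: pd.DataFrame, path) -> None:
    out = peaks[PEAK_COLUMNS].copy()
    out["score"] = out["score"].map(lambda v: format(float(v), "g"))
    out.to_csv(path, sep="\t", header=False, index=False)


# -- MAF ---------------------------------------------------------------------

def write_maf(blocks: Iterable[MultipleSeqAlignment], path) -> None:
    with open(path, "w") as fh:
        AlignIO.write(list(blocks), fh, "maf")


def read_maf(path) -> list[MultipleSeqAlignment]:
    with open(_require(path)) as fh:
        return list(AlignIO.parse(fh, "maf"))


def maf_block(rows: Iterable[tuple[str, int, int, str, int, str]]) -> MultipleSeqAlignment:
    """Build one alignment block from (src, start, size, strand, srcSize, text)."""
    records = []
    for src, start, size, strand, src_size, text in rows:
        rec = SeqRecord(Seq(text), id=src, description="")
        rec.annotations.update(
            {"start": start, "size": size, "strand": strand, "srcSize": src_size}
        )
        records.append(rec)
    return MultipleSeqAlignment(records)


# -- tables and reports ------------------------------------------------------

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(_require(path), sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n")


def read_json(path):
    return json.loads(_require(path).read_text())
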