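"""File formats: FASTA/FASTQ via Biopython, catalogs and pair tables as TSV,
masked regions as BED. Simulated FASTA headers carry ``circular=true``."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ChromosomeSeq,
    GenomeModel,
    RepeatCatalog,
    RepeatCopy,
    RepeatPair,
)
from .simulate import ReadPairSet

CATALOG_COLUMNS = [
    "chromA", "startA", "endA", "strandA",
    "chromB", "startB", "endB", "strandB",
    "length", "identity", "score",
]


def write_genome_fasta(genome: GenomeModel, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=c.id, description=f"circular={str(c.circular).lower()}")
        for c in genome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> GenomeModel:
    chroms = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = "circular=true" in rec.description.lower()
        chroms[rec.id] = ChromosomeSeq(rec.id, str(rec.seq).upper(), circular)
    return GenomeModel(chroms)


def write_fastq_pair(reads: ReadPairSet, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    paths = (prefix.with_suffix(".1.fastq"), prefix.with_suffix(".2.fastq"))
    for path, rlist, mate in zip(paths, (reads.reads1, reads.reads2), "12"):
        with open(path, "w") as fh:
            for rid, seq in rlist:
                fh.write(f"@{rid}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
    return paths


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id.split("/")[0], str(rec.seq).upper()))
    return out


def write_truth_table(reads: ReadPairSet, path: str | Path) -> None:
    reads.truth.to_csv(path, sep="\t", index=False)


def catalog_to_frame(catalog: RepeatCatalog) -> pd.DataFrame:
    rows = [
        (
            p.copy_a.chrom, p.copy_a.start, p.copy_a.end, p.copy_a.strand,
            p.copy_b.chrom, p.copy_b.start, p.copy_b.end, p.copy_b.strand,
            p.aligned_length, round(p.identity, 2), p.raw_score,
        )
        for p in catalog
    ]
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def write_catalog_tsv(catalog: RepeatCatalog, path: str | Path) -> None:
    catalog_to_frame(catalog).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> RepeatCatalog:
    df = pd.read_csv(path, sep="\t")
    pairs = [
        RepeatPair(
            RepeatCopy(r.chromA, int(r.startA), int(r.endA), r.strandA),
            RepeatCopy(r.chromB, int(r.startB), int(r.endB), r.strandB),
            int(r.length), float(r.identity), int(r.score),
        )
        for r in df.itertuples()
    ]
    return RepeatCatalog(pairs, {"source": str(path)})


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def read_sam_pairs(path: str | Path) -> pd.DataFrame:
    """Ingest pre-mapped pairs from SAM text, coordinate fields only.

    Orientation and span are *not* taken from the stored flags' proper-pair
    bit; only QNAME, the strand bit, RNAME, POS and SEQ length are used, so
    downstream classification stays self-contained. Secondary and
    supplementary records are skipped; pairs with an unmapped end get
    status 'unmapped'.
    """
    ends: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            qname, flag, rname, pos = f[0], int(f[1]), f[2], int(f[3])
            if flag & 0x900:  # secondary/supplementary
                continue
            strand = "-" if flag & 0x10 else "+"
            unmapped = bool(flag & 0x4) or rname == "*"
            rlen = len(f[9]) if f[9] != "*" else 0
            ends.setdefault(qname, []).append(
                (None if unmapped else rname, pos - 1, rlen, strand)
            )
    rows = []
    for qname, recs in ends.items():
        if len(recs) != 2:
            continue
        (c1, p1, l1, s1), (c2, p2, l2, s2) = recs
        status = "unmapped" if c1 is None or c2 is None else "mapped"
        rows.append(
            (qname, c1 or ".", p1, l1, s1, 0, c2 or ".", p2, l2, s2, 0, status)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "chrom1", "pos1", "len1", "strand1", "nm1",
            "chrom2", "pos2", "len2", "strand2", "nm2",
            "status",
        ],
    )


def read_fasta_db(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    aln = AlignIO.read(str(path), "fasta")
    return {rec.id: str(rec.seq).upper().replace(".", "-") for rec in aln}
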