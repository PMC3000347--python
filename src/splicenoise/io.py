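"""Readers and writers for the standard interchange formats.

FASTA is read through pyfaidx and FASTQ through pysam's FastxFile;
writing uses plain text since the formats are line-oriented.  Gene
models go out as both GTF and BED12; junction tables as TSV and BED12
(two blocks per junction, score = read count).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic.genome import Genome
from .synthetic.reads import ReadRecord
from .synthetic.truth import GeneModel


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> Genome:
    return Genome.from_fasta(path)


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def read_fastq(path) -> list[ReadRecord]:
    import pysam

    out = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            out.append(ReadRecord(entry.name, entry.sequence.upper()))
    return out


def write_gtf(genes: list[GeneModel], path, source: str = "splicenoise") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attrs} exon_number {i};\n")


def read_gtf(path) -> list[GeneModel]:
    """Reconstruct gene models from exon records of a GTF file."""
    import re

    tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            m = re.search(r'gene_id "([^"]+)"', f[8])
            gid = m.group(1) if m else f[8]
            rec = tx.setdefault(gid, dict(chrom=f[0], strand=f[6], exons=[]))
            rec["exons"].append((int(f[3]) - 1, int(f[4])))
    return [GeneModel(gid, r["chrom"], r["strand"], tuple(sorted(r["exons"])))
            for gid, r in tx.items()]


def write_bed12_genes(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, e in g.exons) + ","
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                     f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n")


def read_bed12_genes(path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + sz) for o, sz in zip(starts, sizes))
            out.append(GeneModel(f[3], f[0], f[5], exons))
    return out


def write_junctions_tsv(junctions: pd.DataFrame, path) -> None:
    junctions.to_csv(path, sep="\t", index=False)


def read_junctions_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_junctions_bed12(junctions: pd.DataFrame, path, overhang: int = 20) -> None:
    """Junctions as BED12: two anchor blocks bridging the intron."""
    with open(path, "w") as fh:
        for i, row in enumerate(junctions.itertuples(index=False)):
            s, e = int(row.start), int(row.end)
            bstart = s - overhang
            bend = e + overhang
            name = f"JUNC{i:08d}"
            fh.write(f"{row.chrom}\t{bstart}\t{bend}\t{name}\t{int(row.reads)}\t"
                     f"{row.strand}\t{bstart}\t{bend}\t0\t2\t"
                     f"{overhang},{overhang},\t0,{e - bstart},\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
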