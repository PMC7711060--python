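"""Readers and writers for the plain-text interchange formats.

Genes travel as BED6 (0-based half-open, name = gene id) with the biotype in
a companion two-column TSV; promoter sequences as FASTA (record id = gene
id); matrices as TSV with the feature/site id in the first column and sample
ids in the header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .promoters import GeneModel


def write_genes_bed(
    genes: Iterable[GeneModel], bed_path: str | Path, biotype_path: str | Path
) -> None:
    """Write gene TSS anchors as single-base BED6 plus a biotype companion TSV."""
    genes = list(genes)
    with open(bed_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")
    pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "biotype": [g.biotype for g in genes]}
    ).to_csv(biotype_path, sep="\t", index=False)


def read_genes_bed(bed_path: str | Path, biotype_path: str | Path) -> list[GeneModel]:
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    biotypes = pd.read_csv(biotype_path, sep="\t").set_index("gene_id")["biotype"]
    genes = []
    for row in bed.itertuples(index=False):
        # TSS is the start for "+" and the last base for "-"; identical for
        # the single-base anchors this package writes
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        genes.append(GeneModel(str(row.name), str(row.chrom), str(row.strand), tss, str(biotypes[row.name])))
    return genes


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "assay"}
    if not required.issubset(df.columns):
        raise ValueError(f"samples table must have columns {sorted(required)}")
    return df


def groups_for_assay(samples: pd.DataFrame, assay: str) -> dict[str, str]:
    sub = samples[samples["assay"] == assay]
    return dict(zip(sub["sample_id"], sub["group"]))
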