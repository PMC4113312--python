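"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA via Biopython; tables are TSV with a required header line.  Gene
location tables use 0-based half-open coordinates.  Genotype tables store
allele calls as ``a/b`` with ``-`` for missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simdata import GenotypeTable


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, header: str | None = None) -> None:
    path = Path(path)
    recs = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
    with open(path, "w") as fh:
        if header:
            fh.write(f";{header}\n")
        SeqIO.write(recs, fh, "fasta")


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_genotypes(table: GenotypeTable, path) -> None:
    df = table.data.copy()
    df.insert(0, "marker", df.index)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path, mother: str = "mother",
                   fathers: list[str] | None = None) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("marker")
    if fathers is None:
        fathers = [c for c in df.columns if c.startswith("father")
                   and "_" not in c]
    progeny = [c for c in df.columns if c not in [mother] + fathers]
    progeny_father = {}
    for p in progeny:
        fa = next((f for f in fathers if p.startswith(f + "_")), fathers[0])
        progeny_father[p] = fa
    return GenotypeTable(data=df, mother=mother, fathers=fathers,
                         progeny_father=progeny_father)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
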