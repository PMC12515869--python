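"""Readers and writers for the pipeline's plain-text formats.

TSV everywhere with '#'-prefixed metadata headers, UTF-8, '.' decimal
separator; missing intensity = empty cell (canonical) with "NA" accepted on
read.  FASTA through Biopython; gene sets in the standard GMT dialect.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GroupDesign, SiteCatalog
from .simulate import ProteomeRecord


def read_fasta(path) -> list[ProteomeRecord]:
    """FASTA -> proteome records; accession = header token before whitespace.

    Sequences are upper-cased and a trailing '*' is stripped; duplicate
    accessions are an error.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteomeRecord(accession=acc, sequence=seq))
    return records


def write_fasta(records: list[ProteomeRecord], path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.accession, description="")
            for r in records]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def _strip_comments(path) -> _io.StringIO:
    with open(path, encoding="utf-8") as fh:
        lines = [line for line in fh if not line.startswith("#")]
    return _io.StringIO("".join(lines))


def read_intensity_tsv(path, design: GroupDesign | None = None) -> pd.DataFrame:
    """Intensity TSV (feature id column + sample columns) -> DataFrame.

    Empty cells and "NA" become missing; non-positive values are rejected
    naming the offending row and column.
    """
    table = pd.read_csv(_strip_comments(path), sep="\t", index_col=0,
                        na_values=["NA"])
    try:
        table = table.astype(float)
    except ValueError as err:
        raise ValueError(f"non-numeric intensity in {path}: {err}") from None
    table.index = table.index.astype(str)
    table.index.name = "feature_id"
    if design is not None:
        missing = set(design.samples) - set(table.columns)
        if missing:
            raise ValueError(f"samples missing from {path}: {sorted(missing)}")
    values = table.to_numpy()
    bad = np.asarray((values <= 0) & ~np.isnan(values)).nonzero()
    if bad[0].size:
        r, c = bad[0][0], bad[1][0]
        raise ValueError(
            f"non-positive intensity in {path}: feature {table.index[r]!r}, "
            f"sample {table.columns[c]!r}")
    return table


def write_intensity_tsv(table: pd.DataFrame, path, comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", na_rep="", float_format="%.6g",
                     index_label="feature_id")


def read_site_catalog_tsv(path) -> SiteCatalog:
    frame = pd.read_csv(_strip_comments(path), sep="\t",
                        dtype={"site_id": str, "accession": str,
                               "position": int, "flank": str})
    return SiteCatalog(frame[["site_id", "accession", "position", "flank"]])


def write_site_catalog_tsv(catalog: SiteCatalog, path,
                           comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        catalog.frame.to_csv(fh, sep="\t", index=False)


def read_design_tsv(path) -> GroupDesign:
    frame = pd.read_csv(_strip_comments(path), sep="\t", dtype=str)
    return GroupDesign.from_frame(frame)


def write_design_tsv(design: GroupDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_edge_list_tsv(path) -> nx.Graph:
    """Two/three-column TSV (nodeA, nodeB[, score]) -> undirected simple graph."""
    frame = pd.read_csv(_strip_comments(path), sep="\t", dtype={0: str, 1: str})
    cols = list(frame.columns)
    graph = nx.Graph()
    for _, row in frame.iterrows():
        u, v = str(row[cols[0]]), str(row[cols[1]])
        if u == v:
            raise ValueError(f"self-loop {u!r} in {path}")
        attrs = {"score": float(row[cols[2]])} if len(cols) > 2 else {}
        graph.add_edge(u, v, **attrs)
    return graph


def write_edge_list_tsv(graph: nx.Graph, path,
                        comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write("node_a\tnode_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT (name, description, tab-separated members) -> name -> members."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *members = parts
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
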