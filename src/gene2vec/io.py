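"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: expression TSV (genes/probes in rows, header = sample ids) and the
equivalent HDF5 (`gene_ids`, `values` datasets); two-column probe->gene map;
three-column pair-corpus TSV; word2vec text embeddings; GMT pathway files;
annotation and hierarchy TSVs (with OBO-lite ``is_a`` extraction); map TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .coexpr import CoexprCorpus, ExpressionDataset, ProbeTable, canonical_pair
from .embed import GeneEmbedding, GeneVocabulary
from .ggipnn import AnnotationRecord, AnnotationTable
from .tune import DEFAULT_MAX_PATHWAY_SIZE, PathwayCollection
from .vizmap import MapCoordinates, TissueSpecificity


# -- expression matrices

def read_expression_tsv(path: str | os.PathLike, dataset_id: str | None = None) -> ExpressionDataset:
    """Genes in rows, first column = gene id, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionDataset(
        dataset_id=dataset_id or Path(path).stem,
        gene_ids=[str(g) for g in df.index],
        values=df.to_numpy(dtype=float),
    )


def write_expression_tsv(ds: ExpressionDataset, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        ds.values,
        index=pd.Index(ds.gene_ids, name="gene_id"),
        columns=[f"S{i}" for i in range(ds.sample_count)],
    )
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_expression_hdf5(path: str | os.PathLike, dataset_id: str | None = None) -> ExpressionDataset:
    with h5py.File(path, "r") as f:
        gene_ids = [g.decode() if isinstance(g, bytes) else str(g) for g in f["gene_ids"][()]]
        values = f["values"][()]
    return ExpressionDataset(
        dataset_id=dataset_id or Path(path).stem, gene_ids=gene_ids, values=values
    )


def read_probe_map(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV probe_id -> gene_id; each probe maps to one gene."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"],
                     dtype=str, comment="#")
    if df["probe"].duplicated().any():
        dup = df.loc[df["probe"].duplicated(), "probe"].iloc[0]
        raise ValueError(f"probe {dup!r} maps to more than one gene")
    return dict(zip(df["probe"], df["gene"]))


def probes_from_dataset(
    ds: ExpressionDataset, probe_map: dict[str, str]
) -> list[ProbeTable]:
    """Reinterpret a probe-level matrix's rows as probes via the map."""
    probes = []
    for row_id, values in zip(ds.gene_ids, ds.values):
        gene = probe_map.get(row_id)
        if gene is not None:
            probes.append(ProbeTable(probe_id=row_id, gene_id=gene, values=values))
    return probes


# -- pair corpus

def write_corpus(corpus: CoexprCorpus, path: str | os.PathLike) -> None:
    """`gene_a<TAB>gene_b<TAB>multiplicity`, gene_a < gene_b, sorted."""
    with open(path, "w") as f:
        f.write(f"# co-expression pair corpus; {corpus.total_occurrences} occurrences\n")
        for (a, b), n in sorted(corpus.pairs.items()):
            f.write(f"{a}\t{b}\t{n}\n")


def read_corpus(path: str | os.PathLike) -> CoexprCorpus:
    corpus = CoexprCorpus()
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, n = line.split("\t")
            corpus.pairs[canonical_pair(a, b)] += int(n)
    return corpus


# -- embeddings (word2vec text dialect)

def write_embedding(emb: GeneEmbedding, path: str | os.PathLike) -> None:
    """First line `d k`, then `gene_id v1 ... vk`, 6 significant digits."""
    with open(path, "w") as f:
        f.write(f"{len(emb.vocab)} {emb.k}\n")
        for gene, row in zip(emb.vocab.gene_ids, emb.W):
            f.write(gene + " " + " ".join(f"{v:.6g}" for v in row) + "\n")


def read_embedding(path: str | os.PathLike) -> GeneEmbedding:
    with open(path) as f:
        header = f.readline().split()
        d, k = int(header[0]), int(header[1])
        genes, rows = [], []
        for line in f:
            parts = line.split()
            if not parts:
                continue
            genes.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if len(genes) != d:
        raise ValueError(f"header declares {d} genes, file has {len(genes)}")
    W = np.array(rows, dtype=float)
    if W.shape[1] != k:
        raise ValueError(f"header declares k={k}, rows have {W.shape[1]} values")
    vocab = GeneVocabulary(gene_ids=genes, frequency={g: 0 for g in genes})
    return GeneEmbedding(vocab=vocab, W=W, meta={"source": str(path)})


# -- pathways (GMT)

def read_gmt(path: str | os.PathLike, max_size: int = DEFAULT_MAX_PATHWAY_SIZE) -> PathwayCollection:
    """Standard GMT: name, description, then gene symbols; dups deduplicated."""
    sets: dict[str, list[str]] = {}
    with open(path) as f:
        for line in f:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return PathwayCollection.from_dict(sets, max_size=max_size)


def write_gmt(pc: PathwayCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as f:
        for name in sorted(pc.pathways):
            genes = "\t".join(sorted(pc.pathways[name]))
            f.write(f"{name}\tna\t{genes}\n")


# -- annotations and hierarchy

def read_annotations(
    ann_path: str | os.PathLike,
    hierarchy_path: str | os.PathLike,
    root: str | None = None,
) -> AnnotationTable:
    """3-column TSV (gene, term, evidence) + 2-column (parent, child) or OBO."""
    ann = pd.read_csv(ann_path, sep="\t", header=None,
                      names=["gene", "term", "evidence"], dtype=str, comment="#")
    records = [AnnotationRecord(*row) for row in ann.itertuples(index=False)]
    hp = Path(hierarchy_path)
    if hp.suffix == ".obo":
        edges = _edges_from_obo(hp)
    else:
        hier = pd.read_csv(hp, sep="\t", header=None,
                           names=["parent", "child"], dtype=str, comment="#")
        edges = list(hier.itertuples(index=False, name=None))
    return AnnotationTable(records=records, edges=edges, root=root)


def _edges_from_obo(path: Path) -> list[tuple[str, str]]:
    """Minimal OBO reader: [Term] stanzas, `id:` and `is_a:` lines only."""
    edges: list[tuple[str, str]] = []
    term = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if line == "[Term]":
            term = None
        elif line.startswith("id:"):
            term = line.split("id:", 1)[1].strip()
        elif line.startswith("is_a:") and term:
            parent = line.split("is_a:", 1)[1].split("!")[0].strip()
            edges.append((parent, term))
    return edges


def write_annotations(ann: AnnotationTable, ann_path: str | os.PathLike,
                      hierarchy_path: str | os.PathLike) -> None:
    with open(ann_path, "w") as f:
        for gene, term, evidence in sorted(ann.records):
            f.write(f"{gene}\t{term}\t{evidence}\n")
    with open(hierarchy_path, "w") as f:
        for parent, child in sorted(ann.edges):
            f.write(f"{parent}\t{child}\n")


# -- map output

def write_map(
    coords: MapCoordinates,
    path: str | os.PathLike,
    tissue: TissueSpecificity | None = None,
) -> None:
    """`gene_id  F1  F2` plus optional per-tissue z columns (NA if absent)."""
    df = pd.DataFrame(coords.xy, columns=["F1", "F2"],
                      index=pd.Index(coords.gene_ids, name="gene_id"))
    if tissue is not None:
        zdf = pd.DataFrame(tissue.z, index=tissue.gene_ids, columns=tissue.tissues)
        df = df.join(zdf)
    df.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")
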