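"""Plain-text readers and writers for the pipeline's interchange formats.

Everything is line-oriented text: GCT 1.3 for perturbation references, GMT
for paired signatures (``<name>_UP`` / ``<name>_DN``), TSV for counts,
metadata, loadings, edge lists and results, hex strings for fingerprints,
and a TSV edge list (term_id, parent_id, relation) plus GMT annotations for
the ontology.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .diffexp import ExpressionStudy, GeneSignature
from .ontosim import Ontology

__all__ = [
    "read_gct", "write_gct",
    "read_gmt", "write_gmt",
    "read_signature_gmt", "write_signature_gmt",
    "read_study", "read_loadings",
    "read_fingerprints", "bits_to_hex", "hex_to_bits",
    "read_ontology",
]


def write_gct(path: str | Path, matrix: pd.DataFrame) -> None:
    """Write a row x column matrix as GCT version 1.3 (no extra metadata)."""
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\t0\t0\n")
        fh.write("id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for rid, row in zip(matrix.index, matrix.to_numpy()):
            fh.write(str(rid) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_gct(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise ValueError(f"not a GCT file: version line {version!r}")
        dims = fh.readline().split()
        n_rows, n_cols = int(dims[0]), int(dims[1])
        n_rmeta = int(dims[2]) if len(dims) > 2 else 0
        header = fh.readline().rstrip("\n").split("\t")
        col_ids = header[1 + n_rmeta:]
        if len(col_ids) != n_cols:
            raise ValueError("GCT header column count mismatch")
        rows, index = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            index.append(parts[0])
            rows.append([float(v) for v in parts[1 + n_rmeta:]])
    if len(rows) != n_rows:
        raise ValueError("GCT row count mismatch")
    return pd.DataFrame(rows, index=index, columns=col_ids)


def write_gmt(path: str | Path, sets: dict, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def read_gmt(path: str | Path) -> dict:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:     # a 2-field line is a valid empty set
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_signature_gmt(path: str | Path, sig: GeneSignature, name: str) -> None:
    write_gmt(path, {f"{name}_UP": sig.up, f"{name}_DN": sig.down},
              description=sig.method)


def read_signature_gmt(path: str | Path) -> GeneSignature:
    sets = read_gmt(path)
    up_keys = [k for k in sets if k.endswith("_UP")]
    dn_keys = [k for k in sets if k.endswith("_DN")]
    if len(up_keys) != 1 or len(dn_keys) != 1:
        raise ValueError("signature GMT must contain exactly one _UP and one _DN set")
    return GeneSignature(
        up=sets[up_keys[0]], down=sets[dn_keys[0]], method="from_gmt",
        universe=set(sets[up_keys[0]]) | set(sets[dn_keys[0]]),
    )


def read_study(
    counts_path: str | Path,
    meta_path: str | Path,
    lengths_path: str | Path,
) -> ExpressionStudy:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionStudy(
        counts=counts,
        gene_lengths=lengths.reindex(counts.index),
        condition=meta["condition"].reindex(counts.columns),
        database=meta["database"].reindex(counts.columns),
    )


def read_loadings(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def bits_to_hex(bits: np.ndarray) -> str:
    bits = np.asarray(bits, dtype=bool)
    return np.packbits(bits).tobytes().hex()


def hex_to_bits(s: str, n_bits: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(s), dtype=np.uint8)
    return np.unpackbits(raw)[:n_bits].astype(bool)


def read_fingerprints(path: str | Path, n_bits: int) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {
        row["drug_id"]: hex_to_bits(row["fingerprint_hex"], n_bits)
        for _, row in df.iterrows()
    }


def read_ontology(edges_path: str | Path, annotations_path: str | Path) -> Ontology:
    edges = pd.read_csv(edges_path, sep="\t")
    needed = {"term_id", "parent_id", "relation"}
    if not needed <= set(edges.columns):
        raise ValueError(f"ontology edge table needs columns {sorted(needed)}")
    annot = {k: set(v) for k, v in read_gmt(annotations_path).items()}
    terms = sorted(
        set(edges["term_id"]) | set(edges["parent_id"].dropna()) | set(annot)
    )
    parents: dict[str, list] = {}
    for _, row in edges.iterrows():
        if pd.isna(row["parent_id"]) or row["parent_id"] == "":
            continue
        parents.setdefault(row["term_id"], []).append(
            (row["parent_id"], row["relation"])
        )
    return Ontology(terms=terms, parents=parents, annotations=annot)
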