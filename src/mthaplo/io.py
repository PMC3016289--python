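"""File formats: FASTA, variant-profile TSV, annotated Newick, trace TSV, rasters.

Sequences are read with Biopython; trees are serialised as Newick with
``[&muts=...]`` comment annotations (dendropy underneath) so that branch
mutation lists survive a round trip; posterior traces are plain tab-separated
tables with one sampled state per row; frequency surfaces use the ESRI ASCII
grid format.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .tree import MutationTree, Node
from .variants import (
    MISSING,
    NUCLEOTIDES,
    ReferenceSequence,
    SequenceProfile,
    call_variants,
    format_mutation,
    parse_mutation,
)

log = logging.getLogger("mthaplo")

__all__ = [
    "read_fasta", "write_fasta", "read_profiles", "write_profiles",
    "read_tree", "write_tree", "tree_to_newick", "tree_from_newick",
    "read_trace", "write_trace", "read_ascii_grid", "write_ascii_grid",
    "load_config",
]


def read_fasta(path, reference: Optional[ReferenceSequence] = None
               ) -> list[tuple[str, str]]:
    """Read a FASTA file into (label, uppercased sequence) pairs, in order.

    If a reference is given, every record must match its length (site-wise
    scoring assumes aligned, equal-length sequences); a mismatch raises an
    error naming the offending record. Characters outside {A,C,G,T,N,-} are
    rejected.
    """
    allowed = NUCLEOTIDES | MISSING
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - allowed
        if bad:
            raise ValueError(f"record {rec.id!r}: invalid characters {sorted(bad)}")
        if reference is not None and len(seq) != len(reference):
            raise ValueError(
                f"record {rec.id!r}: length {len(seq)} does not match reference "
                f"{reference.name!r} length {len(reference)}"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def profiles_from_fasta(path, reference: ReferenceSequence) -> list[SequenceProfile]:
    """Read sequences and score each against the reference."""
    return [call_variants(seq, reference, sample_id=label)
            for label, seq in read_fasta(path, reference)]


# ---------------------------------------------------------------------------
# variant-profile TSV: sample_id, population, lon, lat, haplogroup, mutations
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = ["sample_id", "population", "lon", "lat", "haplogroup", "mutations"]


def write_profiles(path, profiles: Sequence[SequenceProfile]) -> None:
    rows = []
    for p in profiles:
        rows.append({
            "sample_id": p.sample_id,
            "population": p.population or "",
            "lon": "" if p.lon is None else p.lon,
            "lat": "" if p.lat is None else p.lat,
            "haplogroup": p.haplogroup or "",
            "mutations": " ".join(p.tokens()),
        })
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_profiles(path, reference: Optional[ReferenceSequence] = None
                  ) -> list[SequenceProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        tokens = row["mutations"].split()
        variants = frozenset(parse_mutation(t, reference) for t in tokens)
        out.append(SequenceProfile(
            sample_id=row["sample_id"],
            variants=variants,
            population=row["population"] or None,
            lon=float(row["lon"]) if row.get("lon", "") != "" else None,
            lat=float(row["lat"]) if row.get("lat", "") != "" else None,
            haplogroup=row["haplogroup"] or None,
        ))
    return out


# ---------------------------------------------------------------------------
# annotated Newick for MutationTree
# ---------------------------------------------------------------------------

def tree_to_newick(tree: MutationTree) -> str:
    """Serialise with mutation lists as [&muts=...] branch comments."""
    def render(node: Node) -> str:
        if node.children:
            inner = ",".join(render(c) for c in node.children)
            s = f"({inner})" + (node.name or "")
        else:
            s = node.name or ""
        if node.length is not None:
            s += f":{node.length:.10g}"
        if node.mutations:
            toks = " ".join(format_mutation(v) for v in node.mutations)
            s += f'[&muts="{toks}"]'
        return s
    return render(tree.root) + ";"


def tree_from_newick(newick: str, reference: Optional[ReferenceSequence] = None,
                     name: str = "tree") -> MutationTree:
    dtree = dendropy.Tree.get(
        data=newick, schema="newick", extract_comment_metadata=True,
        suppress_internal_node_taxa=False, preserve_underscores=True,
    )
    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon else dnode.label
        muts = []
        ann = dnode.annotations.get_value("muts")
        if ann:
            for tok in str(ann).replace(",", " ").replace('"', " ").split():
                muts.append(parse_mutation(tok, reference))
        node = Node(label, mutations=muts, length=dnode.edge.length)
        for c in dnode.child_nodes():
            node.add(convert(c))
        return node
    return MutationTree(convert(dtree.seed_node), name=name)


def write_tree(path, tree: MutationTree) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def read_tree(path, reference: Optional[ReferenceSequence] = None) -> MutationTree:
    text = Path(path).read_text()
    try:
        return tree_from_newick(text, reference, name=Path(path).stem)
    except Exception as exc:  # dendropy errors are line-aware already
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# posterior trace TSV
# ---------------------------------------------------------------------------

def write_trace(path, trace: pd.DataFrame) -> None:
    trace.to_csv(path, sep="\t", index=False)


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise ValueError(f"non-rectangular trace in {path} near line {bad}")
    return df


# ---------------------------------------------------------------------------
# ESRI ASCII grid raster
# ---------------------------------------------------------------------------

def write_ascii_grid(path, values: np.ndarray, xllcorner: float, yllcorner: float,
                     cellsize: float, nodata: float = -9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = northernmost row)."""
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner:.10g}\nyllcorner {yllcorner:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\nNODATA_value {nodata:.10g}\n")
        out = np.where(np.isnan(values), nodata, values)
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    for i, line in enumerate(lines[:6]):
        key, val = line.split()
        header[key.lower()] = float(val)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.array([[float(v) for v in line.split()]
                     for line in lines[6:6 + nrows]])
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid in {path} is not {nrows}x{ncols}")
    data[data == header.get("nodata_value", -9999.0)] = np.nan
    return data, header


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
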