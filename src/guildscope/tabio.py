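"""Table and tree input/output plus basic normalisation.

All abundance data in this package lives in pandas DataFrames oriented
taxa x samples (rows x columns): row index = taxon identifiers (bare genus
names or ';'-delimited lineage strings), column index = sample identifiers.
Count tables hold non-negative integers; relative-abundance tables hold
fractions whose columns sum to one.

Trees are ``skbio.TreeNode`` objects read from newick files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("guildscope")

#: Recognised rank prefixes in lineage strings (QIIME/Silva style).
RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}
RANK_ORDER = list(RANK_PREFIXES)
LINEAGE_SEP = ";"


def _check_unique(index: pd.Index, kind: str, path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {kind} identifiers in {path}: {dup}")


def read_count_table(path) -> pd.DataFrame:
    """Read a taxa x samples TSV of integer counts.

    First column holds taxon ids, header row holds sample ids.  Rejects
    duplicate ids, negative values and non-integer entries.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(pd.Index(header), "sample", path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "taxon", path)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.index[df.apply(lambda r: pd.to_numeric(r, errors="coerce").isna().any(), axis=1)]
        raise ValueError(f"non-numeric entries in {path}, rows: {bad.tolist()}")
    if (values < 0).any():
        bad = df.index[(values < 0).any(axis=1)]
        raise ValueError(f"negative counts in {path}, rows: {bad.tolist()}")
    if not np.allclose(values, np.round(values)):
        bad = df.index[(~np.isclose(values, np.round(values))).any(axis=1)]
        raise ValueError(f"non-integer counts in {path}, rows: {bad.tolist()}")
    return df.astype(np.int64)


def write_count_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="taxon")


def read_abundance_table(path) -> pd.DataFrame:
    """Read a taxa x samples TSV of relative abundances (fractions)."""
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    _check_unique(df.index, "taxon", path)
    _check_unique(df.columns, "sample", path)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative abundances in {path}")
    return df


def write_abundance_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="taxon", float_format="%.12g")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV indexed by sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    _check_unique(df.index, "sample", path)
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def to_relative(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-normalise a count (or abundance) table so each sample sums to 1.

    Raises ``ValueError`` listing any all-zero sample.
    """
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total abundance: {zero}")
    return counts.astype(float).div(totals, axis=1)


def parse_lineage(taxon: str) -> dict[str, str]:
    """Split a lineage string into rank -> name; bare names map to genus."""
    fields = [f.strip() for f in taxon.split(LINEAGE_SEP)]
    out: dict[str, str] = {}
    last = -1
    for field in fields:
        matched = None
        for rank, prefix in RANK_PREFIXES.items():
            if field.startswith(prefix):
                out[rank] = field[len(prefix):]
                matched = rank
                break
        if matched is None:
            if len(fields) == 1:
                return {"genus": field}
            raise ValueError(f"malformed lineage field {field!r} in {taxon!r}")
        idx = RANK_ORDER.index(matched)
        if idx <= last:
            raise ValueError(f"out-of-order rank {matched!r} in lineage {taxon!r}")
        last = idx
    return out


def collapse_to_rank(counts: pd.DataFrame, rank: str = "genus") -> pd.DataFrame:
    """Sum rows sharing the same lineage down to ``rank``.

    Rows unassigned at ``rank`` (missing or empty name) are pooled into one
    ``unclassified-<parent>`` row per deepest assigned parent.  Bare taxon
    names (no prefixes) are treated as already collapsed at ``rank``.
    """
    if rank not in RANK_PREFIXES:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANK_ORDER}")
    keys = []
    for taxon in counts.index:
        lin = parse_lineage(str(taxon))
        name = lin.get(rank, "")
        if name:
            keys.append(name)
        else:
            parent = ""
            for r in RANK_ORDER[: RANK_ORDER.index(rank)]:
                if lin.get(r):
                    parent = lin[r]
            keys.append(f"unclassified-{parent}" if parent else "unclassified")
    collapsed = counts.groupby(pd.Index(keys, name=counts.index.name), sort=False).sum()
    return collapsed


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        logger.warning("tree %s: %d missing branch lengths set to 0", path, n_missing)
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length in {path}")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate leaf names in {path}")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_manifest(params: dict, path) -> None:
    """Write a plain-text key/value run manifest (one ``key = value`` per line)."""
    with open(path, "w") as fh:
        for key, value in params.items():
            fh.write(f"{key} = {value}\n")


def read_manifest(path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
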