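"""Sequence encoding, activity-matrix transforms, and fold assignment.

The prediction unit is an open chromatin region (OCR): a summit-centered
DNA window paired with a vector of per-output accessibility scores. Targets
can be used raw, row z-scored (each region standardized across outputs), or
transformed to differences along a cell-lineage tree ("tree-diff"), where
each output column becomes child minus parent accessibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
INDEX_BASE = "ACGT"

__all__ = [
    "EncodedBatch",
    "ActivityMatrix",
    "LineageTree",
    "FoldAssignment",
    "encode_sequences",
    "decode_sequence",
    "zscore_rows",
    "tree_diff",
    "assign_folds",
    "read_fasta",
    "read_activity_tsv",
    "write_activity_tsv",
    "read_tree_tsv",
    "extract_bed_windows",
]


@dataclass
class EncodedBatch:
    """One-hot encoded sequences: (n, 4, L) in A,C,G,T channel order.

    Unknown bases (N etc.) are all-zero columns, so they contribute nothing
    to any convolution score.
    """

    onehot: np.ndarray
    region_ids: list[str]

    @property
    def n(self) -> int:
        return self.onehot.shape[0]

    @property
    def L(self) -> int:
        return self.onehot.shape[2]

    def subset(self, idx) -> "EncodedBatch":
        idx = np.asarray(idx)
        return EncodedBatch(self.onehot[idx], [self.region_ids[i] for i in idx])


@dataclass
class ActivityMatrix:
    """Per-region, per-output real-valued targets."""

    values: np.ndarray  # (n, c)
    region_ids: list[str]
    output_names: list[str]
    transform: str = "raw"  # raw | zscore | treediff

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def c(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "ActivityMatrix":
        idx = np.asarray(idx)
        return ActivityMatrix(
            self.values[idx],
            [self.region_ids[i] for i in idx],
            list(self.output_names),
            self.transform,
        )


@dataclass
class LineageTree:
    """A forest over output names given as a child -> parent mapping."""

    parent: dict[str, str]

    def __post_init__(self):
        for child, par in self.parent.items():
            seen = {child}
            node = par
            while node in self.parent:
                if node in seen:
                    raise ValueError(f"lineage tree contains a cycle through {node!r}")
                seen.add(node)
                node = self.parent[node]

    @property
    def nodes(self) -> list[str]:
        ns: list[str] = []
        for c, p in self.parent.items():
            for x in (c, p):
                if x not in ns:
                    ns.append(x)
        return ns

    @property
    def roots(self) -> list[str]:
        return [n for n in self.nodes if n not in self.parent]

    def edges(self) -> list[tuple[str, str]]:
        """(child, parent) pairs in insertion order."""
        return list(self.parent.items())


@dataclass
class FoldAssignment:
    fold_of: dict[str, int]
    k: int

    def members(self, fold: int) -> list[str]:
        return [r for r, f in self.fold_of.items() if f == fold]

    def indices(self, region_ids: list[str], fold: int) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(region_ids) if self.fold_of[r] == fold], dtype=int
        )


# ----------------------------------------------------------------- encoding
def encode_sequences(
    sequences: dict[str, str], L: int = 300, pad: bool = False
) -> EncodedBatch:
    """One-hot encode named sequences, center-cropping each to length L.

    For an odd overhang the extra base is dropped from the right end.
    Sequences shorter than L raise unless ``pad`` is set, in which case they
    are centered and flanked by all-zero (unknown) columns.
    """
    if not sequences:
        raise ValueError("no sequences provided")
    ids, rows = [], []
    for name, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < L and not pad:
            raise ValueError(
                f"sequence {name!r} has length {len(seq)} < window {L}; "
                "enable padding or provide longer sequences"
            )
        arr = np.zeros((4, L))
        if len(seq) >= L:
            start = (len(seq) - L) // 2
            window = seq[start : start + L]
            dest = 0
        else:
            window = seq
            dest = (L - len(seq)) // 2
        for j, base in enumerate(window):
            idx = BASE_INDEX.get(base)
            if idx is not None:
                arr[idx, dest + j] = 1.0
        ids.append(name)
        rows.append(arr)
    return EncodedBatch(np.stack(rows), ids)


def decode_sequence(onehot: np.ndarray) -> str:
    """Inverse of encoding for a single (4, L) array; zero columns -> N."""
    out = []
    for col in onehot.T:
        if col.sum() == 0:
            out.append("N")
        else:
            out.append(INDEX_BASE[int(col.argmax())])
    return "".join(out)


# --------------------------------------------------------------- transforms
def zscore_rows(raw: ActivityMatrix) -> ActivityMatrix:
    """Standardize each region's activity across outputs (population SD).

    Zero-variance rows cannot be standardized and are dropped with a
    warning, keeping the squared-error loss well defined.
    """
    if raw.transform != "raw":
        raise ValueError(f"expected raw activities, got {raw.transform!r}")
    if raw.c < 2:
        raise ValueError("z-scoring needs at least two outputs")
    mu = raw.values.mean(axis=1, keepdims=True)
    sd = raw.values.std(axis=1, keepdims=True)  # population (1/c) SD
    keep = sd[:, 0] > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d constant region(s) during z-scoring", dropped)
    vals = (raw.values[keep] - mu[keep]) / sd[keep]
    ids = [r for r, k in zip(raw.region_ids, keep) if k]
    return ActivityMatrix(vals, ids, list(raw.output_names), "zscore")


def tree_diff(raw: ActivityMatrix, tree: LineageTree) -> ActivityMatrix:
    """Replace output columns by child-minus-parent differences along the
    lineage tree; one column per tree edge, named ``<child>-<parent>``."""
    col = {name: i for i, name in enumerate(raw.output_names)}
    for name in raw.output_names:
        if name not in tree.parent and name not in tree.roots:
            raise KeyError(f"output {name!r} missing from lineage tree")
    edges = [(c, p) for c, p in tree.edges() if c in col]
    for child, par in edges:
        if par not in col:
            raise KeyError(f"parent {par!r} of {child!r} has no activity column")
    vals = np.column_stack(
        [raw.values[:, col[c]] - raw.values[:, col[p]] for c, p in edges]
    )
    names = [f"{c}-{p}" for c, p in edges]
    return ActivityMatrix(vals, list(raw.region_ids), names, "treediff")


def assign_folds(region_ids: list[str], k: int = 10, seed: int = 0) -> FoldAssignment:
    """Balanced random split into k folds (sizes differ by at most one)."""
    n = len(region_ids)
    if len(set(region_ids)) != n:
        raise ValueError("region ids must be unique")
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} regions into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = f
    return FoldAssignment({r: int(labels[i]) for i, r in enumerate(region_ids)}, k)


# ----------------------------------------------------------------- file I/O
def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_activity_tsv(path) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ActivityMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        "raw",
    )


def write_activity_tsv(act: ActivityMatrix, path) -> None:
    pd.DataFrame(act.values, index=act.region_ids, columns=act.output_names).to_csv(
        path, sep="\t", index_label="region"
    )


def read_tree_tsv(path) -> LineageTree:
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"])
    return LineageTree({str(r.child): str(r.parent) for r in df.itertuples()})


def extract_bed_windows(bed_path, fasta_path, L: int = 300) -> dict[str, str]:
    """Extract L-bp windows around BED interval summits from a reference.

    BED is 0-based half-open. If a 7th column is present it is read as the
    summit offset relative to the interval start; otherwise the midpoint is
    used. Region ids come from the name column when present.
    """
    from pyfaidx import Fasta

    ref = Fasta(str(fasta_path))
    out: dict[str, str] = {}
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"{chrom}:{start}-{end}"
            summit = start + (int(parts[6]) if len(parts) > 6 else (end - start) // 2)
            lo = summit - L // 2
            hi = lo + L
            if lo < 0 or hi > len(ref[chrom]):
                raise ValueError(f"{bed_path}:{ln}: window around summit leaves {chrom}")
            out[name] = str(ref[chrom][lo:hi]).upper()
    return out
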