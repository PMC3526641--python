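"""Cloning-support computations: ORF finding/translation, protein mass
and isoelectric point, domain bookkeeping, and UPGMA trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "ProteinRecord",
    "find_orf",
    "protein_mw",
    "protein_pI",
    "charge_at_pH",
    "p_distance_matrix",
    "TreeNode",
    "upgma",
    "cophenetic_matrix",
]

# Average residue masses (Da); monoisotopic masses are out of scope
# because the reported quantity is a relative molecular mass.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# pKa tables for the Henderson-Hasselbalch net-charge function.
PKA_TABLES = {
    "emboss": {
        "n_term": 8.6, "c_term": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    "bjellqvist": {
        "n_term": 7.5, "c_term": 3.55,
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0, "Y": 10.0,
    },
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptModel:
    sequence: str
    orf_start: int  # 0-based, half-open; includes the stop codon
    orf_end: int

    @property
    def utr5_len(self) -> int:
        return self.orf_start

    @property
    def utr3_len(self) -> int:
        return len(self.sequence) - self.orf_end

    @property
    def orf_len(self) -> int:
        return self.orf_end - self.orf_start


@dataclass
class ProteinRecord:
    residues: str
    domains: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based inclusive

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def mw(self) -> float:
        return protein_mw(self.residues)

    @property
    def pI(self) -> float:
        return protein_pI(self.residues)

    def add_domain(self, name: str, start_aa: int, end_aa: int) -> None:
        if not 1 <= start_aa <= end_aa <= self.length:
            raise ValueError(f"domain {name}: [{start_aa}, {end_aa}] outside [1, {self.length}]")
        self.domains.append((name, start_aa, end_aa))


def find_orf(sequence: str) -> tuple[TranscriptModel | None, ProteinRecord | None]:
    """Longest forward-strand ATG..stop ORF across the three frames.

    The ORF span includes the stop codon; the translated protein does
    not.  Returns ``(None, None)`` when no complete ORF exists.  Ties on
    length go to the leftmost start.
    """
    seq = sequence.upper()
    if len(seq) < 6:
        raise ValueError("sequence shorter than 6 nt cannot contain an ORF")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be over {A, C, G, T}")
    best: tuple[int, int] | None = None
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                length = i + 3 - start
                if (
                    best is None
                    or length > best[1] - best[0]
                    or (length == best[1] - best[0] and start < best[0])
                ):
                    best = (start, i + 3)
                start = None
    if best is None:
        return None, None
    model = TranscriptModel(seq, best[0], best[1])
    protein = str(Seq(seq[best[0] : best[1] - 3]).translate())
    return model, ProteinRecord(protein)


def protein_mw(residues: str) -> float:
    """Average-mass molecular weight: sum of residue masses plus one water."""
    if not residues:
        raise ValueError("empty protein has no molecular weight")
    total = WATER_MASS
    for i, aa in enumerate(residues):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}") from None
    return total


def charge_at_pH(residues: str, pH: float, pka_table: str = "emboss") -> float:
    """Net charge by Henderson-Hasselbalch; strictly decreasing in pH."""
    pka = PKA_TABLES[pka_table]
    counts = {aa: residues.count(aa) for aa in _POSITIVE + _NEGATIVE}
    pos = 1.0 / (1.0 + 10 ** (pH - pka["n_term"]))
    for aa in _POSITIVE:
        pos += counts[aa] / (1.0 + 10 ** (pH - pka[aa]))
    neg = 1.0 / (1.0 + 10 ** (pka["c_term"] - pH))
    for aa in _NEGATIVE:
        neg += counts[aa] / (1.0 + 10 ** (pka[aa] - pH))
    return pos - neg


def protein_pI(residues: str, pka_table: str = "emboss", tol: float = 0.01) -> float:
    """pH of zero net charge, by bisection on [0, 14]."""
    if not residues:
        raise ValueError("empty protein has no isoelectric point")
    for i, aa in enumerate(residues):
        if aa not in AVERAGE_RESIDUE_MASS:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
    lo, hi = 0.0, 14.0
    while hi - lo > tol / 2:
        mid = (lo + hi) / 2
        if charge_at_pH(residues, mid, pka_table) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2, 4)


# ---------------------------------------------------------------------------
# distances and UPGMA


def p_distance_matrix(aligned: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Uncorrected p-distance over aligned columns where both are non-gaps."""
    labels = list(aligned)
    n = len(labels)
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) > 1:
        raise ValueError("aligned sequences differ in length")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aligned[labels[i]], aligned[labels[j]]
            pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not pairs:
                raise ValueError(f"no comparable columns between {labels[i]} and {labels[j]}")
            d = sum(x != y for x, y in pairs) / len(pairs)
            dm[i, j] = dm[j, i] = d
    return labels, dm


@dataclass
class TreeNode:
    """Rooted (ultrametric, for UPGMA output) tree node."""

    label: str | None
    height: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def to_newick(self) -> str:
        return self._newick_inner(None) + ";"

    def _newick_inner(self, parent_height: float | None) -> str:
        if self.is_leaf:
            core = self.label or ""
        else:
            core = "(" + ",".join(c._newick_inner(self.height) for c in self.children) + ")"
        if parent_height is None:
            return core
        return f"{core}:{parent_height - self.height:.10g}"


def _validate_matrix(labels: Sequence[str], dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    n = len(labels)
    if dm.shape != (n, n):
        raise ValueError(f"matrix shape {dm.shape} does not match {n} labels")
    if n < 2:
        raise ValueError("need at least two taxa")
    if np.any(dm < 0):
        raise ValueError("negative distances")
    if not np.allclose(dm, dm.T):
        raise ValueError("asymmetric distance matrix")
    if np.any(np.diag(dm) != 0):
        raise ValueError("nonzero diagonal")
    return dm


def upgma(labels: Sequence[str], dm: np.ndarray) -> TreeNode:
    """UPGMA agglomeration: merge the closest pair at height d/2, update
    distances by the size-weighted arithmetic mean.

    Ties on the minimum distance are broken by the lexicographically
    smallest (sorted) pair of cluster keys, where a cluster's key is its
    smallest leaf label — so the result is invariant to input order.
    """
    dm = _validate_matrix(labels, dm)
    nodes = [TreeNode(lbl, 0.0) for lbl in labels]
    keys = [lbl for lbl in labels]
    sizes = [1] * len(labels)
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[(i, j)] = dm[i, j]
    active = list(range(len(labels)))
    next_id = len(labels)
    store: dict[int, TreeNode] = dict(enumerate(nodes))
    key_of = dict(enumerate(keys))
    size_of = dict(enumerate(sizes))

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                pair_key = tuple(sorted((key_of[i], key_of[j])))
                cand = (d(i, j), pair_key, (i, j))
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dmin, _, (i, j) = best
        node = TreeNode(None, dmin / 2.0, children=sorted(
            [store[i], store[j]], key=lambda nd: min(l.label for l in nd.leaves())
        ))
        store[next_id] = node
        key_of[next_id] = min(key_of[i], key_of[j])
        size_of[next_id] = size_of[i] + size_of[j]
        for k in active:
            if k in (i, j):
                continue
            dn = (size_of[i] * d(i, k) + size_of[j] * d(j, k)) / (size_of[i] + size_of[j])
            dist[(k, next_id) if k < next_id else (next_id, k)] = dn
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return store[active[0]]


def cophenetic_matrix(tree: TreeNode, labels: Sequence[str]) -> np.ndarray:
    """Pairwise cophenetic distances (2 x LCA height) in label order."""
    index = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))

    def walk(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        ia, ib = index[a], index[b]
                        out[ia, ib] = out[ib, ia] = 2.0 * node.height
        return [lbl for g in groups for lbl in g]

    walk(tree)
    return out


def read_distance_tsv(path: str) -> tuple[list[str], np.ndarray]:
    """Square TSV with a header row and a label column."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column labels differ")
    return list(df.columns), df.to_numpy(dtype=float)
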