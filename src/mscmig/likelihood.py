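"""Phylogenetic likelihood p(X|G) under JC69 via Felsenstein pruning.

Site patterns are compressed once per locus; the pruning itself runs in a
compiled kernel with per-node rescaling.  Migration events never enter the
likelihood: they change a lineage's population, not its mutational path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import jc_pruning
from .model import GeneTree, Locus

__all__ = ["jc69_transition", "SitePatternTable", "log_likelihood"]


def jc69_transition(t: float) -> np.ndarray:
    """JC69 transition matrix for a branch of length ``t`` mutations/site."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    e = np.exp(-4.0 * t / 3.0)
    p_same = 0.25 + 0.75 * e
    p_diff = 0.25 - 0.25 * e
    P = np.full((4, 4), p_diff)
    np.fill_diagonal(P, p_same)
    return P


@dataclass
class SitePatternTable:
    """Unique site patterns of one locus with multiplicities.

    Rows of ``patterns`` follow the order of ``names``; ``counts`` sums to
    the alignment length.
    """

    names: list[str]
    patterns: np.ndarray  # (n_seq, n_patterns) int8
    counts: np.ndarray  # float64

    @classmethod
    def from_locus(cls, locus: Locus) -> "SitePatternTable":
        cols, counts = np.unique(locus.seqs.T, axis=0, return_counts=True)
        return cls(names=list(locus.names),
                   patterns=np.ascontiguousarray(cols.T, dtype=np.int8),
                   counts=counts.astype(np.float64))

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def reorder(self, tip_labels: list[str]) -> np.ndarray:
        """Pattern rows permuted into a gene tree's tip order."""
        row = {name: i for i, name in enumerate(self.names)}
        try:
            idx = np.array([row[lab] for lab in tip_labels], dtype=np.int64)
        except KeyError as e:
            raise ValueError(f"sequence {e.args[0]!r} missing from locus") from None
        return np.ascontiguousarray(self.patterns[idx])


def loglik_table(table: SitePatternTable, gtree: GeneTree,
                 tipcodes: np.ndarray | None = None) -> float:
    """Pruning log likelihood of a gene tree given a compressed locus."""
    if tipcodes is None:
        tipcodes = table.reorder(gtree.labels)
    post = np.array([nd for nd in gtree.postorder()
                     if gtree.children[nd, 0] >= 0], dtype=np.int64)
    val = jc_pruning(post, gtree.children, gtree.time, tipcodes, table.counts)
    if np.isnan(val):
        raise ValueError("negative branch length in gene tree")
    return float(val)


def log_likelihood(locus: Locus, gtree: GeneTree) -> float:
    """log p(X|G) for one alignment and one gene tree under JC69."""
    return loglik_table(SitePatternTable.from_locus(locus), gtree)
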