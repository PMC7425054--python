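"""Rank-rank overlap matrices between two ranked gene lists.

For two lists ranked by effect strength (rank 1 = strongest) and a grid of
rank cutoffs, each cell counts the overlap of the two prefixes and scores
it with the hypergeometric upper tail against a background of ``N`` genes:
cell (i, j) holds ``-log10 P(X >= k_ij)`` with ``X ~ hypergeom(N, i, j)``,
capped at a maximum.  This is a minimal prefix-overlap variant
(one-sided enrichment only, no four-quadrant split, no permutation
correction); concordant lists light up along the diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEResult
from .enrichment import hypergeom_tail


@dataclass(frozen=True)
class RankedList:
    """Ordered gene ids, rank 1 first, with the ordering key recorded."""

    label: str
    genes: tuple
    key: str = "abs_log2fc"

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("ranked list must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(
    de: DEResult,
    n: int = 100,
    alpha: float = 0.05,
    p_column: str = "adjusted",
    direction: str = "both",
) -> RankedList:
    """Top ``n`` significant genes by |log2fc| (ties: p asc, id asc).

    Returns a shorter list when fewer genes are significant; raises when
    none are.
    """
    cols = {"adjusted": "padj", "padj": "padj", "raw": "p_value",
            "p_value": "p_value"}
    if p_column not in cols:
        raise ValueError(f"unknown p_column {p_column!r}")
    pcol = cols[p_column]
    t = de.table
    sel = (t["status"] == "tested") & t[pcol].notna() & (t[pcol] <= alpha)
    if direction == "up":
        sel &= t["log2fc"] > 0
    elif direction == "down":
        sel &= t["log2fc"] < 0
    elif direction != "both":
        raise ValueError(f"unknown direction {direction!r}")
    sig = t[sel]
    if not len(sig):
        raise ValueError(f"no significant genes in {de.label}")
    order = sig.assign(_abs=sig["log2fc"].abs(), _id=sig.index).sort_values(
        ["_abs", pcol, "_id"], ascending=[False, True, True]
    )
    return RankedList(label=de.label, genes=tuple(order.index[:n]))


@dataclass
class RRMatrix:
    """Prefix-overlap grid between two ranked lists."""

    label_a: str
    label_b: str
    thresholds_a: tuple
    thresholds_b: tuple
    overlap: np.ndarray
    neglog10_p: np.ndarray
    background_n: int
    cap: float

    def overlap_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.overlap, index=list(self.thresholds_a),
                            columns=list(self.thresholds_b))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.neglog10_p, index=list(self.thresholds_a),
                            columns=list(self.thresholds_b))


def rr_matrix(
    a: RankedList,
    b: RankedList,
    background_n: int,
    step: int = 10,
    cap: float = 300.0,
) -> RRMatrix:
    """Rank-rank overlap matrix on a step grid of prefix cutoffs."""
    if step <= 0:
        raise ValueError("step must be positive")
    union = set(a.genes) | set(b.genes)
    if background_n < len(union):
        raise ValueError(
            f"background_n ({background_n}) smaller than the union of the "
            f"compared lists ({len(union)})"
        )
    ta = tuple(range(step, len(a) + 1, step)) or (len(a),)
    tb = tuple(range(step, len(b) + 1, step)) or (len(b),)
    pos_b = {g: i for i, g in enumerate(b.genes)}
    # position in b for each entry of a (len(b) -> beyond every cutoff)
    posb_of_a = np.array([pos_b.get(g, len(b)) for g in a.genes])
    overlap = np.empty((len(ta), len(tb)), dtype=int)
    nlp = np.empty((len(ta), len(tb)))
    for i, ci in enumerate(ta):
        pb = posb_of_a[:ci]
        for j, cj in enumerate(tb):
            k = int((pb < cj).sum())
            overlap[i, j] = k
            p = hypergeom_tail(background_n, ci, cj, k)
            nlp[i, j] = cap if p <= 0.0 else min(-math.log10(p), cap)
    return RRMatrix(
        label_a=a.label, label_b=b.label, thresholds_a=ta, thresholds_b=tb,
        overlap=overlap, neglog10_p=nlp, background_n=background_n, cap=cap,
    )


def plot_rr_heatmap(m: RRMatrix, path) -> None:
    """Write a static heatmap of the -log10 p grid (unclustered)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(m.neglog10_p, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(m.thresholds_b)), [str(t) for t in m.thresholds_b])
    ax.set_yticks(range(len(m.thresholds_a)), [str(t) for t in m.thresholds_a])
    ax.set_xlabel(f"{m.label_b} rank cutoff")
    ax.set_ylabel(f"{m.label_a} rank cutoff")
    fig.colorbar(im, ax=ax, label="-log10 p (hypergeometric tail)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
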