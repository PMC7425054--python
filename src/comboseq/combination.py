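"""Set algebra over DEG sets: three-way overlaps, combination-exclusive
genes, enhanced regulation, fold-change ranges and top-k signatures.

Exclusivity is defined on significance status (DEG membership), not on fold
change: a combination-exclusive gene is significant under the combination
and under neither mono application.  "Enhanced" regulation requires the
gene to be significant in both the combination and the mono contrast, with
the same fold-change sign and strictly larger magnitude under the
combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEGSet, DEResult, call_degs

logger = logging.getLogger(__name__)


def _genes(s) -> frozenset:
    return frozenset(s.genes if isinstance(s, DEGSet) else s)


@dataclass(frozen=True)
class VennCounts:
    """Disjoint region counts of a three-set Venn partition."""

    labels: tuple
    only_a: int
    only_b: int
    only_c: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    def as_dict(self) -> dict:
        return {
            "only_a": self.only_a,
            "only_b": self.only_b,
            "only_c": self.only_c,
            "ab_only": self.ab_only,
            "ac_only": self.ac_only,
            "bc_only": self.bc_only,
            "abc": self.abc,
        }

    @property
    def union_size(self) -> int:
        return sum(self.as_dict().values())

    def set_size(self, which: str) -> int:
        if which == "a":
            return self.only_a + self.ab_only + self.ac_only + self.abc
        if which == "b":
            return self.only_b + self.ab_only + self.bc_only + self.abc
        if which == "c":
            return self.only_c + self.ac_only + self.bc_only + self.abc
        raise ValueError(which)


def venn_counts(set_a, set_b, set_c, labels: tuple | None = None) -> VennCounts:
    """Exact partition of three gene sets into the seven Venn regions."""
    a, b, c = _genes(set_a), _genes(set_b), _genes(set_c)
    if labels is None:
        labels = tuple(
            s.contrast if isinstance(s, DEGSet) else f"set_{i}"
            for i, s in enumerate((set_a, set_b, set_c))
        )
    return VennCounts(
        labels=labels,
        only_a=len(a - b - c),
        only_b=len(b - a - c),
        only_c=len(c - a - b),
        ab_only=len((a & b) - c),
        ac_only=len((a & c) - b),
        bc_only=len((b & c) - a),
        abc=len(a & b & c),
    )


def exclusive_genes(combo, mono_a, mono_b) -> frozenset:
    """Genes significant under the combination but under neither mono."""
    return _genes(combo) - (_genes(mono_a) | _genes(mono_b))


def combo_vs_combo_exclusive(combo_a, combo_b) -> tuple[frozenset, frozenset]:
    """Per-combination exclusive sets: (A \\ B, B \\ A)."""
    a, b = _genes(combo_a), _genes(combo_b)
    return a - b, b - a


def enhanced_genes(
    combo_de: DEResult,
    mono_de: DEResult,
    deg_combo: DEGSet,
    deg_mono: DEGSet,
) -> pd.DataFrame:
    """Genes significant in both contrasts whose fold change keeps its sign
    and strictly grows in magnitude under the combination.

    Returns a frame indexed by gene with ``lfc_combo`` and ``lfc_mono``.
    Genes present in only one DE result are excluded (and logged).
    """
    common = _genes(deg_combo) & _genes(deg_mono)
    tc, tm = combo_de.table, mono_de.table
    missing = [g for g in common if g not in tc.index or g not in tm.index]
    if missing:
        logger.warning("%d genes present in one DE result only; excluded",
                       len(missing))
        common -= set(missing)
    genes = sorted(common)
    lc = tc.loc[genes, "log2fc"]
    lm = tm.loc[genes, "log2fc"]
    keep = (np.sign(lc) == np.sign(lm)) & (lc.abs() > lm.abs())
    out = pd.DataFrame({"lfc_combo": lc[keep], "lfc_mono": lm[keep]})
    out.index.name = "gene_id"
    return out


@dataclass(frozen=True)
class LfcRange:
    """Min/max log2 fold change over a contrast's DEG set."""

    contrast: str
    min_lfc: float
    max_lfc: float
    n: int

    @property
    def empty(self) -> bool:
        return self.n == 0


def lfc_range(de: DEResult, degs: DEGSet) -> LfcRange:
    """Fold-change range over DEG members; empty set gives an explicit
    empty-range result rather than an exception."""
    genes = [g for g in _genes(degs) if g in de.table.index]
    if not genes:
        return LfcRange(contrast=de.label, min_lfc=float("nan"),
                        max_lfc=float("nan"), n=0)
    vals = de.table.loc[genes, "log2fc"]
    return LfcRange(contrast=de.label, min_lfc=float(vals.min()),
                    max_lfc=float(vals.max()), n=len(genes))


@dataclass
class TopKSignature:
    """Top-k combination DEGs by |log2fc|, annotated with both mono fold
    changes and exclusivity / enhancement flags."""

    contrast: str
    direction: str
    k: int
    table: pd.DataFrame


def top_k_signature(
    combo_de: DEResult,
    mono_des: tuple[DEResult, DEResult],
    k: int = 20,
    direction: str = "both",
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
    p_column: str = "adjusted",
) -> TopKSignature:
    """Top ``k`` combination DEGs ranked by |log2fc| (ties: p asc, id asc).

    ``exclusive`` flags genes significant in neither mono contrast;
    ``enhanced`` flags genes significant in at least one mono whose fold
    change, for every mono where significant, keeps its sign and strictly
    grows under the combination.  A shorter list is returned when fewer
    than ``k`` genes are significant.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    degs = call_degs(combo_de, alpha=alpha, min_abs_lfc=min_abs_lfc,
                     p_column=p_column, direction=direction)
    mono_a, mono_b = mono_des
    deg_a = call_degs(mono_a, alpha=alpha, min_abs_lfc=min_abs_lfc,
                      p_column=p_column, direction="both")
    deg_b = call_degs(mono_b, alpha=alpha, min_abs_lfc=min_abs_lfc,
                      p_column=p_column, direction="both")
    pcol = "padj" if p_column in ("adjusted", "padj") else "p_value"
    t = combo_de.table.loc[sorted(degs.genes)]
    order = t.assign(_abs=t["log2fc"].abs(), _id=t.index).sort_values(
        ["_abs", pcol, "_id"], ascending=[False, True, True]
    )
    top = order.head(k)
    rows = []
    for g in top.index:
        la = mono_a.table["log2fc"].get(g, np.nan)
        lb = mono_b.table["log2fc"].get(g, np.nan)
        lc = top.loc[g, "log2fc"]
        sig_a, sig_b = g in deg_a, g in deg_b
        exclusive = not (sig_a or sig_b)
        enh = (sig_a or sig_b) and all(
            np.sign(lc) == np.sign(lm) and abs(lc) > abs(lm)
            for lm, sig in ((la, sig_a), (lb, sig_b))
            if sig
        )
        rows.append((g, lc, la, lb, sig_a, sig_b, exclusive, enh))
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "log2fc_combo", "log2fc_monoA", "log2fc_monoB",
            "monoA_significant", "monoB_significant", "exclusive", "enhanced",
        ],
    ).set_index("gene_id")
    return TopKSignature(contrast=combo_de.label, direction=direction, k=k,
                         table=table)
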