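"""Directional pathway over-representation ranking and the
combination-specific pathway selection rule.

Enrichment of a selected (direction-aware) gene set within each pathway is
scored by the hypergeometric upper tail: with ``N`` universe genes, ``K``
pathway members in the universe, ``n`` selected genes and ``k`` selected
members, ``p = P(X >= k)``.  Pathways with too few affected genes
(``k < min_affected``, default 6 per the "affected genes > 5" gate) or
``p > alpha`` are dropped before ranking; rankings are per direction,
ordered by (p asc, k desc, name asc) and truncated to a top list.

A pathway is *combination specific* when it ranks within the combination's
top ``top_in`` (default 20) while being absent from the top ``top_out``
(default 30) of both mono rankings; unranked mono pathways count as
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import DEResult

logger = logging.getLogger(__name__)


class GmtParseError(ValueError):
    """Raised on malformed GMT lines."""


@dataclass
class PathwayDB:
    """Named gene sets (pathway -> members) with descriptions."""

    members: dict
    descriptions: dict = field(default_factory=dict)
    source: str | None = None

    def __post_init__(self) -> None:
        for name, genes in self.members.items():
            if len(genes) == 0:
                raise GmtParseError(f"pathway {name!r} has no members")
            self.members[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def names(self) -> list[str]:
        return list(self.members)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.members:
                desc = self.descriptions.get(name, "")
                genes = "\t".join(sorted(self.members[name]))
                fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gmt(path) -> PathwayDB:
    """Parse a GMT file (name, description, tab-separated members per line).

    Duplicate members within a line are deduplicated with a warning; lines
    with fewer than three fields or no members raise :class:`GmtParseError`
    naming the line.
    """
    members: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: pathway {name!r} has no members")
            if name in members:
                raise GmtParseError(f"{path}: line {lineno}: duplicate pathway {name!r}")
            if len(set(genes)) < len(genes):
                logger.warning("%s: line %d: duplicate members in %r deduplicated",
                               path, lineno, name)
            members[name] = frozenset(genes)
            descriptions[name] = desc
    return PathwayDB(members=members, descriptions=descriptions, source=str(path))


def select_genes_for_enrichment(
    de: DEResult,
    alpha: float = 0.05,
    min_abs_lfc: float = 1.25,
    p_column: str = "raw",
    direction: str = "both",
) -> frozenset:
    """Genes passing the enrichment gates (raw p by default) in a direction."""
    cols = {"raw": "p_value", "p_value": "p_value", "adjusted": "padj", "padj": "padj"}
    if p_column not in cols:
        raise ValueError(f"unknown p_column {p_column!r}")
    t = de.table
    sel = (t["status"] == "tested") & t[cols[p_column]].notna() & (
        t[cols[p_column]] <= alpha
    )
    if direction == "up":
        sel &= t["log2fc"] >= min_abs_lfc
    elif direction == "down":
        sel &= t["log2fc"] <= -min_abs_lfc
    elif direction == "both":
        sel &= t["log2fc"].abs() >= min_abs_lfc
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return frozenset(t.index[sel])


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail ``P(X >= k)`` of the hypergeometric(N, K, n) law."""
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent arguments N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K, n)={min(K, n)}]")
    if k == 0:
        return 1.0
    return float(min(max(hypergeom.sf(k - 1, N, K, n), 0.0), 1.0))


def rank_pathways(
    selected_up: frozenset,
    selected_down: frozenset,
    universe: frozenset,
    db: PathwayDB,
    alpha: float = 0.05,
    min_affected: int = 6,
    top: int = 50,
    key: str = "p",
) -> pd.DataFrame:
    """Per-direction over-representation ranking.

    Pathways are intersected with the universe first; records failing the
    gates (``k < min_affected`` or ``p > alpha``) are dropped before ranks
    are assigned.  ``key="p"`` orders by (p asc, k desc, name asc);
    ``key="k"`` by (k desc, p asc, name asc).  Returns one frame with a
    ``direction`` column and 1-based ``rank`` within each direction,
    truncated to ``top`` rows per direction.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    if not len(db):
        raise ValueError("empty pathway collection")
    if key not in ("p", "k"):
        raise ValueError(f"unknown ranking key {key!r}")
    frames = []
    for direction, selected in (("up", selected_up), ("down", selected_down)):
        selected = frozenset(selected)
        if not selected <= universe:
            raise ValueError(f"selected {direction} genes not contained in universe")
        N, n = len(universe), len(selected)
        rows = []
        for name in db.names:
            memb = db.members[name] & universe
            K = len(memb)
            if K == 0:
                continue
            affected = selected & memb
            k = len(affected)
            if k < min_affected:
                continue
            p = hypergeom_tail(N, K, n, k)
            if p > alpha:
                continue
            rows.append(
                (name, direction, N, K, n, k, p, ",".join(sorted(affected)))
            )
        dtypes = {"pathway": object, "direction": object, "N": np.int64,
                  "K": np.int64, "n": np.int64, "k": np.int64, "p": float,
                  "affected_genes": object}
        f = pd.DataFrame(rows, columns=list(dtypes)).astype(dtypes)
        if key == "p":
            f = f.sort_values(["p", "k", "pathway"], ascending=[True, False, True])
        else:
            f = f.sort_values(["k", "p", "pathway"], ascending=[False, True, True])
        f = f.head(top).reset_index(drop=True)
        f.insert(7, "rank", np.arange(1, len(f) + 1, dtype=np.int64))
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ComboPathwayRule:
    """Rank gates of the combination-specificity rule."""

    top_in: int = 20
    top_out: int = 30

    def __post_init__(self) -> None:
        if self.top_in > self.top_out:
            raise ValueError(
                f"top_in ({self.top_in}) must not exceed top_out ({self.top_out})"
            )


def _rank_lookup(ranking: pd.DataFrame) -> dict:
    return {
        (r.pathway, r.direction): int(r.rank) for r in ranking.itertuples()
    }


def combo_specific_pathways(
    rank_combo: pd.DataFrame,
    rank_monoA: pd.DataFrame,
    rank_monoB: pd.DataFrame,
    rule: ComboPathwayRule = ComboPathwayRule(),
) -> pd.DataFrame:
    """Apply the combination-specificity rule to three rankings.

    A (pathway, direction) qualifies when its combination rank is
    ``<= rule.top_in`` and each mono ranking either does not contain it or
    ranks it strictly beyond ``rule.top_out``.  Rows whose only failure is a
    mono rank *exactly at* ``top_out`` are flagged ``boundary`` instead of
    silently dropped, since the inclusive/exclusive reading of the mono gate
    is ambiguous.  Returns all combination rows within ``top_in`` with
    ``qualifies`` and ``boundary`` flags; mono ranks are nullable integers.
    """
    la, lb = _rank_lookup(rank_monoA), _rank_lookup(rank_monoB)
    rows = []
    for r in rank_combo.itertuples():
        rc = int(r.rank)
        if rc > rule.top_in:
            continue
        key_pd = (r.pathway, r.direction)
        ra, rb = la.get(key_pd), lb.get(key_pd)
        ok_a = ra is None or ra > rule.top_out
        ok_b = rb is None or rb > rule.top_out
        qualifies = ok_a and ok_b
        loose_a = ra is None or ra >= rule.top_out
        loose_b = rb is None or rb >= rule.top_out
        boundary = (not qualifies) and loose_a and loose_b
        rows.append((r.pathway, r.direction, rc, ra, rb, qualifies, boundary))
    out = pd.DataFrame(
        rows,
        columns=[
            "pathway", "direction", "rank_combo", "rank_monoA", "rank_monoB",
            "qualifies", "boundary",
        ],
    )
    out["rank_monoA"] = out["rank_monoA"].astype("Int64")
    out["rank_monoB"] = out["rank_monoB"].astype("Int64")
    return out
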