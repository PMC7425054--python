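"""Synthetic bulk RNA-seq counts for a drug-combination study design.

Emulates a design with two cell lines, five exposure conditions per line
(vehicle control, two single agents, and each agent combined with a pathway
inhibitor) and triplicate libraries per condition.  Genes belong to planted
effect classes:

``null``
    no expression change anywhere;
``monoA_only`` / ``monoB_only``
    responds to one agent; the effect carries into that agent's combination
    at the same size (the drug is still present in the combination);
``shared``
    responds to both agents and both combinations;
``comboA_exclusive`` / ``comboB_exclusive``
    responds only under the combination — the class the downstream
    exclusivity analysis is meant to recover;
``enhanced``
    responds to one agent and more strongly (same sign) to its combination.

Counts are negative binomial with ``Var = mu + alpha * mu^2`` and mean
``mu_gj = s_j * q_g * 2^lfc(g, condition(j))`` where ``q_g`` is a
log-normal baseline and ``s_j`` a jittered per-sample size factor.  All
randomness is governed by the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de import CountMatrix
from .enrichment import PathwayDB

CONDITIONS = ("control", "monoA", "monoB", "comboA", "comboB")
EFFECT_CLASSES = (
    "null",
    "monoA_only",
    "monoB_only",
    "shared",
    "comboA_exclusive",
    "comboB_exclusive",
    "enhanced",
)

#: which conditions a class perturbs (enhanced handled separately, per axis)
_CLASS_CONDITIONS = {
    "null": (),
    "monoA_only": ("monoA", "comboA"),
    "monoB_only": ("monoB", "comboB"),
    "shared": ("monoA", "monoB", "comboA", "comboB"),
    "comboA_exclusive": ("comboA",),
    "comboB_exclusive": ("comboB",),
}


def _default_proportions() -> dict:
    return {
        "null": 0.60,
        "monoA_only": 0.08,
        "monoB_only": 0.08,
        "shared": 0.08,
        "comboA_exclusive": 0.06,
        "comboB_exclusive": 0.06,
        "enhanced": 0.04,
    }


@dataclass
class SimulationConfig:
    """Study-design and distributional parameters of the generator.

    ``effect_lfc`` is the planted |log2 fold change| of the non-enhanced
    effect classes; enhanced genes get ``enhanced_mono_lfc`` under their
    mono condition and ``enhanced_mono_lfc + enhanced_delta`` (same sign)
    under the matching combination.  ``size_factor_log2_jitter`` is the
    half-width of the log2-uniform per-sample depth jitter.
    """

    n_genes: int = 22000
    n_replicates: int = 3
    cell_lines: tuple = ("L1", "L2")
    conditions: tuple = CONDITIONS
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    effect_proportions: dict = field(default_factory=_default_proportions)
    effect_lfc: float = 2.0
    enhanced_mono_lfc: float = 1.5
    enhanced_delta: float = 1.0
    size_factor_log2_jitter: float = 0.2
    n_pathways: int = 50
    pathway_size: int = 20
    pathway_purity: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes and n_replicates must be positive")
        if tuple(self.conditions) != CONDITIONS:
            raise ValueError(f"conditions must be {CONDITIONS}")
        if not self.cell_lines:
            raise ValueError("at least one cell line required")
        unknown = set(self.effect_proportions) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")
        props = np.array(
            [self.effect_proportions.get(c, 0.0) for c in EFFECT_CLASSES]
        )
        if (props < 0).any():
            raise ValueError("effect proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"effect proportions sum to {props.sum()}, not 1")
        disp = np.asarray(self.dispersion, dtype=float)
        if disp.ndim not in (0, 1):
            raise ValueError("dispersion must be scalar or per-gene")
        if disp.ndim == 1 and disp.size != self.n_genes:
            raise ValueError("per-gene dispersion length must equal n_genes")
        if (disp < 0).any():
            raise ValueError("dispersion must be >= 0")
        if self.size_factor_log2_jitter < 0:
            raise ValueError("size-factor jitter must be >= 0")
        if self.enhanced_delta <= 0:
            raise ValueError("enhanced_delta must be > 0")
        if not 0.0 <= self.pathway_purity <= 1.0:
            raise ValueError("pathway_purity must lie in [0, 1]")
        if self.n_pathways < 0:
            raise ValueError("n_pathways must be >= 0")
        if self.n_pathways > 0 and not 2 <= self.pathway_size:
            raise ValueError("pathway_size must be >= 2")
        if self.n_pathways > 0 and self.pathway_size > self.n_genes:
            raise ValueError("pathway_size exceeds n_genes")


@dataclass
class GroundTruth:
    """Planted per-gene labels and fold changes, and (after
    :func:`emit_pathways`) the seeded-pathway table.

    ``genes`` is indexed by gene id with columns ``effect_class``, ``sign``,
    ``enhanced_axis`` ("A"/"B"/"") and one ``lfc_<condition>`` column per
    condition.  Combination-exclusive genes have nonzero lfc only under
    their combination; enhanced genes satisfy |lfc_combo| > |lfc_mono| with
    equal sign by construction.
    """

    genes: pd.DataFrame
    pathways: pd.DataFrame | None = None

    def lfc_table(self) -> pd.DataFrame:
        return self.genes[[f"lfc_{c}" for c in CONDITIONS]]

    def genes_in_class(self, effect_class: str) -> list[str]:
        sel = self.genes["effect_class"] == effect_class
        return list(self.genes.index[sel])


def _apportion(n: int, proportions: dict) -> dict:
    """Largest-remainder apportionment of ``n`` genes over classes."""
    classes = [c for c in EFFECT_CLASSES if proportions.get(c, 0.0) > 0]
    raw = np.array([proportions[c] * n for c in classes])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(classes, base))


def _planted_lfc(genes: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    lfc = pd.DataFrame(
        0.0, index=genes.index, columns=[f"lfc_{c}" for c in CONDITIONS]
    )
    for cls, conds in _CLASS_CONDITIONS.items():
        sel = genes["effect_class"] == cls
        for c in conds:
            lfc.loc[sel, f"lfc_{c}"] = genes.loc[sel, "sign"] * cfg.effect_lfc
    enh = genes["effect_class"] == "enhanced"
    for axis, mono, combo in (("A", "monoA", "comboA"), ("B", "monoB", "comboB")):
        sel = enh & (genes["enhanced_axis"] == axis)
        lfc.loc[sel, f"lfc_{mono}"] = genes.loc[sel, "sign"] * cfg.enhanced_mono_lfc
        lfc.loc[sel, f"lfc_{combo}"] = genes.loc[sel, "sign"] * (
            cfg.enhanced_mono_lfc + cfg.enhanced_delta
        )
    return lfc


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a count matrix with planted effects; returns counts + truth.

    Reproducible: the same config (including seed) yields bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    G = config.n_genes
    gene_ids = [f"G{i:06d}" for i in range(1, G + 1)]

    counts_per_class = _apportion(G, config.effect_proportions)
    labels = np.concatenate(
        [np.repeat(c, k) for c, k in counts_per_class.items()]
    )
    labels = labels[rng.permutation(G)]
    signs = rng.choice([-1.0, 1.0], size=G)
    axes = rng.choice(["A", "B"], size=G)
    genes = pd.DataFrame(
        {
            "effect_class": labels,
            "sign": np.where(labels == "null", 0.0, signs),
            "enhanced_axis": np.where(labels == "enhanced", axes, ""),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    lfc = _planted_lfc(genes, config)
    truth = GroundTruth(genes=pd.concat([genes, lfc], axis=1))

    q = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=G))
    alpha = np.broadcast_to(
        np.asarray(config.dispersion, dtype=float), (G,)
    ).copy()

    samples = []
    for cl in config.cell_lines:
        for cond in CONDITIONS:
            for r in range(1, config.n_replicates + 1):
                samples.append((f"{cl}_{cond}_r{r}", cl, cond, r))
    meta = pd.DataFrame(
        samples, columns=["sample", "cell_line", "condition", "replicate"]
    ).set_index("sample")

    j = config.size_factor_log2_jitter
    sf = 2.0 ** rng.uniform(-j, j, size=len(meta)) if j > 0 else np.ones(len(meta))

    lfc_arr = lfc.to_numpy()
    cond_idx = {c: i for i, c in enumerate(CONDITIONS)}
    mat = np.empty((G, len(meta)), dtype=np.int64)
    pois = alpha == 0
    for jcol, (sid, row) in enumerate(meta.iterrows()):
        mu = sf[jcol] * q * 2.0 ** lfc_arr[:, cond_idx[row["condition"]]]
        col = np.empty(G, dtype=np.int64)
        if pois.any():
            col[pois] = rng.poisson(mu[pois])
        if (~pois).any():
            r_par = 1.0 / alpha[~pois]
            p_par = r_par / (r_par + mu[~pois])
            col[~pois] = rng.negative_binomial(r_par, p_par)
        mat[:, jcol] = col

    counts = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                          columns=meta.index)
    return CountMatrix(counts, meta), truth


def emit_pathways(
    ground_truth: GroundTruth, config: SimulationConfig
) -> PathwayDB:
    """Build a pathway collection with seeded and background sets.

    One pathway per effect class present in the config is seeded with that
    class's genes at ``pathway_purity`` (remaining members uniform over all
    genes); the rest of the ``n_pathways`` draw members uniformly.  Updates
    ``ground_truth.pathways`` with the seeding table and returns a
    :class:`PathwayDB` (GMT-writable).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    all_genes = np.asarray(ground_truth.genes.index)
    members: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    rows = []

    seed_classes = [
        c
        for c in EFFECT_CLASSES
        if c != "null" and config.effect_proportions.get(c, 0.0) > 0
    ]
    size = config.pathway_size
    n_seeded = min(len(seed_classes), config.n_pathways)
    for cls in seed_classes[:n_seeded]:
        pool = np.asarray(ground_truth.genes_in_class(cls))
        n_from = int(round(config.pathway_purity * size))
        n_from = min(n_from, len(pool))
        chosen = rng.choice(pool, size=n_from, replace=False) if n_from else np.array([], dtype=object)
        rest_pool = np.setdiff1d(all_genes, chosen, assume_unique=False)
        n_rest = size - n_from
        rest = rng.choice(rest_pool, size=n_rest, replace=False) if n_rest else np.array([], dtype=object)
        name = f"PW_{cls.upper()}"
        members[name] = frozenset(np.concatenate([chosen, rest]).tolist())
        descriptions[name] = f"seeded:{cls}"
        rows.append((name, cls, config.pathway_purity, size))

    for i in range(config.n_pathways - n_seeded):
        name = f"PW_BG{i + 1:03d}"
        members[name] = frozenset(
            rng.choice(all_genes, size=size, replace=False).tolist()
        )
        descriptions[name] = "background"
        rows.append((name, "", 0.0, size))

    ground_truth.pathways = pd.DataFrame(
        rows, columns=["pathway", "seeded_class", "purity", "n_members"]
    ).set_index("pathway")
    return PathwayDB(members=members, descriptions=descriptions, source=None)
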