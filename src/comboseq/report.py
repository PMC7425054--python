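"""End-to-end analysis: counts -> per-contrast DE -> combination set
algebra -> pathway rankings -> combination-specific pathways -> rank-rank
matrices -> consolidated TSV tree plus a machine-readable summary.

Every threshold is carried in :class:`RunConfig`, echoed to the run log and
to ``summary.json``; every number in the summary is re-derivable from the
per-stage TSVs.  Output is deterministic for a fixed input and config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import combination as comb
from . import enrichment as enr
from . import rankrank as rr
from .de import CountMatrix, call_degs, estimate_dispersion, size_factors, wald_test
from .io import read_counts, read_flat_config, write_de_table, write_gene_set

logger = logging.getLogger(__name__)

CONTRAST_ROLES = ("monoA", "monoB", "comboA", "comboB")
COMBO_OF_MONO = {"comboA": "monoA", "comboB": "monoB"}


class ReportError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """All inputs and thresholds of a full analysis run."""

    counts: str
    samples: str
    gmt: str
    outdir: str
    # condition labels in the sample sheet for each design role
    condition_control: str = "control"
    condition_monoA: str = "monoA"
    condition_monoB: str = "monoB"
    condition_comboA: str = "comboA"
    condition_comboB: str = "comboB"
    # DEG thresholds
    de_alpha: float = 0.05
    de_lfc: float = 1.0
    de_p_column: str = "adjusted"
    # enrichment gates
    enrich_alpha: float = 0.05
    enrich_lfc: float = 1.25
    enrich_p_column: str = "raw"
    min_affected: int = 6
    top: int = 50
    # combination-specificity rule
    top_in: int = 20
    top_out: int = 30
    # rank-rank
    rr_n: int = 100
    rr_step: int = 10
    # top-k gene signature
    top_k: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("de_alpha", "de_lfc", "enrich_alpha", "enrich_lfc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("min_affected", "top", "top_in", "top_out", "rr_n",
                     "rr_step", "top_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.top_in > self.top_out:
            raise ValueError(
                f"top_in ({self.top_in}) must not exceed top_out ({self.top_out})"
            )

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        raw = read_flat_config(path)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        kwargs = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name not in raw:
                continue
            v = raw[f_.name]
            if f_.type in ("float",):
                v = float(v)
            elif f_.type in ("int",):
                v = int(v)
            kwargs[f_.name] = v
        missing = {"counts", "samples", "gmt", "outdir"} - set(kwargs)
        if missing:
            raise ValueError(f"config misses required keys: {sorted(missing)}")
        return cls(**kwargs)


def _condition_map(config: RunConfig) -> dict:
    return {
        "control": config.condition_control,
        "monoA": config.condition_monoA,
        "monoB": config.condition_monoB,
        "comboA": config.condition_comboA,
        "comboB": config.condition_comboB,
    }


def run_report(config: RunConfig) -> dict:
    """Run the full analysis; writes the output tree and returns the summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config.{k} = {v}" for k, v in asdict(config).items()]

    def stage(name):
        log_lines.append(f"stage {name} @ {time.strftime('%H:%M:%S')}")

    def fail(name, exc):
        log_lines.append(f"stage {name} FAILED: {exc}")
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise ReportError(f"stage {name!r} failed: {exc}") from exc

    try:
        stage("read_inputs")
        cm = read_counts(config.counts, config.samples)
        db = enr.read_gmt(config.gmt)
    except ReportError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("read_inputs", exc)

    cond_map = _condition_map(config)
    have = set(cm.sample_meta["condition"])
    missing = [v for v in cond_map.values() if v not in have]
    if missing:
        fail("read_inputs", ValueError(f"conditions absent from sample sheet: {missing}"))

    # thresholds only: paths vary between runs and live in the run log
    summary: dict = {
        "config": {k: v for k, v in asdict(config).items()
                   if k not in ("counts", "samples", "gmt", "outdir")},
        "cell_lines": {},
    }
    for cl in sorted(cm.sample_meta["cell_line"].unique()):
        cl_dir = outdir / cl
        cl_dir.mkdir(exist_ok=True)
        s: dict = {}
        try:
            stage(f"{cl}:differential_expression")
            sub = cm.subset(cell_line=cl)
            factors = size_factors(sub)
            disp = estimate_dispersion(sub, factors=factors)
            de = {}
            for role in CONTRAST_ROLES:
                res = wald_test(
                    sub, (cond_map[role], cond_map["control"]),
                    factors=factors, dispersions=disp,
                )
                de[role] = res
                write_de_table(res, cl_dir / f"de_{role}_vs_control.tsv")
            degs = {
                role: call_degs(de[role], alpha=config.de_alpha,
                                min_abs_lfc=config.de_lfc,
                                p_column=config.de_p_column)
                for role in CONTRAST_ROLES
            }
            s["deg_counts"] = {r: len(degs[r]) for r in CONTRAST_ROLES}
        except ReportError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(f"{cl}:differential_expression", exc)

        try:
            stage(f"{cl}:combination_sets")
            s["venn"] = {}
            s["exclusive_counts"] = {}
            s["enhanced_counts"] = {}
            s["lfc_ranges"] = {}
            for combo in ("comboA", "comboB"):
                v = comb.venn_counts(degs["monoA"], degs["monoB"], degs[combo],
                                     labels=("monoA", "monoB", combo))
                pd.Series(v.as_dict()).to_csv(
                    cl_dir / f"venn_{combo}.tsv", sep="\t", header=["genes"]
                )
                s["venn"][combo] = v.as_dict()
                excl = comb.exclusive_genes(degs[combo], degs["monoA"], degs["monoB"])
                write_gene_set(excl, cl_dir / f"exclusive_{combo}.tsv")
                s["exclusive_counts"][combo] = len(excl)
                enh = comb.enhanced_genes(de[combo], de[COMBO_OF_MONO[combo]],
                                          degs[combo], degs[COMBO_OF_MONO[combo]])
                enh.to_csv(cl_dir / f"enhanced_{combo}.tsv", sep="\t",
                           float_format="%.10g")
                s["enhanced_counts"][combo] = int(len(enh))
            a_only, b_only = comb.combo_vs_combo_exclusive(degs["comboA"],
                                                           degs["comboB"])
            write_gene_set(a_only, cl_dir / "exclusive_comboA_vs_comboB.tsv")
            write_gene_set(b_only, cl_dir / "exclusive_comboB_vs_comboA.tsv")
            s["combo_vs_combo_exclusive"] = {
                "comboA_only": len(a_only), "comboB_only": len(b_only),
            }
            ranges = []
            for role in CONTRAST_ROLES:
                r_ = comb.lfc_range(de[role], degs[role])
                ranges.append((role, r_.min_lfc, r_.max_lfc, r_.n))
                s["lfc_ranges"][role] = {
                    "min": None if r_.empty else r_.min_lfc,
                    "max": None if r_.empty else r_.max_lfc,
                    "n": r_.n,
                }
            pd.DataFrame(ranges, columns=["contrast", "min_lfc", "max_lfc", "n"]
                         ).to_csv(cl_dir / "lfc_ranges.tsv", sep="\t",
                                  index=False, float_format="%.10g")
            for combo in ("comboA", "comboB"):
                for direction in ("up", "down"):
                    sig = comb.top_k_signature(
                        de[combo], (de["monoA"], de["monoB"]), k=config.top_k,
                        direction=direction, alpha=config.de_alpha,
                        min_abs_lfc=config.de_lfc, p_column=config.de_p_column,
                    )
                    sig.table.to_csv(
                        cl_dir / f"top{config.top_k}_{combo}_{direction}.tsv",
                        sep="\t", float_format="%.10g",
                    )
        except ReportError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(f"{cl}:combination_sets", exc)

        try:
            stage(f"{cl}:pathways")
            rankings = {}
            for role in CONTRAST_ROLES:
                t = de[role].table
                universe = frozenset(t.index[t["status"] == "tested"])
                sel_up = enr.select_genes_for_enrichment(
                    de[role], alpha=config.enrich_alpha,
                    min_abs_lfc=config.enrich_lfc,
                    p_column=config.enrich_p_column, direction="up")
                sel_dn = enr.select_genes_for_enrichment(
                    de[role], alpha=config.enrich_alpha,
                    min_abs_lfc=config.enrich_lfc,
                    p_column=config.enrich_p_column, direction="down")
                ranking = enr.rank_pathways(
                    sel_up, sel_dn, universe, db, alpha=config.enrich_alpha,
                    min_affected=config.min_affected, top=config.top)
                ranking.to_csv(cl_dir / f"pathways_{role}.tsv", sep="\t",
                               index=False, float_format="%.10g")
                rankings[role] = ranking
            rule = enr.ComboPathwayRule(top_in=config.top_in,
                                        top_out=config.top_out)
            s["combo_specific_pathways"] = {}
            for combo in ("comboA", "comboB"):
                spec_ = enr.combo_specific_pathways(
                    rankings[combo], rankings["monoA"], rankings["monoB"],
                    rule=rule)
                spec_.to_csv(cl_dir / f"combo_specific_{combo}.tsv", sep="\t",
                             index=False)
                qual = spec_[spec_["qualifies"]]
                s["combo_specific_pathways"][combo] = sorted(
                    f"{r.pathway} ({r.direction})" for r in qual.itertuples()
                )
        except ReportError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(f"{cl}:pathways", exc)

        try:
            stage(f"{cl}:rank_rank")
            s["rank_rank"] = {}
            for combo, mono in COMBO_OF_MONO.items():
                name = f"{combo}_vs_{mono}"
                try:
                    la = rr.rank_genes(de[combo], n=config.rr_n,
                                       alpha=config.de_alpha,
                                       p_column=config.de_p_column)
                    lb = rr.rank_genes(de[mono], n=config.rr_n,
                                       alpha=config.de_alpha,
                                       p_column=config.de_p_column)
                except ValueError:
                    s["rank_rank"][name] = None  # no significant genes
                    continue
                t = de[combo].table
                background = int((t["status"] == "tested").sum())
                m = rr.rr_matrix(la, lb, background_n=background,
                                 step=config.rr_step)
                m.to_frame().to_csv(cl_dir / f"rr_{name}.tsv", sep="\t",
                                    index_label="cutoff_combo",
                                    float_format="%.10g")
                s["rank_rank"][name] = {
                    "background_n": background,
                    "max_neglog10_p": float(m.neglog10_p.max()),
                    "diag_overlap": [int(m.overlap[i, i])
                                     for i in range(min(m.overlap.shape))],
                }
        except ReportError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(f"{cl}:rank_rank", exc)

        summary["cell_lines"][cl] = s

    stage("write_summary")
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return summary
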