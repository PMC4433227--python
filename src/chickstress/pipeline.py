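"""End-to-end run: behaviour, hormones, expression persistence, enrichment.

``run_full_analysis`` binds the stages into one reproducible run with a
single configuration object.  Stages whose inputs are missing are skipped
with an explicit log entry, never silently; every number in the JSON
summary is lifted from one operation's result object — nothing is computed
in the reporting layer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import behaviour as bh
from . import expression as ex
from . import io as cio
from .simulate import pool_samples

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger("chickstress")

STRATUM_PAIRS = [
    ("baseline", "baseline_vs_adult"),
    ("restraint", "restraint_vs_adult"),
]


@dataclass
class RunConfig:
    """Inputs, options and output directory for one analysis run.

    ``behaviour_dir`` holds the CSV tables written by the simulator (or
    user files with the same headers); ``expression``/``meta`` point at the
    log2 matrix and sample table; ``gmt`` optionally supplies gene sets.
    ``K`` is the top-list size (default 1000, the study's choice); when
    ``permutations`` > 0 and the expression input is individual-level, a
    label-permutation P accompanies each correlation.
    """

    behaviour_dir: str | None = None
    expression: str | None = None
    meta: str | None = None
    gmt: str | None = None
    outdir: str = "chickstress-run"
    K: int = 1000
    alpha: float = 0.05
    ss_type: int = 3
    binomial_convention: str = "doubling"
    ranking: str = "absolute"
    permutations: int = 0
    pool_size_young: int = 3
    pool_size_adult: int = 4
    include_zero_rightening: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 3:
            raise ValueError("K must be at least 3")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.ss_type not in (1, 3):
            raise ValueError("ss_type must be 1 or 3")
        if self.permutations < 0:
            raise ValueError("permutations must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _tr(result: bh.TestResult, test: str, stratum: str) -> dict:
    df = result.df
    return {
        "test": test,
        "stratum": stratum,
        "statistic": result.statistic_name,
        "value": result.value,
        "df": "x".join(f"{d:g}" for d in df) if isinstance(df, tuple) else f"{df:g}",
        "p_value": result.p_value,
    }


def _behaviour_stage(cfg: RunConfig, rows: list[dict], summary: dict) -> None:
    bdir = Path(cfg.behaviour_dir)
    tables = {}
    for name, fname in cio.BEHAVIOUR_FILES.items():
        p = bdir / fname
        if p.exists():
            tables[name] = pd.read_csv(p)
        else:
            log.warning("behaviour table %s missing; dependent tests skipped", p)

    # open field: normality gate, two-factor GLM, within-sex follow-ups
    if "open_field" in tables:
        of = tables["open_field"]
        for resp in ("latency_s", "distance_cm"):
            ad = bh.anderson_darling(of[resp])
            rows.append(_tr(ad, f"anderson_darling:{resp}", "all"))
            if ad.p_value <= cfg.alpha:
                log.warning(
                    "open-field %s fails the normality gate (P=%.3g); "
                    "GLM reported anyway — interpret with care", resp, ad.p_value
                )
            tbl = bh.two_way_glm(of, resp, ss_type=cfg.ss_type)
            rows.append(_tr(tbl.treatment, f"glm_treatment:{resp}", "all"))
            rows.append(_tr(tbl.sex, f"glm_sex:{resp}", "all"))
            rows.append(_tr(tbl.interaction, f"glm_interaction:{resp}", "all"))
            summary.setdefault("open_field", {})[resp] = {
                "interaction_F": tbl.interaction.value,
                "interaction_p": tbl.interaction.p_value,
            }
            if tbl.interaction.p_value < cfg.alpha:
                for sex in ("F", "M"):
                    ws = bh.within_sex_effect(of, resp, sex)
                    rows.append(_tr(ws, f"glm_within_sex:{resp}", sex))
                    summary["open_field"][resp][f"within_{sex}_F"] = ws.value
                    summary["open_field"][resp][f"within_{sex}_p"] = ws.p_value

    # tonic immobility: KM / log-rank, overall then per sex
    if "tonic_immobility" in tables:
        ti = tables["tonic_immobility"]
        summary["tonic_immobility"] = {}
        for endpoint, tcol, ccol in (
            ("head_move", "head_move_s", "head_move_censored"),
            ("rightening", "rightening_s", "rightening_censored"),
        ):
            sub = ti.dropna(subset=[tcol])
            if endpoint == "rightening" and not cfg.include_zero_rightening:
                # birds never entering TI carry rightening time 0; a
                # zero-time event is degenerate for the product limit
                sub = sub[sub[tcol] > 0]
            for stratum, sel in (
                ("all", sub),
                ("F", sub[sub.sex == "F"]),
                ("M", sub[sub.sex == "M"]),
            ):
                es = sel[sel.treatment == "ES"]
                ctl = sel[sel.treatment == "C"]
                try:
                    lr = bh.logrank(
                        es[tcol], ~es[ccol].astype(bool),
                        ctl[tcol], ~ctl[ccol].astype(bool),
                    )
                except ValueError as exc:
                    log.warning("log-rank %s/%s skipped: %s", endpoint, stratum, exc)
                    continue
                rows.append(_tr(lr, f"logrank:{endpoint}", stratum))
                summary["tonic_immobility"][f"{endpoint}_{stratum}"] = {
                    "chi2": lr.value, "p": lr.p_value,
                }

    # dominance: exact binomial per sex
    if "dominance" in tables:
        dom = tables["dominance"]
        summary["dominance"] = {}
        for sex, grp in dom.groupby("sex"):
            res = bh.dominance_binomial(grp, convention=cfg.binomial_convention)
            rows.append(_tr(res, "binomial_dominance", sex))
            summary["dominance"][sex] = {
                "es_wins": res.value, "n_pairs": res.df, "p": res.p_value,
            }

    # hormones: log t-test per sex
    if "hormones" in tables:
        horm = tables["hormones"]
        summary["hormones"] = {}
        for (sex, hormone), grp in horm.groupby(["sex", "hormone"]):
            es = grp.loc[grp.treatment == "ES", "concentration"]
            ctl = grp.loc[grp.treatment == "C", "concentration"]
            res = bh.hormone_t_test(es, ctl, log_transform=True)
            rows.append(_tr(res, f"t_test:{hormone}", sex))
            summary["hormones"][f"{hormone}_{sex}"] = {
                "t": res.value, "df": res.df, "p": res.p_value,
            }


def _expression_stage(cfg: RunConfig, rows: list[dict], summary: dict, outdir: Path):
    matrix = cio.read_expression(cfg.expression)
    meta = cio.read_meta(cfg.meta)

    individual = (meta.pool_members == 1).all()
    if individual:
        log.info("individual-level expression input: pooling 3 (young) / 4 (adult)")
        pooled_parts, meta_parts = [], []
        for age, psize in (("young", cfg.pool_size_young), ("adult", cfg.pool_size_adult)):
            m_age = meta[meta.age == age]
            pm, pmeta = pool_samples(matrix[list(m_age.sample_id)], m_age, psize)
            pooled_parts.append(pm)
            meta_parts.append(pmeta)
        pooled = pd.concat(pooled_parts, axis=1)
        pooled_meta = pd.concat(meta_parts, ignore_index=True)
    else:
        pooled, pooled_meta = matrix, meta

    summary["expression"] = {"K": cfg.K, "n_genes": int(len(pooled))}
    overlap_rows = []
    for sex in ("F", "M"):
        for cond, label in STRATUM_PAIRS:
            try:
                py = ex.fold_change_profile(pooled, pooled_meta, "young", sex, cond)
                pa = ex.fold_change_profile(pooled, pooled_meta, "adult", sex, "baseline")
            except ValueError as exc:
                log.warning("expression pair %s/%s skipped: %s", sex, label, exc)
                continue
            res = ex.overlap_correlation(py, pa, cfg.K, ranking=cfg.ranking)
            entry = {
                "overlap": res.overlap_size,
                "expected_null_overlap": res.expected_null_overlap,
                "overlap_tail_p": res.overlap_tail_p,
                "r": res.r,
                "t": res.t_stat,
                "df": res.df,
                "p": res.p_value,
            }
            if cfg.permutations > 0 and individual:
                perm = ex.permutation_null_correlation(
                    matrix, meta, matrix, meta, cfg.K, sex,
                    condition_young=cond, n_perm=cfg.permutations,
                    seed=cfg.seed, ranking=cfg.ranking,
                    pool_sizes=(cfg.pool_size_young, cfg.pool_size_adult),
                )
                entry["p_permutation"] = perm["p_empirical"]
            elif cfg.permutations > 0:
                log.warning(
                    "permutation null skipped for %s/%s: pooled-level input "
                    "admits too few label rearrangements", sex, label,
                )
            summary["expression"][f"{sex}_{label}"] = entry
            overlap_rows.append({"sex": sex, "pair": label, **entry})
            if res.p_value is not None:
                rows.append(
                    _tr(
                        bh.TestResult("r", res.r, float(res.df), res.p_value),
                        f"overlap_correlation:{label}", sex,
                    )
                )
            # per-pair fold-change scatter table for plotting elsewhere
            pd.DataFrame(
                {"fc_young": res.fc_young, "fc_adult": res.fc_adult}
            ).to_csv(outdir / f"overlap_fc_{sex}_{label}.tsv", sep="\t",
                     index_label="gene_id", float_format="%.6g")
    if overlap_rows:
        pd.DataFrame(overlap_rows).to_csv(
            outdir / "overlap_results.tsv", sep="\t", index=False,
            float_format="%.6g",
        )

    # enrichment of overlapping genes from significantly correlated pairs
    if cfg.gmt is not None:
        sets, desc = cio.read_gmt(cfg.gmt)
        universe = set(pooled.index)
        summary["enrichment"] = {}
        for sex in ("F", "M"):
            for cond, label in STRATUM_PAIRS:
                entry = summary["expression"].get(f"{sex}_{label}")
                if not entry or entry["p"] is None or entry["p"] >= cfg.alpha:
                    continue
                py = ex.fold_change_profile(pooled, pooled_meta, "young", sex, cond)
                pa = ex.fold_change_profile(pooled, pooled_meta, "adult", sex, "baseline")
                res = ex.overlap_correlation(py, pa, cfg.K, ranking=cfg.ranking)
                enr = ex.set_enrichment(res.overlap_genes, universe, sets, desc)
                enr.to_csv(outdir / f"enrichment_{sex}_{label}.tsv", sep="\t",
                           index=False, float_format="%.6g")
                summary["enrichment"][f"{sex}_{label}"] = {
                    "n_terms_tested": int(len(enr)),
                    "n_terms_fdr_significant": int(
                        (enr.fdr_adjusted_p < cfg.alpha).sum()
                    ),
                }


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage the configured inputs allow; return the JSON summary.

    Writes ``results.tsv`` (tidy behaviour statistics), per-pair overlap and
    enrichment tables, ``summary.json``, and ``run.log``.  The same config
    and seed produce a byte-identical ``summary.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("chickstress %s; config: %s", __version__, dataclasses.asdict(config))
        rows: list[dict] = []
        summary: dict = {
            "config": dataclasses.asdict(config),
            "version": __version__,
            "stages_skipped": [],
        }
        if config.behaviour_dir is not None:
            _behaviour_stage(config, rows, summary)
        else:
            summary["stages_skipped"].append("behaviour")
            log.warning("no behaviour_dir given: behaviour stages skipped")
        if config.expression is not None and config.meta is not None:
            _expression_stage(config, rows, summary, outdir)
        else:
            summary["stages_skipped"].append("expression")
            log.warning("expression matrix/meta not given: expression stages skipped")

        cio.write_results_tsv(rows, outdir / "results.tsv")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
            fh.write("\n")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
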