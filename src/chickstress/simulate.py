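"""Synthetic cohorts emulating a sex-stratified early-stress study in chickens.

The generator reproduces the *design* of the study this package analyses:
two treatments (early stress ES vs control C) crossed with sex, an open-field
test shortly after the stress period, a tonic-immobility (TI) test with a
600 s cap (right censoring), weight-matched same-sex ES-vs-C dominance pairs,
log-normal gonadal hormone titres (testosterone in males, oestradiol in
females), and a two-age expression study (28 d with a baseline/restraint
split, 213 d baseline only) hybridised as sex-specific RNA pools of three
(young) or four (adult) birds.

Effect sizes are simulation inputs with known ground truth, so every
downstream statistic can be checked for calibration and power.  All
randomness derives from one master seed via fixed stream offsets; a fixed
seed yields bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "HormoneParams",
    "SimConfig",
    "CohortTables",
    "simulate_cohort",
    "simulate_expression_study",
    "pool_samples",
]

SEXES = ("F", "M")
TREATMENTS = ("ES", "C")

# fixed sub-stream offsets from the master seed
_STREAM_OF = 1
_STREAM_TI = 2
_STREAM_DOM = 3
_STREAM_HORM = 4
_STREAM_EXPR = 5


@dataclass(frozen=True)
class HormoneParams:
    """Log-normal hormone model for one sex.

    ``mu`` and ``sigma`` are the mean and sd of log concentration in
    controls; ``effect`` is the standardized shift (in units of ``sigma``)
    applied to ES birds, negative meaning lower titres.
    """

    hormone: str
    mu: float
    sigma: float
    effect: float = 0.0


def _default_hormones() -> dict[str, HormoneParams]:
    # Testosterone ~2.5 ng/ml in control males with a one-sd ES deficit
    # (delayed maturation); oestradiol ~180 pg/ml in females with a smaller,
    # non-significant shift.
    return {
        "M": HormoneParams("T", mu=np.log(2.5), sigma=0.5, effect=-1.0),
        "F": HormoneParams("E2", mu=np.log(180.0), sigma=0.4, effect=-0.6),
    }


@dataclass
class SimConfig:
    """Design constants and effect sizes for one simulated study.

    Counts are per sex x treatment cell.  ``of_effect`` is the standardized
    downward shift of ES-male open-field distance; ``ti_hazard_ratio`` the
    ES-vs-C hazard ratio for male time to first head movement (>1 means ES
    males escape TI sooner); ``p_es_dominant_f`` / ``p_es_dominant_m`` the
    probability the ES bird wins a dominance pair.  Expression effects:
    ``n_persistent`` genes carry, in males only, a common latent treatment
    effect (sd ``fc_sd`` on the log2 scale) shared between the young
    restraint stratum and the adult stratum, which is what makes the
    cross-age fold-change correlation positive.
    """

    n_birds_per_cell: int = 20
    of_effect: float = 0.65
    ti_hazard_ratio: float = 2.0
    p_es_dominant_f: float = 0.11
    p_es_dominant_m: float = 0.5
    p_no_ti: float = 0.1
    n_hormone_per_cell: int = 8
    hormone_lognormal_params: dict[str, HormoneParams] = field(
        default_factory=_default_hormones
    )

    n_genes: int = 5000
    n_persistent: int = 300
    fc_sd: float = 0.5
    noise_sd: float = 0.2
    sex_effect_sd: float = 0.2
    restraint_effect_sd: float = 0.3
    n_expr_young_per_cell: int = 6  # per sex x treatment x condition
    n_expr_adult_per_cell: int = 8  # per sex x treatment, baseline only
    pool_size_young: int = 3
    pool_size_adult: int = 4

    # open-field / TI distributional baselines
    of_distance_mean: float = 1500.0
    of_distance_sd: float = 500.0
    of_latency_mean: float = 90.0
    of_latency_sd: float = 40.0
    ti_weibull_shape: float = 1.1
    ti_head_scale_s: float = 250.0
    ti_right_scale_s: float = 450.0
    censor_cap_s: float = 600.0

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_birds_per_cell": self.n_birds_per_cell,
            "n_hormone_per_cell": self.n_hormone_per_cell,
            "n_genes": self.n_genes,
            "n_expr_young_per_cell": self.n_expr_young_per_cell,
            "n_expr_adult_per_cell": self.n_expr_adult_per_cell,
            "pool_size_young": self.pool_size_young,
            "pool_size_adult": self.pool_size_adult,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("p_es_dominant_f", "p_es_dominant_m", "p_no_ti"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_persistent < 0 or self.n_persistent > self.n_genes:
            raise ValueError(
                f"n_persistent must lie in [0, n_genes]; got "
                f"{self.n_persistent} with n_genes={self.n_genes}"
            )
        if self.n_expr_young_per_cell % self.pool_size_young:
            raise ValueError(
                "n_expr_young_per_cell must be divisible by pool_size_young"
            )
        if self.n_expr_adult_per_cell % self.pool_size_adult:
            raise ValueError(
                "n_expr_adult_per_cell must be divisible by pool_size_adult"
            )
        if self.ti_hazard_ratio <= 0:
            raise ValueError("ti_hazard_ratio must be positive")


@dataclass
class CohortTables:
    """Behaviour and hormone tables for one simulated cohort."""

    birds: pd.DataFrame
    open_field: pd.DataFrame
    tonic_immobility: pd.DataFrame
    dominance: pd.DataFrame
    hormones: pd.DataFrame

    def items(self):
        return {
            "birds": self.birds,
            "open_field": self.open_field,
            "tonic_immobility": self.tonic_immobility,
            "dominance": self.dominance,
            "hormones": self.hormones,
        }.items()


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _roster(config: SimConfig) -> pd.DataFrame:
    n = max(config.n_birds_per_cell, config.n_hormone_per_cell)
    rows = [
        {"bird_id": f"{sex}-{trt}-{i:03d}", "sex": sex, "treatment": trt}
        for sex in SEXES
        for trt in TREATMENTS
        for i in range(1, n + 1)
    ]
    return pd.DataFrame(rows)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Draw from N(mean, sd) truncated at zero by resampling."""
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < 0
    return out


def _weibull_ph(
    rng: np.random.Generator,
    scale: float,
    shape: float,
    hazard_ratio: float,
    size: int,
) -> np.ndarray:
    """Weibull event times under a proportional-hazards multiplier.

    Survival is S(t) = exp(-hr * (t/scale)^shape); inverse-transform
    sampling keeps the draw count per bird fixed, preserving stream
    alignment across configurations.
    """
    u = rng.uniform(size=size)
    return scale * (-np.log(u) / hazard_ratio) ** (1.0 / shape)


def simulate_cohort(config: SimConfig) -> CohortTables:
    """Generate the behaviour tables and roster for one cohort.

    Open-field distance receives the treatment-by-sex interaction (ES males
    only, shifted down by ``of_effect`` standard deviations); TI times are
    Weibull with the ES-male hazard ratio applied to first head movement and
    right-censored at the cap; dominance pairs are same-sex ES-vs-C with a
    Bernoulli winner; hormones are log-normal per sex.
    """
    birds = _roster(config)
    n = config.n_birds_per_cell

    # --- open field -------------------------------------------------------
    rng = _rng(config, _STREAM_OF)
    of_rows = []
    for sex in SEXES:
        for trt in TREATMENTS:
            cell = birds[(birds.sex == sex) & (birds.treatment == trt)].head(n)
            dist_mean = config.of_distance_mean
            if sex == "M" and trt == "ES":
                dist_mean -= config.of_effect * config.of_distance_sd
            latency = _truncated_normal(
                rng, config.of_latency_mean, config.of_latency_sd, len(cell)
            )
            distance = _truncated_normal(
                rng, dist_mean, config.of_distance_sd, len(cell)
            )
            for bid, lat, d in zip(cell.bird_id, latency, distance):
                of_rows.append(
                    {
                        "bird_id": bid,
                        "sex": sex,
                        "treatment": trt,
                        "latency_s": lat,
                        "distance_cm": d,
                    }
                )
    open_field = pd.DataFrame(of_rows)

    # --- tonic immobility -------------------------------------------------
    rng = _rng(config, _STREAM_TI)
    cap = config.censor_cap_s
    ti_rows = []
    for sex in SEXES:
        for trt in TREATMENTS:
            cell = birds[(birds.sex == sex) & (birds.treatment == trt)].head(n)
            hr = config.ti_hazard_ratio if (sex == "M" and trt == "ES") else 1.0
            head = _weibull_ph(
                rng, config.ti_head_scale_s, config.ti_weibull_shape, hr, len(cell)
            )
            right = _weibull_ph(
                rng, config.ti_right_scale_s, config.ti_weibull_shape, 1.0, len(cell)
            )
            induced = rng.uniform(size=len(cell)) >= config.p_no_ti
            attempts = rng.choice([1, 2, 3], size=len(cell), p=[0.7, 0.2, 0.1])
            for i, bid in enumerate(cell.bird_id):
                if not induced[i]:
                    # three failed attempts: scored "no TI induced",
                    # rightening time recorded as 0
                    ti_rows.append(
                        {
                            "bird_id": bid,
                            "sex": sex,
                            "treatment": trt,
                            "ti_induced": False,
                            "inductions": 3,
                            "head_move_s": np.nan,
                            "head_move_censored": False,
                            "rightening_s": 0.0,
                            "rightening_censored": False,
                        }
                    )
                    continue
                h, r = head[i], right[i]
                ti_rows.append(
                    {
                        "bird_id": bid,
                        "sex": sex,
                        "treatment": trt,
                        "ti_induced": True,
                        "inductions": int(attempts[i]),
                        "head_move_s": min(h, cap),
                        "head_move_censored": h >= cap,
                        "rightening_s": min(r, cap),
                        "rightening_censored": r >= cap,
                    }
                )
    tonic = pd.DataFrame(ti_rows)

    # --- dominance pairs --------------------------------------------------
    rng = _rng(config, _STREAM_DOM)
    dom_rows = []
    for sex in SEXES:
        es = birds[(birds.sex == sex) & (birds.treatment == "ES")].head(n)
        ctl = birds[(birds.sex == sex) & (birds.treatment == "C")].head(n)
        if len(es) != len(ctl):
            raise ValueError(
                f"cannot pair cell sex={sex}: {len(es)} ES vs {len(ctl)} C birds"
            )
        p_win = config.p_es_dominant_f if sex == "F" else config.p_es_dominant_m
        order = rng.permutation(len(ctl))
        wins = rng.uniform(size=len(es)) < p_win
        for k, (es_id, j) in enumerate(zip(es.bird_id, order)):
            dom_rows.append(
                {
                    "pair_id": f"{sex}-pair-{k + 1:03d}",
                    "sex": sex,
                    "es_bird_id": es_id,
                    "c_bird_id": ctl.bird_id.iloc[j],
                    "winner": "ES" if wins[k] else "C",
                }
            )
    dominance = pd.DataFrame(dom_rows)

    # --- hormones ---------------------------------------------------------
    rng = _rng(config, _STREAM_HORM)
    horm_rows = []
    for sex in SEXES:
        params = config.hormone_lognormal_params[sex]
        for trt in TREATMENTS:
            cell = birds[(birds.sex == sex) & (birds.treatment == trt)].head(
                config.n_hormone_per_cell
            )
            mu = params.mu + (params.effect * params.sigma if trt == "ES" else 0.0)
            conc = rng.lognormal(mu, params.sigma, len(cell))
            for bid, c in zip(cell.bird_id, conc):
                horm_rows.append(
                    {
                        "bird_id": bid,
                        "sex": sex,
                        "treatment": trt,
                        "hormone": params.hormone,
                        "concentration": c,
                    }
                )
    hormones = pd.DataFrame(horm_rows)

    return CohortTables(birds, open_field, tonic, dominance, hormones)


def _expression_strata(config: SimConfig):
    strata = []
    for sex in SEXES:
        for trt in TREATMENTS:
            strata.append(("young", sex, trt, "baseline", config.n_expr_young_per_cell))
            strata.append(("young", sex, trt, "restraint", config.n_expr_young_per_cell))
            strata.append(("adult", sex, trt, "baseline", config.n_expr_adult_per_cell))
    return strata


def simulate_expression_study(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate individual-level log2 expression for the two-age study.

    Per gene g and bird i: ``x = baseline_g + male_g*[sex=M] +
    restraint_g*[condition=restraint] + delta_g(stratum)*[treatment=ES] +
    noise``.  The treatment effect ``delta_g`` is zero except for the
    ``n_persistent`` signature genes, where males share one latent effect
    between young-restraint and adult (persistence) while young-baseline and
    all female strata get independent draws of the same magnitude — matched
    overlap enrichment at both ages with, in expectation, zero cross-age
    fold-change correlation outside the male restraint/adult pair.

    Returns the matrix (genes x samples, log2) and a metadata table with
    columns sample_id, age, sex, treatment, condition, pool_members (=1).
    """
    rng = _rng(config, _STREAM_EXPR)
    G = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(G)])

    baseline = rng.normal(7.0, 1.5, G)
    male_shift = rng.normal(0.0, config.sex_effect_sd, G)
    restraint_shift = rng.normal(0.0, config.restraint_effect_sd, G)
    persistent = rng.choice(G, size=config.n_persistent, replace=False)

    # latent treatment effects per (sex, age-condition stratum)
    def _fresh_effects() -> np.ndarray:
        delta = np.zeros(G)
        delta[persistent] = rng.normal(0.0, config.fc_sd, config.n_persistent)
        return delta

    male_shared = _fresh_effects()  # young-restraint AND adult, males
    effects = {
        ("M", "young", "baseline"): _fresh_effects(),
        ("M", "young", "restraint"): male_shared,
        ("M", "adult", "baseline"): male_shared,
        ("F", "young", "baseline"): _fresh_effects(),
        ("F", "young", "restraint"): _fresh_effects(),
        ("F", "adult", "baseline"): _fresh_effects(),
    }

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for age, sex, trt, cond, n_ind in _expression_strata(config):
        mu = baseline.copy()
        if sex == "M":
            mu += male_shift
        if cond == "restraint":
            mu += restraint_shift
        if trt == "ES":
            mu += effects[(sex, age, cond)]
        for i in range(1, n_ind + 1):
            sid = f"{age}-{cond}-{sex}-{trt}-i{i:02d}"
            columns[sid] = mu + rng.normal(0.0, config.noise_sd, G)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "age": age,
                    "sex": sex,
                    "treatment": trt,
                    "condition": cond,
                    "pool_members": 1,
                }
            )

    matrix = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(meta_rows)
    return matrix, meta


def pool_samples(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    pool_size: int,
    mode: Literal["linear", "log"] = "linear",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool individual samples within sex x treatment x condition (x age).

    Emulates physical RNA pooling: members are combined on the linear
    intensity scale and re-expressed in log2 (``mode="linear"``, the
    default, closest to mixing equal RNA amounts).  ``mode="log"`` averages
    the log2 values directly.  Pools never mix sex, treatment, condition or
    age; a group whose size is not divisible by ``pool_size`` raises with
    the offending group named.
    """
    if pool_size <= 0:
        raise ValueError("pool_size must be positive")
    missing = set(matrix.columns) - set(meta.sample_id)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    meta_idx = meta.set_index("sample_id").loc[list(matrix.columns)]

    pooled_cols: dict[str, np.ndarray] = {}
    pooled_meta = []
    for (age, sex, trt, cond), grp in meta_idx.groupby(
        ["age", "sex", "treatment", "condition"], sort=True, observed=True
    ):
        ids = list(grp.index)
        if len(ids) % pool_size:
            raise ValueError(
                f"group age={age} sex={sex} treatment={trt} condition={cond} "
                f"has {len(ids)} samples, not divisible by pool_size={pool_size}"
            )
        for j in range(0, len(ids), pool_size):
            members = ids[j : j + pool_size]
            block = matrix[members].to_numpy()
            if mode == "linear":
                value = np.log2(np.exp2(block).mean(axis=1))
            elif mode == "log":
                value = block.mean(axis=1)
            else:
                raise ValueError(f"unknown pooling mode {mode!r}")
            pid = f"{age}-{cond}-{sex}-{trt}-p{j // pool_size + 1:02d}"
            pooled_cols[pid] = value
            pooled_meta.append(
                {
                    "sample_id": pid,
                    "age": age,
                    "sex": sex,
                    "treatment": trt,
                    "condition": cond,
                    "pool_members": len(members),
                }
            )

    pooled = pd.DataFrame(pooled_cols, index=matrix.index)
    return pooled, pd.DataFrame(pooled_meta)
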