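"""Transcriptomic persistence: top-K fold-change overlap across ages.

The procedure asks whether the early-stress differential-expression profile
measured in young birds is still present in adults.  Per sex and stratum,
the per-gene fold change is the difference of mean log2 expression, stressed
minus control.  The K genes with the largest fold changes at each age are
intersected ("the overlapping genes"), and the Pearson correlation of their
fold-change values at the two ages is the persistence statistic; under
independence the expected overlap is K^2/G and the overlap size is
hypergeometric.  A treatment-label permutation null gives a
distribution-free companion P for the correlation.

Gene-set enrichment of the overlapping genes is a one-sided hypergeometric
(Fisher) test per term with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FoldChangeProfile",
    "OverlapResult",
    "fold_change_profile",
    "top_k_genes",
    "overlap_correlation",
    "permutation_null_correlation",
    "set_enrichment",
]

MIN_OVERLAP_FOR_R = 3


@dataclass(frozen=True)
class FoldChangeProfile:
    """Per-gene log2 fold change (ES minus C) within one stratum."""

    age: str
    sex: str
    condition: str
    fc: pd.Series  # indexed by gene id

    @property
    def stratum(self) -> tuple[str, str, str]:
        return (self.age, self.sex, self.condition)


@dataclass(frozen=True)
class OverlapResult:
    """Top-K overlap between two ages and the persistence correlation.

    ``r`` and its t-based P are None when the overlap has fewer than three
    genes (correlation undefined); ``expected_null_overlap`` is K^2/G and
    ``overlap_tail_p`` the hypergeometric upper tail for the observed
    overlap size under independent top-K draws.
    """

    K: int
    n_genes: int
    overlap_genes: tuple[str, ...]
    overlap_size: int
    r: float | None
    t_stat: float | None
    df: int | None
    p_value: float | None
    expected_null_overlap: float
    overlap_tail_p: float
    fc_young: pd.Series = field(repr=False)
    fc_adult: pd.Series = field(repr=False)


def _stratum_mask(meta: pd.DataFrame, age: str, sex: str, condition: str) -> pd.Series:
    return (meta.age == age) & (meta.sex == sex) & (meta.condition == condition)


def fold_change_profile(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    age: str,
    sex: str,
    condition: str = "baseline",
) -> FoldChangeProfile:
    """Mean log2 expression over ES samples minus mean over C samples."""
    sub = meta[_stratum_mask(meta, age, sex, condition)]
    es = sub.loc[sub.treatment == "ES", "sample_id"]
    ctl = sub.loc[sub.treatment == "C", "sample_id"]
    if len(es) == 0 or len(ctl) == 0:
        raise ValueError(
            f"stratum age={age} sex={sex} condition={condition} lacks "
            f"{'ES' if len(es) == 0 else 'C'} samples"
        )
    fc = matrix[list(es)].mean(axis=1) - matrix[list(ctl)].mean(axis=1)
    fc.name = f"fc_{age}_{sex}_{condition}"
    return FoldChangeProfile(age, sex, condition, fc)


def top_k_genes(profile: FoldChangeProfile, k: int, ranking: str = "absolute") -> list[str]:
    """The K genes with the largest fold change, deterministically ordered.

    ``ranking="absolute"`` (default) ranks by |FC| descending — down-
    regulation counts as much as up-regulation; ``ranking="signed"`` ranks
    by FC descending.  Ties are broken by lexicographic gene id so the list
    is reproducible across platforms.
    """
    g = len(profile.fc)
    if not 0 < k <= g:
        raise ValueError(f"K must lie in [1, {g}], got {k}")
    if ranking == "absolute":
        key = profile.fc.abs()
    elif ranking == "signed":
        key = profile.fc
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    # stable sort over lexicographically pre-sorted ids = rank by
    # (-key, gene_id), giving the deterministic tie-break
    ser = key.sort_index(kind="mergesort")
    ser = ser.sort_values(ascending=False, kind="mergesort")
    return list(ser.index[:k])


def _pearson_with_t(x: np.ndarray, y: np.ndarray):
    r = float(st.pearsonr(x, y).statistic)
    df = x.size - 2
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * st.t.sf(abs(t), df)
    return r, t, df, min(p, 1.0)


def overlap_correlation(
    profile_young: FoldChangeProfile,
    profile_adult: FoldChangeProfile,
    k: int,
    ranking: str = "absolute",
) -> OverlapResult:
    """Intersect the two top-K lists and correlate the overlap's fold changes.

    The Pearson r over (FC_young, FC_adult) of the overlapping genes is
    tested with the usual t transform, t = r sqrt(df) / sqrt(1 - r^2),
    df = overlap - 2, two-sided.  Overlaps smaller than three genes return
    a defined result with the correlation marked absent (None) rather than
    raising.  Also reported: the null expectation K^2/G and the
    hypergeometric upper-tail P of the observed overlap size.
    """
    if list(profile_young.fc.index) != list(profile_adult.fc.index):
        raise ValueError("profiles are not over the same gene universe")
    g = len(profile_young.fc)
    top_young = set(top_k_genes(profile_young, k, ranking))
    top_adult = set(top_k_genes(profile_adult, k, ranking))
    overlap = sorted(top_young & top_adult)
    m = len(overlap)
    # overlap size under independent draws of two K-subsets of G genes
    tail_p = float(st.hypergeom.sf(m - 1, g, k, k))
    fc_y = profile_young.fc.loc[overlap]
    fc_a = profile_adult.fc.loc[overlap]
    if m < MIN_OVERLAP_FOR_R:
        r = t = df = p = None
    else:
        r, t, df, p = _pearson_with_t(fc_y.to_numpy(), fc_a.to_numpy())
    return OverlapResult(
        K=k,
        n_genes=g,
        overlap_genes=tuple(overlap),
        overlap_size=m,
        r=r,
        t_stat=t,
        df=df,
        p_value=p,
        expected_null_overlap=k * k / g,
        overlap_tail_p=tail_p,
        fc_young=fc_y,
        fc_adult=fc_a,
    )


def _count_label_assignments(meta: pd.DataFrame, strata_cols) -> float:
    total = 1.0
    for _, grp in meta.groupby(list(strata_cols), observed=True):
        n_es = int((grp.treatment == "ES").sum())
        total *= math.comb(len(grp), n_es)
    return total


def permutation_null_correlation(
    matrix_young: pd.DataFrame,
    meta_young: pd.DataFrame,
    matrix_adult: pd.DataFrame,
    meta_adult: pd.DataFrame,
    k: int,
    sex: str,
    condition_young: str = "restraint",
    n_perm: int = 199,
    seed: int = 0,
    ranking: str = "absolute",
    pool_sizes: tuple[int, int] | None = None,
) -> dict:
    """Treatment-label permutation null for the overlap correlation.

    Re-runs the full fold-change -> top-K -> overlap -> r procedure with
    treatment labels permuted independently within the young and adult
    strata; empirical P = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).
    Permutations with an overlap too small to define r count as
    non-exceeding.  When ``pool_sizes=(young, adult)`` is given the inputs
    are individual-level matrices and each permutation relabels individuals
    before re-pooling, which is the exchangeability actually implied by the
    design (pool-level labels admit too few rearrangements).

    Raises when the number of distinct label assignments is below
    ``n_perm``, reporting the attainable minimum P.
    """
    from .simulate import pool_samples  # deferred: avoids module cycle

    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)

    my = meta_young[_stratum_mask(meta_young, "young", sex, condition_young)].copy()
    ma = meta_adult[_stratum_mask(meta_adult, "adult", sex, "baseline")].copy()
    if len(my) == 0 or len(ma) == 0:
        raise ValueError(f"no samples for sex={sex} in one of the two ages")

    n_distinct = _count_label_assignments(my, ["age", "sex", "condition"]) * (
        _count_label_assignments(ma, ["age", "sex", "condition"])
    )
    if n_distinct < n_perm:
        raise ValueError(
            f"only {n_distinct:.0f} distinct treatment-label assignments; "
            f"attainable minimum P is {1.0 / n_distinct:.4g} — "
            "permute at the individual level (pool_sizes=...) or lower n_perm"
        )

    def observed_r(meta_y: pd.DataFrame, meta_a: pd.DataFrame):
        if pool_sizes is not None:
            m_y, mm_y = pool_samples(matrix_young[list(meta_y.sample_id)], meta_y, pool_sizes[0])
            m_a, mm_a = pool_samples(matrix_adult[list(meta_a.sample_id)], meta_a, pool_sizes[1])
        else:
            m_y, mm_y = matrix_young[list(meta_y.sample_id)], meta_y
            m_a, mm_a = matrix_adult[list(meta_a.sample_id)], meta_a
        py = fold_change_profile(m_y, mm_y, "young", sex, condition_young)
        pa = fold_change_profile(m_a, mm_a, "adult", sex, "baseline")
        return overlap_correlation(py, pa, k, ranking)

    obs = observed_r(my, ma)
    if obs.r is None:
        raise ValueError(
            f"observed overlap of {obs.overlap_size} genes is too small to "
            "define a correlation"
        )

    # vectorised resampling path: same arithmetic as the pandas pipeline
    # (relabel -> chunk into pools on the linear scale -> log2 -> FC ->
    # top-K with the lexicographic tie-break -> Pearson r), kept in numpy
    # because it runs n_perm times
    gene_ids = matrix_young.index.to_numpy()
    lex_rank = np.empty(len(gene_ids), dtype=np.int64)
    lex_rank[np.argsort(gene_ids, kind="stable")] = np.arange(len(gene_ids))

    def _stage(matrix: pd.DataFrame, meta: pd.DataFrame, psize: int | None):
        vals = matrix[list(meta.sample_id)].to_numpy()
        labels = (meta.treatment.to_numpy() == "ES")
        return (np.exp2(vals) if psize else vals), labels, psize

    def _fc_fast(linear: np.ndarray, es_mask: np.ndarray, psize: int | None):
        def arm(mask):
            cols = np.nonzero(mask)[0]
            block = linear[:, cols]
            if psize:
                pooled = np.log2(
                    block.reshape(len(block), -1, psize).mean(axis=2)
                )
                return pooled.mean(axis=1)
            return block.mean(axis=1)
        return arm(es_mask) - arm(~es_mask)

    def _top_mask(fc: np.ndarray) -> np.ndarray:
        order = np.lexsort((lex_rank, -np.abs(fc)))
        mask = np.zeros(fc.size, dtype=bool)
        mask[order[:k]] = True
        return mask

    psize_y = pool_sizes[0] if pool_sizes else None
    psize_a = pool_sizes[1] if pool_sizes else None
    lin_y, lab_y, _ = _stage(matrix_young, my, psize_y)
    lin_a, lab_a, _ = _stage(matrix_adult, ma, psize_a)

    def _r_fast(es_y: np.ndarray, es_a: np.ndarray) -> float:
        fc_y = _fc_fast(lin_y, es_y, psize_y)
        fc_a = _fc_fast(lin_a, es_a, psize_a)
        both = _top_mask(fc_y) & _top_mask(fc_a)
        if both.sum() < MIN_OVERLAP_FOR_R:
            return np.nan
        return float(np.corrcoef(fc_y[both], fc_a[both])[0, 1])

    r_check = _r_fast(lab_y, lab_a)
    if not math.isclose(r_check, obs.r, rel_tol=1e-9, abs_tol=1e-12):
        raise AssertionError(
            f"fast permutation path disagrees with pipeline ({r_check} vs {obs.r})"
        )

    exceed = 0
    r_perms = np.empty(n_perm)
    for b in range(n_perm):
        r = _r_fast(rng.permutation(lab_y), rng.permutation(lab_a))
        r_perms[b] = r
        if not np.isnan(r) and abs(r) >= abs(obs.r):
            exceed += 1
    p_emp = (1.0 + exceed) / (1.0 + n_perm)
    return {
        "observed": obs,
        "r_obs": obs.r,
        "p_empirical": p_emp,
        "n_perm": n_perm,
        "r_perm": r_perms,
    }


def set_enrichment(
    genes,
    universe,
    gene_sets: dict[str, set[str] | list[str]],
    descriptions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``genes`` within ``universe`` per term.

    Each gene set is intersected with the universe; the one-sided upper-tail
    hypergeometric (Fisher) P asks whether the selection hits the term more
    often than chance, and Benjamini-Hochberg adjustment is applied across
    terms.  Returns a table (term_id, term_name, count_in_set,
    count_in_universe, p_value, fdr_adjusted_p) sorted by P.
    """
    universe = set(universe)
    selected = set(genes)
    if not universe:
        raise ValueError("empty gene universe")
    if not selected:
        raise ValueError("empty gene selection")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    rows = []
    for term, members in gene_sets.items():
        in_universe = set(members) & universe
        m = len(in_universe)
        x = len(in_universe & selected)
        # P(X >= x) for X ~ Hypergeom(N=|universe|, K=m, n=|selected|)
        p = float(st.hypergeom.sf(x - 1, len(universe), m, len(selected)))
        rows.append(
            {
                "term_id": term,
                "term_name": (descriptions or {}).get(term, term),
                "count_in_set": x,
                "count_in_universe": m,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
            drop=True
        )
    return out
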