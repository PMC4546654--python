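"""Per-metabolite factorial inference.

Each metabolite in each tissue is modelled with a two-factor linear model
(genotype, diet, genotype x diet interaction) after a detection filter
(at least 3 non-zero values per arm of the 2x2 design).  Sums of squares are
sequential (Type I) in the order genotype, then diet, then interaction by
default, with a marginal (Type II) option; with a near-balanced design the two
nearly coincide.  Zeros are non-detections and are excluded from the fit.
Fold changes are ratios of arithmetic group means on the raw peak-area scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._errors import ValidationError
from .ingest import PeakTable

logger = logging.getLogger(__name__)

_RESULT_COLUMNS = [
    "metabolite",
    "tissue",
    "n_used",
    "mean_mut_fat45",
    "mean_mut_fat60",
    "mean_wt_fat45",
    "mean_wt_fat60",
    "F_genotype",
    "F_diet",
    "F_interaction",
    "p_genotype",
    "p_diet",
    "p_interaction",
    "genotype_direction",
    "percent_change_genotype",
    "diet_direction",
    "percent_change_diet",
]


# ----------------------------------------------------------------------
def filter_detected(table: PeakTable, min_nonzero_per_arm: int = 3) -> PeakTable:
    """Keep metabolites with >= ``min_nonzero_per_arm`` non-zero values per arm.

    Arms are the genotype x diet cells of the design within one tissue; the
    table must therefore contain a single tissue.  The operation is
    idempotent and never adds metabolites.
    """
    tissues = set(table.samples["tissue"])
    if len(tissues) != 1:
        raise ValidationError(
            f"filter_detected expects a single-tissue table, got {sorted(tissues)}"
        )
    genotype = table.samples["genotype"].to_numpy()
    diet = table.samples["diet"].to_numpy()
    arms = list(itertools.product(sorted(set(genotype)), sorted(set(diet))))
    masks = {}
    for g, d in arms:
        mask = (genotype == g) & (diet == d)
        if not mask.any():
            raise ValidationError(
                f"arm genotype={g!r}, diet={d!r} has no samples"
            )
        masks[(g, d)] = mask
    nonzero = table.values.to_numpy() > 0
    keep = np.ones(len(table.metabolites), dtype=bool)
    for mask in masks.values():
        keep &= nonzero[mask].sum(axis=0) >= min_nonzero_per_arm
    kept = [m for m, k in zip(table.metabolites, keep) if k]
    return table.subset_metabolites(kept)


# ----------------------------------------------------------------------
def _anova_shared(
    Y: np.ndarray, g: np.ndarray, d: np.ndarray, ss_type: str
) -> dict[str, np.ndarray]:
    """Batched two-factor ANOVA for columns sharing one complete design."""
    n, p = Y.shape
    one = np.ones(n)
    y_scale = (Y**2).sum(axis=0)
    total = y_scale.copy()

    def rss(*cols):
        X = np.column_stack(cols)
        Q, _ = np.linalg.qr(X)
        return total - ((Q.T @ Y) ** 2).sum(axis=0), np.linalg.matrix_rank(X)

    has_diet = len(set(d)) > 1
    rss0, _ = rss(one)
    rss1, _ = rss(one, g)
    if not has_diet:
        dfr = n - 2
        nanarr = np.full(p, np.nan)
        Fg, pg = _term_stats_vec(rss0 - rss1, rss1, dfr, y_scale)
        return {
            "F_genotype": Fg, "p_genotype": pg,
            "F_diet": nanarr, "p_diet": nanarr,
            "F_interaction": nanarr.copy(), "p_interaction": nanarr.copy(),
        }
    rss2, _ = rss(one, g, d)
    rss3, rank3 = rss(one, g, d, g * d)
    dfr = n - rank3
    if ss_type == "sequential":
        ss_g, ss_d = rss0 - rss1, rss1 - rss2
    else:
        rss_d, _ = rss(one, d)
        ss_g, ss_d = rss_d - rss2, rss1 - rss2
    ss_i = rss2 - rss3
    Fg, pg = _term_stats_vec(ss_g, rss3, dfr, y_scale)
    Fd, pd_ = _term_stats_vec(ss_d, rss3, dfr, y_scale)
    Fi, pi = _term_stats_vec(ss_i, rss3, dfr, y_scale)
    return {
        "F_genotype": Fg, "p_genotype": pg,
        "F_diet": Fd, "p_diet": pd_,
        "F_interaction": Fi, "p_interaction": pi,
    }


def _term_stats_vec(ss, rss_full, dfr, y_scale):
    ss = np.maximum(ss, 0.0)
    if dfr < 1:
        nan = np.full_like(ss, np.nan)
        return nan, nan.copy()
    tol = 1e-12 * np.maximum(y_scale, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss / (rss_full / dfr)
        p = stats.f.sf(F, 1, dfr)
    zero_resid = rss_full <= tol
    F = np.where(zero_resid, np.where(ss <= tol, np.nan, np.inf), F)
    p = np.where(zero_resid, np.where(ss <= tol, np.nan, 0.0), p)
    return F, p


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of a least-squares fit."""
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0]), int(rank)
    fitted = X @ coef
    return float(((y - fitted) ** 2).sum()), int(rank)


def _anova_single(
    y: np.ndarray, g: np.ndarray, d: np.ndarray, ss_type: str
) -> dict:
    """Two-factor ANOVA for one metabolite (y already restricted to used rows).

    Returns F and p for genotype, diet and interaction.  Degenerate designs
    (a single diet level, no residual degrees of freedom) yield NaN for the
    unavailable terms.
    """
    n = len(y)
    one = np.ones(n)
    y_scale = float(np.sum(y**2))
    has_diet = len(set(d)) > 1
    if not has_diet:
        X_full = np.column_stack([one, g])
        rss0, _ = _rss(y, one[:, None])
        rss_full, rank_full = _rss(y, X_full)
        dfr = n - rank_full
        out = _term_stats(rss0 - rss_full, rss_full, dfr, y_scale)
        return {
            "F_genotype": out[0],
            "p_genotype": out[1],
            "F_diet": np.nan,
            "p_diet": np.nan,
            "F_interaction": np.nan,
            "p_interaction": np.nan,
        }
    gd = g * d
    X1 = np.column_stack([one, g])
    X2 = np.column_stack([one, g, d])
    X3 = np.column_stack([one, g, d, gd])
    Xd = np.column_stack([one, d])
    rss0, _ = _rss(y, one[:, None])
    rss1, _ = _rss(y, X1)
    rss2, _ = _rss(y, X2)
    rss3, rank3 = _rss(y, X3)
    dfr = n - rank3
    if ss_type == "sequential":
        ss_g, ss_d = rss0 - rss1, rss1 - rss2
    elif ss_type == "marginal":
        rss_d, _ = _rss(y, Xd)
        ss_g, ss_d = rss_d - rss2, rss1 - rss2
    else:
        raise ValidationError(f"unknown ss_type {ss_type!r}")
    ss_i = rss2 - rss3
    Fg, pg = _term_stats(ss_g, rss3, dfr, y_scale)
    Fd, pd_ = _term_stats(ss_d, rss3, dfr, y_scale)
    Fi, pi = _term_stats(ss_i, rss3, dfr, y_scale)
    return {
        "F_genotype": Fg,
        "p_genotype": pg,
        "F_diet": Fd,
        "p_diet": pd_,
        "F_interaction": Fi,
        "p_interaction": pi,
    }


def _term_stats(
    ss: float, rss_full: float, dfr: int, y_scale: float
) -> tuple[float, float]:
    # y_scale anchors the zero-variance tests to the magnitude of the data,
    # so an exactly-constant input is degenerate rather than F = eps/eps
    ss = max(ss, 0.0)
    if dfr < 1:
        return np.nan, np.nan
    tol = 1e-12 * max(y_scale, 1e-300)
    if rss_full <= tol:
        if ss <= tol:
            logger.warning("degenerate ANOVA cell: zero variance, F undefined")
            return np.nan, np.nan
        logger.warning("zero residual variance: F reported as +inf, p = 0")
        return np.inf, 0.0
    F = ss / (rss_full / dfr)
    return float(F), float(stats.f.sf(F, 1, dfr))


def fit_factor_model(
    values,
    genotype,
    diet,
    metabolite: str = "",
    tissue: str = "",
    ss_type: str = "sequential",
    log_transform: bool = False,
) -> pd.Series:
    """Fit the two-factor model for one metabolite; zeros are missing.

    Returns a Series with F/p per term, arm means on the raw scale, the
    genotype direction (sign of mutant minus wild-type mean) and the percent
    change 100 * (mutant mean / wild-type mean - 1).
    """
    values = np.asarray(values, dtype=float)
    genotype = np.asarray(genotype)
    diet = np.asarray(diet)
    used = values > 0
    y_raw = values[used]
    g = (genotype[used] == "mutant").astype(float)
    d = (diet[used] == "fat60").astype(float)
    n_used = int(used.sum())

    row = {"metabolite": metabolite, "tissue": tissue, "n_used": n_used}
    for key, mask in (
        ("mean_mut_fat45", (g == 1) & (d == 0)),
        ("mean_mut_fat60", (g == 1) & (d == 1)),
        ("mean_wt_fat45", (g == 0) & (d == 0)),
        ("mean_wt_fat60", (g == 0) & (d == 1)),
    ):
        row[key] = float(y_raw[mask].mean()) if mask.any() else np.nan

    if n_used < 3 or len(set(g)) < 2:
        row.update(
            {k: np.nan for k in (
                "F_genotype", "p_genotype", "F_diet", "p_diet",
                "F_interaction", "p_interaction",
            )}
        )
    else:
        y = np.log(y_raw) if log_transform else y_raw
        row.update(_anova_single(y, g, d, ss_type))

    mut_mean = y_raw[g == 1].mean() if (g == 1).any() else np.nan
    wt_mean = y_raw[g == 0].mean() if (g == 0).any() else np.nan
    row.update(_directions(mut_mean, wt_mean, "genotype"))
    f60 = y_raw[d == 1].mean() if (d == 1).any() else np.nan
    f45 = y_raw[d == 0].mean() if (d == 0).any() else np.nan
    row.update(_directions(f60, f45, "diet"))
    return pd.Series(row)


def _directions(num_mean: float, den_mean: float, factor: str) -> dict:
    if not np.isfinite(num_mean) or not np.isfinite(den_mean) or den_mean == 0:
        return {f"{factor}_direction": "none", f"percent_change_{factor}": np.nan}
    pct = 100.0 * (num_mean / den_mean - 1.0)
    direction = "increased" if pct > 0 else ("decreased" if pct < 0 else "none")
    return {f"{factor}_direction": direction, f"percent_change_{factor}": pct}


# ----------------------------------------------------------------------
class FactorialAnova(BaseEstimator):
    """Per-metabolite genotype x diet ANOVA over a peak-area matrix.

    A feature-scoring estimator: ``fit(X, y)`` takes a samples x metabolites
    frame and a metadata frame ``y`` with ``genotype`` and ``diet`` columns,
    and produces ``results_``, one row per metabolite with F statistics,
    p-values, arm means, directions and percent changes.

    Parameters
    ----------
    ss_type : {"sequential", "marginal"}
        Type I (default, order genotype -> diet -> interaction) or Type II
        sums of squares.
    log_transform : bool
        Fit on log peak areas instead of the raw scale (fold changes and arm
        means stay on the raw scale either way).
    """

    def __init__(self, ss_type: str = "sequential", log_transform: bool = False):
        self.ss_type = ss_type
        self.log_transform = log_transform

    def fit(self, X: pd.DataFrame, y: pd.DataFrame) -> "FactorialAnova":
        if self.ss_type not in ("sequential", "marginal"):
            raise ValidationError(f"unknown ss_type {self.ss_type!r}")
        genotype = np.asarray(y["genotype"])
        diet = np.asarray(y["diet"])
        tissue = ""
        if "tissue" in getattr(y, "columns", []):
            uniq = set(y["tissue"])
            if len(uniq) > 1:
                raise ValidationError(
                    "FactorialAnova expects a single tissue per fit"
                )
            tissue = next(iter(uniq))
        arr = X.to_numpy(dtype=float)
        n, p = arr.shape
        cols = list(X.columns)
        stat_keys = (
            "F_genotype", "p_genotype", "F_diet", "p_diet",
            "F_interaction", "p_interaction",
        )
        out = {k: np.full(p, np.nan) for k in stat_keys}

        detected = arr > 0
        g_full = (genotype == "mutant").astype(float)
        d_full = (diet == "fat60").astype(float)
        clean = detected.all(axis=0)
        if clean.any() and n >= 3 and len(set(g_full)) > 1:
            # fully detected metabolites share one design: batch all their
            # RSS computations through four QR factorizations
            Y = arr[:, clean]
            if self.log_transform:
                Y = np.log(Y)
            batch = _anova_shared(Y, g_full, d_full, self.ss_type)
            for k in stat_keys:
                out[k][clean] = batch[k]
        for j in np.flatnonzero(~clean):
            row = fit_factor_model(
                arr[:, j], genotype, diet,
                ss_type=self.ss_type, log_transform=self.log_transform,
            )
            for k in stat_keys:
                out[k][j] = row[k]

        # arm means / directions on the raw scale, zeros excluded, vectorized
        def _arm_mean(mask):
            m = mask[:, None] & detected
            cnt = m.sum(axis=0)
            s = np.where(m, arr, 0.0).sum(axis=0)
            return np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)

        is_mut, is_f60 = g_full == 1, d_full == 1
        means = {
            "mean_mut_fat45": _arm_mean(is_mut & ~is_f60),
            "mean_mut_fat60": _arm_mean(is_mut & is_f60),
            "mean_wt_fat45": _arm_mean(~is_mut & ~is_f60),
            "mean_wt_fat60": _arm_mean(~is_mut & is_f60),
        }
        mut_mean, wt_mean = _arm_mean(is_mut), _arm_mean(~is_mut)
        f60_mean, f45_mean = _arm_mean(is_f60), _arm_mean(~is_f60)

        frame = {"metabolite": cols, "tissue": tissue,
                 "n_used": detected.sum(axis=0)}
        frame.update(means)
        frame.update(out)
        for factor, num, den in (
            ("genotype", mut_mean, wt_mean), ("diet", f60_mean, f45_mean),
        ):
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = 100.0 * (num / den - 1.0)
            pct = np.where(np.isfinite(pct), pct, np.nan)
            frame[f"{factor}_direction"] = np.where(
                ~np.isfinite(pct), "none",
                np.where(pct > 0, "increased",
                         np.where(pct < 0, "decreased", "none")),
            )
            frame[f"percent_change_{factor}"] = pct
        self.results_ = pd.DataFrame(frame)[_RESULT_COLUMNS]
        return self


def fit_tissue_models(
    table: PeakTable,
    min_nonzero_per_arm: int = 3,
    ss_type: str = "sequential",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Filter one tissue's table and fit the factor model per metabolite."""
    filtered = filter_detected(table, min_nonzero_per_arm)
    est = FactorialAnova(ss_type=ss_type, log_transform=log_transform)
    est.fit(filtered.values, filtered.samples)
    return est.results_


# ----------------------------------------------------------------------
def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class GateResult:
    """One metabolite's pass/fail through the FDR + fold-change gate."""

    metabolite: str
    p_raw: float
    q_bh: float
    fold_change: float
    passes: bool
    direction: str


def apply_gate(
    results: pd.DataFrame,
    fdr_level: float = 0.10,
    fc_threshold: float = 0.30,
    p_column: str = "p_genotype",
) -> pd.DataFrame:
    """FDR + symmetric fold-change gate over a set of contrast results.

    A metabolite passes when its BH q-value is <= ``fdr_level`` and its fold
    change (mutant over wild-type mean ratio) is >= 1 + fc_threshold or
    <= 1 / (1 + fc_threshold).  Returns one row per metabolite with the
    direction of passing changes.
    """
    if "fold_change" in results.columns:
        fc = results["fold_change"].to_numpy(dtype=float)
    else:
        fc = 1.0 + results["percent_change_genotype"].to_numpy(dtype=float) / 100.0
    p = results[p_column].to_numpy(dtype=float)
    ok = np.isfinite(p) & np.isfinite(fc)
    q = np.full(len(p), np.nan)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    hi, lo = 1.0 + fc_threshold, 1.0 / (1.0 + fc_threshold)
    fc_pass = (fc >= hi) | (fc <= lo)
    passes = ok & (q <= fdr_level) & fc_pass
    direction = np.where(
        passes & (fc >= hi),
        "increased",
        np.where(passes & (fc <= lo), "decreased", "none"),
    )
    return pd.DataFrame(
        {
            "metabolite": results["metabolite"].to_numpy(),
            "p_raw": p,
            "q_bh": q,
            "fold_change": fc,
            "passes": passes,
            "direction": direction,
        }
    )


# ----------------------------------------------------------------------
def enrichment_rank(
    table: PeakTable, numerator_tissue: str, denominator_tissue: str
) -> pd.DataFrame:
    """Rank metabolites by mean peak-area ratio between two tissues.

    Rank 1 is the most numerator-enriched metabolite.  Metabolites absent
    (all-zero) in the denominator tissue rank ahead of all finite ratios,
    ordered by their numerator mean; ties are broken by metabolite name.
    Only metabolites detected in at least one of the two tissues appear.
    """
    present = set(table.samples["tissue"])
    for t in (numerator_tissue, denominator_tissue):
        if t not in present:
            raise ValidationError(f"tissue {t!r} not present in table")
    num = table.subset_tissue(numerator_tissue).values.mean(axis=0)
    den = table.subset_tissue(denominator_tissue).values.mean(axis=0)
    detected = (num > 0) | (den > 0)
    num, den = num[detected], den[detected]
    with np.errstate(divide="ignore"):
        ratio = num / den
    frame = pd.DataFrame(
        {"metabolite": num.index, "numerator_mean": num, "denominator_mean": den,
         "ratio": ratio}
    )
    infinite = ~np.isfinite(frame["ratio"])
    frame["_inf"] = infinite.astype(int)
    frame = frame.sort_values(
        by=["_inf", "numerator_mean", "metabolite"],
        ascending=[False, False, True],
    )
    finite = frame["_inf"] == 0
    finite_part = frame[finite].sort_values(
        by=["ratio", "metabolite"], ascending=[False, True]
    )
    frame = pd.concat([frame[~finite], finite_part])
    frame = frame.drop(columns="_inf").reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame
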