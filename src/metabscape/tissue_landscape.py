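"""Cross-tissue significance landscape.

Aggregates per-metabolite factor-model results into per-tissue counts of
nominally significant metabolites (raw p < alpha, no multiplicity correction),
a chi-square test of heterogeneity of those proportions across tissues, and
pairwise tissue overlaps with direction concordance.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError

logger = logging.getLogger(__name__)

FACTORS = ("genotype", "diet", "interaction")


def count_significant(
    results: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-tissue, per-factor counts of nominally significant metabolites.

    ``results`` is the concatenated factor-model frame (one row per
    metabolite per tissue).  Fractions use the number of metabolites with a
    defined p-value for that factor as denominator.
    """
    rows = []
    if results.empty:
        logger.warning("count_significant called with no results")
        return pd.DataFrame(
            columns=["tissue", "factor", "n_sig", "n_tested", "fraction"]
        )
    for tissue, grp in results.groupby("tissue", sort=True):
        for factor in FACTORS:
            p = grp[f"p_{factor}"].to_numpy(dtype=float)
            tested = np.isfinite(p)
            n_tested = int(tested.sum())
            n_sig = int((p[tested] < alpha).sum())
            if n_tested == 0:
                logger.warning(
                    "no testable metabolites for %s/%s; fraction reported as 0",
                    tissue,
                    factor,
                )
            rows.append(
                {
                    "tissue": tissue,
                    "factor": factor,
                    "n_sig": n_sig,
                    "n_tested": n_tested,
                    "fraction": (n_sig / n_tested) if n_tested else 0.0,
                }
            )
    return pd.DataFrame(rows)


def heterogeneity_test(summaries: pd.DataFrame) -> tuple[float, int, float]:
    """Chi-square homogeneity of significant proportions across tissues.

    ``summaries`` holds one row per tissue for a single factor (columns
    ``n_sig`` and ``n_tested``).  The test is the Pearson chi-square on the
    2 x k contingency table [significant, not-significant] x tissue, without
    continuity correction; df = k - 1.
    """
    if len(summaries) < 2:
        raise ValidationError("heterogeneity test needs at least 2 tissues")
    n_sig = summaries["n_sig"].to_numpy(dtype=float)
    n_tested = summaries["n_tested"].to_numpy(dtype=float)
    if (n_tested == 0).any():
        raise ValidationError("every tissue must have n_tested > 0")
    contingency = np.vstack([n_sig, n_tested - n_sig])
    if contingency.sum(axis=1).min() == 0:
        # all-zero row (e.g. nothing significant anywhere): no heterogeneity
        return 0.0, len(summaries) - 1, 1.0
    chi, p, df, _ = stats.chi2_contingency(contingency, correction=False)
    return float(chi), int(df), float(p)


def pairwise_overlap(
    results: pd.DataFrame, factor: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Overlap of significant metabolites between every unordered tissue pair.

    Concordance is by direction of the factor's effect: for genotype the sign
    of the mutant minus wild-type marginal mean, for diet the sign of the
    60%-fat minus 45%-fat marginal mean.  Interaction overlaps carry no
    natural sign and are counted without direction.
    """
    if factor not in FACTORS:
        raise ValidationError(f"unknown factor {factor!r}")
    p_col = f"p_{factor}"
    dir_col = f"{factor}_direction" if factor != "interaction" else None
    sig = {}
    for tissue, grp in results.groupby("tissue", sort=True):
        mask = np.nan_to_num(grp[p_col].to_numpy(dtype=float), nan=1.0) < alpha
        sig[tissue] = grp[mask].set_index("metabolite")
    rows = []
    for a, b in itertools.combinations(sorted(sig), 2):
        shared = sorted(set(sig[a].index) & set(sig[b].index))
        if dir_col is None:
            conc = disc = pd.NA
        else:
            same = [
                sig[a].loc[m, dir_col] == sig[b].loc[m, dir_col] for m in shared
            ]
            conc = int(sum(same))
            disc = len(shared) - conc
        rows.append(
            {
                "tissue_a": a,
                "tissue_b": b,
                "factor": factor,
                "n_overlap": len(shared),
                "n_concordant": conc,
                "n_discordant": disc,
                "metabolites": ";".join(shared),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tissue_a",
            "tissue_b",
            "factor",
            "n_overlap",
            "n_concordant",
            "n_discordant",
            "metabolites",
        ],
    )
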