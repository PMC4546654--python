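"""Lipid-species statistics: name parsing, Z-scores, ratio permutation nulls,
cross-tissue ordering and cell-vs-tissue quadrant concordance.

Lipid species are identified by a descriptor of the form ``CX.Y.Z`` where X is
the total acyl-chain carbon count, Y the total number of double bonds and Z
the lipid class (e.g. ``C18.0.LPC``).  The display form ``CLASS X:Y``
(``SM 24:0``) is accepted as a synonym; both parse to the same canonical
descriptor so species measured in different experiments can be matched by
structure rather than by raw string.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._errors import ValidationError

logger = logging.getLogger(__name__)

LIPID_CLASSES = ("TAG", "DAG", "PC", "LPC", "PE", "LPE", "SM", "CE", "FFA")
#: neutral (non-polar) lipid classes
NEUTRAL_CLASSES = frozenset({"TAG", "DAG", "CE"})

_DOT_FORM = re.compile(
    r"^\s*C\s*(?P<carbons>\d+)\.(?P<bonds>\d+)\.(?P<cls>[A-Za-z]+)\s*$"
)
_COLON_FORM = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+)\s+C?(?P<carbons>\d+):(?P<bonds>\d+)\s*$"
)


@dataclass(frozen=True, order=True)
class LipidDescriptor:
    """Canonical identity of one lipid species."""

    lipid_class: str
    total_carbons: int
    double_bonds: int

    @property
    def is_neutral(self) -> bool:
        return self.lipid_class in NEUTRAL_CLASSES

    @property
    def canonical(self) -> str:
        return f"C{self.total_carbons}.{self.double_bonds}.{self.lipid_class}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def parse_lipid_name(name: object) -> LipidDescriptor | None:
    """Parse a metabolite name into a :class:`LipidDescriptor`, or ``None``.

    Total function: any string that does not match a known lipid form (or
    names an unknown class, or has more double bonds than carbons) simply is
    not a lipid.
    """
    if not isinstance(name, str):
        return None
    m = _DOT_FORM.match(name) or _COLON_FORM.match(name)
    if m is None:
        return None
    cls = m.group("cls").upper()
    if cls not in LIPID_CLASSES:
        return None
    carbons = int(m.group("carbons"))
    bonds = int(m.group("bonds"))
    if carbons <= 0 or bonds < 0 or bonds >= carbons:
        return None
    return LipidDescriptor(cls, carbons, bonds)


def lipid_subset(metabolites: list[str]) -> dict[str, LipidDescriptor]:
    """Map each metabolite name that parses as a lipid to its descriptor."""
    out = {}
    for name in metabolites:
        desc = parse_lipid_name(name)
        if desc is not None:
            out[name] = desc
    return out


# ----------------------------------------------------------------------
def zscore_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Per-species Z-scores: subtract the mean, divide by the sample SD.

    Columns are species, rows samples.  A constant species has no scale and is
    returned as all-zero (with a warning) rather than NaN.
    """
    if len(values) < 2:
        raise ValidationError("zscore_matrix needs at least 2 samples")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant species set to all-zero Z-scores", int(constant.sum())
        )
    sd_safe = np.where(constant, 1.0, sd)
    z = (arr - mean) / sd_safe
    z[:, constant] = 0.0
    return pd.DataFrame(z, index=values.index, columns=values.columns)


# ----------------------------------------------------------------------
class LipidRatioPermutation(BaseEstimator):
    """Mutant/wild-type ratio distribution with a label-permutation null.

    For each lipid species the observed ratio is the mutant group mean over
    the wild-type group mean (zeros excluded as non-detections).  The center
    of the ratio distribution is compared against the centers obtained after
    reshuffling genotype labels (group sizes preserved); a center shifted away
    from 1 relative to the null indicates coordinate accumulation (or
    depletion) across the lipid panel.

    Parameters
    ----------
    n_perm : int
        Number of label permutations (ignored when ``exhaustive=True``).
    center : {"arithmetic", "geometric"}
        How the ratio-distribution center is computed.
    exhaustive : bool
        Enumerate all balanced label assignments instead of sampling; only
        sensible for small designs (C(n, n_mutant) labelings).
    random_state : int or None
        Seed for the permutation stream.
    """

    def __init__(
        self,
        n_perm: int = 1000,
        center: str = "arithmetic",
        exhaustive: bool = False,
        random_state: int | None = None,
    ):
        self.n_perm = n_perm
        self.center = center
        self.exhaustive = exhaustive
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "LipidRatioPermutation":
        """Compute observed ratios and the permutation null.

        X is a samples x species peak-area frame, y the genotype labels
        ('mutant' / 'wildtype').
        """
        if not self.exhaustive and self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.center not in ("arithmetic", "geometric"):
            raise ValidationError(f"unknown center {self.center!r}")
        y = np.asarray(y)
        is_mut = y == "mutant"
        is_wt = y == "wildtype"
        if not is_mut.any() or not is_wt.any():
            raise ValidationError("both genotypes must be present")
        arr = np.asarray(X, dtype=float)
        names = list(X.columns) if hasattr(X, "columns") else [
            f"x{i}" for i in range(arr.shape[1])
        ]

        wt_mean = _nonzero_mean(arr[is_wt])
        mut_mean = _nonzero_mean(arr[is_mut])
        keep = (wt_mean > 0) & (mut_mean > 0)
        if not keep.all():
            logger.warning(
                "excluding %d species with a zero group mean",
                int((~keep).sum()),
            )
        if not keep.any():
            raise ValidationError("no species with nonzero wild-type mean")
        arr = arr[:, keep]
        self.species_ = [n for n, k in zip(names, keep) if k]
        self.observed_ratios_ = mut_mean[keep] / wt_mean[keep]
        self.observed_center_ = self._center(self.observed_ratios_)

        n = len(y)
        n_mut = int(is_mut.sum())
        if self.exhaustive:
            from itertools import combinations

            labelings = list(combinations(range(n), n_mut))
            perms = np.zeros((len(labelings), n), dtype=bool)
            for i, combo in enumerate(labelings):
                perms[i, list(combo)] = True
        else:
            rng = np.random.default_rng(self.random_state)
            perms = np.zeros((self.n_perm, n), dtype=bool)
            for i in range(self.n_perm):
                perms[i, rng.permutation(n)[:n_mut]] = True

        centers = np.empty(len(perms))
        for i, mut_mask in enumerate(perms):
            pm = _nonzero_mean(arr[mut_mask])
            pw = _nonzero_mean(arr[~mut_mask])
            ok = (pw > 0) & (pm > 0)
            centers[i] = self._center(pm[ok] / pw[ok]) if ok.any() else np.nan
        self.permuted_centers_ = centers
        self.n_perm_ = len(centers)

        obs_dev = abs(self.observed_center_ - 1.0)
        perm_dev = np.abs(centers - 1.0)
        self.pvalue_ = (1.0 + np.sum(perm_dev >= obs_dev)) / (len(centers) + 1.0)
        return self

    def _center(self, ratios: np.ndarray) -> float:
        if self.center == "geometric":
            return float(np.exp(np.mean(np.log(ratios))))
        return float(np.mean(ratios))


def _nonzero_mean(block: np.ndarray) -> np.ndarray:
    """Column means over nonzero entries; 0 where a column is all zero."""
    nz = block > 0
    counts = nz.sum(axis=0)
    sums = np.where(nz, block, 0.0).sum(axis=0)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def ratio_distribution(
    table,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    center: str = "arithmetic",
) -> LipidRatioPermutation:
    """Fit a :class:`LipidRatioPermutation` on a lipid-subset PeakTable."""
    est = LipidRatioPermutation(
        n_perm=n_perm, center=center, exhaustive=exhaustive, random_state=seed
    )
    return est.fit(table.values, table.samples["genotype"].to_numpy())


# ----------------------------------------------------------------------
def order_by_tissue_pvalue(
    results: pd.DataFrame,
    sort_tissue: str,
    top: int | None = None,
) -> pd.DataFrame:
    """Cross-tissue lipid heatmap data, rows ordered by one tissue's p-value.

    ``results`` is a long frame of per-metabolite factor-model results
    (columns: metabolite, tissue, p_genotype, percent_change_genotype)
    restricted to lipid species.  Rows of the output are species sorted
    ascending by genotype p-value in ``sort_tissue`` (ties broken by name);
    cells are per-tissue mutant/wild-type ratios, with a parallel block of
    nominal-significance flags (p < 0.05).
    """
    tissues = sorted(results["tissue"].unique())
    if sort_tissue not in tissues:
        raise ValidationError(f"sort tissue {sort_tissue!r} not in results")
    ratios = results.pivot_table(
        index="metabolite",
        columns="tissue",
        values="percent_change_genotype",
        aggfunc="first",
    ).apply(lambda c: 1.0 + c / 100.0)
    pvals = results.pivot_table(
        index="metabolite", columns="tissue", values="p_genotype", aggfunc="first"
    )
    key = pvals[sort_tissue]
    order = (
        pd.DataFrame({"p": key, "name": key.index})
        .sort_values(["p", "name"], na_position="last")
        .index
    )
    out = pd.concat(
        [
            ratios.loc[order].add_prefix("ratio_"),
            pvals.loc[order].lt(0.05).add_prefix("sig_"),
            pvals.loc[order, [sort_tissue]].rename(
                columns={sort_tissue: "sort_p"}
            ),
        ],
        axis=1,
    )
    if top is not None:
        out = out.head(top)
    return out.reset_index()


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class QuadrantSummary:
    """Cell-vs-tissue joint classification of shared lipid species.

    Counts follow (tissue up, cell up), (tissue up, cell down),
    (tissue down, cell up), (tissue down, cell down); the chi-square compares
    the counts against an even n/4 expectation per quadrant (df = 3).
    """

    counts: tuple[int, int, int, int]
    n_species: int
    chi_square: float
    df: int
    p: float


def quadrant_concordance(
    tissue_ratios: pd.Series,
    cell_ratios: pd.Series,
    exclude_exact_one: bool = False,
) -> QuadrantSummary:
    """Quadrant concordance of mutant/wild-type ratios across compartments.

    Species are matched by canonicalized lipid descriptor so naming-style
    differences between the two inputs do not break the join.  A ratio of
    exactly 1 is assigned to the "increased" side unless
    ``exclude_exact_one`` is set (a measure-zero event for continuous data).
    """
    t = _canonicalize_index(tissue_ratios)
    c = _canonicalize_index(cell_ratios)
    shared = sorted(set(t.index) & set(c.index))
    if not shared:
        raise ValidationError("no shared lipid species between tissue and cells")
    t = t.loc[shared].astype(float)
    c = c.loc[shared].astype(float)
    if exclude_exact_one:
        keep = (t != 1.0) & (c != 1.0)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("excluding %d species with ratio exactly 1", n_drop)
        t, c = t[keep], c[keep]
        shared = list(t.index)
    else:
        n_one = int(((t == 1.0) | (c == 1.0)).sum())
        if n_one:
            logger.warning(
                "%d species with ratio exactly 1 assigned to the increased side",
                n_one,
            )
    up_t = t >= 1.0
    up_c = c >= 1.0
    counts = (
        int((up_t & up_c).sum()),
        int((up_t & ~up_c).sum()),
        int((~up_t & up_c).sum()),
        int((~up_t & ~up_c).sum()),
    )
    n = sum(counts)
    chi, p = stats.chisquare(counts)  # even expectation n/4, df = 3
    return QuadrantSummary(
        counts=counts, n_species=n, chi_square=float(chi), df=3, p=float(p)
    )


def _canonicalize_index(ratios: pd.Series) -> pd.Series:
    mapped = {}
    for name, value in ratios.items():
        desc = parse_lipid_name(name)
        key = desc.canonical if desc is not None else str(name)
        if key not in mapped:  # first occurrence wins
            mapped[key] = value
    return pd.Series(mapped)
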