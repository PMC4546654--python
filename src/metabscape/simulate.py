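"""Synthetic peak-area tables with the statistical structure of the study.

The generator emulates a two-diet knock-in mouse cohort profiled across six
tissues by LC-MS: non-negative peak areas with multiplicative (log-normal)
noise, tissue-specific baselines, independent-thinning non-detections
(value -> 0), and plantable genotype / diet / interaction effects concentrated
in configurable metabolite subsets.  Defaults reproduce the study design:
16 heterozygous-mutant and 14 wild-type mice, diets split in balanced halves
within genotype, ~250 metabolites per tissue, and a companion cell-culture
experiment of 3 mutant vs 3 wild-type replicates with matched growth-media
samples.

Effects are multiplicative on the group mean: a multiplier of 1.5 raises the
affected arm's expected peak area by 50%, exactly, because the log-normal
location is shifted by log(multiplier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .ingest import PeakTable, TISSUES
from .lipids import LIPID_CLASSES, parse_lipid_name

_FACTORS = ("genotype", "diet", "interaction")


@dataclass(frozen=True)
class EffectSpec:
    """One planted effect: which metabolites/tissues, which factor, how big.

    ``target_metabolites`` is an explicit name list or a selector string:
    ``"all"``, ``"lipids"``, ``"lipids:K"`` (K random lipids) or
    ``"random:K"`` (K random metabolites).  The multiplier scales the affected
    arm's mean: genotype effects act on the mutant arm, diet effects on the
    60%-fat arm, interaction effects on the mutant x 60%-fat cell only.
    """

    target_metabolites: object
    target_tissues: tuple[str, ...] | list[str]
    factor: str
    multiplier: float

    def __post_init__(self):
        if self.factor not in _FACTORS:
            raise ConfigurationError(f"unknown factor {self.factor!r}")
        if not self.multiplier > 0:
            raise ConfigurationError("effect multiplier must be > 0")

    def resolve(self, metabolites: list[str], rng: np.random.Generator) -> list[str]:
        sel = self.target_metabolites
        if isinstance(sel, str):
            if sel == "all":
                return list(metabolites)
            if sel == "lipids":
                return [m for m in metabolites if parse_lipid_name(m)]
            if ":" in sel:
                kind, _, k = sel.partition(":")
                pool = (
                    [m for m in metabolites if parse_lipid_name(m)]
                    if kind == "lipids"
                    else list(metabolites)
                )
                if kind not in ("lipids", "random"):
                    raise ConfigurationError(f"unknown selector {sel!r}")
                k = int(k)
                if k > len(pool):
                    raise ConfigurationError(
                        f"selector {sel!r} asks for {k} of {len(pool)} available"
                    )
                return sorted(rng.choice(pool, size=k, replace=False))
            raise ConfigurationError(f"unknown selector {sel!r}")
        missing = [m for m in sel if m not in metabolites]
        if missing:
            raise ConfigurationError(
                f"effect targets not in design: {missing[:3]!r}"
            )
        return list(sel)


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic tissue cohort.

    Defaults mirror the study: 16 mutant + 14 wild-type mice, six tissues,
    250 metabolites of which 40% are lipid species, log-normal noise with
    log-SD 0.5 (a realistic multiplicative CV for integrated peak areas),
    baseline log-means spread uniformly over [10, 16] (peak areas roughly
    2e4 to 9e6) plus a per-tissue, per-metabolite offset with SD 1.0 so that
    inter-tissue variation dominates intra-tissue variation, and a 5%
    non-detection rate.
    """

    n_mutant: int = 16
    n_wildtype: int = 14
    tissues: tuple[str, ...] = TISSUES
    n_metabolites: int = 250
    fraction_lipid: float = 0.4
    baseline_log_mean_range: tuple[float, float] = (10.0, 16.0)
    tissue_shift_sd: float = 1.0
    log_sd: float = 0.5
    detect_prob: float = 0.95
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_mutant + self.n_wildtype < 4:
            raise ConfigurationError("need at least 4 animals in total")
        if not (0 < self.detect_prob <= 1):
            raise ConfigurationError("detect_prob must be in (0, 1]")
        if not self.log_sd > 0:
            raise ConfigurationError("log_sd must be > 0")
        if not (0 <= self.fraction_lipid <= 1):
            raise ConfigurationError("fraction_lipid must be in [0, 1]")
        unknown = set(self.tissues) - set(TISSUES)
        if unknown:
            raise ConfigurationError(f"unknown tissues {sorted(unknown)!r}")


def metabolite_names(n: int, fraction_lipid: float) -> list[str]:
    """Deterministic metabolite panel: canonical lipid descriptors + polar names.

    Lipid names cycle through the nine supported classes with plausible
    chain lengths and unsaturation; polar metabolites get numbered names.
    """
    n_lipid = int(round(n * fraction_lipid))
    lipids: list[str] = []
    i = 0
    while len(lipids) < n_lipid:
        cls = LIPID_CLASSES[i % len(LIPID_CLASSES)]
        carbons = 14 + 2 * ((i // len(LIPID_CLASSES)) % 22)
        bonds = (i * 3 + i // len(LIPID_CLASSES)) % min(7, carbons - 1)
        name = f"C{carbons}.{bonds}.{cls}"
        if name not in lipids:
            lipids.append(name)
        i += 1
    polar = [f"polar_{k:03d}" for k in range(n - len(lipids))]
    return lipids + polar


def _assign_diets(n: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced random split into fat45 / fat60 (odd n: extra goes to fat60)."""
    half = n // 2
    diets = np.array(["fat45"] * half + ["fat60"] * (n - half), dtype=object)
    rng.shuffle(diets)
    return diets


def generate_tissue_cohort(design: SyntheticDesign) -> PeakTable:
    """Generate the multi-tissue mouse cohort peak table from a design.

    Diets are assigned in balanced halves within each genotype.  Values are
    drawn log-normal around per-(tissue, metabolite) baselines, planted
    effects shift the affected arm's log-location by log(multiplier), and
    each value is independently zeroed (non-detection) with probability
    1 - detect_prob.  Fully reproducible from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    mets = metabolite_names(design.n_metabolites, design.fraction_lipid)

    genotype = np.array(
        ["mutant"] * design.n_mutant + ["wildtype"] * design.n_wildtype,
        dtype=object,
    )
    diet = np.empty(len(genotype), dtype=object)
    diet[genotype == "mutant"] = _assign_diets(design.n_mutant, rng)
    diet[genotype == "wildtype"] = _assign_diets(design.n_wildtype, rng)
    subjects = [f"mouse_{i:03d}" for i in range(len(genotype))]

    lo, hi = design.baseline_log_mean_range
    base = rng.uniform(lo, hi, size=design.n_metabolites)
    tissue_offsets = {
        t: rng.normal(0.0, design.tissue_shift_sd, size=design.n_metabolites)
        for t in design.tissues
    }

    # per-(tissue, metabolite) log-shifts for each factor arm
    shifts = {t: np.zeros((3, design.n_metabolites)) for t in design.tissues}
    factor_row = {"genotype": 0, "diet": 1, "interaction": 2}
    for eff in design.effects:
        unknown = set(eff.target_tissues) - set(design.tissues)
        if unknown:
            raise ConfigurationError(
                f"effect targets unknown tissues {sorted(unknown)!r}"
            )
        targets = eff.resolve(mets, rng)
        idx = [mets.index(m) for m in targets]
        for t in eff.target_tissues:
            shifts[t][factor_row[eff.factor], idx] += np.log(eff.multiplier)

    is_mut = (genotype == "mutant").astype(float)[:, None]
    is_fat60 = (diet == "fat60").astype(float)[:, None]

    meta_rows = []
    blocks = []
    for t in design.tissues:
        loc = base + tissue_offsets[t]
        log_vals = (
            loc[None, :]
            + is_mut * shifts[t][0][None, :]
            + is_fat60 * shifts[t][1][None, :]
            + (is_mut * is_fat60) * shifts[t][2][None, :]
            + rng.normal(0.0, design.log_sd, size=(len(genotype), len(mets)))
        )
        vals = np.exp(log_vals)
        if design.detect_prob < 1.0:
            detected = rng.random(vals.shape) < design.detect_prob
            vals = np.where(detected, vals, 0.0)
        blocks.append(vals)
        for i, subj in enumerate(subjects):
            meta_rows.append(
                {
                    "sample_id": f"{subj}_{t}",
                    "subject_id": subj,
                    "tissue": t,
                    "genotype": genotype[i],
                    "diet": diet[i],
                }
            )
    samples = pd.DataFrame(meta_rows)
    values = pd.DataFrame(
        np.vstack(blocks),
        index=pd.Index(samples["sample_id"], name="sample_id"),
        columns=mets,
    )
    return PeakTable(samples, values)


def generate_cell_experiment(
    n_replicates: int = 3,
    n_metabolites: int = 185,
    effects: tuple[EffectSpec, ...] | list[EffectSpec] = (),
    seed: int = 0,
    fraction_lipid: float = 0.4,
    log_sd: float = 0.3,
    detect_prob: float = 1.0,
    baseline_log_mean_range: tuple[float, float] = (10.0, 16.0),
    metabolites: list[str] | None = None,
) -> PeakTable:
    """Generate a paired cell-pellet / growth-media culture experiment.

    ``n_replicates`` independent cultures per genotype, each contributing one
    pellet and one media sample (so 3 replicates -> 12 samples).  Effect specs
    target ``cell_pellet`` and/or ``growth_media`` as tissues; diet is
    ``none`` throughout.  Passing an explicit ``metabolites`` list lets the
    culture share species names with a tissue cohort for cross-compartment
    matching.
    """
    if n_replicates < 2:
        raise ConfigurationError("need at least 2 replicates per genotype")
    rng = np.random.default_rng(seed)
    mets = (
        list(metabolites)
        if metabolites is not None
        else metabolite_names(n_metabolites, fraction_lipid)
    )
    compartments = ("cell_pellet", "growth_media")

    lo, hi = baseline_log_mean_range
    base = {c: rng.uniform(lo, hi, size=len(mets)) for c in compartments}

    shifts = {c: {"mutant": np.zeros(len(mets))} for c in compartments}
    for eff in effects:
        if eff.factor != "genotype":
            raise ConfigurationError(
                "cell experiments support genotype effects only"
            )
        unknown = set(eff.target_tissues) - set(compartments)
        if unknown:
            raise ConfigurationError(
                f"cell effects must target {compartments}, got {sorted(unknown)!r}"
            )
        targets = eff.resolve(mets, rng)
        idx = [mets.index(m) for m in targets]
        for c in eff.target_tissues:
            shifts[c]["mutant"][idx] += np.log(eff.multiplier)

    meta_rows = []
    rows = []
    for genotype in ("mutant", "wildtype"):
        for rep in range(n_replicates):
            for comp in compartments:
                loc = base[comp].copy()
                if genotype == "mutant":
                    loc = loc + shifts[comp]["mutant"]
                vals = np.exp(loc + rng.normal(0.0, log_sd, size=len(mets)))
                if detect_prob < 1.0:
                    detected = rng.random(len(mets)) < detect_prob
                    vals = np.where(detected, vals, 0.0)
                rows.append(vals)
                meta_rows.append(
                    {
                        "sample_id": f"{genotype}_rep{rep}_{comp}",
                        "subject_id": f"{genotype}_rep{rep}",
                        "tissue": comp,
                        "genotype": genotype,
                        "diet": "none",
                    }
                )
    samples = pd.DataFrame(meta_rows)
    values = pd.DataFrame(
        np.vstack(rows),
        index=pd.Index(samples["sample_id"], name="sample_id"),
        columns=mets,
    )
    return PeakTable(samples, values)
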