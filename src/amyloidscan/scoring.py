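"""Enrichment curves, trapezoidal AUC, and log2 fitness scores.

For each variant and replicate, the read frequency at every ampicillin
concentration is normalised to the unselected (c = 0) frequency, giving a
survival curve anchored at 1.  The area under that curve over the actual
concentration grid (composite trapezoid rule) is the variant's aggregation
score, and the fitness score is ``log2(AUC_variant / AUC_WT)`` — 0 for WT
in every replicate by construction.  Scores are averaged across replicates
after the log2 transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountTable
from .reference import CANONICAL_AA, ReferenceConstruct, VariantId, enumerate_site_saturation


@dataclass
class SurvivalCurve:
    """Enrichment versus ampicillin concentration for one variant/replicate."""

    variant: VariantId
    concentrations: np.ndarray
    enrichment: np.ndarray
    replicate: int


def enrichment_curve(
    counts: CountTable,
    variant: VariantId,
    replicate: int,
    pseudocount: float = 0.5,
    n_variants: int | None = None,
) -> SurvivalCurve:
    """Pseudocounted frequency of ``variant`` normalised to c = 0.

    ``f(c) = (n_v(c) + pc) / (N(c) + pc * V)`` with ``V`` the library size
    (``n_variants``, defaults to the number of distinct variants in the
    table); enrichment is ``f(c)/f(0)``, exactly 1 at c = 0.
    """
    mat = counts.matrix(replicate)
    conc = np.array(mat.columns, dtype=float)
    totals = mat.sum(axis=0).to_numpy()
    V = n_variants if n_variants is not None else mat.shape[0]
    n_v = (
        mat.loc[variant.label].to_numpy()
        if variant.label in mat.index
        else np.zeros(len(conc))
    )
    f = (n_v + pseudocount) / (totals + pseudocount * V)
    return SurvivalCurve(variant, conc, f / f[0], replicate)


def auc(curve_values: np.ndarray, concentrations: np.ndarray) -> float:
    """Composite trapezoid area under a survival curve.

    Handles uneven concentration grids; at least two concentrations are
    required.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if len(concentrations) < 2:
        raise ValueError("need at least 2 concentrations to integrate")
    if np.any(np.diff(concentrations) <= 0):
        raise ValueError("concentrations must be strictly ascending")
    return float(np.trapezoid(np.asarray(curve_values, dtype=float), concentrations))


def fitness_score(auc_variant: float, auc_wt: float) -> float:
    """log2 ratio of variant to wild-type AUC; NaN if either is non-positive."""
    if auc_variant <= 0 or auc_wt <= 0:
        return float("nan")
    return float(np.log2(auc_variant / auc_wt))


def score_fitness(
    counts: CountTable,
    reference: ReferenceConstruct,
    pseudocount: float = 0.5,
    min_count: float = 0.0,
) -> pd.DataFrame:
    """Per-variant fitness table across all replicates.

    Every variant of the site-saturation set is scored in each replicate
    where its raw read count in the unselected (c = 0) library exceeds
    ``min_count`` (the misread floor); others are left NaN for that
    replicate.  Columns: ``variant``, ``position``, ``wt_aa``, ``mut_aa``,
    per-replicate ``fitness_rep<r>``, ``mean_fitness``, ``sem``, ``n_rep``
    and ``scored``.
    """
    variants = enumerate_site_saturation(reference)
    V = len(variants)
    labels = [v.label for v in variants]
    conc = np.array(counts.concentrations, dtype=float)
    reps = counts.replicates

    per_rep: dict[int, np.ndarray] = {}
    for rep in reps:
        mat = counts.matrix(rep).reindex(index=labels, columns=conc, fill_value=0)
        arr = mat.to_numpy(dtype=float)
        totals = arr.sum(axis=0)
        f = (arr + pseudocount) / (totals + pseudocount * V)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = f / f[:, [0]]
            areas = np.trapezoid(e, conc, axis=1)
            wt_area = areas[0]  # WT sentinel is first in the enumeration
            s = np.log2(areas / wt_area)
        s[~np.isfinite(areas) | (areas <= 0) | (wt_area <= 0)] = np.nan
        s[arr[:, 0] <= min_count] = np.nan  # misread floor on the unselected library
        per_rep[rep] = s

    table = pd.DataFrame(
        {
            "variant": labels,
            "position": [v.position for v in variants],
            "wt_aa": [v.wt_aa for v in variants],
            "mut_aa": [v.mut_aa for v in variants],
        }
    )
    for rep in reps:
        table[f"fitness_rep{rep}"] = per_rep[rep]
    return aggregate_replicates(table)


def aggregate_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SEM and replicate count of the per-replicate fitness columns."""
    rep_cols = [c for c in table.columns if c.startswith("fitness_rep")]
    scores = table[rep_cols].to_numpy(dtype=float)
    n = np.isfinite(scores).sum(axis=1)
    table = table.copy()
    masked = np.where(np.isfinite(scores), scores, np.nan)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        table["mean_fitness"] = np.nanmean(masked, axis=1)
        sd = np.nanstd(masked, axis=1, ddof=1)
    table["sem"] = np.where(n > 1, sd / np.sqrt(n), np.nan)
    table["n_rep"] = n
    table["scored"] = n > 0
    return table


def replicate_correlations(table: pd.DataFrame) -> dict[tuple[int, int], float]:
    """Pairwise Pearson correlation between per-replicate fitness scores.

    Computed over variants scored in both members of each pair.
    """
    rep_cols = sorted(
        (int(c.removeprefix("fitness_rep")), c)
        for c in table.columns
        if c.startswith("fitness_rep")
    )
    out: dict[tuple[int, int], float] = {}
    for (ra, ca), (rb, cb) in combinations(rep_cols, 2):
        x = table[ca].to_numpy(dtype=float)
        y = table[cb].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        out[(ra, rb)] = float(stats.pearsonr(x[ok], y[ok]).statistic)
    return out


@dataclass
class LandscapeSummary:
    """Headline statistics of a mutational landscape."""

    matrix: pd.DataFrame               # substituted aa (rows) x position (cols)
    per_position_mean: pd.Series
    per_aa_mean: pd.Series
    fraction_up: float                 # fitness gain >= +1
    fraction_down: float               # fitness loss <= -1
    fraction_neutral: float            # between -1 and +1
    center_mean: float
    center_median: float
    min_variant: str
    min_score: float
    max_variant: str
    max_score: float
    n_present: int
    n_possible: int
    coverage_pct: float
    class_means: pd.Series             # mean score by introduced-residue class


#: Introduced-residue classes reported by the landscape summary.
AA_CLASSES = {
    "negative": "DE",
    "positive": "KRH",
    "polar": "STNQ",
    "hydrophobic": "AVILMFWC",
    "aromatic": "FWY",
    "special": "PG",
}


def landscape_summary(
    table: pd.DataFrame, reference: ReferenceConstruct
) -> LandscapeSummary:
    """Summarise a fitness table as a heatmap matrix plus headline numbers.

    The matrix follows the conventional layout: one row per substituted
    amino acid, one column per POI position; cells of unscored variants are
    NaN and the wild-type residue's own cell is NaN (no substitution).
    Fractions, the distribution centre (mean and median both reported) and
    extreme variants are computed over scored substitutions only.
    """
    L = reference.n_poi
    sub = table[(table["position"] >= 1) & table["mean_fitness"].notna()]
    matrix = pd.DataFrame(
        np.nan, index=list(CANONICAL_AA), columns=range(1, L + 1)
    )
    for _, row in sub.iterrows():
        matrix.loc[row["mut_aa"], row["position"]] = row["mean_fitness"]

    scores = sub["mean_fitness"].to_numpy()
    n_possible = 19 * L
    frac_up = float((scores >= 1).mean()) if len(scores) else float("nan")
    frac_down = float((scores <= -1).mean()) if len(scores) else float("nan")
    imin = scores.argmin() if len(scores) else None
    imax = scores.argmax() if len(scores) else None
    per_class = {}
    for name, residues in AA_CLASSES.items():
        cls_scores = sub[sub["mut_aa"].isin(set(residues))]["mean_fitness"]
        per_class[name] = float(cls_scores.mean()) if len(cls_scores) else float("nan")

    return LandscapeSummary(
        matrix=matrix,
        per_position_mean=matrix.mean(axis=0),
        per_aa_mean=matrix.mean(axis=1),
        fraction_up=frac_up,
        fraction_down=frac_down,
        fraction_neutral=1.0 - frac_up - frac_down,
        center_mean=float(scores.mean()) if len(scores) else float("nan"),
        center_median=float(np.median(scores)) if len(scores) else float("nan"),
        min_variant=sub.iloc[imin]["variant"] if imin is not None else "",
        min_score=float(scores.min()) if len(scores) else float("nan"),
        max_variant=sub.iloc[imax]["variant"] if imax is not None else "",
        max_score=float(scores.max()) if len(scores) else float("nan"),
        n_present=int(len(scores)),
        n_possible=n_possible,
        coverage_pct=100.0 * len(scores) / n_possible,
        class_means=pd.Series(per_class),
    )
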