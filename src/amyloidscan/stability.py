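"""Comparison of mutational fitness profiles with fibril stability profiles.

Per-residue free-energy contributions of fibril structures (e.g. FoldX
output on cryo-EM polymorphs) are compared with the per-position mean
variant fitness score.  Both profiles are smoothed with a five-residue
running average and correlated per structure; a fibril-stability readout
manifests as a strong positive correlation between the inverted fitness
profile and the stability contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StabilityProfile:
    """Per-residue free-energy contribution of one fibril structure.

    ``residues`` are 1-based indices, contiguous within the resolved range
    (fibril cores may omit flexible termini); ``dg`` is the corresponding
    free-energy contribution in kcal/mol (negative = stabilising, FoldX
    convention).
    """

    structure_id: str
    residues: np.ndarray
    dg: np.ndarray

    def __post_init__(self) -> None:
        res = np.asarray(self.residues, dtype=int)
        dg = np.asarray(self.dg, dtype=float)
        if res.shape != dg.shape or res.ndim != 1:
            raise ValueError("residues and dg must be 1-D arrays of equal length")
        if len(res) and (np.any(np.diff(res) != 1) or res[0] < 1):
            raise ValueError("residues must be contiguous 1-based indices")
        object.__setattr__(self, "residues", res)
        object.__setattr__(self, "dg", dg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"structure_id": self.structure_id, "residue": self.residues, "dg": self.dg}
        )


def write_profiles(profiles: list[StabilityProfile], path: str | Path) -> None:
    pd.concat([p.to_frame() for p in profiles]).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[StabilityProfile]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, sub in df.groupby("structure_id", sort=False):
        sub = sub.sort_values("residue")
        out.append(
            StabilityProfile(str(sid), sub["residue"].to_numpy(), sub["dg"].to_numpy())
        )
    return out


def sliding_window_mean(values: np.ndarray, w: int = 5) -> np.ndarray:
    """Centred running mean with shrink-to-valid edges.

    At the profile ends the window shrinks to the residues actually
    available (no padding).  NaN entries are ignored within each window; a
    window with no finite entry yields NaN.

    Parameters
    ----------
    values : per-residue values, may contain NaN for unscored positions.
    w : odd window width >= 1 (default 5 residues).
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("window width must be odd and >= 1")
    series = pd.Series(np.asarray(values, dtype=float))
    return (
        series.rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )


def per_position_mean_fitness(
    fitness: pd.DataFrame, length: int, invert: bool = False
) -> np.ndarray:
    """Mean fitness over all scored substitutions at each POI position.

    Parameters
    ----------
    fitness :
        FitnessTable frame with ``position`` and ``mean_fitness`` columns
        (the WT sentinel, position 0, is ignored).
    length : POI length; the result has one entry per position 1..length.
    invert : multiply by -1 so that low fitness maps to high values
        (aligning with stabilising, negative dG contributions).

    Positions with no scored substitution are NaN.
    """
    sub = fitness[(fitness["position"] >= 1) & fitness["mean_fitness"].notna()]
    means = sub.groupby("position")["mean_fitness"].mean()
    out = np.full(length, np.nan)
    idx = means.index.to_numpy(dtype=int)
    out[idx - 1] = means.to_numpy()
    return -out if invert else out


@dataclass(frozen=True)
class ProfileCorrelation:
    structure_id: str
    r: float
    n: int


def correlate_profiles(
    fitness_profile: np.ndarray,
    stability_profiles: list[StabilityProfile],
    window: int = 5,
    min_overlap: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Pearson correlation of a fitness profile with each stability profile.

    Both the fitness profile (indexed 1..L) and each structure's dG profile
    are smoothed with :func:`sliding_window_mean` over ``window`` residues,
    then correlated over the residues resolved in both.  Structures with
    fewer than ``min_overlap`` shared residues are skipped with a warning.

    Returns
    -------
    (report, median_r) :
        ``report`` has one row per structure (``structure_id``, ``r``,
        ``n``); ``median_r`` is the median Pearson R across structures.
    """
    fitness_profile = np.asarray(fitness_profile, dtype=float)
    smoothed_fitness = sliding_window_mean(fitness_profile, window)
    rows = []
    for prof in stability_profiles:
        smoothed_dg = sliding_window_mean(prof.dg, window)
        # residues of this structure that fall inside the fitness profile
        in_range = (prof.residues >= 1) & (prof.residues <= len(fitness_profile))
        res = prof.residues[in_range]
        x = smoothed_fitness[res - 1]
        y = smoothed_dg[in_range]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_overlap:
            warnings.warn(
                f"structure {prof.structure_id}: only {int(ok.sum())} overlapping "
                "residues, skipped"
            )
            continue
        r = stats.pearsonr(x[ok], y[ok]).statistic
        rows.append({"structure_id": prof.structure_id, "r": r, "n": int(ok.sum())})
    report = pd.DataFrame(rows, columns=["structure_id", "r", "n"])
    median_r = float(report["r"].median()) if len(report) else float("nan")
    return report, median_r
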