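"""Feature-based regression of variant fitness from sequence.

A random-forest regressor maps single-substitution variant sequences to
fitness scores using a deliberately length-independent encoding — site
identity one-hots, relative position, dipeptide composition of the whole
variant sequence, global physicochemical means and site-delta descriptors
— so a model trained on one peptide's landscape can be applied to
amyloidogenic IDP sequences of any length.  Evaluation is k-fold
cross-validation; interpretation uses permutation feature importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from .reference import CANONICAL_AA, ReferenceConstruct, VariantId
from .scales import SCALES
from .stability import StabilityProfile, correlate_profiles, sliding_window_mean

_DIPEPTIDES = [a + b for a in CANONICAL_AA for b in CANONICAL_AA]


def feature_names() -> list[str]:
    """Ordered names of all 449 features emitted by :func:`featurize`."""
    names = [f"wt_is_{aa}" for aa in CANONICAL_AA]
    names += [f"mut_is_{aa}" for aa in CANONICAL_AA]
    names += ["relative_position"]
    names += [f"dipep_{d}" for d in _DIPEPTIDES]
    names += [f"mean_{s}" for s in SCALES]
    names += [f"delta_{s}" for s in SCALES]
    return names


def _variant_sequence(variant: VariantId, poi_sequence: str) -> str:
    if variant.is_wildtype:
        return poi_sequence
    if poi_sequence[variant.position - 1] != variant.wt_aa:
        raise ValueError(f"{variant.label}: reference residue mismatch")
    return (
        poi_sequence[: variant.position - 1]
        + variant.mut_aa
        + poi_sequence[variant.position:]
    )


def featurize(variant: VariantId, poi_sequence: str) -> np.ndarray:
    """Encode one variant as a length-independent numeric vector.

    Blocks: one-hot of the wild-type residue at the mutated site (20) and
    of the introduced residue (20) — both all-zero for the WT sentinel;
    relative site position (site/L); dipeptide composition of the full
    variant sequence (400 fractions summing to 1); mean hydrophobicity,
    polarity, beta-sheet propensity and bulkiness of the variant sequence;
    and the introduced-minus-wild-type delta on each scale (0 for WT).
    """
    for aa in poi_sequence:
        if aa not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue {aa!r}")
    seq = _variant_sequence(variant, poi_sequence)
    L = len(seq)

    wt_hot = np.zeros(20)
    mut_hot = np.zeros(20)
    rel_pos = 0.0
    deltas = np.zeros(len(SCALES))
    if not variant.is_wildtype:
        wt_hot[CANONICAL_AA.index(variant.wt_aa)] = 1.0
        mut_hot[CANONICAL_AA.index(variant.mut_aa)] = 1.0
        rel_pos = variant.position / L
        deltas = np.array(
            [tab[variant.mut_aa] - tab[variant.wt_aa] for tab in SCALES.values()]
        )

    dipep = np.zeros(400)
    for i in range(L - 1):
        dipep[_DIPEPTIDES.index(seq[i : i + 2])] += 1.0
    dipep /= max(L - 1, 1)

    means = np.array([np.mean([tab[aa] for aa in seq]) for tab in SCALES.values()])
    return np.concatenate([wt_hot, mut_hot, [rel_pos], dipep, means, deltas])


def featurize_library(
    variants: list[VariantId], poi_sequence: str
) -> pd.DataFrame:
    """Feature matrix for a list of variants (rows labelled by variant)."""
    X = np.vstack([featurize(v, poi_sequence) for v in variants])
    return pd.DataFrame(X, index=[v.label for v in variants], columns=feature_names())


@dataclass
class ModelReport:
    """Cross-validation record of one trained fitness model."""

    fold_r2: list[float]
    mean_r2: float
    median_r2: float
    sem_r2: float
    k: int
    seed: int
    fold_assignment: np.ndarray
    degenerate_target: bool = False
    attribution: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "fold_r2": self.fold_r2,
            "mean_r2": self.mean_r2,
            "median_r2": self.median_r2,
            "sem_r2": self.sem_r2,
            "k": self.k,
            "seed": self.seed,
            "degenerate_target": self.degenerate_target,
        }


def train_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_estimators: int = 300,
    max_depth: int | None = None,
) -> tuple[RandomForestRegressor, ModelReport]:
    """k-fold cross-validated random-forest regression of fitness.

    Folds are a disjoint cover of the variants (shuffled, seeded); per-fold
    R^2 is computed on the held-out variants and the final model is
    refitted on all data.  A constant target leaves R^2 undefined: the
    report is flagged ``degenerate_target`` and fold R^2 are NaN.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y must have equal length")
    Xv = X.to_numpy(dtype=float)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    degenerate = bool(np.all(y == y[0]))
    fold_r2: list[float] = []
    assignment = np.zeros(len(y), dtype=int)
    for fold, (tr, te) in enumerate(kf.split(Xv)):
        assignment[te] = fold
        if degenerate:
            fold_r2.append(float("nan"))
            continue
        model = RandomForestRegressor(
            n_estimators=n_estimators, max_depth=max_depth, random_state=seed,
            n_jobs=1,
        )
        model.fit(Xv[tr], y[tr])
        fold_r2.append(float(r2_score(y[te], model.predict(Xv[te]))))
    final = RandomForestRegressor(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    final.fit(Xv, y)
    arr = np.array(fold_r2)
    report = ModelReport(
        fold_r2=fold_r2,
        mean_r2=float(np.nanmean(arr)) if not degenerate else float("nan"),
        median_r2=float(np.nanmedian(arr)) if not degenerate else float("nan"),
        sem_r2=(
            float(np.nanstd(arr, ddof=1) / np.sqrt(k)) if not degenerate else float("nan")
        ),
        k=k,
        seed=seed,
        fold_assignment=assignment,
        degenerate_target=degenerate,
    )
    return final, report


def attribute(
    model: RandomForestRegressor,
    X: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance, ranked by mean importance drop.

    Each feature column is shuffled ``n_repeats`` times and the decrease
    in R^2 recorded; the report adds the sign of the (Pearson) association
    between the feature and the model's prediction, so directionality
    (e.g. high beta-sheet propensity lowering predicted fitness) is
    visible alongside magnitude.  Features the model never splits on score
    (numerically) zero.
    """
    imp = permutation_importance(
        model, X.to_numpy(dtype=float), np.asarray(y, dtype=float),
        n_repeats=n_repeats, random_state=seed,
    )
    pred = model.predict(X.to_numpy(dtype=float))
    signs = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(pred) == 0:
            signs.append(0.0)
        else:
            signs.append(float(np.sign(np.corrcoef(x, pred)[0, 1])))
    out = pd.DataFrame(
        {
            "feature": X.columns,
            "importance": imp.importances_mean,
            "importance_sd": imp.importances_std,
            "sign": signs,
        }
    )
    return out.sort_values("importance", ascending=False).reset_index(drop=True)


def predict_landscape(
    model: RandomForestRegressor,
    sequence: str,
    window: int = 5,
    invert: bool = False,
) -> np.ndarray:
    """Windowed per-position mean predicted substitution effect.

    All ``19 * L`` single substitutions of ``sequence`` are featurised and
    scored by the model; per-position means (optionally inverted) are
    smoothed with a centred ``window``-residue running mean.  The encoding
    is length-independent, so any IDP sequence over the canonical alphabet
    is accepted.
    """
    for aa in sequence:
        if aa not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue {aa!r} in sequence")
    L = len(sequence)
    variants = [
        VariantId(pos, wt, mut)
        for pos, wt in enumerate(sequence, start=1)
        for mut in CANONICAL_AA
        if mut != wt
    ]
    X = np.vstack([featurize(v, sequence) for v in variants])
    pred = model.predict(X)
    per_pos = pred.reshape(L, 19).mean(axis=1)
    if invert:
        per_pos = -per_pos
    return sliding_window_mean(per_pos, window)


def compare_prediction_to_stability(
    predicted_profile: np.ndarray,
    stability_profiles: list[StabilityProfile],
    window: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Correlate a predicted per-position profile with stability profiles.

    Thin wrapper over :func:`amyloidscan.stability.correlate_profiles`
    (both the predicted profile and each structure's dG profile are
    smoothed with the same ``window`` before the per-structure Pearson R
    is taken).
    """
    return correlate_profiles(predicted_profile, stability_profiles, window=window)
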