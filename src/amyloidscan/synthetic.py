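"""Synthetic data with known ground truth for every pipeline stage.

Emulates the statistical structure of a site-saturation selection read out
by sequencing: a planted fitness landscape with aggregation-prone-region
(APR) structure, logistic ampicillin survival, multinomial read sampling
from a skewed library, per-base misreads (including in the invariant G/S
linker), fibril-stability profiles anticorrelated with per-position
fitness, and noisy kinetic / endpoint-titration traces from the package's
own generative models.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .counts import CountTable
from .reference import CANONICAL_AA, ReferenceConstruct, VariantId, enumerate_site_saturation
from .stability import StabilityProfile
from .thermokinetics import CcritSeries, KineticTrace, model_mass

# Physicochemical classes used to plant substitution effects.
HYDROPHOBIC = frozenset("AVILMFWYC")
CHARGED = frozenset("DEKRH")
POLAR = frozenset("STNQ")
BREAKER = frozenset("PG")
DISRUPTIVE = CHARGED | POLAR | BREAKER

#: Default APRs of Abeta42 (1-based closed intervals): L17-A21 and I31-I41.
DEFAULT_APR_REGIONS = ((17, 21), (31, 41))


@dataclass(frozen=True)
class SelectionDesign:
    """Layout of one selection experiment.

    ``concentrations`` are ascending ampicillin concentrations (ug/mL)
    starting at 0 (the unselected library); each of ``n_replicates``
    biological repeats is sequenced to ``read_depth`` reads per plate with
    substitution misreads at ``per_base_error`` per nucleotide.
    """

    concentrations: tuple[float, ...] = (0.0, 6.25, 12.5, 25.0, 50.0, 100.0)
    n_replicates: int = 3
    read_depth: int = 30_000
    per_base_error: float = 0.0

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        if not conc or conc[0] != 0.0:
            raise ValueError("concentrations must start at 0 (unselected library)")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly ascending")
        if self.n_replicates < 1 or self.read_depth < 1:
            raise ValueError("replicates and read depth must be positive")
        if not 0.0 <= self.per_base_error < 1.0:
            raise ValueError("per_base_error must be in [0, 1)")
        object.__setattr__(self, "concentrations", conc)

    def to_dict(self) -> dict:
        return {
            "concentrations": list(self.concentrations),
            "n_replicates": self.n_replicates,
            "read_depth": self.read_depth,
            "per_base_error": self.per_base_error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionDesign":
        return cls(
            concentrations=tuple(d["concentrations"]),
            n_replicates=int(d["n_replicates"]),
            read_depth=int(d["read_depth"]),
            per_base_error=float(d.get("per_base_error", 0.0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


@dataclass
class GroundTruth:
    """Planted per-variant fitness and survival midpoints.

    ``true_fitness`` is 0 for WT by construction; ``true_survival_midpoint``
    (ug/mL ampicillin) increases strictly with true fitness.
    """

    true_fitness: dict[VariantId, float]
    true_survival_midpoint: dict[VariantId, float]
    seed: int

    @property
    def variants(self) -> list[VariantId]:
        return list(self.true_fitness)

    def fitness_array(self) -> np.ndarray:
        return np.array(list(self.true_fitness.values()))


def _substitution_effect(
    wt: str, mut: str, in_apr: bool, effect_scale: float
) -> float:
    """Deterministic class-based effect of one substitution.

    Within an APR, replacing a hydrophobic residue with a charged, polar,
    Pro or Gly residue relieves aggregation (positive fitness, charged
    strongest); the reverse swap anywhere extends or strengthens an APR
    (negative fitness, strongest within the APR).
    """
    if in_apr:
        if wt in HYDROPHOBIC and mut in DISRUPTIVE:
            return effect_scale * (1.2 if mut in CHARGED else 1.0)
        if wt not in HYDROPHOBIC and mut in HYDROPHOBIC:
            return -effect_scale
    if mut in HYDROPHOBIC and wt not in HYDROPHOBIC:
        return -0.6 * effect_scale
    return 0.0


def simulate_ground_truth(
    reference: ReferenceConstruct,
    seed: int = 0,
    apr_regions: tuple[tuple[int, int], ...] = DEFAULT_APR_REGIONS,
    effect_scale: float = 2.8,
    jitter_sd: float = 0.7,
    fitness_range: tuple[float, float] = (-4.5, 4.5),
    wt_midpoint: float = 20.0,
    midpoint_log2_scale: float = 0.9,
) -> GroundTruth:
    """Plant a fitness landscape with APR stripes over the POI.

    Substitution effects follow :func:`_substitution_effect` plus Gaussian
    jitter (sd ``jitter_sd``) and are clipped to ``fitness_range``.  The
    survival midpoint of a variant scales exponentially with its fitness,
    ``wt_midpoint * 2**(midpoint_log2_scale * fitness)``: ampicillin
    resistance is a fold-change (MIC-like) phenotype, so one fitness unit
    shifts the midpoint by a constant dilution factor, and the default
    two-fold concentration series samples that scale uniformly.

    Raises
    ------
    ValueError : APR intervals out of range, inverted, or overlapping.
    """
    L = reference.n_poi
    prev_end = 0
    for start, end in sorted(apr_regions):
        if not (1 <= start <= end <= L):
            raise ValueError(f"APR interval ({start}, {end}) outside 1..{L}")
        if start <= prev_end:
            raise ValueError("APR intervals overlap")
        prev_end = end
    in_apr = np.zeros(L + 1, dtype=bool)
    for start, end in apr_regions:
        in_apr[start : end + 1] = True

    rng = np.random.default_rng(seed)
    lo, hi = fitness_range
    fitness: dict[VariantId, float] = {}
    for v in enumerate_site_saturation(reference):
        if v.is_wildtype:
            fitness[v] = 0.0
            continue
        eff = _substitution_effect(v.wt_aa, v.mut_aa, bool(in_apr[v.position]),
                                   effect_scale)
        fitness[v] = float(np.clip(eff + rng.normal(0.0, jitter_sd), lo, hi))

    midpoints = {
        v: wt_midpoint * 2.0 ** (midpoint_log2_scale * f)
        for v, f in fitness.items()
    }
    return GroundTruth(fitness, midpoints, seed)


def survival_probability(
    concentration: float, midpoint: np.ndarray, width: float = 0.35
) -> np.ndarray:
    """Log-dose logistic survival under ampicillin; no selection at c = 0.

    Survival is sigmoidal in log2 concentration — the standard dose-
    response shape — with a slope (``width``, in log2 units) shared across
    variants; only the midpoint (ug/mL) varies.  Plating without
    antibiotic (c = 0) retains the library composition exactly.
    """
    if concentration == 0.0:
        return np.ones_like(midpoint)
    with np.errstate(over="ignore"):
        return 1.0 / (
            1.0 + np.exp((np.log2(concentration) - np.log2(midpoint)) / width)
        )


def simulate_counts(
    truth: GroundTruth,
    design: SelectionDesign,
    library_dropout: float = 0.0,
    library_alpha: float = 50.0,
    survival_width: float = 0.35,
    seed: int | None = None,
    library_freq: np.ndarray | None = None,
) -> CountTable:
    """Draw a CountTable from the planted landscape.

    The unselected library composition is Dirichlet-multinomial around
    uniform (concentration parameter ``library_alpha`` per variant,
    emulating uneven cloning) unless an explicit ``library_freq`` over
    ``truth.variants`` is given; a fraction ``library_dropout`` of non-WT
    variants is absent from all conditions.  At each (concentration,
    replicate) the expected frequency is the library frequency times the
    logistic survival probability, renormalised, and counts are multinomial
    with total ``design.read_depth``.
    """
    if not 0.0 <= library_dropout < 1.0:
        raise ValueError("library_dropout must be in [0, 1)")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    variants = truth.variants
    n = len(variants)
    midpoints = np.array([truth.true_survival_midpoint[v] for v in variants])

    if library_freq is not None:
        f0 = np.asarray(library_freq, dtype=float)
        if f0.shape != (n,) or np.any(f0 < 0):
            raise ValueError("library_freq must be a non-negative vector over variants")
        f0 = f0 / f0.sum()
    else:
        f0 = rng.dirichlet(np.full(n, library_alpha))
    if library_dropout > 0.0:
        non_wt = [i for i, v in enumerate(variants) if not v.is_wildtype]
        n_drop = int(round(library_dropout * len(non_wt)))
        dropped = rng.choice(non_wt, size=n_drop, replace=False)
        f0[dropped] = 0.0
        f0 /= f0.sum()

    counts: dict[tuple[VariantId, float, int], int] = {}
    for conc in design.concentrations:
        p_survive = survival_probability(conc, midpoints, survival_width)
        weights = f0 * p_survive
        probs = weights / weights.sum()
        for rep in range(1, design.n_replicates + 1):
            drawn = rng.multinomial(design.read_depth, probs)
            for v, k in zip(variants, drawn):
                counts[(v, conc, rep)] = int(k)
    return CountTable.from_mapping(counts)


# ----------------------------------------------------------------------
# read synthesis

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def emit_reads(
    counts: CountTable,
    reference: ReferenceConstruct,
    design: SelectionDesign,
    out_dir: str | Path,
    seed: int = 0,
) -> dict[tuple[float, int], Path]:
    """Write one FASTQ per (concentration, replicate) from a CountTable.

    Each read covers the invariant linker plus the POI with the variant's
    codon substituted; independent per-base substitution errors are applied
    at ``design.per_base_error`` (uniform over the three alternative
    bases), so apparent variants arise both in the POI and in the linker.
    Qualities are a constant placeholder ('I').
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    read_len = reference.read_length
    qual = "I" * read_len

    labels = sorted(set(counts.df["variant"]))
    templates = np.zeros((len(labels), read_len), dtype=np.uint8)
    for i, lab in enumerate(labels):
        nt = reference.variant_read(VariantId.from_label(lab))
        templates[i] = np.frombuffer(nt.encode(), dtype=np.uint8)
    label_index = {lab: i for i, lab in enumerate(labels)}

    files: dict[tuple[float, int], Path] = {}
    for conc in counts.concentrations:
        for rep in counts.replicates:
            sub = counts.variant_counts(conc, rep)
            n_reads = int(sub.sum())
            idx = np.repeat(
                [label_index[lab] for lab in sub.index], sub.to_numpy()
            )
            rng.shuffle(idx)
            reads = templates[idx].copy()
            if design.per_base_error > 0.0 and n_reads:
                mask = rng.random(reads.shape) < design.per_base_error
                k = int(mask.sum())
                if k:
                    cur = _BASE_INDEX[reads[mask]].astype(np.int64)
                    shift = rng.integers(1, 4, size=k)
                    reads[mask] = _BASES[(cur + shift) % 4]
            path = out_dir / f"reads_c{conc:g}_r{rep}.fastq"
            with open(path, "w") as fh:
                for i in range(n_reads):
                    fh.write(
                        f"@read_{conc:g}_{rep}_{i}\n"
                        f"{reads[i].tobytes().decode()}\n+\n{qual}\n"
                    )
            files[(conc, rep)] = path
    return files


# ----------------------------------------------------------------------
# downstream observables

def per_position_mean_truth(
    truth: GroundTruth, reference: ReferenceConstruct
) -> np.ndarray:
    """Mean planted fitness over the 19 substitutions at each position."""
    L = reference.n_poi
    sums = np.zeros(L)
    counts = np.zeros(L)
    for v, f in truth.true_fitness.items():
        if not v.is_wildtype:
            sums[v.position - 1] += f
            counts[v.position - 1] += 1
    return sums / np.maximum(counts, 1)


def simulate_stability_profiles(
    truth: GroundTruth,
    reference: ReferenceConstruct,
    n_structures: int = 21,
    noise_sd: float = 0.25,
    seed: int = 0,
    dg_range: tuple[float, float] = (-3.0, 1.0),
    trim_max: int = 0,
) -> list[StabilityProfile]:
    """Fibril stability profiles coupled to the planted landscape.

    The noiseless profile is the inverted per-position mean planted
    fitness rescaled affinely to ``dg_range`` (kcal/mol; negative =
    stabilising, matching the convention of per-residue free-energy
    decompositions of fibril cores).  Each of ``n_structures`` profiles
    adds independent Gaussian noise (``noise_sd`` kcal/mol) and may have
    up to ``trim_max`` unresolved residues trimmed from each terminus.
    """
    rng = np.random.default_rng(seed)
    signal = -per_position_mean_truth(truth, reference)
    lo, hi = dg_range
    span = signal.max() - signal.min()
    scaled = lo + (signal - signal.min()) * (hi - lo) / span if span else signal * 0.0
    L = reference.n_poi
    profiles = []
    for i in range(n_structures):
        start = int(rng.integers(0, trim_max + 1)) if trim_max else 0
        stop = L - (int(rng.integers(0, trim_max + 1)) if trim_max else 0)
        residues = np.arange(start + 1, stop + 1)
        dg = scaled[start:stop] + rng.normal(0.0, noise_sd, stop - start)
        profiles.append(StabilityProfile(f"SYN{i + 1:02d}", residues, dg))
    return profiles


def simulate_kinetic_trace(
    lambda_rate: float,
    kappa_rate: float,
    nc: float = 2.0,
    n2: float = 2.0,
    t_grid: np.ndarray | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    m0: float = 8.0,
) -> KineticTrace:
    """Normalised aggregation trace from the integrated rate law + noise."""
    if t_grid is None:
        t_grid = np.linspace(0.0, 10.0, 100)
    rng = np.random.default_rng(seed)
    y = model_mass(np.asarray(t_grid, dtype=float), lambda_rate, kappa_rate, nc, n2)
    return KineticTrace(np.asarray(t_grid, dtype=float),
                        y + rng.normal(0.0, noise_sd, len(y)), m0)


def simulate_ccrit_series(
    c_crit: float,
    slope: float,
    m0_list: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> CcritSeries:
    """Endpoint yield titration: signal = max(0, slope*(m0 - c_crit)) + noise."""
    rng = np.random.default_rng(seed)
    m0 = np.asarray(m0_list, dtype=float)
    signal = np.maximum(0.0, slope * (m0 - c_crit))
    return CcritSeries(m0, signal + rng.normal(0.0, noise_sd, len(m0)), label)
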