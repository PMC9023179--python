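"""Synthetic perioperative cohort generation.

No public perioperative dataset with this attribute layout exists, so the
pipeline is exercised on synthetic cohorts that reproduce the statistical
structure the downstream stages assume: 24 input attributes per system
(patient physiology A1-A18, ASA class A19, anesthesia type A20,
clinician title/seniority/age A21-A23, surgical grade or surgery-duration
class A24), imbalanced 4-class surgery-duration labels, and a monotone
dependence of the emergence duration on the surgery duration.

Continuous attributes are drawn from truncated normals parameterized by
published physiological reference ranges; class signal is injected as a
configurable mean shift (in within-class standard deviations) on a subset
of informative attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Informative continuous attributes whose class-conditional means shift
#: with the surgery-duration class.
SURGERY_INFORMATIVE = ("A2", "A3", "A4", "A5", "A9", "A10", "A16", "A17")

#: Attributes additionally shifted by the emergence-duration class, so the
#: emergence predictor can learn beyond the A24 dependence alone.
EMERGENCE_INFORMATIVE = ("A6", "A7", "A13", "A18")

#: (mean, sd, lower truncation, upper truncation) for continuous attributes.
CONTINUOUS_DEFS: dict[str, tuple[float, float, float, float]] = {
    "A2": (23.5, 3.5, 10.0, 45.0),    # BMI
    "A3": (125.0, 15.0, 60.0, 210.0),  # systolic blood pressure
    "A4": (78.0, 10.0, 35.0, 130.0),   # diastolic blood pressure
    "A5": (78.0, 12.0, 35.0, 150.0),   # pulse rate
    "A6": (17.0, 2.5, 6.0, 32.0),      # respiration rate
    "A7": (36.6, 0.4, 34.5, 39.5),     # body temperature
    "A9": (4.6, 0.5, 2.0, 7.5),        # red blood cells
    "A10": (135.0, 15.0, 60.0, 210.0),  # hemoglobin
    "A11": (0.42, 0.05, 0.15, 0.65),   # hematocrit
    "A12": (250.0, 60.0, 30.0, 650.0),  # platelets
    "A13": (4.2, 0.4, 2.2, 7.0),       # potassium
    "A14": (140.0, 3.0, 122.0, 158.0),  # sodium
    "A15": (103.0, 3.0, 85.0, 120.0),  # chloride
    "A16": (30.0, 4.0, 12.0, 62.0),    # APTT
    "A17": (12.5, 1.2, 6.0, 26.0),     # prothrombin time
    "A18": (16.5, 1.5, 8.0, 32.0),     # thrombin time
    "A22": (12.0, 7.0, 0.0, 40.0),     # clinician seniority, years
    "A23": (40.0, 8.0, 24.0, 66.0),    # clinician age, years
}

#: (levels, probabilities) for categorical attributes.
CATEGORICAL_DEFS: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "A1": ((1, 2), (0.5, 0.5)),               # gender
    "A8": ((1, 2, 3), (0.6, 0.3, 0.1)),       # heart function class
    "A19": ((1, 2, 3), (0.5, 0.35, 0.15)),    # ASA class
    "A20": ((1, 2), (0.3, 0.7)),              # local vs general anesthesia
    "A21": ((1, 2, 3, 4), (0.2, 0.4, 0.25, 0.15)),  # clinician title
}

#: General-anesthesia subtype levels used by the emergence system's A20 slot.
ANESTHESIA_SUBTYPE_LEVELS = (1, 2, 3, 4)
ANESTHESIA_SUBTYPE_PROBS = (0.4, 0.3, 0.2, 0.1)

#: Default conditional distribution P(emergence class | surgery class); rows
#: are stochastically ordered so larger surgery classes yield stochastically
#: larger emergence classes.
DEFAULT_EMERGENCE_DEPENDENCE = (
    (0.82, 0.12, 0.04, 0.02),
    (0.10, 0.72, 0.12, 0.06),
    (0.04, 0.12, 0.70, 0.14),
    (0.02, 0.06, 0.14, 0.78),
)

SURGERY_DURATION_CAP = 240.0
EMERGENCE_DURATION_CAP = 60.0

#: Minute intervals per class, right-closed: class c covers (lo_c, hi_c].
SURGERY_CLASS_EDGES = (0.0, 60.0, 120.0, 180.0, 240.0)
EMERGENCE_CLASS_EDGES = (0.0, 15.0, 40.0, 50.0, 60.0)

ATTRIBUTE_COLUMNS = tuple(f"A{i}" for i in range(1, 25))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_cases : int
        Number of records to generate.
    class_probs_surgery : tuple of 4 floats
        Marginal probabilities of the surgery-duration classes (imbalance
        control); must be nonnegative and sum to 1.
    effect_size : float
        Separation, in within-class standard deviations, between the
        extreme class-conditional means of informative continuous
        attributes (the class-1 and class-4 means differ by
        ``effect_size`` standard deviations).
    emergence_dependence : 4x4 row-stochastic matrix
        ``emergence_dependence[c-1]`` is the probability vector of the
        emergence class given surgery class ``c``.
    seed : int
        Seed for all random draws; identical spec implies identical cohort.
    """

    n_cases: int
    class_probs_surgery: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    effect_size: float = 2.0
    emergence_dependence: tuple[tuple[float, ...], ...] = DEFAULT_EMERGENCE_DEPENDENCE
    seed: int = 0
    grade_fidelity: float = 0.7  # P(surgical grade == surgery class)

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValueError(f"n_cases must be >= 0, got {self.n_cases}")
        probs = np.asarray(self.class_probs_surgery, dtype=float)
        if probs.shape != (4,):
            raise ValueError("class_probs_surgery must have exactly 4 entries")
        if (probs < 0).any():
            raise ValueError("class probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"class probabilities must sum to 1, got {probs.sum()!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        dep = np.asarray(self.emergence_dependence, dtype=float)
        if dep.shape != (4, 4):
            raise ValueError("emergence_dependence must be a 4x4 matrix")
        if (dep < 0).any() or (np.abs(dep.sum(axis=1) - 1.0) > 1e-9).any():
            raise ValueError("emergence_dependence rows must be probability vectors")
        if not 0.0 <= self.grade_fidelity <= 1.0:
            raise ValueError("grade_fidelity must lie in [0, 1]")


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Rejection-free truncated normal via inverse-CDF on the retained mass."""
    from scipy.stats import norm

    a = norm.cdf((lo - mean) / sd)
    b = norm.cdf((hi - mean) / sd)
    u = rng.random(mean.shape)
    return mean + sd * norm.ppf(a + u * (b - a))


def _class_shift(classes: np.ndarray, effect_size: float, sd: float) -> np.ndarray:
    # spread between class-1 and class-4 means equals effect_size * sd
    return effect_size * sd * (classes - 2.5) / 3.0


def _duration_within_class(
    rng: np.random.Generator, classes: np.ndarray, edges: tuple[float, ...]
) -> np.ndarray:
    lo = np.asarray(edges)[classes - 1]
    hi = np.asarray(edges)[classes]
    # (lo, hi] to match the right-closed binning convention
    return lo + (hi - lo) * (1.0 - rng.random(classes.shape))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a synthetic perioperative cohort.

    Returns a DataFrame with one row per case and columns ``case_id``,
    ``A1`` .. ``A24`` (surgery-system attribute view), ``anesthesia_subtype``
    (the emergence-system A20 level for general-anesthesia cases),
    ``surgery_minutes`` and ``emergence_minutes``. Durations are emitted in
    minutes; binning into classes is the preprocessing stage's job.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases

    surgery_class = rng.choice(
        np.arange(1, 5), size=n, p=np.asarray(spec.class_probs_surgery, dtype=float)
    )
    dep = np.asarray(spec.emergence_dependence, dtype=float)
    u = rng.random(n)
    cdf = np.cumsum(dep, axis=1)[surgery_class - 1]
    emergence_class = 1 + (u[:, None] > cdf).sum(axis=1)

    data: dict[str, np.ndarray] = {"case_id": np.arange(n)}
    for name in ATTRIBUTE_COLUMNS:
        if name in CATEGORICAL_DEFS:
            levels, probs = CATEGORICAL_DEFS[name]
            data[name] = rng.choice(np.asarray(levels), size=n, p=np.asarray(probs))
        elif name in CONTINUOUS_DEFS:
            mean, sd, lo, hi = CONTINUOUS_DEFS[name]
            shift = np.zeros(n)
            if name in SURGERY_INFORMATIVE:
                shift = shift + _class_shift(surgery_class, spec.effect_size, sd)
            if name in EMERGENCE_INFORMATIVE:
                shift = shift + _class_shift(emergence_class, spec.effect_size, sd)
            data[name] = _truncated_normal(rng, mean + shift, sd, lo, hi)
        elif name == "A24":
            # surgical grade tracks the surgery class with configurable fidelity
            keep = rng.random(n) < spec.grade_fidelity
            random_grade = rng.integers(1, 5, size=n)
            data[name] = np.where(keep, surgery_class, random_grade)
        else:  # pragma: no cover - every column is covered above
            raise AssertionError(name)

    data["anesthesia_subtype"] = rng.choice(
        np.asarray(ANESTHESIA_SUBTYPE_LEVELS),
        size=n,
        p=np.asarray(ANESTHESIA_SUBTYPE_PROBS),
    )
    data["surgery_minutes"] = _duration_within_class(
        rng, surgery_class, SURGERY_CLASS_EDGES
    )
    data["emergence_minutes"] = _duration_within_class(
        rng, emergence_class, EMERGENCE_CLASS_EDGES
    )
    return pd.DataFrame(data)


def surgery_view(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attribute view of the surgery-duration system: A1..A24 + outcome.

    A20 is the coarse anesthesia type (1 local, 2 general) and A24 the
    surgical grade; the outcome column is ``duration_minutes``.
    """
    cols = ["case_id", *ATTRIBUTE_COLUMNS]
    view = cohort[cols].copy()
    view["duration_minutes"] = cohort["surgery_minutes"].to_numpy()
    return view


def emergence_view(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attribute view of the emergence-duration system (general anesthesia only).

    A20 holds the general-anesthesia subtype, A24 the true surgery-duration
    class (binned from minutes), and ``duration_minutes`` the emergence
    outcome. Only general-anesthesia cases (coarse A20 == 2) are retained.
    """
    mask = cohort["A20"].to_numpy() == 2
    sub = cohort.loc[mask]
    view = sub[["case_id", *ATTRIBUTE_COLUMNS]].copy()
    view["A20"] = sub["anesthesia_subtype"].to_numpy()
    edges = np.asarray(SURGERY_CLASS_EDGES)
    minutes = sub["surgery_minutes"].to_numpy()
    view["A24"] = np.searchsorted(edges[1:-1], minutes, side="left") + 1
    view["duration_minutes"] = sub["emergence_minutes"].to_numpy()
    return view


@dataclass(frozen=True)
class WorkedExampleCounts:
    """The printed two-category balancing fixture."""

    n_i: dict[int, int] = field(default_factory=lambda: {1: 60, 2: 30, 3: 100})

    @property
    def n_max(self) -> int:
        return max(self.n_i.values())


def worked_example_counts() -> WorkedExampleCounts:
    """Return the worked balancing fixture: sizes 60 and 30 with maximum 100."""
    return WorkedExampleCounts()
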