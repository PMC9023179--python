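"""Automatic data preprocessing: cleaning, normalization to [0.1, 0.9],
duration binning, one-hot coding, automatic class balancing, bounded-noise
augmentation, and 60/20/20 partitioning.

The balancing step picks, for each outcome class, the integer replication
multiple that brings the replicated class size as close as possible to the
largest class size (ties resolved to the larger multiple); augmentation
then enriches the balanced set by an overall multiple M, each extra copy
perturbed by i.i.d. uniform noise bounded by +/-0.03 in normalized units
with the target left unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORM_LO = 0.1
NORM_HI = 0.9
NOISE_BOUND = 0.03

PROV_ORIGINAL = "original"
PROV_REPLICA = "balanced-replica"
PROV_AUGMENTED = "augmented"


@dataclass(frozen=True)
class BinningScheme:
    """Right-closed duration bins in minutes: class c covers (edges[c-1], edges[c]]."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size != 5:
            raise ValueError("exactly 4 classes (5 edges) are required")
        if not (np.diff(e) > 0).all():
            raise ValueError("edges must be strictly increasing")

    @property
    def cap(self) -> float:
        return self.edges[-1]

    @property
    def n_classes(self) -> int:
        return len(self.edges) - 1


SURGERY_SCHEME = BinningScheme((0.0, 60.0, 120.0, 180.0, 240.0))
EMERGENCE_SCHEME = BinningScheme((0.0, 15.0, 40.0, 50.0, 60.0))


def bin_duration(minutes, scheme: BinningScheme):
    """Map minutes to the class index in {1..4} of the right-closed bin.

    Accepts a scalar or array; raises for values outside (0, cap].
    """
    m = np.asarray(minutes, dtype=float)
    if (m <= 0).any() or (m > scheme.cap).any():
        raise ValueError(
            f"duration outside (0, {scheme.cap}]: "
            f"min={m.min() if m.size else None}, max={m.max() if m.size else None}"
        )
    edges = np.asarray(scheme.edges)
    idx = np.searchsorted(edges[1:-1], m, side="left") + 1
    return int(idx) if np.isscalar(minutes) else idx


def one_hot(class_index) -> np.ndarray:
    """Encode class index/indices in {1..4} as 4-bit rows (1 at the index)."""
    c = np.asarray(class_index)
    if ((c < 1) | (c > 4)).any():
        raise ValueError("class index must lie in {1..4}")
    eye = np.eye(4, dtype=int)
    out = eye[c - 1]
    return out


def un_hot(vector) -> int | np.ndarray:
    """Invert :func:`one_hot`; raises on rows without exactly one 1."""
    v = np.asarray(vector)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    if v.shape[1] != 4 or not (((v == 0) | (v == 1)).all() and (v.sum(axis=1) == 1).all()):
        raise ValueError("malformed one-hot vector(s)")
    idx = v.argmax(axis=1) + 1
    return int(idx[0]) if single else idx


@dataclass(frozen=True)
class NormalizationParams:
    """Per-attribute min/max fitted on a dataset, mapping onto [lo, hi]."""

    columns: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    lo: float = NORM_LO
    hi: float = NORM_HI

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("lo must be < hi")
        if (self.maxs < self.mins).any():
            raise ValueError("per-attribute max must be >= min")


def fit_normalization(
    records: pd.DataFrame, columns: tuple[str, ...] | None = None
) -> NormalizationParams:
    """Fit per-attribute min/max for the affine map onto [0.1, 0.9]."""
    if len(records) == 0:
        raise ValueError("cannot fit normalization on an empty dataset")
    if columns is None:
        columns = tuple(c for c in records.columns if c.startswith("A"))
    values = records.loc[:, list(columns)].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite attribute values")
    return NormalizationParams(
        columns=tuple(columns), mins=values.min(axis=0), maxs=values.max(axis=0)
    )


def apply_normalization(records: pd.DataFrame, params: NormalizationParams) -> np.ndarray:
    """x -> lo + (hi-lo) * (x - min) / (max - min); constant attributes map to the midpoint."""
    missing = [c for c in params.columns if c not in records.columns]
    if missing:
        raise KeyError(f"attributes absent from records: {missing}")
    x = records.loc[:, list(params.columns)].to_numpy(dtype=float)
    span = params.maxs - params.mins
    mid = 0.5 * (params.lo + params.hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = params.lo + (params.hi - params.lo) * (x - params.mins) / span
    return np.where(span == 0, mid, out)


def invert_normalization(matrix: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Analytic inverse of :func:`apply_normalization` (constant attributes
    return their fitted value)."""
    span = params.maxs - params.mins
    x = params.mins + (matrix - params.lo) * span / (params.hi - params.lo)
    return np.where(span == 0, params.mins, x)


@dataclass(frozen=True)
class CategoryCounts:
    """Per-class record counts with their maximum."""

    n_i: dict[int, int]

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_i.values()):
            raise ValueError("class counts must be >= 0")

    @property
    def n_max(self) -> int:
        return max(self.n_i.values())


def category_counts(classes) -> CategoryCounts:
    c = np.asarray(classes)
    return CategoryCounts({k: int((c == k).sum()) for k in (1, 2, 3, 4)})


def compute_balance_multiple(n_i: int, n_max: int) -> int:
    """Replication multiple for a class of size ``n_i`` given the largest
    class size ``n_max``.

    Returns the smallest positive integer m with (2m+1) * n_i > 2 * n_max,
    i.e. the unique m whose interval
    2*n_max/(2m-1) >= n_i > 2*n_max/(2m+1) contains n_i. Equivalently m
    minimizes ``|m*n_i - n_max|`` over positive integers with exact ties
    resolved to the larger m.
    """
    if n_i <= 0:
        raise ValueError("n_i must be positive")
    if n_i > n_max:
        raise ValueError("n_i cannot exceed n_max")
    m = 1
    while (2 * m + 1) * n_i <= 2 * n_max:
        m += 1
    return m


@dataclass(frozen=True)
class BalancePlan:
    """Replication multiple per class; 1 for the largest class."""

    multiples: dict[int, int]

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.multiples.values()):
            raise ValueError("multiples must be >= 1")


def build_balance_plan(counts: CategoryCounts) -> BalancePlan:
    """Compute each class's replication multiple; empty classes are skipped
    with a warning (their multiple is undefined)."""
    n_max = counts.n_max
    multiples: dict[int, int] = {}
    for cls, n in sorted(counts.n_i.items()):
        if n == 0:
            logger.warning("class %d is empty; balancing multiple undefined, skipped", cls)
            continue
        multiples[cls] = compute_balance_multiple(n, n_max)
    return BalancePlan(multiples)


@dataclass
class EncodedDataset:
    """Normalized inputs, one-hot targets, and per-record provenance tags."""

    X: np.ndarray
    Y: np.ndarray
    provenance: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if self.X.shape[0] != self.Y.shape[0] or self.X.shape[0] != len(self.provenance):
            raise ValueError("input, target, and provenance row counts differ")
        if self.Y.ndim != 2 or self.Y.shape[1] != 4 or not (self.Y.sum(axis=1) == 1).all():
            raise ValueError("targets must be one-hot rows of width 4")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return self.Y.argmax(axis=1) + 1

    def take(self, index: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            self.X[index],
            self.Y[index],
            self.provenance[index],
            None if self.ids is None else self.ids[index],
        )

    @staticmethod
    def concat(parts: list["EncodedDataset"]) -> "EncodedDataset":
        ids = None
        if all(p.ids is not None for p in parts):
            ids = np.concatenate([p.ids for p in parts])
        return EncodedDataset(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.Y for p in parts]),
            np.concatenate([p.provenance for p in parts]),
            ids,
        )


def apply_balance(dataset: EncodedDataset, plan: BalancePlan) -> EncodedDataset:
    """Duplicate each class's records (m_i - 1) times as exact copies tagged
    as balanced replicas; the largest class is unchanged."""
    parts = [dataset]
    classes = dataset.classes
    for cls, m in sorted(plan.multiples.items()):
        if m == 1:
            continue
        idx = np.flatnonzero(classes == cls)
        for _ in range(m - 1):
            replica = dataset.take(idx)
            replica.provenance = np.full(len(idx), PROV_REPLICA, dtype=object)
            parts.append(replica)
    return EncodedDataset.concat(parts)


@dataclass(frozen=True)
class AugmentationConfig:
    """Enrichment multiple M with the bounded uniform noise law."""

    multiple: int = 3
    noise_bound: float = NOISE_BOUND
    seed: int = 0
    additive: bool = False  # True: add M noisy copies (total (M+1)x) instead of Mx total

    def __post_init__(self) -> None:
        if self.multiple < 1:
            raise ValueError("enrichment multiple must be >= 1")
        if self.noise_bound < 0:
            raise ValueError("noise bound must be >= 0")


def augment(dataset: EncodedDataset, config: AugmentationConfig) -> EncodedDataset:
    """Enrich a normalized dataset to M times its size: the originals plus
    (M - 1) noisy copies of each record. Noise is i.i.d. uniform on
    [-noise_bound, +noise_bound] per input cell; targets are copied
    unchanged and no clipping is applied."""
    n_copies = config.multiple if config.additive else config.multiple - 1
    if n_copies == 0:
        return dataset
    rng = np.random.default_rng(config.seed)
    parts = [dataset]
    for _ in range(n_copies):
        noise = rng.uniform(-config.noise_bound, config.noise_bound, size=dataset.X.shape)
        parts.append(
            EncodedDataset(
                dataset.X + noise,
                dataset.Y.copy(),
                np.full(len(dataset), PROV_AUGMENTED, dtype=object),
                None if dataset.ids is None else dataset.ids.copy(),
            )
        )
    return EncodedDataset.concat(parts)


@dataclass(frozen=True)
class SplitSpec:
    """60/20/20 train/test/validation split specification."""

    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if (r <= 0).any() or abs(r.sum() - 1.0) > 1e-9:
            raise ValueError("split ratios must be positive and sum to 1")


def partition(
    dataset: EncodedDataset, spec: SplitSpec
) -> tuple[EncodedDataset, EncodedDataset, EncodedDataset]:
    """Disjoint exhaustive uniformly-random split with sizes
    floor(r1*n) / floor(r2*n) / remainder."""
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot partition an empty dataset")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(spec.ratios[0] * n))
    n_test = int(np.floor(spec.ratios[1] * n))
    return (
        dataset.take(perm[:n_train]),
        dataset.take(perm[n_train : n_train + n_test]),
        dataset.take(perm[n_train + n_test :]),
    )


@dataclass(frozen=True)
class CleaningRules:
    """Inspection and exclusion rules applied before encoding."""

    duration_cap: float
    categorical_levels: dict[str, tuple[int, ...]] = field(default_factory=dict)
    iqr_outliers: bool = False
    iqr_factor: float = 3.0


DEFAULT_SURGERY_LEVELS = {
    "A1": (1, 2),
    "A8": (1, 2, 3),
    "A19": (1, 2, 3),
    "A20": (1, 2),
    "A21": (1, 2, 3, 4),
    "A24": (1, 2, 3, 4),
}
DEFAULT_EMERGENCE_LEVELS = {
    "A1": (1, 2),
    "A8": (1, 2, 3),
    "A19": (1, 2, 3),
    "A20": (1, 2, 3, 4),
    "A21": (1, 2, 3, 4),
    "A24": (1, 2, 3, 4),
}


def default_rules(system: str) -> CleaningRules:
    if system == "surgery":
        return CleaningRules(SURGERY_SCHEME.cap, DEFAULT_SURGERY_LEVELS)
    if system == "emergence":
        return CleaningRules(EMERGENCE_SCHEME.cap, DEFAULT_EMERGENCE_LEVELS)
    raise ValueError(f"unknown system {system!r}")


def clean(records: pd.DataFrame, rules: CleaningRules) -> tuple[pd.DataFrame, int]:
    """Drop records violating level sets, the duration cap, or (optionally)
    an IQR outlier rule on continuous attributes; returns (kept, n_removed)."""
    if len(records) == 0:
        return records, 0
    keep = np.ones(len(records), dtype=bool)
    for col, levels in rules.categorical_levels.items():
        if col not in records.columns:
            raise KeyError(f"cleaning rule references unknown attribute {col!r}")
        keep &= records[col].isin(levels).to_numpy()
    d = records["duration_minutes"].to_numpy(dtype=float)
    keep &= (d > 0) & (d <= rules.duration_cap)
    cont_cols = [
        c
        for c in records.columns
        if c.startswith("A") and c not in rules.categorical_levels
    ]
    vals = records.loc[:, cont_cols].to_numpy(dtype=float)
    keep &= np.isfinite(vals).all(axis=1)
    if rules.iqr_outliers:
        q1, q3 = np.percentile(vals[keep], [25, 75], axis=0)
        iqr = q3 - q1
        lo, hi = q1 - rules.iqr_factor * iqr, q3 + rules.iqr_factor * iqr
        keep &= ((vals >= lo) & (vals <= hi)).all(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("clean: removed %d of %d records", n_removed, len(records))
    return records.loc[keep], n_removed


@dataclass(frozen=True)
class PipelineConfig:
    """Full preprocessing configuration for one system."""

    system: str = "surgery"  # 'surgery' | 'emergence'
    enrichment_multiple: int = 3
    noise_bound: float = NOISE_BOUND
    mode: str = "paper_faithful"  # | 'leakage_safe'
    split: SplitSpec = SplitSpec()
    seed: int = 0
    balance: bool = True
    additive_enrichment: bool = False
    rules: CleaningRules | None = None

    @property
    def scheme(self) -> BinningScheme:
        return SURGERY_SCHEME if self.system == "surgery" else EMERGENCE_SCHEME


@dataclass
class PipelineResult:
    train: EncodedDataset
    test: EncodedDataset
    validation: EncodedDataset
    norm_params: NormalizationParams
    plan: BalancePlan | None
    report: dict


def _encode(records: pd.DataFrame, scheme: BinningScheme, params: NormalizationParams):
    X = apply_normalization(records, params)
    classes = bin_duration(records["duration_minutes"].to_numpy(dtype=float), scheme)
    Y = one_hot(classes)
    ids = records["case_id"].to_numpy() if "case_id" in records.columns else None
    return EncodedDataset(X, Y, np.full(len(records), PROV_ORIGINAL, dtype=object), ids)


def _balance_and_augment(ds: EncodedDataset, config: PipelineConfig, report: dict):
    plan = None
    if config.balance:
        plan = build_balance_plan(category_counts(ds.classes))
        ds = apply_balance(ds, plan)
        report["after_balance"] = len(ds)
    ds = augment(
        ds,
        AugmentationConfig(
            multiple=config.enrichment_multiple,
            noise_bound=config.noise_bound,
            seed=config.seed + 1,
            additive=config.additive_enrichment,
        ),
    )
    report["after_augment"] = len(ds)
    return ds, plan


def preprocess_pipeline(records: pd.DataFrame, config: PipelineConfig) -> PipelineResult:
    """Compose clean -> encode -> normalize -> balance -> augment -> partition.

    In ``paper_faithful`` mode balancing and augmentation happen before the
    split, so replicas of one source record may land in different splits; in
    ``leakage_safe`` mode the split comes first and replicas/augmented
    copies stay inside the training split. The returned report records
    counts at every stage and the mode used.
    """
    if config.mode not in ("paper_faithful", "leakage_safe"):
        raise ValueError(f"unknown pipeline mode {config.mode!r}")
    report: dict = {"mode": config.mode, "input": len(records)}
    rules = config.rules or default_rules(config.system)
    kept, n_removed = clean(records, rules)
    report["after_clean"] = len(kept)
    report["removed_by_clean"] = n_removed
    params = fit_normalization(kept)
    encoded = _encode(kept, config.scheme, params)

    if config.mode == "paper_faithful":
        encoded, plan = _balance_and_augment(encoded, config, report)
        split = replace(config.split, seed=config.split.seed + config.seed)
        train, test, validation = partition(encoded, split)
    else:
        split = replace(config.split, seed=config.split.seed + config.seed)
        train, test, validation = partition(encoded, split)
        train, plan = _balance_and_augment(train, config, report)

    report["train"] = len(train)
    report["test"] = len(test)
    report["validation"] = len(validation)
    if plan is not None:
        report["balance_multiples"] = dict(plan.multiples)
    return PipelineResult(train, test, validation, params, plan, report)
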