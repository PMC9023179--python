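"""Replicate grid search, t-test comparison, and the accuracy-then-runtime
architecture selection protocol, plus the dropout and enrichment follow-up
experiments.

Each grid cell trains R independently seeded replicates and is summarized
by Mean/Std/Max/Min of accuracy and loss on the training, testing, and
validation datasets, plus total wall-clock runtime. Architectures are
compared with a one-tailed pooled-variance two-sample t-test at alpha =
0.05 (Welch and two-tailed variants are configurable); a top architecture
is demoted to a cheaper rival when it is not significantly better and the
rival saves runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from periopredict.network import (
    ArchitectureSpec,
    TrainConfig,
    TrialResult,
    build_mlp,
    train,
)

DATASET_NAMES = ("test", "train", "validation")


def derive_seed(master_seed: int, *indices: int) -> int:
    """Deterministic child seed from the master seed and an index path."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), *map(int, indices)))
    return int(ss.generate_state(1)[0])


@dataclass(frozen=True)
class GridSpec:
    """The replicate grid: layer counts x widths, R replicates per cell."""

    layer_counts: tuple[int, ...] = (3, 4, 5, 6)
    widths: tuple[int, ...] = (64, 128, 256, 512)
    replicates: int = 10
    train_config: TrainConfig = TrainConfig()
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if not self.layer_counts or not self.widths:
            raise ValueError("grid must be nonempty")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates are required for t-tests")

    @property
    def architectures(self) -> list[ArchitectureSpec]:
        return [
            ArchitectureSpec(hidden_layers=l, width=w, dropout=self.dropout)
            for l in self.layer_counts
            for w in self.widths
        ]


@dataclass
class CellResult:
    """Raw replicate results and total runtime for one architecture."""

    arch: ArchitectureSpec
    trials: list[TrialResult]
    runtime_s: float

    def accuracies(self, dataset: str = "test") -> np.ndarray:
        return np.array([t.accuracy(dataset) for t in self.trials])


@dataclass
class GridResult:
    cells: dict[str, CellResult]
    summary: pd.DataFrame
    runtimes: pd.DataFrame


def _run_cell(
    arch: ArchitectureSpec,
    train_set,
    test_set,
    validation_set,
    replicates: int,
    train_config: TrainConfig,
    master_seed: int,
    cell_index: int,
) -> CellResult:
    trials = []
    for r in range(replicates):
        seed = derive_seed(master_seed, cell_index, r)
        model = build_mlp(arch, seed=seed)
        cfg = replace(train_config, seed=seed)
        trials.append(train(model, train_set, cfg, test_set, validation_set))
    return CellResult(arch, trials, sum(t.runtime_s for t in trials))


def summarize_cells(cells: dict[str, CellResult]) -> pd.DataFrame:
    """Mean/Std/Max/Min of accuracy and loss per architecture x dataset."""
    rows = []
    for name, cell in cells.items():
        row: dict = {"architecture": name}
        for ds in DATASET_NAMES:
            acc = cell.accuracies(ds)
            loss = np.array([getattr(t, f"{ds}_loss") for t in cell.trials])
            row[f"{ds}_acc_mean"] = acc.mean()
            row[f"{ds}_acc_std"] = acc.std(ddof=1)
            row[f"{ds}_acc_max"] = acc.max()
            row[f"{ds}_acc_min"] = acc.min()
            row[f"{ds}_loss_mean"] = loss.mean()
            row[f"{ds}_loss_std"] = loss.std(ddof=1)
            row[f"{ds}_loss_max"] = loss.max()
            row[f"{ds}_loss_min"] = loss.min()
        rows.append(row)
    return pd.DataFrame(rows).set_index("architecture")


def run_grid(grid: GridSpec, train_set, test_set, validation_set, seed: int = 0) -> GridResult:
    """Train R seeded replicates per architecture and summarize.

    Replicate seeds derive deterministically from ``seed`` through
    :func:`derive_seed`, so a rerun with the same master seed reproduces
    the summary exactly.
    """
    cells: dict[str, CellResult] = {}
    for i, arch in enumerate(grid.architectures):
        cells[arch.name] = _run_cell(
            arch, train_set, test_set, validation_set,
            grid.replicates, grid.train_config, seed, i,
        )
    summary = summarize_cells(cells)
    runtimes = pd.DataFrame(
        {"runtime_s": {name: c.runtime_s for name, c in cells.items()}}
    )
    return GridResult(cells, summary, runtimes)


@dataclass(frozen=True)
class TTestResult:
    """One comparison 'is mean(A) greater than mean(B)?'."""

    pair: tuple[str, str]
    t_statistic: float
    p_value: float
    alpha: float
    significant: bool
    direction: str  # 'a_greater' | 'b_greater' | 'equal'
    degenerate: bool = False


def compare_t_test(
    a,
    b,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
    equal_var: bool = True,
    tails: int = 1,
) -> TTestResult:
    """Two-sample t-test for 'mean(a) > mean(b)' (one-tailed by default,
    pooled variance; Welch via ``equal_var=False``, two-tailed via
    ``tails=2``). Zero variance in both samples with equal means is
    degenerate: p = 0.5 by convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    mean_a, mean_b = a.mean(), b.mean()
    direction = (
        "a_greater" if mean_a > mean_b else "b_greater" if mean_b > mean_a else "equal"
    )
    if a.std() == 0.0 and b.std() == 0.0:
        if mean_a == mean_b:
            return TTestResult(labels, 0.0, 0.5, alpha, False, "equal", degenerate=True)
        p = 0.0 if mean_a > mean_b else 1.0
        if tails == 2:
            p = 0.0
        return TTestResult(
            labels, np.inf if mean_a > mean_b else -np.inf, p, alpha, p < alpha,
            direction, degenerate=True,
        )
    alternative = "greater" if tails == 1 else "two-sided"
    t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return TTestResult(labels, float(t_stat), float(p), alpha, bool(p < alpha), direction)


def runtime_savings(slow_s: float, fast_s: float) -> float:
    """Runtime saving of the fast architecture versus the slow one, in percent."""
    if slow_s <= 0:
        raise ValueError("slow runtime must be positive")
    return 100.0 * (slow_s - fast_s) / slow_s


@dataclass
class SelectionTrace:
    steps: list[dict] = field(default_factory=list)

    def record(self, **kwargs) -> None:
        self.steps.append(kwargs)


def _pick_among(
    names: list[str],
    cells: dict[str, CellResult],
    runtimes: dict[str, float],
    alpha: float,
    trace: SelectionTrace,
    stage: str,
) -> str:
    ordered = sorted(
        names, key=lambda n: cells[n].accuracies("test").mean(), reverse=True
    )
    winner = ordered[0]
    for challenger in ordered[1:]:
        test = compare_t_test(
            cells[winner].accuracies("test"),
            cells[challenger].accuracies("test"),
            alpha=alpha,
            labels=(winner, challenger),
        )
        saves_runtime = runtimes[challenger] < runtimes[winner]
        demote = (not test.significant) and saves_runtime
        trace.record(
            stage=stage,
            winner=winner,
            challenger=challenger,
            p_value=test.p_value,
            significant=test.significant,
            challenger_saves_runtime=saves_runtime,
            runtime_savings_pct=(
                runtime_savings(runtimes[winner], runtimes[challenger])
                if saves_runtime
                else None
            ),
            demoted=demote,
        )
        if demote:
            winner = challenger
    return winner


def select_architecture(
    result: GridResult, alpha: float = 0.05
) -> tuple[ArchitectureSpec, SelectionTrace]:
    """Two-stage accuracy-then-runtime rule.

    Within each layer count, the width with the highest mean testing
    accuracy wins unless a cheaper width is statistically indistinguishable
    (p >= alpha) and saves runtime, in which case the cheaper width takes
    over; the per-layer winners are then compared the same way. Every
    comparison is recorded in the returned trace.
    """
    cells = result.cells
    if not cells:
        raise ValueError("empty grid result")
    runtimes = {name: cell.runtime_s for name, cell in cells.items()}
    by_layers: dict[int, list[str]] = {}
    for name, cell in cells.items():
        by_layers.setdefault(cell.arch.hidden_layers, []).append(name)
    trace = SelectionTrace()
    finalists = [
        _pick_among(names, cells, runtimes, alpha, trace, stage=f"layers={layers}")
        for layers, names in sorted(by_layers.items())
    ]
    final = _pick_among(finalists, cells, runtimes, alpha, trace, stage="final")
    trace.record(stage="selected", winner=final)
    return cells[final].arch, trace


def dropout_experiment(
    arch: ArchitectureSpec,
    train_set,
    test_set,
    validation_set,
    p_values: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3),
    replicates: int = 10,
    train_config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Rerun the selected architecture across dropout settings; the summary
    carries a ``monotone_nonincreasing`` flag on mean testing accuracy."""
    cells: dict[str, CellResult] = {}
    for i, p in enumerate(p_values):
        a = replace(arch, dropout=p)
        cells[f"p={p}"] = _run_cell(
            a, train_set, test_set, validation_set, replicates, train_config, seed, i
        )
    summary = summarize_cells(cells)
    means = [cells[f"p={p}"].accuracies("test").mean() for p in p_values]
    summary.attrs["monotone_nonincreasing"] = bool(
        all(x >= y for x, y in zip(means, means[1:]))
    )
    return summary


def enrichment_experiment(
    arch: ArchitectureSpec,
    raw_records,
    pipeline_config,
    settings: tuple[tuple[int, int], ...] = ((3, 200), (10, 200), (10, 1000)),
    replicates: int = 10,
    train_config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Rerun preprocessing at each enrichment multiple M and training at each
    epoch count E; rows are labelled ``M=<m>,E=<e>`` and the summary notes the
    ordering of mean testing accuracies in ``accuracy_order``."""
    from periopredict.preprocess import preprocess_pipeline

    cells: dict[str, CellResult] = {}
    for i, (multiple, epochs) in enumerate(settings):
        cfg = replace(pipeline_config, enrichment_multiple=multiple)
        prep = preprocess_pipeline(raw_records, cfg)
        tc = replace(train_config, epochs=epochs)
        cells[f"M={multiple},E={epochs}"] = _run_cell(
            arch, prep.train, prep.test, prep.validation, replicates, tc, seed, i
        )
    summary = summarize_cells(cells)
    means = {name: cell.accuracies("test").mean() for name, cell in cells.items()}
    summary.attrs["accuracy_order"] = sorted(means, key=means.get)
    return summary
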