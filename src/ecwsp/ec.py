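"""Exhaustive equidistant-combination (EC) wavelength screening.

An EC model is an arithmetic progression of grid wavelengths described by
three parameters: the initial wavelength ``I`` (nm, on grid), the number of
wavelengths ``N`` and the gap ``G`` in grid steps between consecutive
wavelengths. Its ending wavelength is ``E = I + step_nm * (N - 1) * G``.
Wide gaps thin out neighbouring wavelengths, which weakens the spectral
autocorrelation that violates the naive-Bayes independence assumption.

The search enumerates *every* valid model within the parameter bounds,
scores each on the prediction set with calibration-fit class statistics,
and ranks by the composite indicator ``RAR_Total - RAR_SD``. Scoring runs
off a precomputed log-density cube, so each model costs one contiguous
subset sum; models are batched over the initial wavelength to keep the
Python overhead per model negligible. Batched scores are bit-identical to
a direct per-model evaluation (same summation order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from . import bayes
from .errors import ConfigError, ModelSpecError
from .io import SpectralDataset, WavelengthGrid
from .metrics import EvaluationResult

#: target element count per scoring batch (keeps peak memory ~tens of MB)
_BATCH_ELEMENTS = 4_000_000


@dataclass(frozen=True)
class ECSpec:
    """One equidistant wavelength model (I, N, G)."""

    start_nm: float  # I
    n_wavelengths: int  # N
    gap_steps: int = 1  # G, in grid steps

    def __post_init__(self) -> None:
        if self.n_wavelengths < 1:
            raise ModelSpecError("N must be >= 1")
        if self.gap_steps < 1:
            raise ModelSpecError("G must be >= 1")
        if self.n_wavelengths == 1 and self.gap_steps != 1:
            raise ModelSpecError("canonical form requires G = 1 when N = 1")

    def end_nm(self, step_nm: float) -> float:
        """Ending wavelength E = I + step * (N - 1) * G."""
        return self.start_nm + step_nm * (self.n_wavelengths - 1) * self.gap_steps

    def wavelengths(self, grid: WavelengthGrid) -> np.ndarray:
        return ec_wavelengths(self, grid)

    def indices(self, grid: WavelengthGrid) -> np.ndarray:
        i0 = grid.index(self.start_nm)
        idx = i0 + self.gap_steps * np.arange(self.n_wavelengths)
        if idx[-1] >= grid.point_count:
            raise ModelSpecError(
                f"model (I={self.start_nm:g}, N={self.n_wavelengths}, "
                f"G={self.gap_steps}) ends at "
                f"{self.end_nm(grid.step_nm):g} nm, beyond the grid end {grid.end_nm:g} nm"
            )
        return idx.astype(np.intp)


def ec_wavelengths(spec: ECSpec, grid: WavelengthGrid) -> np.ndarray:
    """The model's wavelength list [I, I + step*G, ..., E] in nm."""
    return grid.wavelengths[spec.indices(grid)]


@dataclass(frozen=True)
class SearchParams:
    """Bounds and evaluation settings for the exhaustive EC search."""

    n_max: int = 1050
    g_max: int = 50
    eval_set: str = "prediction"
    priors_mode: str = "proportional"
    include_prior: bool = True
    sd_floor: float = bayes.DEFAULT_SD_FLOOR
    top_k: int = 10
    criterion: str = "composite"  # phase-out scoring: "composite" or "rar-total"
    i_stride: int = 1  # coarser initial-wavelength stride for desk-scale runs
    budget: int | None = None  # cap on the number of models evaluated

    def __post_init__(self) -> None:
        if self.n_max < 1 or self.g_max < 1 or self.i_stride < 1 or self.top_k < 1:
            raise ConfigError("n_max, g_max, i_stride and top_k must be >= 1")
        if self.criterion not in ("composite", "rar-total"):
            raise ConfigError(f"unknown criterion {self.criterion!r}")
        if self.budget is not None and self.budget < 0:
            raise ConfigError("budget must be >= 0")


def _ng_blocks(p: int, params: SearchParams) -> Iterator[tuple[int, int]]:
    """(N, G) pairs in enumeration order: singletons first, then G asc, N asc."""
    yield (1, 1)
    for g in range(1, params.g_max + 1):
        for n in range(2, params.n_max + 1):
            if (n - 1) * g > p - 1:
                break  # larger N can only overshoot further for this G
            yield (n, g)


def enumerate_specs(grid: WavelengthGrid, params: SearchParams) -> Iterator[ECSpec]:
    """Yield every canonical EC model within bounds whose E stays on the grid."""
    p = grid.point_count
    wl = grid.wavelengths
    for n, g in _ng_blocks(p, params):
        span = (n - 1) * g
        for i0 in range(0, p - span, params.i_stride):
            yield ECSpec(float(wl[i0]), n, g)


def count_specs(grid: WavelengthGrid, params: SearchParams) -> int:
    """Number of models the search will enumerate (cheap arithmetic)."""
    p = grid.point_count
    total = 0
    for n, g in _ng_blocks(p, params):
        span = (n - 1) * g
        total += len(range(0, p - span, params.i_stride))
    return total


@dataclass
class SearchContext:
    """Everything needed to score wavelength subsets on one evaluation set."""

    stats: bayes.ClassStats
    priors: bayes.PriorSpec
    include_prior: bool
    cube: bayes.LogDensityCube  # over the evaluation spectra, full grid
    true_labels: np.ndarray
    eval_set: str
    criterion: str = "composite"

    @property
    def class_ids(self) -> np.ndarray:
        return np.asarray(self.stats.class_ids)

    @property
    def _true_idx(self) -> np.ndarray:
        return np.searchsorted(self.class_ids, self.true_labels)

    @property
    def _log_prior(self) -> np.ndarray:
        if self.include_prior:
            return self.priors.log_values
        return np.zeros(len(self.class_ids))

    def evaluate_indices(self, idx: np.ndarray) -> EvaluationResult:
        """Score one wavelength-index subset via the cube."""
        scores = self.cube.subset_log_conditional(idx) + self._log_prior
        pred = self.class_ids[np.argmax(scores, axis=1)]
        from .metrics import evaluate

        return evaluate(self.true_labels, pred, self.class_ids, eval_set=self.eval_set)

    def criterion_value(self, result: EvaluationResult) -> float:
        return result.composite if self.criterion == "composite" else result.rar_total


def make_context(
    dataset: SpectralDataset,
    params: SearchParams,
    stats: bayes.ClassStats | None = None,
    eval_set: str | None = None,
) -> SearchContext:
    """Fit on calibration (full grid, once) and cache the evaluation-set cube."""
    if stats is None:
        stats = bayes.fit(dataset, sd_floor=params.sd_floor)
    cal = dataset.subset("calibration")
    priors = bayes.PriorSpec.for_stats(stats, params.priors_mode, cal.class_labels)
    tag = params.eval_set if eval_set is None else eval_set
    ev = dataset.subset(tag)
    if ev.n_spectra == 0:
        raise ConfigError(f"evaluation set {tag!r} is empty")
    cube = bayes.precompute_cube(ev.absorbance, stats)
    return SearchContext(
        stats, priors, params.include_prior, cube, ev.class_labels, tag, params.criterion
    )


def run_search(
    dataset: SpectralDataset,
    params: SearchParams,
    context: SearchContext | None = None,
    keep: int | None = None,
    progress: callable | None = None,
) -> list[tuple[ECSpec, EvaluationResult]]:
    """Evaluate every EC model and rank by the composite indicator.

    Ranking is a total order: composite descending, then N ascending, then
    G ascending, then I ascending — simpler models win ties. ``keep``
    limits how many ranked results are materialised (default: all).
    Deterministic: identical inputs yield identical rankings.
    """
    ctx = context if context is not None else make_context(dataset, params)
    grid = ctx.stats.grid
    p = grid.point_count
    cube = ctx.cube.values  # (n, K, p)
    n_eval, K, _ = cube.shape
    y_idx = ctx._true_idx
    log_prior = ctx._log_prior
    sizes = np.array([(y_idx == j).sum() for j in range(K)])
    class_masks = [y_idx == j for j in range(K)]

    all_I: list[np.ndarray] = []
    all_N: list[np.ndarray] = []
    all_G: list[np.ndarray] = []
    all_counts: list[np.ndarray] = []
    evaluated = 0
    budget = params.budget

    for n, g in _ng_blocks(p, params):
        if budget is not None and evaluated >= budget:
            break
        span = (n - 1) * g
        starts = np.arange(0, p - span, params.i_stride, dtype=np.intp)
        if budget is not None and evaluated + len(starts) > budget:
            starts = starts[: budget - evaluated]
        if len(starts) == 0:
            continue
        chunk = max(1, _BATCH_ELEMENTS // max(1, n_eval * K * n))
        for lo in range(0, len(starts), chunk):
            s = starts[lo : lo + chunk]
            idxmat = s[:, None] + g * np.arange(n, dtype=np.intp)[None, :]
            # (n_eval, K, c, n) -> contiguous last-axis sum, same order as the
            # direct per-model path
            cond = cube[:, :, idxmat].sum(axis=-1)
            scores = cond + log_prior[None, :, None]
            pred = np.argmax(scores, axis=1)  # (n_eval, c)
            correct = pred == y_idx[:, None]
            counts = np.vstack([correct[m].sum(axis=0) for m in class_masks])  # (K, c)
            all_I.append(s)
            all_N.append(np.full(len(s), n, dtype=np.intp))
            all_G.append(np.full(len(s), g, dtype=np.intp))
            all_counts.append(counts)
            evaluated += len(s)
        if progress is not None:
            progress(evaluated)

    if evaluated == 0:
        return []
    I = np.concatenate(all_I)
    N = np.concatenate(all_N)
    G = np.concatenate(all_G)
    counts = np.hstack(all_counts)  # (K, total)
    rar = 100.0 * counts / sizes[:, None]
    rar_total = 100.0 * counts.sum(axis=0) / sizes.sum()
    rar_sd = np.std(rar, axis=0, ddof=1) if K > 1 else np.zeros(len(I))
    composite = rar_total - rar_sd

    order = np.lexsort((I, G, N, -composite))
    if keep is not None:
        order = order[:keep]
    wl = grid.wavelengths
    out: list[tuple[ECSpec, EvaluationResult]] = []
    for j in order:
        spec = ECSpec(float(wl[I[j]]), int(N[j]), int(G[j]) if N[j] > 1 else 1)
        res = EvaluationResult(
            ctx.class_ids, sizes, counts[:, j], eval_set=ctx.eval_set
        )
        out.append((spec, res))
    return out


def top_k(
    ranked: Sequence[tuple[ECSpec, EvaluationResult]], k: int
) -> list[tuple[ECSpec, EvaluationResult]]:
    """First k results of the deterministic ranking (fewer if fewer exist)."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    return list(ranked[:k])
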