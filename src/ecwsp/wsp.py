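"""Wavelength step-by-step phase-out (WSP) and the full screening pipeline.

WSP is greedy backward elimination: starting from a wavelength set, each
step evaluates every single-wavelength removal with the calibration-fit
class statistics on the prediction set and discards the wavelength whose
removal scores best, until one wavelength remains. The final model is the
best state seen anywhere along the path, so it can never score below the
starting set. Applied to the top-ranked equidistant models, this strips
redundant wavelengths the coarse equidistant lattice could not avoid.

The pipeline mirrors the full modeling workflow: grouped split -> direct
full-grid Bayes baseline -> exhaustive EC search on the prediction set ->
top-10 models -> WSP refinement of each -> overall winner -> one
independent evaluation of the winner on the untouched validation set
(class statistics are never refit after calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import bayes
from .ec import ECSpec, SearchContext, SearchParams, make_context, run_search, top_k
from .errors import ConfigError
from .io import SpectralDataset
from .metrics import EvaluationResult


@dataclass
class WSPState:
    """One point on the elimination path: the surviving set and its score."""

    wavelengths_nm: tuple
    result: EvaluationResult


@dataclass
class WSPPath:
    """Ordered elimination record, from the full starting set down to one."""

    states: list[WSPState]
    removed_nm: list[float]

    def __len__(self) -> int:
        return len(self.states)

    def trace_rows(self) -> list[dict]:
        """Step log: removed wavelength, remaining N and scores per state."""
        rows = []
        for step, st in enumerate(self.states):
            rows.append(
                {
                    "step": step,
                    "removed_nm": self.removed_nm[step - 1] if step > 0 else "",
                    "n_wavelengths": len(st.wavelengths_nm),
                    "RAR_Total": round(st.result.rar_total, 3),
                    "RAR_SD": round(st.result.rar_sd, 3),
                    "composite": round(st.result.composite, 3),
                }
            )
        return rows


def _score(ctx: SearchContext, wavelengths_nm: Sequence[float]) -> EvaluationResult:
    idx = ctx.stats.grid.indices(wavelengths_nm)
    return ctx.evaluate_indices(idx)


def wsp_step(
    current: Sequence[float], evaluator: SearchContext
) -> tuple[float, EvaluationResult]:
    """Best single-wavelength removal from the current set.

    Evaluates all |current| candidate removals; returns the removed
    wavelength and the resulting score. Ties are removed at the smallest
    wavelength (candidates are scanned in ascending order and only a
    strictly better score displaces the incumbent).
    """
    wl = sorted(float(w) for w in current)
    if len(wl) < 2:
        raise ConfigError("phase-out step needs at least 2 wavelengths")
    best: tuple[float, EvaluationResult] | None = None
    best_val = -np.inf
    for w in wl:
        remaining = [v for v in wl if v != w]
        res = _score(evaluator, remaining)
        val = evaluator.criterion_value(res)
        if val > best_val:
            best = (w, res)
            best_val = val
    assert best is not None
    return best


def wsp_path(start: Sequence[float], evaluator: SearchContext) -> WSPPath:
    """Run the phase-out to a single wavelength, recording every state."""
    wl = sorted(float(w) for w in start)
    if not wl:
        raise ConfigError("starting wavelength set is empty")
    states = [WSPState(tuple(wl), _score(evaluator, wl))]
    removed: list[float] = []
    while len(wl) > 1:
        w, res = wsp_step(wl, evaluator)
        wl = [v for v in wl if v != w]
        removed.append(w)
        states.append(WSPState(tuple(wl), res))
    return WSPPath(states, removed)


def select_best(path: WSPPath, evaluator: SearchContext | None = None) -> WSPState:
    """The state maximising the scoring criterion along the path.

    Ties go to the smaller wavelength count and then to the later (more
    reduced) state; since the path shrinks by one wavelength per step, a
    later tied state always wins.
    """
    if not path.states:
        raise ConfigError("empty phase-out path")
    crit = (
        (lambda r: r.composite)
        if evaluator is None or evaluator.criterion == "composite"
        else (lambda r: r.rar_total)
    )
    best = path.states[0]
    for st in path.states[1:]:
        if crit(st.result) >= crit(best.result):
            best = st
    return best


@dataclass
class RefinedModel:
    """A top-ranked EC model together with its phase-out refinement."""

    rank: int  # 1-based rank of the EC parent
    parent: ECSpec
    parent_result: EvaluationResult
    path: WSPPath
    wavelengths_nm: tuple
    result: EvaluationResult


@dataclass
class PipelineReport:
    """Everything the screening workflow produces, before any file output."""

    baseline: EvaluationResult  # direct full-grid Bayes on the evaluation set
    ec_top: list  # [(ECSpec, EvaluationResult)] ranked
    refined: list  # [RefinedModel], same order as ec_top
    winner: RefinedModel
    winner_validation: EvaluationResult
    manifest: dict = field(default_factory=dict)


def ec_wsp_pipeline(
    dataset: SpectralDataset,
    params: SearchParams,
    ranked: Sequence[tuple[ECSpec, EvaluationResult]] | None = None,
    progress: callable | None = None,
) -> PipelineReport:
    """Full search: baseline -> EC ranking -> WSP on the top models -> winner.

    The prediction set drives every selection decision; the validation set
    is scored exactly once, for the winner, with the calibration-fit
    statistics. Pass a precomputed ``ranked`` list to skip the exhaustive
    search (resume path).
    """
    ctx = make_context(dataset, params)
    fingerprint = ctx.stats.fingerprint()
    grid = ctx.stats.grid

    baseline = ctx.evaluate_indices(np.arange(grid.point_count, dtype=np.intp))

    if ranked is None:
        ranked = run_search(dataset, params, context=ctx, keep=params.top_k, progress=progress)
    if not ranked:
        raise ConfigError("EC search produced no models (check bounds/budget)")
    leaders = top_k(ranked, params.top_k)

    refined: list[RefinedModel] = []
    for rank, (spec, res) in enumerate(leaders, start=1):
        path = wsp_path(spec.wavelengths(grid), ctx)
        best = select_best(path, ctx)
        refined.append(
            RefinedModel(rank, spec, res, path, best.wavelengths_nm, best.result)
        )

    # overall winner: criterion desc, then fewer wavelengths, then parent rank
    def _key(m: RefinedModel):
        return (-ctx.criterion_value(m.result), len(m.wavelengths_nm), m.rank)

    winner = min(refined, key=_key)

    # single validation evaluation, after all selection, same fitted stats
    val_ctx = make_context(dataset, params, stats=ctx.stats, eval_set="validation")
    winner_validation = _score(val_ctx, winner.wavelengths_nm)

    manifest = {
        "eval_set": params.eval_set,
        "criterion": params.criterion,
        "priors_mode": params.priors_mode,
        "include_prior": params.include_prior,
        "sd_floor": params.sd_floor,
        "n_max": params.n_max,
        "g_max": params.g_max,
        "top_k": params.top_k,
        "i_stride": params.i_stride,
        "budget": params.budget,
        "grid": f"{grid.start_nm:g}:{grid.end_nm:g}:{grid.step_nm:g}",
        "stats_fingerprint_after_fit": fingerprint,
        "stats_fingerprint_at_validation": ctx.stats.fingerprint(),
        "validation_evaluations": 1,
        "winner_parent": {
            "rank": winner.rank,
            "I": winner.parent.start_nm,
            "N": winner.parent.n_wavelengths,
            "G": winner.parent.gap_steps,
            "E": winner.parent.end_nm(grid.step_nm),
        },
        "winner_wavelengths_nm": list(winner.wavelengths_nm),
    }
    return PipelineReport(baseline, list(ranked), refined, winner, winner_validation, manifest)
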