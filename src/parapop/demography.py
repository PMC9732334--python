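"""SFS-based composite-likelihood demographic inference and model selection.

The expected joint SFS under a model is approximated by Monte-Carlo
coalescent simulation (branch-length accumulation, conditioned on
polymorphism in the pooled sample).  The composite log-likelihood is the
multinomial log-likelihood over polymorphic SFS cells.  Free parameters are
optimised ECM-style: parameters are grouped into blocks (split times |
sizes | migration rates) and each is maximised conditionally by bounded
one-dimensional search, with common random numbers within a cycle so the
noisy objective stays comparable along a line search.  Concurrent models
are compared by AIC = 2k - 2 lnCL, and the study's sequential hierarchical
selection propagates each step's winner to the next.  Uncertainty comes
from a parametric bootstrap: datasets of the observed size are resampled
from the fitted spectrum and refitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .coalescent import sfs_branch_lengths
from .errors import DegenerateModelError, ValidationError
from .models import DemographicModel, FreeParameter
from .sfs import JointSFS, sfs_from_probabilities

__all__ = [
    "FitResult",
    "ScenarioSet",
    "expected_sfs",
    "composite_loglik",
    "fit_model",
    "compare_models_aic",
    "hierarchical_selection",
    "bootstrap_ci",
    "generations_to_years",
]

#: desk-scale defaults; the full-scale study values are 100_000 simulations,
#: 100 starts and 100 cycles, accepted through the same keyword arguments.
DEFAULT_N_SIMS = 2_000
DEFAULT_N_STARTS = 10
DEFAULT_MAX_CYCLES = 20
DEFAULT_TOL = 1e-3


def _polymorphic_mask(shape: tuple[int, ...]) -> np.ndarray:
    total = np.indices(shape).sum(axis=0)
    return (total > 0) & (total < sum(d - 1 for d in shape))


def expected_sfs(model: DemographicModel, n_sims: int, seed: int) -> np.ndarray:
    """Monte-Carlo probability that a segregating site falls in each SFS cell.

    Conditioned on polymorphism in the pooled sample; simulated-zero
    polymorphic cells are floored at 0.5/n_sims and the distribution
    renormalised, so any observed cell has finite log-probability.
    """
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    bl = sfs_branch_lengths(model, n_sims, seed)
    mask = _polymorphic_mask(bl.shape)
    total = bl[mask].sum()
    if total <= 0:
        raise DegenerateModelError(
            f"model {model.model_id}: no expected polymorphism in {n_sims} simulations"
        )
    p = np.zeros_like(bl)
    p[mask] = bl[mask] / total
    floor = 0.5 / n_sims
    p[mask & (p == 0)] = floor
    p[mask] /= p[mask].sum()
    return p


def composite_loglik(obs: JointSFS, probs: np.ndarray) -> float:
    """Multinomial composite log-likelihood sum m_cell * ln p_cell (natural log)."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != obs.counts.shape:
        raise ValidationError(
            f"probability shape {probs.shape} does not match observed {obs.counts.shape}"
        )
    mask = obs.polymorphic_mask()
    m = obs.counts[mask]
    p = probs[mask]
    used = m > 0
    if np.any(p[used] <= 0):
        raise ValidationError("zero probability at an observed cell (flooring missing)")
    return float(np.sum(m[used] * np.log(p[used])))


@dataclass
class FitResult:
    """Outcome of one model fit: estimates, lnCL, AIC and diagnostics."""

    model_id: str
    params: dict[str, float]
    loglik: float
    k: int
    aic: float
    n_starts: int
    converged: bool
    seed: int
    data_hash: str
    start_logliks: list[float] = field(default_factory=list)
    model: DemographicModel | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.aic, 2 * self.k - 2 * self.loglik):
            raise ValidationError("AIC must equal 2k - 2 lnCL")


def _blocks(free: list[FreeParameter]) -> list[list[FreeParameter]]:
    """ECM blocks in fixed order: split times, sizes, migrations, rest."""
    order = {"split_time": 0, "size": 1, "migration": 2}
    groups: dict[int, list[FreeParameter]] = {}
    for fp in free:
        groups.setdefault(order.get(fp.name.split(":")[0], 3), []).append(fp)
    return [groups[k] for k in sorted(groups)]


def _check_obs(obs: JointSFS, model: DemographicModel) -> None:
    sampled = model.sampled_populations()
    if list(obs.pop_labels) != [p.label for p in sampled]:
        raise ValidationError(
            f"observed SFS populations {obs.pop_labels} do not match model "
            f"{[p.label for p in sampled]}"
        )
    if list(obs.sample_sizes) != [2 * p.samples for p in sampled]:
        raise ValidationError("observed SFS sample sizes do not match model")


def fit_model(
    obs: JointSFS,
    model: DemographicModel,
    n_starts: int = DEFAULT_N_STARTS,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    tol: float = DEFAULT_TOL,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> FitResult:
    """Maximise the composite likelihood over the model's free parameters.

    Multi-start ECM: each start initialises free parameters uniformly within
    bounds (log-uniformly when flagged), then cycles through parameter
    blocks maximising each parameter by bounded 1-D search; evaluations
    within a cycle share one simulation seed (common random numbers), and
    all starts share the cycle-seed sequence plus a final common evaluation
    seed so the best-of-starts comparison is like-for-like.  Stops when the
    relative lnCL improvement falls below ``tol``.
    """
    model.validate()
    _check_obs(obs, model)
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    free = model.free_parameters
    ss = np.random.SeedSequence(int(seed))
    seeds = ss.generate_state(max_cycles + 1) % (2**31)
    cycle_seeds, eval_seed = seeds[:-1], int(seeds[-1])
    data_hash = obs.data_hash()

    if not free:
        ll = composite_loglik(obs, expected_sfs(model, n_sims, eval_seed))
        return FitResult(
            model_id=model.model_id, params={}, loglik=ll, k=0, aic=-2 * ll,
            n_starts=n_starts, converged=True, seed=seed, data_hash=data_hash,
            start_logliks=[ll], model=model.with_params({}),
        )

    rng = np.random.default_rng(ss.spawn(1)[0])
    blocks = _blocks(free)
    start_lls: list[float] = []
    start_params: list[dict[str, float]] = []
    start_conv: list[bool] = []
    for _ in range(n_starts):
        values: dict[str, float] = {}
        for fp in free:
            lo, hi = fp.bounds
            if fp.log:
                values[fp.name] = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            else:
                values[fp.name] = rng.uniform(lo, hi)
        prev = None
        converged = False
        for cycle in range(max_cycles):
            cs = int(cycle_seeds[cycle])
            for block in blocks:
                for fp in block:
                    lo, hi = fp.bounds
                    if fp.log:
                        blo, bhi = np.log10(lo), np.log10(hi)
                        back = lambda x: 10**x
                    else:
                        blo, bhi = lo, hi
                        back = lambda x: x

                    def objective(x, _fp=fp, _back=back):
                        trial = dict(values)
                        trial[_fp.name] = _back(x)
                        m = model.with_params(trial)
                        return -composite_loglik(obs, expected_sfs(m, n_sims, cs))

                    res = minimize_scalar(
                        objective, bounds=(blo, bhi), method="bounded",
                        options={"maxiter": 16, "xatol": (bhi - blo) * 1e-3},
                    )
                    values[fp.name] = float(back(res.x))
            cur = composite_loglik(
                obs, expected_sfs(model.with_params(values), n_sims, cs)
            )
            if prev is not None and abs(cur - prev) <= tol * abs(prev):
                converged = True
                break
            prev = cur
        final = composite_loglik(
            obs, expected_sfs(model.with_params(values), n_sims, eval_seed)
        )
        start_lls.append(final)
        start_params.append(values)
        start_conv.append(converged)

    best = int(np.argmax(start_lls))
    ll = start_lls[best]
    k = len(free)
    return FitResult(
        model_id=model.model_id, params=dict(start_params[best]), loglik=ll,
        k=k, aic=2 * k - 2 * ll, n_starts=n_starts,
        converged=bool(start_conv[best]), seed=seed, data_hash=data_hash,
        start_logliks=list(start_lls), model=model.with_params(start_params[best]),
    )


def compare_models_aic(fits: list[FitResult]) -> list[FitResult]:
    """Rank fits by AIC ascending; ties broken by smaller k, then model id.

    All fits must share the observed data (same data hash).  The selected
    model is the first element of the returned ranking.
    """
    if len(fits) < 2:
        raise ValidationError("AIC comparison needs at least two fits")
    hashes = {f.data_hash for f in fits}
    if len(hashes) != 1:
        raise ValidationError("fits compare different observed data")
    return sorted(fits, key=lambda f: (f.aic, f.k, f.model_id))


@dataclass
class ScenarioSet:
    """Candidate models for one hierarchical selection step."""

    name: str
    candidates: list[DemographicModel]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValidationError(f"step {self.name}: no candidate models")
        ids = [m.model_id for m in self.candidates]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"step {self.name}: duplicate model ids")


def hierarchical_selection(
    steps: list[ScenarioSet],
    observations: list[JointSFS],
    **fit_kwargs,
) -> tuple[list[FitResult], list[dict]]:
    """Sequential model selection: fit each step's candidates, select by AIC,
    and carry the winner forward.

    Populations that appeared in a step's candidates but not in its winner
    are pruned; a later candidate that references a pruned population is a
    contradiction of the earlier decision and raises a validation error.
    Returns the per-step winners and a decision trace (one record per
    candidate with its lnCL, AIC and selection flag).
    """
    if len(steps) != len(observations):
        raise ValidationError("one observed SFS required per step")
    pruned: set[str] = set()
    winners: list[FitResult] = []
    trace: list[dict] = []
    for step, obs in zip(steps, observations):
        for cand in step.candidates:
            used = {p.label for p in cand.populations}
            bad = used & pruned
            if bad:
                raise ValidationError(
                    f"step {step.name}: candidate {cand.model_id} references "
                    f"population(s) {sorted(bad)} pruned at an earlier step"
                )
        fits = [fit_model(obs, cand, **fit_kwargs) for cand in step.candidates]
        ranked = compare_models_aic(fits) if len(fits) > 1 else list(fits)
        winner = ranked[0]
        winners.append(winner)
        winner_pops = {p.label for p in winner.model.populations}
        for cand in step.candidates:
            pruned |= {p.label for p in cand.populations} - winner_pops
        for f in fits:
            trace.append(
                {
                    "step": step.name,
                    "model_id": f.model_id,
                    "loglik": f.loglik,
                    "k": f.k,
                    "aic": f.aic,
                    "selected": f.model_id == winner.model_id,
                }
            )
    return winners, trace


def bootstrap_ci(
    fit: FitResult,
    obs: JointSFS,
    n_boot: int,
    level: float = 0.95,
    seed: int = 0,
    n_starts: int = 2,
    n_sims: int = DEFAULT_N_SIMS,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    tol: float = DEFAULT_TOL,
) -> tuple[dict[str, tuple[float, float]], dict[str, np.ndarray]]:
    """Parametric-bootstrap percentile intervals for the fitted parameters.

    Simulates ``n_boot`` datasets of the observed (polymorphic) size from
    the fitted spectrum, refits each with a reduced start count, and takes
    percentile intervals at the requested level.
    """
    if not fit.converged:
        raise ValidationError("bootstrap refused: fit did not converge")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must be in (0,1)")
    if fit.model is None:
        raise ValidationError("fit carries no model")
    rng = np.random.default_rng(seed)
    mask = obs.polymorphic_mask()
    n_sites = int(obs.counts[mask].sum())
    p = expected_sfs(fit.model, n_sims, int(rng.integers(2**31)))
    draws: dict[str, list[float]] = {name: [] for name in fit.params}
    for _ in range(n_boot):
        boot_obs = sfs_from_probabilities(p, obs.pop_labels, n_sites, rng)
        bfit = fit_model(
            boot_obs, fit.model, n_starts=n_starts, max_cycles=max_cycles,
            tol=tol, n_sims=n_sims, seed=int(rng.integers(2**31)),
        )
        for name in draws:
            draws[name].append(bfit.params[name])
    alpha = (1.0 - level) / 2.0
    intervals = {
        name: (
            float(np.percentile(vals, 100 * alpha)),
            float(np.percentile(vals, 100 * (1 - alpha))),
        )
        for name, vals in ((n, np.array(v)) for n, v in draws.items())
    }
    return intervals, {n: np.array(v) for n, v in draws.items()}


def generations_to_years(
    t_generations: float, generation_time_years: float | tuple[float, float]
):
    """Convert generations to calendar years; a generation-time range maps to
    a (min, max) range of years."""
    if t_generations < 0:
        raise ValidationError("generations must be non-negative")
    if np.isscalar(generation_time_years):
        if generation_time_years <= 0:
            raise ValidationError("generation time must be positive")
        return t_generations * float(generation_time_years)
    lo, hi = generation_time_years
    if lo <= 0 or hi <= 0:
        raise ValidationError("generation time must be positive")
    return (t_generations * float(lo), t_generations * float(hi))
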