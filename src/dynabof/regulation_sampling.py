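"""Near-optimal flux-space sampling and up/down-regulation calls.

Single FBA solutions are vertices of a degenerate optimal set, so calling
a reaction up- or down-regulated from two point solutions is fragile.
Instead the feasible polytope {S·v = 0, lb ≤ v ≤ ub, v_obj ≥ f·μ*}
(default f = 0.9, i.e. within 90% of the optimum) is sampled at each
timepoint — 5000 points by default — and a reaction is called regulated
between two timepoints when a one-tailed paired t test on the two flux
distributions rejects at α = 0.05 (right tail → up, left tail → down).

The sampler is hit-and-run in null-space coordinates: fluxes are
parameterized as v = v0 + N·z with N an orthonormal basis of the null
space of S, so every iterate satisfies the steady-state constraint to
machine precision and only the box bounds limit each chord.  A fixed seed
makes chains fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from cobra import Model
from cobra.util.array import create_stoichiometric_matrix
from scipy import stats
from scipy.linalg import null_space

from .fba_engine import solve_fba

try:  # the chain kernel is hot; JIT it when numba is available
    from numba import njit
except ImportError:  # pragma: no cover - numba is an optional speedup
    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap

logger = logging.getLogger(__name__)

__all__ = ["SampleSet", "RegulationCall", "sample_fluxes",
           "validate_samples", "regulation_test", "regulation_report",
           "coupled_reaction_groups"]

DEFAULT_FRACTION = 0.9
DEFAULT_N_SAMPLES = 5000
DEFAULT_ALPHA = 0.05
DEFAULT_WARMUP = 1000
DEFAULT_THINNING = 10

_BOUND_TOL = 1e-6
_DIRECTION_EPS = 1e-11


@dataclass
class SampleSet:
    """Flux samples from the near-optimal polytope of one timepoint."""

    samples: pd.DataFrame            # n_samples × reactions
    fraction: float
    objective_id: str
    objective_optimum: float
    seed: int
    lower_bounds: np.ndarray = field(repr=False, default=None)
    upper_bounds: np.ndarray = field(repr=False, default=None)
    stoichiometry: np.ndarray = field(repr=False, default=None)

    @property
    def reaction_ids(self) -> List[str]:
        return list(self.samples.columns)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class RegulationCall:
    reaction_id: str
    direction: str                   # up | down | ns
    p_up: float
    p_down: float
    mean_t0: float
    mean_tf: float


def sample_fluxes(
    model: Model,
    fraction: float = DEFAULT_FRACTION,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    warmup: int = DEFAULT_WARMUP,
    thinning: int = DEFAULT_THINNING,
) -> SampleSet:
    """Sample the polytope within `fraction` of the objective optimum.

    The chain starts at the FBA vertex, discards ``warmup`` steps, then
    keeps every ``thinning``-th iterate until ``n_samples`` are collected.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    base = solve_fba(model)
    if not base.ok:
        raise ValueError(f"model is {base.status}; cannot sample")

    work = model.copy()
    objective = [r for r in work.reactions if r.objective_coefficient != 0]
    if len(objective) != 1:
        raise ValueError("objective must be a single reaction")
    obj = objective[0]
    obj.lower_bound = max(obj.lower_bound, fraction * base.objective_value)

    start = solve_fba(work)
    if not start.ok:
        raise ValueError("near-optimal polytope is empty")

    rxn_ids = [r.id for r in work.reactions]
    S = create_stoichiometric_matrix(work)
    lb = np.array([r.lower_bound for r in work.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in work.reactions], dtype=float)
    v0 = start.fluxes.reindex(rxn_ids).to_numpy(dtype=float)
    v0 = np.clip(v0, lb, ub)

    N = null_space(S)
    d = N.shape[1]
    rng = np.random.default_rng(seed)

    if d == 0:  # fully determined network: the polytope is a point
        data = np.tile(v0, (n_samples, 1))
    else:
        data = _hit_and_run(v0, N, lb, ub, n_samples, warmup, thinning, rng)

    samples = pd.DataFrame(data, columns=rxn_ids)
    return SampleSet(samples=samples, fraction=fraction,
                     objective_id=obj.id,
                     objective_optimum=base.objective_value, seed=seed,
                     lower_bounds=lb, upper_bounds=ub, stoichiometry=S)


def _hit_and_run(v0: np.ndarray, N: np.ndarray, lb: np.ndarray,
                 ub: np.ndarray, n_samples: int, warmup: int,
                 thinning: int, rng: np.random.Generator) -> np.ndarray:
    """Isotropic hit-and-run in null-space coordinates.

    Directions and chord positions are drawn in blocks (the chain itself
    is necessarily sequential); each step picks a uniform point on the
    feasible chord through the current point.
    """
    d = N.shape[1]
    v = v0.copy()
    out = np.empty((n_samples, v0.size))
    collected = 0
    total = warmup + n_samples * thinning
    block = 8192
    step = 0
    while collected < n_samples:
        D = rng.standard_normal((block, d))
        D /= np.linalg.norm(D, axis=1, keepdims=True)
        A = D @ N.T                            # flux-space directions
        U = rng.random(block)
        step, collected = _chain_block(A, U, v, lb, ub, out, step,
                                       collected, n_samples, warmup,
                                       thinning, _DIRECTION_EPS)
        if collected < n_samples and step > 100 * total:
            raise RuntimeError(  # pragma: no cover - numerical safety
                "hit-and-run failed to collect samples")
    return out


@njit(cache=False)
def _chain_block(A, U, v, lb, ub, out, step, collected, n_samples,
                 warmup, thinning, eps):  # pragma: no cover - jitted
    """Advance the chain over one block of pre-drawn directions.

    For each direction the feasible chord through the current point is
    bounded by the box constraints only (mass balance holds exactly in
    null-space coordinates); the step lands uniformly on the chord.  The
    current point is always feasible, so t = 0 lies in every chord; a
    zero-length chord (degenerate polytope direction) leaves the point
    unchanged.
    """
    n = v.size
    for k in range(A.shape[0]):
        t_min = -1e300
        t_max = 1e300
        any_active = False
        for i in range(n):
            a = A[k, i]
            if a > eps:
                any_active = True
                lo = (lb[i] - v[i]) / a
                hi = (ub[i] - v[i]) / a
            elif a < -eps:
                any_active = True
                lo = (ub[i] - v[i]) / a
                hi = (lb[i] - v[i]) / a
            else:
                continue
            if lo > t_min:
                t_min = lo
            if hi < t_max:
                t_max = hi
        if not any_active:
            continue
        t = t_min + U[k] * (t_max - t_min) if t_max > t_min else 0.0
        for i in range(n):
            vi = v[i] + t * A[k, i]
            if vi < lb[i]:
                vi = lb[i]
            elif vi > ub[i]:
                vi = ub[i]
            v[i] = vi
        step += 1
        if step > warmup and (step - warmup) % thinning == 0:
            for i in range(n):
                out[collected, i] = v[i]
            collected += 1
            if collected == n_samples:
                return step, collected
    return step, collected


def validate_samples(sample_set: SampleSet, tol: float = _BOUND_TOL) -> bool:
    """Hard validity check: mass balance, bounds and the optimality floor.

    Raises AssertionError when any sample violates a constraint; returns
    True otherwise.
    """
    V = sample_set.samples.to_numpy(dtype=float)
    residual = np.abs(sample_set.stoichiometry @ V.T).max() if V.size else 0.0
    assert residual < tol, f"mass-balance residual {residual} exceeds {tol}"
    assert (V >= sample_set.lower_bounds - tol).all(), "lower bound violated"
    assert (V <= sample_set.upper_bounds + tol).all(), "upper bound violated"
    floor = sample_set.fraction * sample_set.objective_optimum
    obj = sample_set.samples[sample_set.objective_id].to_numpy()
    assert (obj >= floor - tol).all(), "objective fraction violated"
    return True


def coupled_reaction_groups(sample_set: SampleSet,
                            threshold: float = 0.9999) -> List[List[str]]:
    """Partition variable reactions into flux-coupled groups.

    Reactions whose sample vectors correlate with |ρ| above `threshold`
    carry the same statistical information (they are affine functions of
    one another on the polytope), so any per-reaction test treats a whole
    group as a single effective test.  Constant-flux reactions are
    omitted.
    """
    V = sample_set.samples.to_numpy(dtype=float)
    sd = V.std(axis=0)
    variable = np.where(sd > 1e-9)[0]
    if variable.size == 0:
        return []
    if variable.size == 1:
        return [[sample_set.reaction_ids[variable[0]]]]
    corr = np.corrcoef(V[:, variable].T)
    parent = list(range(variable.size))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(variable.size):
        for j in range(i + 1, variable.size):
            if abs(corr[i, j]) > threshold:
                parent[find(i)] = find(j)
    groups: Dict[int, List[str]] = {}
    cols = sample_set.reaction_ids
    for i in range(variable.size):
        groups.setdefault(find(i), []).append(cols[variable[i]])
    return list(groups.values())


def regulation_test(
    samples_t0: SampleSet,
    samples_tf: SampleSet,
    alpha: float = DEFAULT_ALPHA,
    paired: bool = True,
    fdr: bool = False,
) -> List[RegulationCall]:
    """Per-reaction one-tailed t tests between two timepoints' samples.

    ``paired=True`` pairs samples by index, as a paired test implies;
    since the two chains are statistically independent, an unpaired Welch
    alternative is available.  No multiple-testing correction is applied
    by default (α is per reaction); ``fdr=True`` switches both one-tailed
    p-value sets to Benjamini–Hochberg-adjusted values before calling.
    """
    if samples_t0.reaction_ids != samples_tf.reaction_ids:
        raise ValueError("sample sets cover different reaction sets")
    if paired and samples_t0.n_samples != samples_tf.n_samples:
        raise ValueError("paired test requires equal sample counts")

    a0 = samples_t0.samples.to_numpy(dtype=float)
    af = samples_tf.samples.to_numpy(dtype=float)
    n_rxn = a0.shape[1]
    p_up = np.full(n_rxn, np.nan)
    p_down = np.full(n_rxn, np.nan)
    for j in range(n_rxn):
        x0, xf = a0[:, j], af[:, j]
        if paired:
            diff = xf - x0
            if diff.std() < 1e-12 * max(1.0, np.abs(diff).max()):
                shift = diff.mean()
                scale = max(np.abs(x0).max(), np.abs(xf).max(), 1.0)
                if abs(shift) > 1e-9 * scale:
                    # a constant nonzero shift: the t statistic diverges
                    p_up[j] = 0.0 if shift > 0 else 1.0
                    p_down[j] = 1.0 if shift > 0 else 0.0
                continue  # identical distributions: ns, p undefined
            p_up[j] = stats.ttest_rel(xf, x0, alternative="greater").pvalue
            p_down[j] = stats.ttest_rel(xf, x0, alternative="less").pvalue
        else:
            if np.allclose(x0.std(), 0.0) and np.allclose(xf.std(), 0.0):
                continue
            p_up[j] = stats.ttest_ind(xf, x0, equal_var=False,
                                      alternative="greater").pvalue
            p_down[j] = stats.ttest_ind(xf, x0, equal_var=False,
                                        alternative="less").pvalue

    if fdr:
        ok = ~np.isnan(p_up)
        p_up[ok] = stats.false_discovery_control(p_up[ok])
        p_down[ok] = stats.false_discovery_control(p_down[ok])

    calls: List[RegulationCall] = []
    for j, rid in enumerate(samples_t0.reaction_ids):
        pu, pd_ = p_up[j], p_down[j]
        if np.isnan(pu):
            direction = "ns"
        elif pu < alpha and pd_ < alpha:  # pathological double rejection
            direction = "up" if pu <= pd_ else "down"
            logger.warning("%s rejects both tails (p_up=%.3g, p_down=%.3g); "
                           "smaller p wins", rid, pu, pd_)
        elif pu < alpha:
            direction = "up"
        elif pd_ < alpha:
            direction = "down"
        else:
            direction = "ns"
        calls.append(RegulationCall(
            reaction_id=rid, direction=direction, p_up=float(pu),
            p_down=float(pd_), mean_t0=float(a0[:, j].mean()),
            mean_tf=float(af[:, j].mean())))
    return calls


def regulation_report(calls: Sequence[RegulationCall],
                      model: Model | None = None) -> pd.DataFrame:
    """Regulation calls as a tidy table (with subsystems if a model is
    given)."""
    rows = [{
        "reaction_id": c.reaction_id, "direction": c.direction,
        "p_up": c.p_up, "p_down": c.p_down,
        "mean_t0": c.mean_t0, "mean_tf": c.mean_tf,
    } for c in calls]
    df = pd.DataFrame(rows)
    if model is not None:
        subsystems = {r.id: r.subsystem for r in model.reactions}
        df["subsystem"] = df["reaction_id"].map(subsystems)
    return df
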