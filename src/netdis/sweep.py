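"""Ensemble sweeps over the missing-fraction / prediction-magnitude plane.

One *realization* is an end-to-end trial: draw a scale-free network G,
hide a fraction alpha of its links, score the candidate pairs on the
observed network G_O, add the top ``round(beta * |E_O|)`` predicted links
to form G_P, rank attack targets by degree in G_P, attack the true G and
record the critical fraction f_c at which kappa drops below 2.

Sweeps average f_c over seeded realizations on a beta grid.  Common random
numbers are used throughout: within a realization the same network, the
same observation split, the same candidate ranking (selections at different
beta are nested prefixes) and the same degree tie-break key are shared
across every beta and the complete-information baseline, so comparisons
along the grid are paired and the location of the optimum beta* is
estimated with low variance.

The beta axis splits at beta* (argmin of mean f_c) into the valid
prediction area VPA = [0, beta*], where adding predicted links helps, and
the excessive prediction area EPA = (beta*, beta_max], where further links
hurt.  Grid points where mean f_c falls below the complete-information
baseline form the surpassing prediction area (SPA): there the predicted
links caricature the true network, exaggerating the degree ranking of its
most important nodes, and the attack beats the one planned on the true
network itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .attack import _AttackEngine
from .generate import GeneratorConfig, configuration_model, sample_power_law_degrees
from .observe import observed_network, sample_missing_links
from .predict import rank_candidates, score_candidates

logger = logging.getLogger(__name__)

# sub-stream tags for one realization's independent random sources
_NET, _SPLIT, _RANKTIE, _DEGTIE = 0, 1, 2, 3


@dataclass(frozen=True)
class SweepResult:
    """Ensemble mean f_c along a beta grid at one missing fraction alpha."""

    alpha: float
    beta_grid: np.ndarray
    mean_fc: np.ndarray
    se_fc: np.ndarray
    fc_no_prediction: float
    fc_complete_info: float
    se_complete_info: float
    n_reps: int
    fc_samples: np.ndarray | None = None        # (n_reps, n_beta) per-rep f_c
    fc_complete_samples: np.ndarray | None = None
    beta_star: float | None = None
    area_labels: tuple[str, ...] | None = None
    spa_flags: np.ndarray | None = None

    @property
    def spa_nonempty(self) -> bool:
        if self.spa_flags is None:
            raise ValueError("classify_areas has not been applied")
        return bool(self.spa_flags.any())


@dataclass(frozen=True)
class AlphaSweepResult:
    """Per-alpha sweeps plus the derived phase-structure curves."""

    alphas: np.ndarray
    sweeps: tuple[SweepResult, ...]
    beta_star: np.ndarray          # optimal prediction magnitude per alpha
    fc_optimal: np.ndarray         # mean f_c at beta* per alpha
    fc_no_prediction: np.ndarray   # mean f_c at beta = 0 per alpha
    fc_complete_info: float        # baseline with targets ranked on the true G
    crossing_alpha: float | None   # smallest alpha where optimum meets beta=0
    spa_boundary_alpha: float | None  # largest alpha with non-empty SPA


def _rep_rng(base_seed: int, rep: int, stage: int) -> np.random.Generator:
    """Independent, reproducible stream for one stage of one realization."""
    return np.random.default_rng([base_seed, rep, stage])


def _realization_fc(
    cfg: GeneratorConfig,
    alpha: float,
    beta_grid: Sequence[float],
    index: str,
    base_seed: int,
    rep: int,
) -> tuple[np.ndarray, float, _AttackEngine, np.ndarray, np.ndarray]:
    """f_c per beta plus the complete-information f_c for one realization.

    Returns the attack engine and per-node arrays as well so callers that
    need S(f) traces can reuse them.
    """
    rng_net = _rep_rng(base_seed, rep, _NET)
    degrees = sample_power_law_degrees(cfg, rng_net)
    g = configuration_model(degrees, rng_net)

    split = sample_missing_links(g, alpha, _rep_rng(base_seed, rep, _SPLIT))
    g_o = observed_network(g, split)
    n_obs = len(split.observed)

    scores = score_candidates(g_o, index)
    max_sel = round(max(beta_grid) * n_obs)
    ranked = rank_candidates(g_o, scores, max_sel, _rep_rng(base_seed, rep, _RANKTIE))

    engine = _AttackEngine(g)
    n = engine.n
    deg_true = engine.deg0.astype(np.int64)
    deg_p = np.array([g_o.degree(v) for v in engine.nodes], dtype=np.int64)

    # one tie-break key per realization, shared by every ranking so that
    # beta comparisons (and the complete-information baseline) are paired
    key = _rep_rng(base_seed, rep, _DEGTIE).random(n)

    fc = np.empty(len(beta_grid))
    added = 0
    for b, beta in enumerate(beta_grid):
        n_sel = round(beta * n_obs)
        if n_sel > len(ranked):
            raise ValueError("beta grid exceeds the prediction space")
        for u, v in ranked[added:n_sel]:
            deg_p[engine.index[u]] += 1
            deg_p[engine.index[v]] += 1
        added = n_sel
        order_idx = np.lexsort((key, -deg_p))
        fc[b] = engine.collapse_step(order_idx) / n

    order_idx = np.lexsort((key, -deg_true))
    fc_complete = engine.collapse_step(order_idx) / n
    return fc, fc_complete, engine, deg_p, key


def run_trial(
    cfg: GeneratorConfig,
    alpha: float,
    beta: float,
    index: str = "ra",
    seed: int = 0,
) -> float:
    """One end-to-end realization; f_c is deterministic given the seed."""
    fc, _, _, _, _ = _realization_fc(cfg, alpha, [beta], index, seed, rep=0)
    return float(fc[0])


def sweep_beta(
    cfg: GeneratorConfig,
    alpha: float,
    beta_grid: Sequence[float],
    n_reps: int = 100,
    base_seed: int = 0,
    index: str = "ra",
) -> SweepResult:
    """Mean and standard error of f_c per beta over seeded realizations."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    beta_grid = np.asarray(sorted(beta_grid), dtype=float)
    if beta_grid[0] < 0:
        raise ValueError("beta must be non-negative")
    fc = np.empty((n_reps, len(beta_grid)))
    fc_complete = np.empty(n_reps)
    for rep in range(n_reps):
        fc[rep], fc_complete[rep], _, _, _ = _realization_fc(
            cfg, alpha, beta_grid, index, base_seed, rep
        )
        logger.debug("alpha=%.3g rep=%d done", alpha, rep)
    mean_fc = fc.mean(axis=0)
    se_fc = fc.std(axis=0, ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.zeros_like(mean_fc)
    if beta_grid[0] == 0.0:
        fc_no_pred = float(mean_fc[0])
    else:
        fc_no_pred = float(
            np.mean([
                _realization_fc(cfg, alpha, [0.0], index, base_seed, rep)[0][0]
                for rep in range(n_reps)
            ])
        )
    se_complete = (
        fc_complete.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else 0.0
    )
    result = SweepResult(
        alpha=alpha,
        beta_grid=beta_grid,
        mean_fc=mean_fc,
        se_fc=se_fc,
        fc_no_prediction=fc_no_pred,
        fc_complete_info=float(fc_complete.mean()),
        se_complete_info=float(se_complete),
        n_reps=n_reps,
        fc_samples=fc,
        fc_complete_samples=fc_complete,
    )
    return classify_areas(result)


def classify_areas(sweep: SweepResult) -> SweepResult:
    """Locate beta* and label the grid into VPA/EPA with SPA flags.

    beta* is the argmin of mean f_c; grid ties are broken toward the
    smaller beta (fewer predicted links at equal performance).  VPA covers
    [0, beta*], EPA the rest; a grid point is flagged SPA when its mean f_c
    is strictly below the complete-information baseline.
    """
    i_star = int(np.argmin(sweep.mean_fc))  # first minimum = smallest beta
    beta_star = float(sweep.beta_grid[i_star])
    labels = tuple(
        "VPA" if beta <= beta_star else "EPA" for beta in sweep.beta_grid
    )
    spa = sweep.mean_fc < sweep.fc_complete_info
    return replace(sweep, beta_star=beta_star, area_labels=labels, spa_flags=spa)


def sweep_alpha(
    cfg: GeneratorConfig,
    alpha_grid: Sequence[float],
    beta_grid: Sequence[float],
    n_reps: int = 100,
    base_seed: int = 0,
    index: str = "ra",
) -> AlphaSweepResult:
    """Sweep beta at every alpha and derive the phase-structure curves.

    The same seeds (hence the same networks and tie-break keys) are reused
    at every alpha, so the complete-information baseline is common to the
    whole sweep and the alpha comparisons are paired.

    The crossing alpha is the smallest grid alpha at which the optimal
    mean f_c agrees with the no-prediction mean f_c within Monte-Carlo
    error (two combined standard errors) — beyond it link prediction no
    longer helps.  The SPA boundary is the largest grid alpha whose sweep
    still contains a point below the complete-information baseline.
    """
    alphas = np.asarray(sorted(alpha_grid), dtype=float)
    sweeps = tuple(
        sweep_beta(cfg, a, beta_grid, n_reps=n_reps, base_seed=base_seed, index=index)
        for a in alphas
    )
    beta_star = np.array([s.beta_star for s in sweeps])
    i_star = [int(np.argmin(s.mean_fc)) for s in sweeps]
    fc_opt = np.array([s.mean_fc[i] for s, i in zip(sweeps, i_star)])
    fc0 = np.array([s.fc_no_prediction for s in sweeps])
    fc_complete = float(np.mean([s.fc_complete_info for s in sweeps]))

    # the optimal curve meets the beta=0 curve exactly where the optimum sits
    # at beta* = 0; this condition is invariant to the number of realizations,
    # unlike a standard-error test, whose verdict shrinks with more reps
    crossing_alpha: float | None = None
    for a, s in zip(alphas, sweeps):
        if s.beta_grid[0] != 0.0:
            raise ValueError("crossing detection needs a beta grid starting at 0")
        if s.beta_star == 0.0:
            crossing_alpha = float(a)
            break

    spa_alphas = [float(a) for a, s in zip(alphas, sweeps) if s.spa_nonempty]
    spa_boundary = max(spa_alphas) if spa_alphas else None

    return AlphaSweepResult(
        alphas=alphas,
        sweeps=sweeps,
        beta_star=beta_star,
        fc_optimal=fc_opt,
        fc_no_prediction=fc0,
        fc_complete_info=fc_complete,
        crossing_alpha=crossing_alpha,
        spa_boundary_alpha=spa_boundary,
    )


def s_curves(
    cfg: GeneratorConfig,
    alpha: float,
    beta_star: float,
    n_reps: int = 30,
    base_seed: int = 0,
    index: str = "ra",
    f_max: float = 1.0,
) -> pd.DataFrame:
    """Mean giant-component fraction S(f) for three information regimes.

    Columns: ``f``, ``S_no_prediction`` (ranking on G_O, beta = 0),
    ``S_beta_star`` (ranking on G_P at the supplied beta*) and
    ``S_complete_info`` (ranking on the true network).
    """
    n_steps = round(f_max * cfg.n)
    acc = {k: np.zeros(n_steps) for k in ("S_no_prediction", "S_beta_star", "S_complete_info")}
    for rep in range(n_reps):
        # deg arrays returned by _realization_fc reflect the last beta in the
        # list, so one pass at [0] gives G_O degrees and one at [0, beta*]
        # gives G_P degrees; both passes replay identical streams.
        _, _, engine, deg_o, key = _realization_fc(cfg, alpha, [0.0], index, base_seed, rep)
        _, _, _, deg_p, _ = _realization_fc(cfg, alpha, [0.0, beta_star], index, base_seed, rep)
        for name, deg in (
            ("S_no_prediction", deg_o),
            ("S_beta_star", deg_p),
            ("S_complete_info", engine.deg0),
        ):
            order_idx = np.lexsort((key, -np.asarray(deg)))
            _, s_trace, _ = engine.trace(order_idx, n_steps)
            acc[name] += s_trace
    f = np.arange(1, n_steps + 1) / cfg.n
    data = {"f": f}
    data.update({k: v / n_reps for k, v in acc.items()})
    return pd.DataFrame(data)
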