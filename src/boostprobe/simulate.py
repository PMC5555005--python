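"""Synthetic benchmark: correlated Gaussian design, sparse logistic model.

The generator emulates a high-dimensional binary-classification study:
rows of the design matrix are drawn i.i.d. from ``N(0, Sigma)`` with
Toeplitz (AR(1)-type) correlation ``Sigma_ij = rho^|i-j|`` and
``rho = 0.9`` by default, a sparse coefficient vector has ``p_inf``
nonzero entries drawn from ``U(-1, 1)`` at uniformly random positions,
and the binary response follows ``y_i ~ Bernoulli(expit(x_i' beta))``.
Fresh coefficient values *and* positions are drawn for every replicate
so the correlation pattern among informative variables varies.

Selection quality is scored by the true positive rate (fraction of the
true support recovered) and the false discovery rate (fraction of the
selected set outside the support); :func:`run_benchmark` drives a
scenario grid across selection methods and emits one long-format record
per (scenario, replicate, method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz
from scipy.special import expit

from .cv import cv_select
from .data import Dataset
from .probing import probing_select
from .stability import StabilityConfig, stability_select

__all__ = [
    "SimScenario",
    "SimReplicate",
    "toeplitz_sigma",
    "simulate_dataset",
    "tpr_fdr",
    "run_benchmark",
    "make_method",
    "BENCHMARK_GRID",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimScenario:
    """One cell of the simulation grid.

    ``n`` samples, ``p`` candidate variables of which ``p_inf`` carry a
    true effect, Toeplitz correlation parameter ``rho``.
    """

    n: int
    p: int
    p_inf: int
    rho: float = 0.9

    def __post_init__(self) -> None:
        if self.p_inf > self.p or self.p_inf < 0:
            raise ValueError("need 0 <= p_inf <= p")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.n < 2 or self.p < 1:
            raise ValueError("need n >= 2 and p >= 1")

    @property
    def label(self) -> str:
        return f"n{self.n}_p{self.p}_pinf{self.p_inf}"


#: The full 12-scenario benchmark grid: all combinations of n in {100, 500},
#: p in {100, 500, 1000} and p_inf in {5, 20} at rho = 0.9.
BENCHMARK_GRID: list = [
    SimScenario(n=n, p=p, p_inf=p_inf)
    for n in (100, 500)
    for p in (100, 500, 1000)
    for p_inf in (5, 20)
]


@dataclass
class SimReplicate:
    """One generated data set with its ground truth."""

    dataset: Dataset
    beta: np.ndarray
    support: np.ndarray  # sorted indices of truly informative variables
    eta: np.ndarray      # linear predictor per row


def toeplitz_sigma(p: int, rho: float) -> np.ndarray:
    """Covariance matrix ``Sigma_ij = rho^|i-j|`` (symmetric PD)."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    return toeplitz(rho ** np.arange(p))


def _sample_toeplitz_normal(
    n: int, p: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` rows from N(0, Sigma) with Sigma_ij = rho^|i-j|.

    Uses the AR(1) recursion ``x_j = rho*x_{j-1} + sqrt(1-rho^2)*z_j``,
    which reproduces this covariance exactly in O(np) instead of a
    p x p Cholesky factorisation.
    """
    Z = rng.standard_normal((n, p))
    if rho == 0.0 or p == 1:
        return Z
    X = np.empty((n, p))
    X[:, 0] = Z[:, 0]
    s = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        X[:, j] = rho * X[:, j - 1] + s * Z[:, j]
    return X


def simulate_dataset(
    scenario: SimScenario,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    beta_floor: float = 0.0,
    max_redraws: int = 100,
) -> SimReplicate:
    """Generate one replicate of a scenario.

    ``beta_floor`` optionally enforces a minimum absolute effect size by
    resampling small coefficients — useful for easy test fixtures, off
    (0.0) by default.  A response with a single class is redrawn with a
    fresh Bernoulli draw (logged).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n, p, p_inf, rho = scenario.n, scenario.p, scenario.p_inf, scenario.rho
    X = _sample_toeplitz_normal(n, p, rho, rng)

    beta = np.zeros(p)
    support = np.sort(rng.choice(p, size=p_inf, replace=False))
    if p_inf > 0:
        vals = rng.uniform(-1.0, 1.0, size=p_inf)
        if beta_floor > 0.0:
            for _ in range(max_redraws):
                small = np.abs(vals) < beta_floor
                if not small.any():
                    break
                vals[small] = rng.uniform(-1.0, 1.0, size=int(small.sum()))
        beta[support] = vals

    eta = X @ beta
    pi = expit(eta)
    y = (rng.random(n) < pi).astype(float)
    for attempt in range(max_redraws):
        if 0.0 < y.mean() < 1.0:
            break
        logger.info("simulate_dataset: single-class response, redrawing y")
        y = (rng.random(n) < pi).astype(float)
    else:
        raise RuntimeError("could not generate a two-class response")

    data = Dataset(X=X, y=y, names=[f"x{j + 1}" for j in range(p)])
    return SimReplicate(dataset=data, beta=beta, support=support, eta=eta)


def tpr_fdr(selected, support) -> tuple[float, float]:
    """True positive rate and false discovery rate of a selected set.

    TPR is the fraction of the true support recovered; FDR the fraction
    of the selected set lying outside the support, defined as 0 for an
    empty selection.
    """
    selected = set(selected)
    support = set(support)
    if not support:
        raise ValueError("support must be nonempty")
    tpr = len(selected & support) / len(support)
    fdr = len(selected - support) / len(selected) if selected else 0.0
    return tpr, fdr


MethodFn = Callable[[Dataset, np.random.Generator], object]


def make_method(
    name: str,
    family: str = "binomial",
    nu: float = 0.1,
    m_max: int = 1000,
    b_boot: int = 25,
    stability_config: Optional[StabilityConfig] = None,
) -> MethodFn:
    """Build a ``(dataset, rng) -> SelectionResult/StableSet`` callable.

    ``name`` is one of ``probing``, ``cv``, ``stability``; the remaining
    arguments parameterise the chosen strategy.
    """
    if name == "probing":
        def run(data, rng):
            return probing_select(data, family=family, nu=nu, rng=rng)
    elif name == "cv":
        def run(data, rng):
            return cv_select(
                data, family=family, nu=nu, m_max=m_max, b_boot=b_boot, rng=rng
            )
    elif name == "stability":
        if stability_config is None:
            raise ValueError("stability method needs a StabilityConfig")

        def run(data, rng):
            return stability_select(
                data, stability_config, family=family, nu=nu, rng=rng
            )
    else:
        raise ValueError(f"unknown method {name!r}")
    return run


def _selected_indices(result, names: Sequence[str]) -> list[int]:
    """Selected variable indices from either result flavour."""
    chosen = result.stable if hasattr(result, "stable") else result.selected
    index = {name: j for j, name in enumerate(names)}
    return [index[name] for name in chosen]


def _result_m_stop(result) -> Optional[int]:
    return getattr(result, "m_stop", None)


def run_benchmark(
    scenarios: Sequence[SimScenario],
    methods: Dict[str, MethodFn],
    reps: int = 100,
    seed: int = 0,
    beta_floor: float = 0.0,
) -> pd.DataFrame:
    """Run every method on ``reps`` fresh replicates of every scenario.

    Per-replicate RNG streams are spawned deterministically from the
    root seed, so any single record can be reproduced independently.
    Method failures on a replicate are recorded (``error`` column) but
    do not abort the run.

    Returns a long-format table with one row per
    (scenario, replicate, method): TPR, FDR, number selected, m_stop.
    """
    if not scenarios:
        raise ValueError("scenario grid must be nonempty")
    root = np.random.SeedSequence(seed)
    records = []
    for s_id, scen in enumerate(scenarios):
        for rep in range(reps):
            data_ss, method_ss = np.random.SeedSequence(
                seed, spawn_key=(s_id, rep)
            ).spawn(2)
            replicate = simulate_dataset(
                scen, rng=np.random.default_rng(data_ss), beta_floor=beta_floor
            )
            for m_id, (mname, fn) in enumerate(methods.items()):
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(s_id, rep, m_id))
                )
                rec = {
                    "scenario": scen.label,
                    "n": scen.n,
                    "p": scen.p,
                    "p_inf": scen.p_inf,
                    "rho": scen.rho,
                    "rep": rep,
                    "method": mname,
                }
                try:
                    result = fn(replicate.dataset, rng)
                    sel = _selected_indices(result, replicate.dataset.names)
                    tpr, fdr = tpr_fdr(sel, replicate.support)
                    rec.update(
                        tpr=tpr,
                        fdr=fdr,
                        n_selected=len(sel),
                        m_stop=_result_m_stop(result),
                        error="",
                    )
                except Exception as exc:  # failures recorded, not fatal
                    logger.exception(
                        "benchmark: %s failed on %s rep %d", mname, scen.label, rep
                    )
                    rec.update(
                        tpr=np.nan, fdr=np.nan, n_selected=np.nan,
                        m_stop=np.nan, error=str(exc),
                    )
                records.append(rec)
    return pd.DataFrame.from_records(records)
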