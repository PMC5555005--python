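"""Early stopping by bootstrap out-of-bag risk.

The baseline way of choosing the number of boosting iterations: fit the
path on bootstrap resamples (n draws with replacement, 25 resamples by
default), evaluate the loss on the out-of-bag rows at every iteration,
and pick the iteration minimising the average out-of-bag risk.  The
model refitted on the full data and truncated at that iteration yields
the selected variables.  Because the target is prediction error rather
than support recovery, this rule tends to stop late and admit many
uninformative variables — it is the comparison point the shadow-variable
and stability approaches improve on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .boosting import ComponentwiseBoosting
from .data import Dataset
from .families import Family, get_family
from .selection import SelectionResult

__all__ = ["RiskGrid", "bootstrap_stop", "cv_select"]

logger = logging.getLogger(__name__)


@dataclass
class RiskGrid:
    """Out-of-bag risk curve over the iteration grid ``1..m_max``."""

    m_grid: np.ndarray
    risk: np.ndarray
    m_opt: int

    def __post_init__(self) -> None:
        if len(self.m_grid) != len(self.risk):
            raise ValueError("m_grid and risk must have equal length")
        if not (1 <= self.m_opt <= len(self.risk)):
            raise ValueError("m_opt outside the grid")


def bootstrap_stop(
    data: Dataset,
    family: "str | Family" = "gaussian",
    nu: float = 0.1,
    m_max: int = 1000,
    b_boot: int = 25,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    max_redraws: int = 100,
) -> RiskGrid:
    """Out-of-bag risk curve from ``b_boot`` bootstrap resamples.

    For each resample, the boosting path is fitted to ``m_max`` on the
    in-bag rows and the mean loss on the out-of-bag rows is recorded at
    every iteration (evaluation is incremental along the stored path —
    no refit per grid point).  ``risk[m-1]`` is the average over
    resamples; ``m_opt`` is the smallest iteration attaining the
    minimum (ties resolved towards the sparser model).

    Resamples with an empty out-of-bag set or, for the binomial family,
    a single in-bag response class are redrawn (logged).
    """
    if b_boot < 2:
        raise ValueError("b_boot must be >= 2")
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    family = get_family(family)
    n = data.n

    risk_sum = np.zeros(m_max)
    for b in range(b_boot):
        for attempt in range(max_redraws):
            rows = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), rows)
            yin = data.y[rows]
            if len(oob) == 0:
                logger.info("bootstrap_stop: resample %d has no OOB rows", b)
                continue
            if family.name == "binomial" and not (0 < yin.sum() < n):
                logger.info(
                    "bootstrap_stop: resample %d single-class in-bag, redraw", b
                )
                continue
            break
        else:
            raise RuntimeError(
                f"could not draw a valid bootstrap resample in {max_redraws} tries"
            )
        model = ComponentwiseBoosting(
            yin, data.X[rows], family=family, names=data.names
        )
        fit = model.fit(nu=nu, m_stop=m_max)
        risk_sum += fit.staged_risk(data.X[oob], data.y[oob])

    risk = risk_sum / b_boot
    m_opt = int(np.argmin(risk)) + 1  # first minimiser -> smallest m
    return RiskGrid(m_grid=np.arange(1, m_max + 1), risk=risk, m_opt=m_opt)


def cv_select(
    data: Dataset,
    family: "str | Family" = "gaussian",
    nu: float = 0.1,
    m_max: int = 1000,
    b_boot: int = 25,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> SelectionResult:
    """Variables on the full-data path truncated at the OOB-optimal stop.

    Runs :func:`bootstrap_stop`, refits the path on the full data up to
    ``m_opt`` and returns the distinct selected variables in
    first-selection order.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    grid = bootstrap_stop(
        data, family=family, nu=nu, m_max=m_max, b_boot=b_boot, rng=rng
    )
    model = ComponentwiseBoosting(data.y, data.X, family=family, names=data.names)
    fit = model.fit(nu=nu, m_stop=grid.m_opt)
    selected = fit.selected_names()
    coef = {data.names[j]: float(fit.coef[j]) for j in fit.selected()}
    logger.info(
        "cv: n=%d p=%d family=%s nu=%g b_boot=%d -> m_opt=%d, %d selected",
        data.n, data.p, fit.model.family.name, nu, b_boot, grid.m_opt,
        len(selected),
    )
    return SelectionResult(
        selected=selected,
        method="cv",
        m_stop=grid.m_opt,
        coef=coef,
        diagnostics={
            "b_boot": b_boot,
            "m_max": m_max,
            "oob_risk_min": float(grid.risk[grid.m_opt - 1]),
        },
        seed=seed,
    )
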