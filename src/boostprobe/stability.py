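"""Stability selection for component-wise boosting with PFER control.

Boosting is refitted on ``B`` random half-subsamples, each fit stopped
as soon as ``q`` distinct variables have entered the path (or a safety
iteration cap is hit).  A variable is declared *stable* when its
selection frequency across the subsamples reaches a threshold
``pi_thr``.  Under this scheme the expected number of falsely selected
variables — the per-family error rate, PFER — is bounded by

.. math:: E(V) \\le \\frac{q^2}{(2\\pi_{thr} - 1)\\, p}.

Exactly two of ``(q, pi_thr, pfer)`` are supplied by the user; the
third is derived by assuming equality in the bound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .boosting import ComponentwiseBoosting
from .data import Dataset
from .families import Family, get_family

__all__ = [
    "StabilityConfig",
    "StableSet",
    "pfer_bound",
    "q_from_equality",
    "stability_select",
]

logger = logging.getLogger(__name__)


def pfer_bound(q: int, pi_thr: float, p: int) -> float:
    """Upper bound on the expected number of false selections.

    ``E(V) <= q**2 / ((2*pi_thr - 1) * p)`` for per-subsample selection
    cap ``q``, stability threshold ``pi_thr`` and ``p`` candidate
    variables.  Undefined for ``pi_thr <= 0.5``.
    """
    if pi_thr <= 0.5 or pi_thr > 1.0:
        raise ValueError("pi_thr must lie in (0.5, 1]")
    if q < 1 or p < 1:
        raise ValueError("q and p must be >= 1")
    return q * q / ((2.0 * pi_thr - 1.0) * p)


def q_from_equality(pfer: float, pi_thr: float, p: int) -> int:
    """Per-subsample cap ``q`` from equality in the PFER bound.

    Solves ``pfer = q**2 / ((2*pi_thr - 1) * p)`` for ``q`` and rounds
    *down* (so the realised bound never exceeds the requested PFER),
    clamping at 1.
    """
    if pfer <= 0.0:
        raise ValueError("pfer must be positive")
    if pi_thr <= 0.5 or pi_thr > 1.0:
        raise ValueError("pi_thr must lie in (0.5, 1]")
    # tiny epsilon guards against floor(19.9999999) from float round-off
    q = int(math.floor(math.sqrt(pfer * (2.0 * pi_thr - 1.0) * p) + 1e-9))
    while q > 1 and pfer_bound(q, pi_thr, p) > pfer * (1.0 + 1e-12):
        q -= 1
    if q < 1:
        q = 1
    if pfer_bound(q, pi_thr, p) > pfer * (1.0 + 1e-12):
        logger.warning(
            "q_from_equality: even q=1 exceeds the requested PFER=%g "
            "(configuration more conservative than representable)", pfer,
        )
    return q


@dataclass
class StabilityConfig:
    """Hyperparameters of a stability-selection run.

    Exactly two of ``q``, ``pi_thr`` and ``pfer`` must be supplied; the
    third is derived from equality in the PFER bound when
    :meth:`resolve` is called with the number of candidate variables.

    Parameters
    ----------
    B : int
        Number of half-subsamples (100 is the conventional default).
    q : int, optional
        Maximum number of distinct variables each subsample fit may
        select before it is stopped.
    pi_thr : float in (0.5, 1], optional
        Selection-frequency threshold for the stable set.
    pfer : float, optional
        Target per-family error rate (expected false selections).
    m_cap : int
        Safety cap on iterations per subsample fit; a fit hitting the
        cap with fewer than ``q`` selections contributes its partial
        set (logged).
    """

    B: int = 100
    q: Optional[int] = None
    pi_thr: Optional[float] = None
    pfer: Optional[float] = None
    m_cap: int = 1000
    _resolved: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        given = sum(v is not None for v in (self.q, self.pi_thr, self.pfer))
        if given != 2 and not self._resolved:
            raise ValueError(
                "exactly two of (q, pi_thr, pfer) must be supplied; "
                f"got {given}"
            )
        if self.pi_thr is not None and not (0.5 < self.pi_thr <= 1.0):
            raise ValueError("pi_thr must lie in (0.5, 1]")
        if self.q is not None and self.q < 1:
            raise ValueError("q must be >= 1")
        if self.pfer is not None and self.pfer <= 0:
            raise ValueError("pfer must be positive")

    def resolve(self, p: int) -> "StabilityConfig":
        """Fill in the missing hyperparameter for ``p`` variables."""
        q, pi_thr, pfer = self.q, self.pi_thr, self.pfer
        if q is None:
            q = q_from_equality(pfer, pi_thr, p)
        elif pi_thr is None:
            pi_thr = 0.5 * (q * q / (pfer * p) + 1.0)
            if not (0.5 < pi_thr <= 1.0):
                raise ValueError(
                    f"derived pi_thr={pi_thr:.4g} outside (0.5, 1]; "
                    "q too large or PFER too small for this p"
                )
        elif pfer is None:
            pfer = pfer_bound(q, pi_thr, p)
        return StabilityConfig(
            B=self.B, q=q, pi_thr=pi_thr, pfer=pfer, m_cap=self.m_cap,
            _resolved=True,
        )


@dataclass
class StableSet:
    """Result of a stability-selection run.

    ``freq`` holds per-variable selection frequencies (exact rationals
    with denominator ``B``), ``stable`` the names whose frequency
    reaches the threshold, ``per_subsample_sets`` the ``B`` selected
    sets, and ``bound`` the realised PFER bound.
    """

    freq: pd.Series
    stable: list
    per_subsample_sets: list
    bound: float
    config: StabilityConfig
    seed: Optional[int] = None
    diagnostics: dict = field(default_factory=dict)

    def stable_at(self, pi_thr: float) -> list:
        """Stable set for an alternative threshold on the same runs."""
        return [name for name, f in self.freq.items() if f >= pi_thr]

    def to_dict(self) -> dict:
        return {
            "method": "stability",
            "seed": self.seed,
            "selected": list(self.stable),
            "order": list(self.stable),
            "coef": {},
            "m_stop": int(self.config.m_cap),
            "diagnostics": {
                "freq": {k: float(v) for k, v in self.freq.items()},
                "B": int(self.config.B),
                "q": int(self.config.q),
                "pi_thr": float(self.config.pi_thr),
                "pfer_target": float(self.config.pfer),
                "pfer_bound": float(self.bound),
                **self.diagnostics,
            },
        }


def _q_limited_stop(q: int):
    """Stop callback halting the fit once q distinct variables entered.

    The callback sees each candidate update *before* it is applied and
    tracks the applied selections itself, so the cap is enforced before
    — never after — a (q+1)-th variable could enter.
    """
    seen: set[int] = set()

    def stop(j: int, m: int) -> bool:
        if len(seen) >= q:
            return True
        # update will be applied; record it
        seen.add(j)
        return False

    return stop, seen


def stability_select(
    data: Dataset,
    config: StabilityConfig,
    family: "str | Family" = "gaussian",
    nu: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    max_redraws: int = 100,
) -> StableSet:
    """Run stability selection on ``B`` half-subsamples.

    Each subsample of size ``floor(n/2)`` is drawn without replacement;
    the boosting fit on it stops once ``q`` distinct variables are in
    the path or ``m_cap`` iterations are reached.  For the binomial
    family, subsamples containing a single response class are redrawn
    (logged) up to ``max_redraws`` times.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    family = get_family(family)
    cfg = config.resolve(data.p)
    n = data.n
    if n < 4:
        raise ValueError("need at least 4 samples for half-subsampling")
    half = n // 2

    counts = np.zeros(data.p, dtype=int)
    per_sets: list[list[str]] = []
    n_capped = 0
    for b in range(cfg.B):
        for attempt in range(max_redraws):
            rows = rng.choice(n, size=half, replace=False)
            ysub = data.y[rows]
            if family.name != "binomial" or (0 < ysub.sum() < half):
                break
            logger.info(
                "stability: subsample %d attempt %d single-class, redrawing",
                b, attempt,
            )
        else:
            raise RuntimeError(
                "could not draw a two-class subsample after "
                f"{max_redraws} attempts"
            )
        model = ComponentwiseBoosting(
            ysub, data.X[rows], family=family, names=data.names
        )
        stop, seen = _q_limited_stop(cfg.q)
        res = model.fit(nu=nu, m_stop=cfg.m_cap, stop=stop)
        sel = res.selected()
        if len(sel) > cfg.q:  # pragma: no cover - guarded by the callback
            raise AssertionError("per-subsample cap violated")
        if len(sel) < cfg.q and res.m_stop >= cfg.m_cap:
            n_capped += 1
            logger.warning(
                "stability: subsample %d hit m_cap=%d with only %d < q=%d "
                "selections; contributing the partial set",
                b, cfg.m_cap, len(sel), cfg.q,
            )
        counts[sel] += 1
        per_sets.append([data.names[j] for j in sel])

    freq = pd.Series(counts / cfg.B, index=data.names, name="freq")
    stable = [name for name, f in freq.items() if f >= cfg.pi_thr]
    bound = pfer_bound(cfg.q, cfg.pi_thr, data.p)
    logger.info(
        "stability: n=%d p=%d B=%d q=%d pi_thr=%g -> %d stable, bound=%.3g",
        n, data.p, cfg.B, cfg.q, cfg.pi_thr, len(stable), bound,
    )
    return StableSet(
        freq=freq,
        stable=stable,
        per_subsample_sets=per_sets,
        bound=bound,
        config=cfg,
        seed=seed,
        diagnostics={"n_capped_fits": n_capped},
    )
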