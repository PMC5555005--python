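"""Shadow-variable probing: variable selection in a single boosting fit.

The design matrix is augmented with one *shadow variable* per covariate
— an independent random permutation of that column, which preserves the
marginal distribution but is unrelated to the response by construction.
Boosting is then run on the inflated ``n x 2p`` design and stopped the
first time a shadow would be selected: in a greedy algorithm, once the
best available loss reduction comes from a variable known to carry no
signal, anything selected afterwards is suspect.  The variables that
entered the path *before* that point are returned as informative.

No resampling and no tuning parameters (beyond the learning rate) are
required, which makes the procedure one model fit cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .boosting import BoostingResults, ComponentwiseBoosting
from .data import Dataset
from .families import Family
from .selection import SelectionResult

__all__ = [
    "AugmentedDesign",
    "augment_with_shadows",
    "probing_select",
    "prefix_property_check",
]

logger = logging.getLogger(__name__)

SHADOW_PREFIX = "shadow_"


@dataclass
class AugmentedDesign:
    """A design matrix doubled with per-column shadow permutations.

    ``Xaug`` holds the ``p`` original columns followed by their ``p``
    shadows; ``shadow_of`` maps each shadow column index (``p..2p-1``)
    back to its source, and ``permutations`` records the row permutation
    applied to each shadow column so the augmentation is reproducible.
    """

    Xaug: np.ndarray
    names: list
    shadow_of: dict
    permutations: np.ndarray

    @property
    def p_original(self) -> int:
        return self.Xaug.shape[1] // 2

    def is_shadow(self, j: int) -> bool:
        return j >= self.p_original


def augment_with_shadows(
    data: Dataset, rng: np.random.Generator
) -> AugmentedDesign:
    """Append one randomly permuted copy of every column.

    Each shadow column is an independent uniform random permutation of
    its source column, so the multiset of values (hence the marginal
    distribution) is preserved exactly while any association with the
    response is destroyed.
    """
    n, p = data.X.shape
    perms = np.empty((p, n), dtype=int)
    for j in range(p):
        perms[j] = rng.permutation(n)
    shadows = data.X[perms.T, np.arange(p)]
    Xaug = np.hstack([data.X, shadows])
    names = list(data.names) + [SHADOW_PREFIX + s for s in data.names]
    shadow_of = {p + j: j for j in range(p)}
    return AugmentedDesign(
        Xaug=Xaug, names=names, shadow_of=shadow_of, permutations=perms
    )


def probing_select(
    data: Dataset,
    family: "str | Family" = "gaussian",
    nu: float = 0.1,
    m_max: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> SelectionResult:
    """Select variables by boosting until the first shadow is preferred.

    Parameters
    ----------
    data : Dataset
    family, nu : loss family and learning rate of the boosting fit.
    m_max : int, optional
        Safety cap on iterations; defaults to ``10 * p``.  Reaching the
        cap without a shadow hit is logged as a warning and the full
        model at ``m_max`` is returned.
    rng : numpy Generator, optional
        Source of the shadow permutations.  ``seed`` is a convenience
        alternative; one of the two should be given for reproducibility.

    Returns
    -------
    SelectionResult
        The original variables selected strictly before the first
        shadow hit, in first-selection order, with the coefficients of
        the model state at that point.  ``diagnostics`` records the
        shadow-hit iteration and column (or None if the cap was
        reached).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p = data.p
    if m_max is None:
        m_max = 10 * p
    aug = augment_with_shadows(data, rng)
    model = ComponentwiseBoosting(
        data.y, aug.Xaug, family=family, names=aug.names
    )

    hit = {"iteration": None, "column": None}

    def stop_on_shadow(j: int, m: int) -> bool:
        if aug.is_shadow(j):
            hit["iteration"] = m
            hit["column"] = j
            return True
        return False

    res = model.fit(nu=nu, m_stop=m_max, stop=stop_on_shadow)
    if hit["iteration"] is None:
        logger.warning(
            "probing: no shadow variable selected within m_max=%d iterations; "
            "returning the capped model", m_max,
        )

    selected_idx = res.selected()  # original-only by construction
    assert all(not aug.is_shadow(j) for j in selected_idx)
    selected = [data.names[j] for j in selected_idx]
    coef = {data.names[j]: float(res.coef[j]) for j in selected_idx}
    diagnostics = {
        "shadow_hit_iteration": hit["iteration"],
        "shadow_hit_source": (
            data.names[aug.shadow_of[hit["column"]]]
            if hit["column"] is not None
            else None
        ),
        "m_max": m_max,
        "capped": hit["iteration"] is None,
    }
    logger.info(
        "probing: n=%d p=%d family=%s nu=%g -> %d selected, m_stop=%d",
        data.n, p, model.family.name, nu, len(selected), res.m_stop,
    )
    return SelectionResult(
        selected=selected,
        method="probing",
        m_stop=res.m_stop,
        coef=coef,
        diagnostics=diagnostics,
        seed=seed,
    )


def prefix_property_check(
    fit_aug: BoostingResults, result: SelectionResult
) -> bool:
    """Validate that a probing result is the pre-shadow prefix of a path.

    Given the boosting path on the augmented design, the probing
    selection must equal the distinct *original* variables appearing in
    the path strictly before the first shadow selection (the whole path
    if no shadow was ever selected).
    """
    p = fit_aug.model.k_vars // 2
    prefix: list[str] = []
    for j in fit_aug.sel_idx:
        if j >= p:
            break
        name = fit_aug.model.names[j]
        if name not in prefix:
            prefix.append(name)
    return list(result.selected) == prefix
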