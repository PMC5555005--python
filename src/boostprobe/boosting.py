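"""Component-wise gradient boosting with linear base learners.

The estimator follows the classical model-based boosting scheme: starting
from the loss-minimising constant, each iteration

1. computes the negative gradient ``u`` of the loss at the current fit,
2. fits a simple linear least-squares base learner ``h_j(x) = b_j x`` to
   ``u`` separately for every (mean-centred) covariate,
3. selects the single component ``j*`` whose base learner has the
   smallest residual sum of squares, and
4. adds a small fraction ``nu`` of that base learner to the predictor.

Because only one coordinate moves per iteration, the number of
iterations ``m_stop`` acts as the sparsity-controlling regularisation
parameter: variables never selected keep an exactly zero coefficient.
Stopping strategies (shadow-variable probing, stability selection's
per-fit cap, bootstrap out-of-bag risk) are layered on top via the
``stop`` callback or by post-hoc truncation of the path.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .families import Family, get_family

__all__ = [
    "ComponentwiseBoosting",
    "BoostingResults",
    "fit_base_learner",
    "select_best",
]


def fit_base_learner(xj: np.ndarray, u: np.ndarray) -> float:
    """Least-squares coefficient of the one-variable base learner.

    ``xj`` must already be mean-centred; the base learner is
    ``h_j(x) = b * x`` with ``b = <xj, u> / <xj, xj>``.
    """
    xj = np.asarray(xj, dtype=float)
    u = np.asarray(u, dtype=float)
    ss = float(xj @ xj)
    if ss <= 0.0:
        raise ValueError("zero-variance column has no usable base learner")
    return float(xj @ u) / ss


def select_best(
    Xc: np.ndarray, u: np.ndarray, usable: Optional[np.ndarray] = None
) -> tuple[int, float]:
    """Best-fitting component for the current negative gradient.

    Minimising the residual sum of squares of the componentwise linear
    base learner is equivalent to maximising ``<xj,u>^2 / <xj,xj>``;
    ties are broken by the smallest column index.

    Parameters
    ----------
    Xc : centred design matrix (n, p)
    u : negative-gradient vector (n,)
    usable : boolean mask of candidate columns (default: all)

    Returns
    -------
    (j_star, coefficient)
    """
    Xc = np.asarray(Xc, dtype=float)
    ss = np.einsum("ij,ij->j", Xc, Xc)
    if usable is None:
        usable = ss > 0.0
    usable = np.asarray(usable, dtype=bool) & (ss > 0.0)
    if not usable.any():
        raise ValueError("no usable columns to select from")
    c = Xc.T @ u
    score = np.where(usable, c * c / np.where(ss > 0.0, ss, 1.0), -np.inf)
    j = int(np.argmax(score))
    return j, float(c[j] / ss[j])


class ComponentwiseBoosting:
    """Component-wise gradient boosting model.

    Parameters
    ----------
    endog : array-like of shape (n,)
        Response; continuous for ``family="gaussian"``, 0/1 coded for
        ``family="binomial"``.
    exog : array-like of shape (n, p)
        Covariates.  Columns are mean-centred internally (no scaling to
        unit variance); the centring values are stored on the results
        object and applied again at prediction time.
    family : {"gaussian", "binomial"} or Family
        Loss family.
    names : sequence of str, optional
        Variable labels, default ``x1..xp``.

    Notes
    -----
    Zero-variance columns cannot host a base learner (the least-squares
    coefficient would be 0/0); they are excluded from the candidate set
    and can never be selected.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal(size=(50, 3))
    >>> y = 2.0 * X[:, 0] + rng.normal(scale=0.1, size=50)
    >>> res = ComponentwiseBoosting(y, X, family="gaussian").fit(m_stop=100)
    >>> res.selected_names()
    ['x1']
    """

    def __init__(
        self,
        endog,
        exog,
        family: "str | Family" = "gaussian",
        names: Optional[Sequence[str]] = None,
    ) -> None:
        self.family = get_family(family)
        self.exog = np.ascontiguousarray(exog, dtype=float)
        if self.exog.ndim != 2:
            raise ValueError("exog must be 2-dimensional")
        self.endog = np.asarray(endog, dtype=float).ravel()
        n, p = self.exog.shape
        if len(self.endog) != n:
            raise ValueError("endog/exog length mismatch")
        if not np.all(np.isfinite(self.exog)):
            raise ValueError("exog contains missing or non-finite values")
        self.family.check_response(self.endog)
        if names is None:
            names = [f"x{j + 1}" for j in range(p)]
        if len(names) != p:
            raise ValueError("wrong number of names")
        self.names = [str(s) for s in names]

        self.centers = self.exog.mean(axis=0)
        self._Xc = self.exog - self.centers
        self._ss = np.einsum("ij,ij->j", self._Xc, self._Xc)
        self.usable = self._ss > 0.0

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        family: "str | Family" = "gaussian",
    ) -> "ComponentwiseBoosting":
        """Build the model from a dataframe with a named outcome column."""
        covars = df.drop(columns=[outcome])
        return cls(
            df[outcome].to_numpy(dtype=float),
            covars.to_numpy(dtype=float),
            family=family,
            names=list(covars.columns),
        )

    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    @property
    def k_vars(self) -> int:
        return self.exog.shape[1]

    def fit(
        self,
        nu: float = 0.1,
        m_stop: int = 100,
        stop: Optional[Callable[[int, int], bool]] = None,
    ) -> "BoostingResults":
        """Run the boosting iterations and return the fitted path.

        Parameters
        ----------
        nu : float in (0, 1]
            Learning rate; 0.1 is the conventional default.
        m_stop : int >= 1
            Maximum number of iterations.
        stop : callable ``stop(j_star, m) -> bool``, optional
            Consulted at each iteration *before* the update is applied;
            if it returns True the fit is returned in its state as of
            iteration ``m - 1`` (the offending update is discarded).

        Returns
        -------
        BoostingResults
        """
        if not (0.0 < nu <= 1.0):
            raise ValueError("nu must be in (0, 1]")
        if m_stop < 1:
            raise ValueError("m_stop must be >= 1")
        if not self.usable.any():
            raise ValueError("all columns have zero variance")

        family = self.family
        y = self.endog
        Xc = self._Xc
        ss = self._ss
        neg_score = np.where(self.usable, 0.0, -np.inf)

        offset = family.init_offset(y)
        f = np.full(self.nobs, offset)
        coef = np.zeros(self.k_vars)
        sel_idx: list[int] = []
        sel_coef: list[float] = []

        for m in range(1, m_stop + 1):
            u = family.negative_gradient(y, f)
            c = Xc.T @ u
            score = neg_score + c * c / np.where(ss > 0.0, ss, 1.0)
            j = int(np.argmax(score))
            b = c[j] / ss[j]
            if stop is not None and stop(j, m):
                break
            step = nu * b
            coef[j] += step
            f += step * Xc[:, j]
            sel_idx.append(j)
            sel_coef.append(float(b))

        return BoostingResults(
            model=self,
            offset=offset,
            nu=nu,
            coef=coef,
            sel_idx=np.asarray(sel_idx, dtype=int),
            sel_coef=np.asarray(sel_coef, dtype=float),
            fittedvalues=f,
        )


class BoostingResults:
    """Fitted boosting path.

    Attributes
    ----------
    offset : float
        Loss-minimising constant the predictor starts from.
    nu : float
        Learning rate used.
    coef : ndarray (p,)
        Final coefficients on the centred-covariate scale; exactly zero
        for variables never selected.
    sel_idx, sel_coef : ndarray (m_stop,)
        Per-iteration selected column index and raw base-learner
        coefficient (before shrinkage by ``nu``).
    centers : ndarray (p,)
        Column means subtracted before fitting.
    m_stop : int
        Iterations actually performed.
    """

    def __init__(self, model, offset, nu, coef, sel_idx, sel_coef, fittedvalues):
        self.model = model
        self.offset = float(offset)
        self.nu = float(nu)
        self.coef = coef
        self.sel_idx = sel_idx
        self.sel_coef = sel_coef
        self.fittedvalues = fittedvalues

    @property
    def centers(self) -> np.ndarray:
        return self.model.centers

    @property
    def m_stop(self) -> int:
        return len(self.sel_idx)

    @property
    def params(self) -> pd.Series:
        """Coefficients indexed by variable name."""
        return pd.Series(self.coef, index=self.model.names, name="coef")

    def path(self) -> pd.DataFrame:
        """Per-iteration record: iteration, selected index/name, coefficient."""
        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.m_stop + 1),
                "index": self.sel_idx,
                "name": [self.model.names[j] for j in self.sel_idx],
                "coef": self.sel_coef,
            }
        )

    def selected(self) -> list[int]:
        """Distinct selected column indices, in first-selection order."""
        seen: dict[int, None] = {}
        for j in self.sel_idx:
            seen.setdefault(int(j), None)
        return list(seen)

    def selected_names(self) -> list[str]:
        return [self.model.names[j] for j in self.selected()]

    def truncate(self, m: int) -> "BoostingResults":
        """The fit as of iteration ``m`` (replaying the stored path)."""
        if not (0 <= m <= self.m_stop):
            raise ValueError(f"m must be in [0, {self.m_stop}]")
        coef = np.zeros_like(self.coef)
        np.add.at(coef, self.sel_idx[:m], self.nu * self.sel_coef[:m])
        f = self.offset + (self.model._Xc @ coef)
        return BoostingResults(
            model=self.model,
            offset=self.offset,
            nu=self.nu,
            coef=coef,
            sel_idx=self.sel_idx[:m].copy(),
            sel_coef=self.sel_coef[:m].copy(),
            fittedvalues=f,
        )

    def predict(self, exog, which: str = "linear") -> np.ndarray:
        """Predict on new data.

        ``which="linear"`` returns the additive predictor on the link
        scale (identity for Gaussian, logit for binomial);
        ``which="response"`` applies the inverse link for the binomial
        family.
        """
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.model.k_vars:
            raise ValueError(
                f"exog must have {self.model.k_vars} columns, got shape {X.shape}"
            )
        eta = self.offset + (X - self.centers) @ self.coef
        if which == "linear":
            return eta
        if which == "response":
            if self.model.family.name == "binomial":
                from scipy.special import expit

                return expit(eta)
            return eta
        raise ValueError("which must be 'linear' or 'response'")

    def staged_risk(self, exog, endog) -> np.ndarray:
        """Mean loss on held-out data after each iteration ``m = 1..m_stop``.

        Replays the stored path incrementally, so the cost is
        ``O(m_stop * n_new)`` rather than one refit per grid point.
        """
        X = np.asarray(exog, dtype=float)
        y = np.asarray(endog, dtype=float).ravel()
        Xc = X - self.centers
        f = np.full(len(y), self.offset)
        family = self.model.family
        risk = np.empty(self.m_stop)
        for m in range(self.m_stop):
            f += self.nu * self.sel_coef[m] * Xc[:, self.sel_idx[m]]
            risk[m] = float(np.mean(family.loss(y, f)))
        return risk

    def train_risk(self) -> float:
        """Mean in-sample loss at the final iteration."""
        return float(np.mean(self.model.family.loss(self.model.endog, self.fittedvalues)))

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        nz = self.selected()
        lines = [
            "Component-wise Gradient Boosting Results",
            "=" * 46,
            f"Family:            {self.model.family.name}",
            f"No. observations:  {self.model.nobs}",
            f"No. variables:     {self.model.k_vars}",
            f"Learning rate nu:  {self.nu:g}",
            f"Iterations m_stop: {self.m_stop}",
            f"Offset:            {self.offset:.6g}",
            f"Selected:          {len(nz)} variable(s)",
            "-" * 46,
            f"{'variable':<20}{'coef':>12}{'order':>8}",
        ]
        for rank, j in enumerate(nz, start=1):
            lines.append(
                f"{self.model.names[j]:<20}{self.coef[j]:>12.6f}{rank:>8d}"
            )
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable description of the fit."""
        return {
            "family": self.model.family.name,
            "offset": self.offset,
            "nu": self.nu,
            "m_stop": self.m_stop,
            "coef": {
                self.model.names[j]: float(self.coef[j]) for j in self.selected()
            },
            "selection_order": self.selected_names(),
        }
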