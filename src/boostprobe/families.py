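"""Loss families for component-wise gradient boosting.

Each family bundles the loss :math:`\\rho(y, f)`, its negative gradient
(the "pseudo-residuals" that base learners are fitted to), and the
loss-minimising constant used to initialise the additive predictor.

Two families are provided:

``Gaussian``
    Squared-error loss :math:`\\rho = (y - f)^2 / 2` for continuous
    responses; the negative gradient is the ordinary residual.
``Binomial``
    Negative Bernoulli log-likelihood on the logit scale for
    :math:`y \\in \\{0, 1\\}`,
    :math:`\\rho = \\log(1 + e^f) - y f`; the negative gradient is
    :math:`y - \\operatorname{expit}(f)`.

Note that some implementations (e.g. mboost) parametrise the binomial
loss with :math:`y \\in \\{-1, +1\\}` and half the logit; that convention
is equivalent up to a scaling of the predictor and leaves the order in
which variables are selected unchanged, so it is not replicated here.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Family", "Gaussian", "Binomial", "get_family"]


class Family:
    """Abstract loss family.

    Subclasses implement :meth:`loss`, :meth:`negative_gradient` and
    :meth:`init_offset`.  The offset is the empirical minimiser of the
    total loss over constant predictors, which guarantees the negative
    gradient evaluated at the offset has mean exactly zero.
    """

    name: str = ""

    def loss(self, y: np.ndarray, f: np.ndarray) -> np.ndarray:
        """Element-wise loss :math:`\\rho(y, f)`."""
        raise NotImplementedError

    def negative_gradient(self, y: np.ndarray, f: np.ndarray) -> np.ndarray:
        """Negative gradient :math:`u = -\\partial\\rho/\\partial f` at ``f``."""
        raise NotImplementedError

    def init_offset(self, y: np.ndarray) -> float:
        """Constant :math:`c` minimising :math:`\\sum_i \\rho(y_i, c)`."""
        raise NotImplementedError

    def check_response(self, y: np.ndarray) -> None:
        """Validate a response vector; raise ``ValueError`` if unusable."""
        y = np.asarray(y)
        if y.ndim != 1:
            raise ValueError("response must be one-dimensional")
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains missing or non-finite values")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}()"


class Gaussian(Family):
    """Squared-error loss for continuous responses."""

    name = "gaussian"

    def loss(self, y, f):
        r = np.asarray(y, dtype=float) - np.asarray(f, dtype=float)
        return 0.5 * r * r

    def negative_gradient(self, y, f):
        return np.asarray(y, dtype=float) - np.asarray(f, dtype=float)

    def init_offset(self, y):
        self.check_response(y)
        return float(np.mean(y))


class Binomial(Family):
    """Bernoulli log-likelihood loss on the logit scale, y in {0, 1}."""

    name = "binomial"

    def loss(self, y, f):
        y = np.asarray(y, dtype=float)
        f = np.asarray(f, dtype=float)
        # log(1 + e^f) - y*f, computed stably for large |f|
        return np.logaddexp(0.0, f) - y * f

    def negative_gradient(self, y, f):
        return np.asarray(y, dtype=float) - expit(np.asarray(f, dtype=float))

    def init_offset(self, y):
        self.check_response(y)
        ybar = float(np.mean(y))
        if ybar <= 0.0 or ybar >= 1.0:
            raise ValueError(
                "degenerate binomial response: both classes must be present "
                "(offset would be infinite)"
            )
        return float(np.log(ybar / (1.0 - ybar)))

    def check_response(self, y):
        super().check_response(y)
        y = np.asarray(y)
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("binomial response must be coded 0/1")


_FAMILIES = {"gaussian": Gaussian, "binomial": Binomial}


def get_family(family: "str | Family") -> Family:
    """Resolve a family name or instance to a :class:`Family` object."""
    if isinstance(family, Family):
        return family
    try:
        return _FAMILIES[str(family).lower()]()
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(_FAMILIES)}"
        ) from None
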