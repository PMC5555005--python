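"""Common result container for the variable-selection strategies."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["SelectionResult"]


@dataclass
class SelectionResult:
    """Outcome of one variable-selection run.

    Attributes
    ----------
    selected : list of str
        Names of the selected original variables, in the order they
        first entered the boosting path.
    method : str
        One of ``"probing"``, ``"cv"``, ``"stability"``.
    m_stop : int
        Number of boosting iterations retained in the returned model
        (for stability selection: the per-fit cap actually relevant is
        recorded in ``diagnostics`` instead).
    coef : dict
        Nonzero coefficients of the returned model, keyed by name.
    diagnostics : dict
        Method-specific metadata (e.g. the iteration at which the first
        shadow variable was hit, the out-of-bag-optimal iteration, or
        the selection-frequency table).
    seed : int or None
        Seed controlling the stochastic parts of the method.
    """

    selected: list
    method: str
    m_stop: int
    coef: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected variables must be unique")

    def __len__(self) -> int:
        return len(self.selected)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "selected": list(self.selected),
            "order": list(self.selected),
            "coef": {k: float(v) for k, v in self.coef.items()},
            "m_stop": int(self.m_stop),
            "diagnostics": _jsonable(self.diagnostics),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            selected=list(d["selected"]),
            method=d["method"],
            m_stop=int(d["m_stop"]),
            coef=dict(d.get("coef", {})),
            diagnostics=dict(d.get("diagnostics", {})),
            seed=d.get("seed"),
        )


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays into plain python."""
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj
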