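"""Containers for force-extension and force-distance curves."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class ForceExtensionCurve:
    """Extension versus force for one molecule or condition.

    ``x`` may be total extension (nm) or extension per base; ``per_base``
    records which.  ``se`` is the per-point standard error where available.
    """

    f: np.ndarray
    x: np.ndarray
    se: np.ndarray | None = None
    per_base: bool = False
    N: int | None = None
    N_loop: int | None = None
    salt_M: float | None = None
    molecule_id: str | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.f.shape != self.x.shape:
            raise ValueError("f and x must have the same shape")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.f.shape:
                raise ValueError("se must match f in shape")
        if np.any(np.diff(self.f) <= 0):
            raise ValueError("force grid must be strictly increasing")

    def __len__(self) -> int:
        return self.f.size

    def to_frame(self) -> pd.DataFrame:
        d = {"force_pN": self.f, "x_nm": self.x}
        d["se_nm"] = self.se if self.se is not None else np.full_like(self.f, np.nan)
        return pd.DataFrame(d)

    def interp(self, f_grid: np.ndarray) -> "ForceExtensionCurve":
        """Linear interpolation onto a new force grid (within support only)."""
        f_grid = np.asarray(f_grid, dtype=float)
        if f_grid.min() < self.f.min() - 1e-9 or f_grid.max() > self.f.max() + 1e-9:
            raise ValueError("requested grid extends beyond curve support")
        x = np.interp(f_grid, self.f, self.x)
        se = np.interp(f_grid, self.f, self.se) if self.se is not None else None
        return ForceExtensionCurve(
            f=f_grid, x=x, se=se, per_base=self.per_base, N=self.N,
            N_loop=self.N_loop, salt_M=self.salt_M, molecule_id=self.molecule_id,
            meta=dict(self.meta),
        )


@dataclass
class ForceDistanceCurve:
    """Trap position versus force over one or more pulling cycles.

    ``branch`` holds per-point labels: "folded", "unfolded" or "unassigned".
    """

    lam: np.ndarray
    f: np.ndarray
    cycle: np.ndarray | None = None
    direction: np.ndarray | None = None  # "pull" / "relax"
    branch: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.lam.shape != self.f.shape:
            raise ValueError("lambda and f must have the same shape")
        n = self.lam.size
        if self.cycle is None:
            self.cycle = np.zeros(n, dtype=int)
        else:
            self.cycle = np.asarray(self.cycle, dtype=int)
        if self.direction is None:
            self.direction = np.full(n, "pull", dtype=object)
        else:
            self.direction = np.asarray(self.direction, dtype=object)
        if self.branch is None:
            self.branch = np.full(n, "unassigned", dtype=object)
        else:
            self.branch = np.asarray(self.branch, dtype=object)

    def __len__(self) -> int:
        return self.f.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda_nm": self.lam,
                "force_pN": self.f,
                "cycle": self.cycle,
                "direction": self.direction,
                "branch": self.branch,
            }
        )
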