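"""The analytic dataset of a test-negative design (TND) study.

A TND sample contains only tested individuals (the selected ``S = 1``
subsample of the target population).  Each record carries the vaccination
indicator ``A``, the test result ``Y`` (1 = test-positive case, 0 =
test-negative control), one or more negative control exposures ``Z``, one
or more negative control outcomes ``W``, and measured covariates ``X``
(possibly none).  Latent variables of the generating process (the
unmeasured confounder, auxiliary illness and selection indicators) are
never part of a :class:`TNDSample`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TNDSample", "read_sample_csv", "write_sample_csv"]


def _as_matrix(v, name: str, n: int | None) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 1- or 2-dimensional")
    if n is not None and arr.shape[0] != n:
        raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite values")
    return arr


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite values")
    bad = ~np.isin(arr, (0.0, 1.0))
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"column {name!r} must be binary (0/1); row {i} has value {arr[i]!r}"
        )
    return arr.astype(np.int8)


@dataclass(frozen=True)
class TNDSample:
    """Observed data ``(A_i, Y_i, Z_i, W_i, X_i)`` for the tested sample.

    Parameters
    ----------
    a, y : array-like of shape (n,)
        Binary vaccination and test-result indicators.
    z, w : array-like of shape (n,) or (n, k)
        Negative control exposure(s) and outcome(s); binary or continuous.
    x : array-like of shape (n,) or (n, p), optional
        Measured covariates; may be empty (``p = 0``).
    """

    a: np.ndarray
    y: np.ndarray
    z: np.ndarray
    w: np.ndarray
    x: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        a = _as_binary(self.a, "a")
        y = _as_binary(self.y, "y")
        n = a.shape[0]
        if n < 1:
            raise ValueError("sample must contain at least one subject")
        if y.shape[0] != n:
            raise ValueError("a and y differ in length")
        z = _as_matrix(self.z, "z", n)
        w = _as_matrix(self.w, "w", n)
        x = self.x
        if x is None:
            x = np.empty((n, 0))
        x = _as_matrix(x, "x", n)
        for nm, v in (("a", a), ("y", y), ("z", z), ("w", w), ("x", x)):
            object.__setattr__(self, nm, v)
            v.setflags(write=False)

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    def controls(self) -> "TNDSample":
        """Subsample of test-negative controls (``Y = 0``)."""
        keep = self.y == 0
        if not keep.any():
            raise ValueError("sample contains no test-negative controls")
        return TNDSample(self.a[keep], self.y[keep], self.z[keep],
                         self.w[keep], self.x[keep])

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"a": self.a, "y": self.y}
        cols.update(_wide("z", self.z))
        cols.update(_wide("w", self.w))
        cols.update(_wide("x", self.x))
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       mapping: dict[str, object] | None = None) -> "TNDSample":
        """Build a sample from a data frame.

        ``mapping`` assigns column names to roles, e.g.
        ``{"a": "vaccinated", "y": "positive", "z": ["z1"], "w": ["w1"],
        "x": ["age", "sex"]}``.  Roles are analyst-declared, never inferred:
        by default the conventional names ``a``, ``y``, ``z``/``z1…``,
        ``w``/``w1…``, ``x1…`` are used.  Rows with missing values in any
        mapped column are dropped with a logged count.
        """
        mapping = dict(mapping or {})
        a_col = str(mapping.get("a", "a"))
        y_col = str(mapping.get("y", "y"))
        z_cols = _role_columns(df, mapping.get("z"), "z")
        w_cols = _role_columns(df, mapping.get("w"), "w")
        x_cols = _role_columns(df, mapping.get("x"), "x", required=False)
        for c in [a_col, y_col, *z_cols, *w_cols, *x_cols]:
            if c not in df.columns:
                raise ValueError(f"mapped column {c!r} not found in input")
        use = df[[a_col, y_col, *z_cols, *w_cols, *x_cols]]
        complete = use.notna().all(axis=1)
        dropped = int((~complete).sum())
        if dropped:
            logger.warning("dropped %d row(s) with missing values in mapped columns",
                           dropped)
        use = use[complete]
        if not len(use):
            raise ValueError("no complete rows after dropping missing values")
        return cls(
            a=use[a_col].to_numpy(),
            y=use[y_col].to_numpy(),
            z=use[z_cols].to_numpy(),
            w=use[w_cols].to_numpy(),
            x=use[x_cols].to_numpy() if x_cols else None,
        )


def _wide(prefix: str, mat: np.ndarray) -> dict[str, np.ndarray]:
    if mat.shape[1] == 0:
        return {}
    if mat.shape[1] == 1:
        return {prefix: mat[:, 0]}
    return {f"{prefix}{j + 1}": mat[:, j] for j in range(mat.shape[1])}


def _role_columns(df, spec, prefix: str, required: bool = True) -> list[str]:
    if spec is not None:
        return [spec] if isinstance(spec, str) else [str(c) for c in spec]
    if prefix in df.columns:
        return [prefix]
    found = sorted((c for c in df.columns
                    if c.startswith(prefix) and c[len(prefix):].isdigit()),
                   key=lambda c: int(c[len(prefix):]))
    if not found and required:
        raise ValueError(f"no column found for role {prefix!r}")
    return found


def read_sample_csv(path, mapping: dict[str, object] | None = None) -> TNDSample:
    """Read a TND sample from a headered CSV file."""
    df = pd.read_csv(path)
    latent = [c for c in ("u", "d", "s") if c in df.columns]
    if latent:
        logger.warning("ignoring latent column(s) %s present in %s", latent, path)
    return TNDSample.from_dataframe(df, mapping)


def write_sample_csv(sample: TNDSample, path) -> None:
    sample.to_dataframe().to_csv(path, index=False)
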