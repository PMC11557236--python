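"""Shared eigen-spectrum report used by the global and local analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EigenReport:
    """Ordered eigen-spectrum with an identifiability threshold.

    `eigenvalues` are sorted descending; `eigenvectors` holds the
    corresponding unit-norm directions in parameter coordinates as
    columns.  `normalized_pct` is 100 * lambda / sum(lambda) (sums to
    100 %).  The threshold is either a percentage of the eigenvalue sum
    (`kind='percent'`, global analysis) or an absolute noise floor
    (`kind='absolute'`, local Hessian analysis); `n_identifiable` counts
    the directions above it.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns
    parameter_names: tuple[str, ...]
    threshold: float
    kind: str  # 'percent' | 'absolute'

    def __post_init__(self):
        order = np.argsort(self.eigenvalues)[::-1]
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)[order]
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)[:, order]
        if self.kind not in ("percent", "absolute"):
            raise ValueError("kind must be 'percent' or 'absolute'")

    @property
    def normalized_pct(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / total

    @property
    def n_identifiable(self) -> int:
        if self.kind == "percent":
            return int(np.sum(self.normalized_pct > self.threshold))
        return int(np.sum(self.eigenvalues > self.threshold))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.eigenvectors,
            index=list(self.parameter_names),
            columns=[f"v{i + 1}" for i in range(self.eigenvalues.size)],
        )
        df.loc["eigenvalue"] = self.eigenvalues
        df.loc["normalized_pct"] = self.normalized_pct
        return df

    def summary(self) -> str:
        lines = [
            f"{self.eigenvalues.size} directions; threshold "
            f"{self.threshold:g} ({self.kind}); "
            f"{self.n_identifiable} constrained directions",
        ]
        for lam, pct in zip(self.eigenvalues, self.normalized_pct):
            lines.append(f"  lambda = {lam: .6e}  ({pct:7.3f} %)")
        return "\n".join(lines)
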