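"""Tabular (treatment, outcome, covariates) sample container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TriSample"]


@dataclass
class TriSample:
    """One continuous treatment, one outcome and an n x p covariate block."""

    t: np.ndarray
    y: np.ndarray
    z: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        z = np.asarray(self.z, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        self.z = z
        n = self.t.shape[0]
        if self.y.shape[0] != n or self.z.shape[0] != n:
            raise ValueError("t, y and z must share the sample size")
        for name, arr in (("treatment", self.t), ("outcome", self.y), ("covariates", self.z)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} column contains non-finite values")
        if not self.covariate_names:
            self.covariate_names = [f"Z{j + 1}" for j in range(self.z.shape[1])]
        if len(self.covariate_names) != self.z.shape[1]:
            raise ValueError("covariate_names length does not match covariate count")

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def p(self) -> int:
        return self.z.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        treatment: str = "T",
        outcome: str = "Y",
        covariates: list[str] | None = None,
    ) -> "TriSample":
        for col in (treatment, outcome):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if covariates is None:
            covariates = [c for c in df.columns if c not in (treatment, outcome)]
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        sub = df[[treatment, outcome, *covariates]]
        bad = sub.isna() | ~sub.map(np.isreal)
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric or missing cell at row {sub.index[r]}, column {sub.columns[c]!r}"
            )
        return cls(
            t=sub[treatment].to_numpy(float),
            y=sub[outcome].to_numpy(float),
            z=sub[covariates].to_numpy(float),
            covariate_names=list(covariates),
        )

    def to_dataframe(self, treatment: str = "T", outcome: str = "Y") -> pd.DataFrame:
        out = pd.DataFrame({treatment: self.t, outcome: self.y})
        for j, name in enumerate(self.covariate_names):
            out[name] = self.z[:, j]
        return out
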