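"""Features x samples expression container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "sample_table"]


def sample_table(samples: list[tuple[str, str, str]], ids: list[str] | None = None) -> pd.DataFrame:
    """Build sample metadata from (species, tissue, replicate) tuples."""
    if ids is None:
        ids = [f"{sp}.{ti}.{rep}" for sp, ti, rep in samples]
    return pd.DataFrame(samples, columns=["species", "tissue", "replicate"], index=ids)


@dataclass
class ExpressionMatrix:
    """Counts or normalized expression, features as rows, samples as columns.

    ``samples`` is indexed by sample id with columns species/tissue/replicate.
    ``factors`` (present after normalization) are effective per-sample size
    factors with geometric mean 1.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False
    factors: pd.Series | None = None
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns must match samples index")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.factors is not None:
            logf = np.log(self.factors.to_numpy(float))
            if abs(logf.mean()) > 1e-9:
                raise ValueError("factors must have geometric mean 1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def subset_features(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[ids], self.samples,
                                self.normalized, self.factors, dict(self.qc))

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str, samples: pd.DataFrame | None = None,
                 normalized: bool = False) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        if samples is None:
            parsed = [tuple(c.split(".")) if c.count(".") == 2 else ("NA", c, "1")
                      for c in values.columns]
            samples = sample_table(parsed, ids=list(values.columns))
        return cls(values, samples, normalized=normalized)
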