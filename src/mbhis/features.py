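"""Feature-matrix container shared by the extraction, wavelet and fusion stages.

A :class:`FeatureMatrix` is an ``n_samples x d`` float array plus the
bookkeeping the cascade needs: row-aligned sample identifiers, a provenance
tag saying which stage produced the values (``spatial`` = CNN global-average
-pooling embeddings, ``stf`` = wavelet detail coefficients of those
embeddings, ``fused`` = concatenation/reduction output) and, where a single
backbone is responsible, its name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError

PROVENANCES = ("spatial", "stf", "fused")


@dataclass
class FeatureMatrix:
    values: np.ndarray
    sample_ids: list[str]
    provenance: str
    backbone: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataError(f"feature matrix must be 2-D, got shape {self.values.shape}")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.shape[0]:
            raise DataError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[0]} rows"
            )
        if self.provenance not in PROVENANCES:
            raise DataError(f"unknown provenance {self.provenance!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        """Row subset keeping provenance/backbone and id alignment."""
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            self.provenance,
            self.backbone,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"))
        df.columns = [f"f{j}" for j in range(self.width)]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(
        cls, path: str | Path, provenance: str, backbone: str | None = None
    ) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(df.to_numpy(), list(df.index.astype(str)), provenance, backbone)
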