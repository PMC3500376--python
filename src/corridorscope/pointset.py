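"""Lightweight point collections (presence fixes, ground-truth samples)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PointSet"]


@dataclass
class PointSet:
    """Planar points with optional individual ids and timestamps."""

    x: np.ndarray
    y: np.ndarray
    ids: np.ndarray | None = None
    t: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if self.ids is not None:
            self.ids = np.asarray(self.ids)
            if self.ids.shape != self.x.shape:
                raise ValueError("ids length mismatch")
        if self.t is not None:
            self.t = np.asarray(self.t)
            if self.t.shape != self.x.shape:
                raise ValueError("t length mismatch")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        data = {"x": self.x, "y": self.y}
        if self.ids is not None:
            data = {"id": self.ids, **data}
        if self.t is not None:
            data["t"] = self.t
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "PointSet":
        df = pd.read_csv(path)
        return cls(
            df["x"].to_numpy(),
            df["y"].to_numpy(),
            ids=df["id"].to_numpy() if "id" in df else None,
            t=pd.to_datetime(df["t"]).to_numpy() if "t" in df else None,
        )

    @classmethod
    def concat(cls, sets: list["PointSet"]) -> "PointSet":
        if not sets:
            raise ValueError("cannot concatenate zero point sets")
        has_ids = all(s.ids is not None for s in sets)
        has_t = all(s.t is not None for s in sets)
        return cls(
            np.concatenate([s.x for s in sets]),
            np.concatenate([s.y for s in sets]),
            ids=np.concatenate([s.ids for s in sets]) if has_ids else None,
            t=np.concatenate([s.t for s in sets]) if has_t else None,
        )
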