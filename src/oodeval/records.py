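"""Sample records: identifiers, domain tags, labels, features and logits.

The canonical in-memory container is :class:`FeatureTable`, a column-oriented
dataclass holding one row per sample.  In-distribution (ID) rows carry an
integer class label; out-of-distribution (OOD) rows carry no label at all
(``None``, never a sentinel value), so they cannot accidentally enter a
class-conditional fit.

On disk a table is a delimited text file with header
``id,domain,label,f_1..f_d[,l_1..l_k]`` where ``domain`` is ``ID`` or ``OOD``
and ``label`` is empty for OOD rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ID_DOMAIN = "ID"
OOD_DOMAIN = "OOD"


@dataclass
class FeatureTable:
    """One row per sample: identifier, domain tag, optional label, vectors.

    Parameters
    ----------
    ids : array of str, shape (n,)
        Unique sample identifiers.
    domain : array of str, shape (n,)
        Each entry ``"ID"`` or ``"OOD"``.
    labels : object array, shape (n,)
        Integer class label for ID rows, ``None`` for OOD rows.
    features : float array, shape (n, d)
        Feature vectors (e.g. penultimate-layer activations, or raw inputs
        when a linear adapter supplies the logit map).
    logits : float array, shape (n, C), optional
        Pre-computed logit vectors; absent when an adapter computes them.
    """

    ids: np.ndarray
    domain: np.ndarray
    labels: np.ndarray
    features: np.ndarray
    logits: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.domain = np.asarray(self.domain, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        n = len(self.ids)
        if not (len(self.domain) == len(self.labels) == self.features.shape[0] == n):
            raise ValueError("FeatureTable columns have inconsistent lengths")
        bad = set(np.unique(self.domain.astype(str))) - {ID_DOMAIN, OOD_DOMAIN}
        if bad:
            raise ValueError(f"unknown domain tags: {sorted(bad)}")
        for dom, lab in zip(self.domain, self.labels):
            if dom == OOD_DOMAIN and lab is not None:
                raise ValueError("OOD rows must not carry a class label")
            if dom == ID_DOMAIN and lab is None:
                raise ValueError("ID rows must carry a class label")
        if self.logits is not None:
            self.logits = np.atleast_2d(np.asarray(self.logits, dtype=float))
            if self.logits.shape[0] != n:
                raise ValueError("logits row count does not match ids")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def is_id(self) -> np.ndarray:
        return np.asarray([d == ID_DOMAIN for d in self.domain], dtype=bool)

    @property
    def is_ood(self) -> np.ndarray:
        return ~self.is_id

    def label_array(self) -> np.ndarray:
        """Integer labels; raises if any row is unlabeled (OOD)."""
        if any(lab is None for lab in self.labels):
            raise ValueError("table contains unlabeled (OOD) rows")
        return np.asarray([int(lab) for lab in self.labels], dtype=int)

    def take(self, indices: Sequence[int] | np.ndarray) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            ids=self.ids[idx],
            domain=self.domain[idx],
            labels=self.labels[idx],
            features=self.features[idx],
            logits=None if self.logits is None else self.logits[idx],
        )

    def id_rows(self) -> "FeatureTable":
        return self.take(np.flatnonzero(self.is_id))

    def ood_rows(self) -> "FeatureTable":
        return self.take(np.flatnonzero(self.is_ood))

    @staticmethod
    def concat(tables: Iterable["FeatureTable"]) -> "FeatureTable":
        tables = list(tables)
        if not tables:
            raise ValueError("cannot concatenate zero tables")
        logits = None
        if all(t.logits is not None for t in tables):
            logits = np.vstack([t.logits for t in tables])
        return FeatureTable(
            ids=np.concatenate([t.ids for t in tables]),
            domain=np.concatenate([t.domain for t in tables]),
            labels=np.concatenate([t.labels for t in tables]),
            features=np.vstack([t.features for t in tables]),
            logits=logits,
        )

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        d = self.features.shape[1]
        data: dict[str, object] = {
            "id": self.ids.astype(str),
            "domain": self.domain.astype(str),
            "label": ["" if lab is None else int(lab) for lab in self.labels],
        }
        for j in range(d):
            data[f"f_{j + 1}"] = self.features[:, j]
        if self.logits is not None:
            for j in range(self.logits.shape[1]):
                data[f"l_{j + 1}"] = self.logits[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        fcols = sorted(
            (c for c in frame.columns if c.startswith("f_")),
            key=lambda c: int(c.split("_")[1]),
        )
        lcols = sorted(
            (c for c in frame.columns if c.startswith("l_")),
            key=lambda c: int(c.split("_")[1]),
        )
        if not fcols:
            raise ValueError("feature table needs at least one f_* column")
        labels = np.asarray(
            [
                None if (pd.isna(v) or str(v) == "") else int(float(v))
                for v in frame["label"]
            ],
            dtype=object,
        )
        return cls(
            ids=frame["id"].astype(str).to_numpy(dtype=object),
            domain=frame["domain"].astype(str).to_numpy(dtype=object),
            labels=labels,
            features=frame[fcols].to_numpy(dtype=float),
            logits=frame[lcols].to_numpy(dtype=float) if lcols else None,
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


def make_ids(prefix: str, n: int, start: int = 0) -> np.ndarray:
    """Deterministic zero-padded sample identifiers."""
    return np.asarray([f"{prefix}-{i:06d}" for i in range(start, start + n)], dtype=object)
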