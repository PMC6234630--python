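"""Numeric encoding of discrete feature frames (internal).

Shared by the over-samplers, the similarity features and the tree learner:
ordinal attributes become integer codes in domain order, binary attributes
0/1, nominal attributes one-hot indicator columns, and set-valued attributes
one membership indicator per domain member.  The inverse transform snaps
continuous vectors (e.g. SMOTE interpolations) back onto valid discrete
codes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .kb import BINARY, NOMINAL, ORDINAL, SET_VALUED, AttributeSpec


class NumericEncoder:
    """Maps a discrete dataset frame to a dense float matrix and back."""

    def __init__(
        self,
        vocab: Sequence[AttributeSpec],
        attributes: Sequence[str] | None = None,
        extra_numeric: Sequence[str] = (),
    ):
        vocab = list(vocab)
        if attributes is not None:
            keep = set(attributes)
            vocab = [a for a in vocab if a.name in keep]
        self.vocab = vocab
        self.extra_numeric = list(extra_numeric)
        self.columns: list[str] = []
        self._blocks: list[tuple[AttributeSpec, slice]] = []
        start = 0
        for spec in vocab:
            if spec.kind in (ORDINAL, BINARY):
                width = 1
                self.columns.append(spec.name)
            else:
                width = len(spec.domain)
                self.columns.extend(f"{spec.name}={v}" for v in spec.domain)
            self._blocks.append((spec, slice(start, start + width)))
            start += width
        self.columns.extend(self.extra_numeric)
        self.width = start + len(self.extra_numeric)

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        X = np.zeros((len(frame), self.width))
        for spec, sl in self._blocks:
            col = frame[spec.name].astype(str)
            if spec.kind == ORDINAL:
                codes = {v: float(i) for i, v in enumerate(spec.domain)}
                X[:, sl.start] = col.map(codes).to_numpy(dtype=float)
            elif spec.kind == BINARY:
                X[:, sl.start] = (col == "true").to_numpy(dtype=float)
            elif spec.kind == NOMINAL:
                for j, v in enumerate(spec.domain):
                    X[:, sl.start + j] = (col == v).to_numpy(dtype=float)
            else:  # SET_VALUED
                dummies = col.str.get_dummies(sep=";")
                for j, v in enumerate(spec.domain):
                    if v in dummies.columns:
                        X[:, sl.start + j] = dummies[v].to_numpy(dtype=float)
        for k, name in enumerate(self.extra_numeric):
            X[:, self.width - len(self.extra_numeric) + k] = frame[name].to_numpy(
                dtype=float
            )
        return X

    def inverse_transform(
        self, X: np.ndarray, tie_prefer: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        """Snap continuous encoded rows back onto valid discrete cells.

        Ordinal codes are rounded half-to-even and clipped; binary and set
        membership indicators threshold at 0.5; one-hot nominal blocks snap
        to the argmax, with exact ties resolved in favour of ``tie_prefer``
        (a frame of parent rows, aligned to ``X``) when the preferred value
        is among the tied maxima, else the first tied value in domain order.
        """
        X = np.asarray(X, dtype=float)
        out: dict[str, list[str]] = {}
        for spec, sl in self._blocks:
            block = X[:, sl]
            if spec.kind == ORDINAL:
                idx = np.clip(
                    np.rint(block[:, 0]).astype(int), 0, len(spec.domain) - 1
                )
                out[spec.name] = [spec.domain[i] for i in idx]
            elif spec.kind == BINARY:
                out[spec.name] = [
                    "true" if v >= 0.5 else "false" for v in block[:, 0]
                ]
            elif spec.kind == NOMINAL:
                cells = []
                for i in range(block.shape[0]):
                    row = block[i]
                    best = row.max()
                    tied = [
                        spec.domain[j]
                        for j in range(len(spec.domain))
                        if row[j] == best
                    ]
                    if (
                        len(tied) > 1
                        and tie_prefer is not None
                        and str(tie_prefer.iloc[i][spec.name]) in tied
                    ):
                        cells.append(str(tie_prefer.iloc[i][spec.name]))
                    else:
                        cells.append(tied[0])
                out[spec.name] = cells
            else:  # SET_VALUED
                cells = []
                for i in range(block.shape[0]):
                    members = [
                        spec.domain[j]
                        for j in range(len(spec.domain))
                        if block[i, j] >= 0.5
                    ]
                    cells.append(";".join(sorted(members)))
                out[spec.name] = cells
        return pd.DataFrame(out)
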