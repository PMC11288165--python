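"""k-mer (N-gram) featurization of DNA sequences.

Each sequence is represented by the counts of its overlapping k-mers for a
range of orders (monomers through quad-mers by default). Windows containing
any character outside {A, C, G, T} are skipped, so ambiguity codes never
contribute to counts. Optional per-order frequency normalization divides
each k-block of a row by that sequence's number of valid windows, making
sequences of different lengths comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import LabeledSequenceSet

MAX_K = 8

# byte value -> base code; 255 marks characters outside the DNA alphabet
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class FeatureMatrix:
    """Rows = sequences, columns = k-mer counts or frequencies.

    ``feature_names`` are ordered by (k ascending, lexicographic within k);
    ``y`` encodes labels as indices into ``class_names``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    class_names: list[str]
    ids: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X columns")
        if np.any(self.X < 0):
            raise ValueError("feature values must be non-negative")
        if not self.ids:
            self.ids = [f"r{i}" for i in range(self.X.shape[0])]

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=list(self.feature_names),
            class_names=list(self.class_names),
            ids=[self.ids[i] for i in idx],
            normalized=self.normalized,
        )

    def subset_features(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        names = [n for n, m in zip(self.feature_names, mask) if m]
        return FeatureMatrix(
            X=self.X[:, mask],
            y=self.y.copy(),
            feature_names=names,
            class_names=list(self.class_names),
            ids=list(self.ids),
            normalized=self.normalized,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", [self.class_names[c] for c in self.y])
        df.insert(0, "id", self.ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
        if list(df.columns[:2]) != ["id", "label"]:
            raise ValueError(f"{path}: first two columns must be 'id' and 'label'")
        class_names = list(dict.fromkeys(df["label"]))
        y = np.array([class_names.index(l) for l in df["label"]])
        return cls(
            X=df.iloc[:, 2:].to_numpy(dtype=float),
            y=y,
            feature_names=list(df.columns[2:]),
            class_names=class_names,
            ids=list(df["id"]),
            normalized=normalized,
        )


def enumerate_grams(k: int) -> list[str]:
    """All 4**k strings over {A,C,G,T} in lexicographic order."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def count_ngrams(seq: str, k: int) -> np.ndarray:
    """Counts of overlapping k-mers of ``seq`` over ``enumerate_grams(k)``.

    Windows touching a non-ACGT character are skipped. A sequence shorter
    than ``k`` yields an all-zero vector.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n_feats = 4**k
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.zeros(n_feats, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win != 255).all(axis=1)
    if not valid.any():
        return np.zeros(n_feats, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win[valid].astype(np.int64) @ powers
    return np.bincount(vals, minlength=n_feats)


def valid_window_count(seq: str, k: int) -> int:
    """Number of length-k windows consisting only of A/C/G/T."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return 0
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    return int((win != 255).all(axis=1).sum())


def feature_names_for(k_min: int, k_max: int) -> list[str]:
    names: list[str] = []
    for k in range(k_min, k_max + 1):
        names.extend(enumerate_grams(k))
    return names


def build_feature_matrix(
    sset: LabeledSequenceSet,
    k_min: int = 1,
    k_max: int = 4,
    normalize: bool = False,
) -> FeatureMatrix:
    """Concatenate per-order k-mer vectors for every record.

    With ``normalize=True`` each per-k block of a row is divided by that
    sequence's valid-window count for that k (rows with no valid window for
    some k keep an all-zero block).
    """
    if not 1 <= k_min <= k_max <= MAX_K:
        raise ValueError(f"need 1 <= k_min <= k_max <= {MAX_K}")
    if len(sset) == 0:
        raise ValueError("empty sequence set")
    ks = list(range(k_min, k_max + 1))
    rows = []
    for rec in sset.records:
        blocks = []
        for k in ks:
            block = count_ngrams(rec.sequence, k).astype(float)
            if normalize:
                total = block.sum()
                if total > 0:
                    block = block / total
            blocks.append(block)
        rows.append(np.concatenate(blocks))
    label_to_idx = {name: i for i, name in enumerate(sset.class_names)}
    y = np.array([label_to_idx[rec.label] for rec in sset.records])
    return FeatureMatrix(
        X=np.vstack(rows),
        y=y,
        feature_names=feature_names_for(k_min, k_max),
        class_names=list(sset.class_names),
        ids=sset.ids,
        normalized=normalize,
    )
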