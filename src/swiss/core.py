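"""Core SWISS computations.

SWISS (Standardized WithIn class Sum of Squares) measures how well a
dataset clusters into a-priori classes.  For samples ``x_ij`` (the j-th
sample of class i, each a d-vector of features) with overall mean
``x_bar`` and class means ``x_bar_i``::

    SST   = sum_ij ||x_ij - x_bar||^2        (total sum of squares)
    WISS  = sum_ij ||x_ij - x_bar_i||^2      (total within-class SS)
    SWISS = WISS / SST

SWISS is the proportion of total variation left unexplained by the class
structure; it lies in [0, 1] and lower means tighter classes and/or
larger between-class separation.  Because it is standardized by SST,
scores are comparable across datasets on different scales and even of
different dimensionality.

All matrices here are features x samples; distances are Euclidean
distances between sample columns in feature space.  No centering or
scaling is applied internally: the data are scored exactly as processed,
since the processing itself is what SWISS is meant to evaluate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClassAssignment",
    "SwissResult",
    "total_sum_of_squares",
    "within_class_sum_of_squares",
    "swiss_score",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features x samples numeric matrix with identifiers.

    Parameters
    ----------
    values
        Real matrix of shape (d features, N samples).  Must be complete:
        missing values have to be resolved upstream (imputation is a
        processing choice, not something the score should silently make).
    feature_ids, sample_ids
        Unique string identifiers for the rows and columns.
    """

    values: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expression matrix must be 2-D, got shape {values.shape}")
        d, n = values.shape
        if d < 1 or n < 1:
            raise ValueError("expression matrix must have at least one feature and one sample")
        feature_ids = tuple(str(f) for f in self.feature_ids)
        sample_ids = tuple(str(s) for s in self.sample_ids)
        if len(feature_ids) != d:
            raise ValueError(f"{len(feature_ids)} feature ids for {d} rows")
        if len(sample_ids) != n:
            raise ValueError(f"{len(sample_ids)} sample ids for {n} columns")
        for name, ids in (("feature", feature_ids), ("sample", sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dups = sorted({i for i in ids if i in seen or seen.add(i)})
                raise ValueError(f"duplicate {name} ids: {', '.join(dups)}")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "matrix contains missing or non-finite values; first at "
                f"feature {feature_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", feature_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame indexed by feature id with sample columns."""
        return cls(df.to_numpy(dtype=float), tuple(map(str, df.index)), tuple(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.feature_ids), columns=list(self.sample_ids))

    def restrict_features(self, keep: Iterable[str]) -> "ExpressionMatrix":
        """Return the sub-matrix with only the given features.

        Row order of the original matrix is preserved (``keep`` is treated
        as a set), so restricting to the full feature set reproduces the
        matrix exactly.
        """
        keep = set(keep)
        missing = sorted(keep - set(self.feature_ids))
        if missing:
            raise ValueError(f"features not present in matrix: {', '.join(missing)}")
        mask = np.fromiter((f in keep for f in self.feature_ids), dtype=bool, count=self.n_features)
        return ExpressionMatrix(
            self.values[mask],
            tuple(f for f in self.feature_ids if f in keep),
            self.sample_ids,
        )


@dataclass(frozen=True)
class ClassAssignment:
    """A mapping from sample id to a-priori class label.

    ``classes`` keeps first-appearance order; it affects reporting only,
    never scores.
    """

    labels: Mapping[str, str]
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = {str(k): str(v) for k, v in dict(self.labels).items()}
        if not labels:
            raise ValueError("class assignment is empty")
        classes = tuple(self.classes) if self.classes else tuple(dict.fromkeys(labels.values()))
        if set(classes) != set(labels.values()):
            raise ValueError("classes does not match the set of labels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "classes", classes)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ClassAssignment":
        labels: dict[str, str] = {}
        for sid, lab in pairs:
            sid = str(sid)
            if sid in labels:
                raise ValueError(f"duplicate sample id in labels: {sid!r}")
            labels[sid] = str(lab)
        return cls(labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def class_sizes(self) -> dict[str, int]:
        sizes = dict.fromkeys(self.classes, 0)
        for lab in self.labels.values():
            sizes[lab] += 1
        return sizes

    def indices_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Class index per sample, matched by sample id (order-free join).

        Raises if any sample is unlabeled or any label refers to a sample
        absent from ``sample_ids``.
        """
        sample_set = set(sample_ids)
        unlabeled = sorted(sample_set - set(self.labels))
        if unlabeled:
            raise ValueError(f"samples without class label: {', '.join(unlabeled)}")
        extra = sorted(set(self.labels) - sample_set)
        if extra:
            raise ValueError(f"labels for samples absent from matrix: {', '.join(extra)}")
        pos = {c: i for i, c in enumerate(self.classes)}
        return np.fromiter((pos[self.labels[s]] for s in sample_ids), dtype=np.intp, count=len(sample_ids))


@dataclass(frozen=True)
class SwissResult:
    """SWISS score together with its ANOVA-style decomposition.

    ``contributions`` holds each sample's standardized within-class term
    ``||x_j - class_mean(j)||^2 / SST`` in ``sample_ids`` order; the
    contributions are nonnegative and sum to ``swiss``.  This per-sample
    decomposition is what the permutation test resamples.
    """

    sst: float
    wiss: float
    swiss: float
    overall_mean: np.ndarray
    class_means: np.ndarray
    classes: tuple[str, ...]
    sample_ids: tuple[str, ...]
    contributions: np.ndarray

    def contributions_by_sample(self) -> dict[str, float]:
        return {s: float(c) for s, c in zip(self.sample_ids, self.contributions)}


def _class_stats(X: ExpressionMatrix, C: ClassAssignment) -> tuple[np.ndarray, np.ndarray]:
    """(class index per sample, k x d class-mean matrix)."""
    idx = C.indices_for(X.sample_ids)
    k = C.n_classes
    d = X.n_features
    sums = np.zeros((k, d))
    counts = np.bincount(idx, minlength=k).astype(float)
    if (counts == 0).any():
        empty = [c for c, n in zip(C.classes, counts) if n == 0]
        raise ValueError(f"empty class(es): {', '.join(empty)}")
    np.add.at(sums, idx, X.values.T)
    return idx, sums / counts[:, None]


def total_sum_of_squares(X: ExpressionMatrix) -> float:
    """Sum over samples of squared Euclidean distance to the overall mean.

    Computed two-pass (mean first, then squared deviations) to avoid the
    catastrophic cancellation of the one-pass ``sum(x^2) - N*m^2`` form.
    """
    mean = X.values.mean(axis=1, keepdims=True)
    return float(((X.values - mean) ** 2).sum())


def within_class_sum_of_squares(X: ExpressionMatrix, C: ClassAssignment) -> float:
    """Sum over classes of squared distances of members to the class mean."""
    idx, class_means = _class_stats(X, C)
    dev = X.values - class_means[idx].T
    return float((dev**2).sum())


def swiss_score(X: ExpressionMatrix, C: ClassAssignment) -> SwissResult:
    """Compute SWISS = WISS / SST with the per-sample decomposition.

    Raises if SST is zero (all sample columns identical), in which case
    the score is undefined.  Singleton classes are permitted — labelings
    derived from clustering can produce them — but a warning is emitted
    because a singleton contributes 0 to WISS and so deflates the score.
    """
    overall_mean = X.values.mean(axis=1)
    sst = float(((X.values - overall_mean[:, None]) ** 2).sum())
    if sst == 0.0:
        raise ValueError("SWISS undefined: zero total variation (all samples identical)")
    idx, class_means = _class_stats(X, C)
    counts = np.bincount(idx, minlength=C.n_classes)
    singletons = [c for c, n in zip(C.classes, counts) if n == 1]
    if singletons:
        warnings.warn(
            "singleton class(es) "
            + ", ".join(singletons)
            + ": they contribute 0 to WISS and deflate the SWISS score",
            UserWarning,
            stacklevel=2,
        )
    dev = X.values - class_means[idx].T
    per_sample = (dev**2).sum(axis=0)
    contributions = per_sample / sst
    wiss = float(per_sample.sum())
    # rounding in the two mean computations can push the ratio one ulp
    # past 1 (e.g. k = 1, where WISS = SST analytically); clamp to [0, 1]
    return SwissResult(
        sst=sst,
        wiss=wiss,
        swiss=min(max(wiss / sst, 0.0), 1.0),
        overall_mean=overall_mean,
        class_means=class_means,
        classes=C.classes,
        sample_ids=X.sample_ids,
        contributions=contributions,
    )
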