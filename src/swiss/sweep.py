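"""Variance-filtering sweeps: SWISS as a function of gene-set size.

Filtering to the genes with the largest across-sample variances is a
common preprocessing step, and SWISS can quantify its effect: compute
the score after keeping the top ``m`` features for a grid of ``m``
values (by default powers of two from 16 up to the full feature count).
With two methods, an optional permutation test at every level yields a
90% confidence band and a per-level verdict.

When the two methods share a gene universe, the ranking can be taken
from one method and applied to both (``ranking="a"`` / ``"b"``), so both
curves are computed on identical gene sets; with
``ranking="independent"`` each method keeps its own top-variance genes,
and the retained sets may differ.  Curves over a shared gene set tend to
move together level-by-level; divergent shapes under independent
rankings signal that the methods disagree about which genes vary most.

A warning against over-interpretation: the sweep describes how filtering
affects class separation — it is not a gene-set selector, and picking
the ``m`` that minimizes SWISS would overfit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ClassAssignment, ExpressionMatrix, swiss_score
from .permutation import MethodPair, PermutationReport, permutation_test

__all__ = ["SweepResult", "rank_features_by_variance", "default_count_grid", "swiss_sweep"]


def rank_features_by_variance(X: ExpressionMatrix) -> list[str]:
    """Feature ids sorted by decreasing across-sample variance.

    Variance is the unbiased (N-1 divisor) sample variance; ties break
    deterministically by feature id ascending.  Requires N >= 2.
    """
    if X.n_samples < 2:
        raise ValueError("variance ranking needs at least 2 samples")
    var = X.values.var(axis=1, ddof=1)
    order = sorted(range(X.n_features), key=lambda i: (-var[i], X.feature_ids[i]))
    return [X.feature_ids[i] for i in order]


def default_count_grid(d: int) -> list[int]:
    """Doubling grid 16, 32, 64, ... below d, always ending with d."""
    counts = []
    m = 16
    while m < d:
        counts.append(m)
        m *= 2
    counts.append(d)
    return counts


@dataclass(frozen=True)
class SweepResult:
    """SWISS per (method, retained-gene count), with optional CI bands."""

    counts: tuple[int, ...]
    method_names: tuple[str, ...]
    scores: dict[str, tuple[float, ...]]  # method name -> one SWISS per count
    ranking_source: str
    ci90: Optional[dict[int, tuple[float, float]]] = None
    verdicts: Optional[dict[int, str]] = None
    seed: Optional[int] = None
    B: Optional[int] = None

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: method, count, swiss [, ci_lo, ci_hi, verdict]."""
        rows = []
        for name in self.method_names:
            for count, score in zip(self.counts, self.scores[name]):
                row = {"method": name, "count": count, "swiss": score}
                if self.ci90 is not None:
                    row["ci_lo"], row["ci_hi"] = self.ci90[count]
                    row["verdict"] = self.verdicts[count]
                rows.append(row)
        return pd.DataFrame(rows)


def _count_seed(master: int, count: int) -> int:
    # independent substream per gene count: adding grid points never
    # perturbs the tests at other counts
    ss = np.random.SeedSequence(entropy=master, spawn_key=(count,))
    return int(ss.generate_state(1)[0] % (2**31))


def swiss_sweep(
    methods: Sequence[tuple[str, ExpressionMatrix]],
    labels: ClassAssignment,
    counts: Optional[Sequence[int]] = None,
    ranking: str = "independent",
    with_ci: bool = False,
    B: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> SweepResult:
    """Compute SWISS across a grid of top-variance gene counts.

    Parameters
    ----------
    methods
        One or two ``(name, matrix)`` pairs over the same samples.
    counts
        Gene counts to evaluate; defaults to the doubling grid of each
        method's full feature count.  Every count must be <= the feature
        count of every matrix it is applied to.
    ranking
        ``"independent"`` (each matrix ranked by its own variances) or
        ``"a"`` / ``"b"`` (the first / second method's ranking applied
        to both matrices; every retained gene must exist in both).
    with_ci
        With two methods, run a permutation test at every count and
        record the null 90% CI and verdict (seeded per count from
        ``seed``).
    """
    if len(methods) not in (1, 2):
        raise ValueError("swiss_sweep takes one or two methods")
    if ranking not in ("independent", "a", "b"):
        raise ValueError(f"ranking must be 'independent', 'a' or 'b', got {ranking!r}")
    if ranking == "b" and len(methods) < 2:
        raise ValueError("ranking 'b' requires a second method")
    names = tuple(name for name, _ in methods)
    if len(set(names)) != len(names):
        raise ValueError("method names must be distinct")
    mats = {name: mat for name, mat in methods}

    d_min = min(mat.n_features for mat in mats.values())
    if counts is None:
        counts = default_count_grid(d_min)
    counts = sorted(int(c) for c in counts)
    if counts and counts[0] < 1:
        raise ValueError("gene counts must be >= 1")
    for name, mat in mats.items():
        too_big = [c for c in counts if c > mat.n_features]
        if too_big:
            raise ValueError(
                f"count(s) {too_big} exceed the {mat.n_features} features of method {name!r}"
            )

    if ranking == "independent":
        rankings = {name: rank_features_by_variance(mat) for name, mat in mats.items()}
    else:
        source = names[0] if ranking == "a" else names[1]
        shared = rank_features_by_variance(mats[source])
        for name, mat in mats.items():
            missing = sorted(set(shared[: max(counts)]) - set(mat.feature_ids))
            if missing:
                raise ValueError(
                    f"shared-ranking feature(s) missing from method {name!r}: " + ", ".join(missing)
                )
        rankings = {name: shared for name in mats}

    scores: dict[str, list[float]] = {name: [] for name in names}
    restricted: dict[int, dict[str, ExpressionMatrix]] = {}
    for count in counts:
        restricted[count] = {}
        for name, mat in mats.items():
            sub = mat.restrict_features(rankings[name][:count])
            restricted[count][name] = sub
            scores[name].append(swiss_score(sub, labels).swiss)

    ci90 = verdicts = None
    resolved_seed = None
    if with_ci:
        if len(methods) != 2:
            raise ValueError("confidence bands require exactly two methods")
        resolved_seed = seed if seed is not None else int(np.random.SeedSequence().entropy % (2**31))
        ci90, verdicts = {}, {}
        for count in counts:
            pair = MethodPair(
                restricted[count][names[0]], restricted[count][names[1]], labels, names[0], names[1]
            )
            report = permutation_test(pair, B=B, alpha=alpha, seed=_count_seed(resolved_seed, count))
            ci90[count] = report.ci90
            verdicts[count] = report.verdict

    return SweepResult(
        counts=tuple(counts),
        method_names=names,
        scores={name: tuple(vals) for name, vals in scores.items()},
        ranking_source={"independent": "per_method_independent", "a": f"from_method_{names[0]}",
                        "b": f"from_method_{names[1] if len(names) > 1 else 'b'}"}[ranking],
        ci90=ci90,
        verdicts=verdicts,
        seed=resolved_seed,
        B=B if with_ci else None,
    )
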