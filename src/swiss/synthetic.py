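"""Seeded synthetic expression data with known class structure.

Generates K-class Gaussian datasets in the spirit of the classic
two-cluster, two-dimensional toy picture: a handful of *informative*
features whose class means are spaced ``delta`` apart (class *i*'s mean
is ``i * delta`` on every informative axis), plus *noise* features that
are mean-zero for every class — modelling genes with little variation
across samples, as opposed to differentially expressed genes.  All
features share a within-class standard deviation ``sigma``, and the
whole matrix can be multiplied by a global ``scale`` to exercise SWISS's
cross-scale comparability.

Defaults describe a moderately separated two-class experiment of 40
samples with 10 informative and 90 noise genes — large enough for the
permutation machinery to be exercised realistically, small enough for
fast simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .core import ClassAssignment, ExpressionMatrix

__all__ = ["SimulationDesign", "simulate"]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of a synthetic K-class Gaussian expression dataset.

    Parameters
    ----------
    k
        Number of classes (>= 1).
    n_per_class
        Samples per class: a single int (balanced) or one int per class.
    d_informative, d_noise
        Counts of class-separating and pure-noise features;
        ``d_informative + d_noise >= 1``.
    delta
        Distance between adjacent class means along each informative
        axis, in expression units (0 = labels carry no information).
    sigma
        Within-class standard deviation, shared by all features (> 0).
    scale
        Global multiplier applied to the final matrix.
    seed
        RNG seed; outputs are bit-reproducible given the design.
    """

    k: int = 2
    n_per_class: Union[int, Sequence[int]] = 20
    d_informative: int = 10
    d_noise: int = 90
    delta: float = 2.0
    sigma: float = 1.0
    scale: float = 1.0
    seed: int = 0

    def class_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_class, int):
            return (self.n_per_class,) * self.k
        sizes = tuple(int(n) for n in self.n_per_class)
        if len(sizes) != self.k:
            raise ValueError(f"{len(sizes)} class sizes for k = {self.k}")
        return sizes

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.d_informative < 0 or self.d_noise < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.d_informative + self.d_noise < 1:
            raise ValueError("need at least one feature")
        if any(n < 1 for n in self.class_sizes()):
            raise ValueError("every class needs at least one sample")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.scale == 0:
            raise ValueError("scale must be nonzero")


def simulate(design: SimulationDesign) -> tuple[ExpressionMatrix, ClassAssignment]:
    """Draw one dataset from ``design``.

    Returns a features x samples :class:`~swiss.core.ExpressionMatrix`
    (informative rows ``inf0001...``, noise rows ``noise0001...``;
    samples ``s0001...`` grouped by class ``C1..Ck``) and the matching
    :class:`~swiss.core.ClassAssignment`.
    """
    design.validate()
    sizes = design.class_sizes()
    n = sum(sizes)
    d = design.d_informative + design.d_noise
    rng = np.random.default_rng(design.seed)

    class_idx = np.repeat(np.arange(design.k), sizes)
    means = np.zeros((d, n))
    # class i sits at offset i*delta on every informative axis
    means[: design.d_informative, :] = class_idx[None, :] * design.delta
    values = design.scale * (means + rng.normal(0.0, design.sigma, size=(d, n)))

    width_f = len(str(max(d, 1)))
    feature_ids = [f"inf{i + 1:0{width_f}d}" for i in range(design.d_informative)] + [
        f"noise{i + 1:0{width_f}d}" for i in range(design.d_noise)
    ]
    width_s = len(str(n))
    sample_ids = [f"s{j + 1:0{width_s}d}" for j in range(n)]
    labels = ClassAssignment.from_pairs(
        (sid, f"C{ci + 1}") for sid, ci in zip(sample_ids, class_idx)
    )
    return ExpressionMatrix(values, tuple(feature_ids), tuple(sample_ids)), labels
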