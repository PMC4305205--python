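"""Allele-score instruments.

A single allele score collapses ``J`` genotype columns into one instrument:
the unweighted score ``S_i = sum_j G_ij`` counts trait-increasing alleles,
the weighted score ``S_i = sum_j w_j G_ij`` scales each variant by an
externally estimated per-allele effect (e.g. published GWAS coefficients).
Using a score as the single instrument in 2SLS sidesteps the many-weak-
instrument bias at the cost of imposing the weights.

Weights are taken as given: re-estimating them on the analysis sample would
reintroduce the overfitting that external weights avoid.  (If in-sample
first-stage coefficients *are* supplied as weights, score-IV reproduces the
full-instrument 2SLS estimate exactly -- a useful algebraic check, not a
recommended analysis.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataValidationError

__all__ = ["GenotypeMatrix", "unweighted_score", "weighted_score", "standardize"]


@dataclass
class GenotypeMatrix:
    """Additively coded genotypes (0/1/2 trait-increasing allele counts).

    Attributes
    ----------
    G : ndarray (n, J) of integers in {0, 1, 2}
    variant_ids : list of str, length J
    weights : optional ndarray (J,) of external per-allele effects
    """

    G: np.ndarray
    variant_ids: list
    weights: np.ndarray | None = None

    def __post_init__(self):
        G = np.asarray(self.G)
        if G.ndim != 2:
            raise DataValidationError("genotype matrix must be 2-dimensional")
        if not np.all(np.isin(G, (0, 1, 2))):
            bad = np.argwhere(~np.isin(G, (0, 1, 2)))[0]
            raise DataValidationError(
                f"genotype entry at row {bad[0]}, column {bad[1]} is "
                f"{G[tuple(bad)]!r}; entries must be 0, 1 or 2")
        self.G = G.astype(np.int64)
        if self.variant_ids is None:
            self.variant_ids = [f"v{j+1}" for j in range(G.shape[1])]
        self.variant_ids = list(self.variant_ids)
        if len(self.variant_ids) != G.shape[1]:
            raise DataValidationError("variant_ids length must equal J")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=np.float64)
            if w.shape != (G.shape[1],) or not np.all(np.isfinite(w)):
                raise DataValidationError(
                    "weights must be a finite vector of length J")
            self.weights = w

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def J(self) -> int:
        return self.G.shape[1]


def unweighted_score(gm: GenotypeMatrix) -> np.ndarray:
    """Per-individual count of trait-increasing alleles, ``sum_j G_ij``."""
    return gm.G.sum(axis=1).astype(np.float64)


def weighted_score(gm: GenotypeMatrix) -> np.ndarray:
    """Externally weighted allele score ``sum_j w_j G_ij``."""
    if gm.weights is None:
        raise DataValidationError(
            "no weights attached to this GenotypeMatrix; "
            "use unweighted_score or supply weights")
    return gm.G @ gm.weights


def standardize(x) -> np.ndarray:
    """Scale to mean zero and unit sample standard deviation (n-1 denominator).

    IV estimates with a score instrument are invariant to this rescaling; it
    only eases interpretation of first-stage coefficients.
    """
    x = np.asarray(x, dtype=np.float64)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DataValidationError("cannot standardize a constant vector")
    return (x - x.mean()) / sd
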