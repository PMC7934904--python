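"""Principal coordinates analysis and the shared trait space.

All communities, species pools and extirpated species are ordinated
*once*, in a single PCoA of the Gower dissimilarities over the union of
species.  This preserves total inertia and guarantees that the same
species occupies the same point in trait space in every assemblage, so
per-site functional diversity values are directly comparable.

Gower dissimilarities of mixed trait data are generally non-Euclidean and
produce negative PCoA eigenvalues; the available corrections are

* ``sqrt``  — ordinate the elementwise square root of the dissimilarities
  (default; sqrt-Gower is Euclidean for many mixed tables),
* ``cailliez`` — add the smallest additive constant to off-diagonal
  dissimilarities that makes them Euclidean,
* ``lingoes`` — add a constant to the *squared* dissimilarities,
* ``none`` — keep only the non-negative-eigenvalue axes.

Coordinates are scaled so that the sum of squares on axis k equals the
k-th eigenvalue (the standard principal-coordinate scaling: Euclidean
distances in the full retained space reproduce the corrected input
dissimilarities).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .gower import GowerDistance
from .traits import TraitTable, concat_trait_tables

CORRECTIONS = ("none", "sqrt", "cailliez", "lingoes")

#: Default number of axes for convex-hull functional richness.
DEFAULT_M_FRIC = 3


def _validate_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 species")
    if not np.isfinite(d).all():
        raise ValueError("dissimilarities must be finite")
    if np.abs(d - d.T).max() > 1e-12:
        raise ValueError("dissimilarity matrix is not symmetric (tolerance 1e-12)")
    if np.abs(np.diag(d)).max() > 0:
        raise ValueError("dissimilarity matrix has nonzero diagonal")
    if d.max() == 0:
        raise ValueError("degenerate trait table: all dissimilarities are zero")
    return 0.5 * (d + d.T)


def _gower_center(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ m @ j


def cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making ``d + c`` (off-diagonal) Euclidean."""
    n = d.shape[0]
    d1 = _gower_center(-0.5 * d**2)
    d2 = _gower_center(-0.5 * d)
    sp = np.block([[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]])
    eig = scipy.linalg.eigvals(sp)
    return float(max(eig.real.max(), 0.0))


def lingoes_constant(d: np.ndarray) -> float:
    """Smallest constant c with sqrt(d^2 + 2c) Euclidean (off-diagonal)."""
    b = _gower_center(-0.5 * d**2)
    lam_min = float(scipy.linalg.eigvalsh(b).min())
    return max(-lam_min, 0.0)


class PCoA(TransformerMixin, BaseEstimator):
    """Principal coordinates analysis with negative-eigenvalue corrections.

    Parameters
    ----------
    correction : {"sqrt", "cailliez", "lingoes", "none"}
        How to handle non-Euclidean input (see module docstring).
        ``cailliez``/``lingoes`` constants are only applied when the
        uncorrected decomposition actually has a negative eigenvalue.
    eig_rtol : float
        Axes with eigenvalue below ``eig_rtol * max_eigenvalue`` are
        dropped as numerically null.

    Attributes
    ----------
    coordinates_ : DataFrame, species x retained axes (``axis_1`` ...).
    eigenvalues_ : ndarray of retained (non-negative) eigenvalues.
    negative_inertia_ : sum of negative eigenvalues before correction.
    correction_constant_ : additive constant used (0 when not applied).
    """

    def __init__(self, correction: str = "sqrt", eig_rtol: float = 1e-9):
        self.correction = correction
        self.eig_rtol = eig_rtol

    def fit(self, X, y=None) -> "PCoA":
        if self.correction not in CORRECTIONS:
            raise ValueError(f"unknown correction {self.correction!r}; choose from {CORRECTIONS}")
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
        d = _validate_dissimilarity(np.asarray(X, dtype=float))

        raw_eigs = scipy.linalg.eigvalsh(_gower_center(-0.5 * d**2))
        self.negative_inertia_ = float(raw_eigs[raw_eigs < 0].sum())

        self.correction_constant_ = 0.0
        dc = d
        if self.correction == "sqrt":
            dc = np.sqrt(d)
        elif self.correction == "cailliez" and raw_eigs.min() < -self.eig_rtol * raw_eigs.max():
            c = cailliez_constant(d)
            self.correction_constant_ = c
            dc = d + c
            np.fill_diagonal(dc, 0.0)
        elif self.correction == "lingoes" and raw_eigs.min() < -self.eig_rtol * raw_eigs.max():
            c = lingoes_constant(d)
            self.correction_constant_ = c
            dc = np.sqrt(d**2 + 2.0 * c)
            np.fill_diagonal(dc, 0.0)

        b = _gower_center(-0.5 * dc**2)
        eigval, eigvec = scipy.linalg.eigh(b)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        keep = eigval > self.eig_rtol * max(eigval.max(), 0.0)
        if not keep.any():
            raise ValueError("degenerate trait table: no positive eigenvalues")
        eigval, eigvec = eigval[keep], eigvec[:, keep]
        coords = eigvec * np.sqrt(eigval)

        self.eigenvalues_ = eigval
        self.coordinates_ = pd.DataFrame(
            coords, index=index, columns=[f"axis_{k + 1}" for k in range(coords.shape[1])]
        )
        return self

    def transform(self, X=None) -> pd.DataFrame:
        return self.coordinates_

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).coordinates_


def pcoa(d, correction: str = "sqrt") -> PCoA:
    """Functional wrapper: fit a :class:`PCoA` on a dissimilarity matrix."""
    return PCoA(correction=correction).fit(d)


@dataclasses.dataclass
class OrdinationSpace:
    """Shared low-dimensional trait space for all assemblages.

    ``coordinates`` holds one row per species of the full union; every
    community, pool or extirpated-species list is a row subset, so a
    species has identical coordinates wherever it occurs.  ``m_fric`` is
    the number of leading axes used for convex-hull volumes.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    correction: str
    m_fric: int = DEFAULT_M_FRIC
    correction_constant: float = 0.0
    negative_inertia: float = 0.0

    @property
    def species(self) -> pd.Index:
        return self.coordinates.index

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def coords_for(self, species: Sequence[str], m: int | None = None) -> np.ndarray:
        """Coordinates of ``species`` on the first ``m`` axes (all if None)."""
        species = list(species)
        missing = [s for s in species if s not in self.coordinates.index]
        if missing:
            raise KeyError(f"species absent from ordination space: {missing}")
        coords = self.coordinates.loc[species]
        if m is not None:
            if m > self.n_axes:
                raise ValueError(f"requested {m} axes but only {self.n_axes} retained")
            coords = coords.iloc[:, :m]
        return coords.to_numpy(float)


def build_shared_space(
    tables: TraitTable | Iterable[TraitTable],
    equalize_traits: bool = True,
    binary: str = "symmetric",
    correction: str = "sqrt",
    m_fric: int = DEFAULT_M_FRIC,
    log_mass: bool = False,
) -> OrdinationSpace:
    """Ordinate the deduplicated species union into one shared trait space.

    ``tables`` may be a single :class:`TraitTable` or several (site,
    pool and extirpated-species tables); duplicates with conflicting
    trait rows raise an error listing the conflicts.  ``log_mass``
    enters body mass as log10(kg) before the Gower computation.
    """
    if isinstance(tables, TraitTable):
        union = tables
    else:
        union = concat_trait_tables(*tables)
    data = union.data.copy()
    if log_mass:
        data["mass"] = np.log10(data["mass"])
    dist = GowerDistance(equalize_traits=equalize_traits, binary=binary)
    d = dist.fit_transform(data)
    model = PCoA(correction=correction).fit(d)
    if m_fric < 1:
        raise ValueError("m_fric must be >= 1")
    return OrdinationSpace(
        coordinates=model.coordinates_,
        eigenvalues=model.eigenvalues_,
        correction=correction,
        m_fric=min(m_fric, model.coordinates_.shape[1]),
        correction_constant=model.correction_constant_,
        negative_inertia=model.negative_inertia_,
    )
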