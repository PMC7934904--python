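"""Community functional-diversity metrics in the shared trait space.

Two complementary metrics are computed per site:

* **Functional dispersion (FDis)** — the (optionally occupancy-weighted)
  mean distance of community members to their weighted centroid over all
  retained ordination axes.  Weighting by occupancy makes abundant
  species pull the centroid toward themselves and contribute more to the
  mean, so FDis responds to how function is distributed among
  individuals, not just which functions are present.
* **Functional richness (FRic)** — the volume of the convex hull of the
  community on the first ``m`` ordination axes.  FRic is presence-based
  by construction (a hull cannot weight its vertices).

Local extinction impact is the hull-volume difference between the
current community plus its recently extirpated species and the current
community alone; redundant (interior) species can be lost with zero
impact, while hull-vertex species (top predators, large specialists)
shrink the occupied trait volume when extirpated.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .ordination import OrdinationSpace

REGIONS = ("Neotropics", "Africa", "Asia", "Madagascar")


@dataclasses.dataclass
class Community:
    """Realized community of one site with per-species occupancy weights."""

    site_id: str
    members: list[str]
    occupancy: pd.Series  # indexed by species_id, values in (0, 1]
    region: str = "Neotropics"

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"site {self.site_id!r}: community has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"site {self.site_id!r}: duplicate members")
        if self.region not in REGIONS:
            raise ValueError(f"site {self.site_id!r}: unknown region {self.region!r}")
        self.occupancy = pd.Series(self.occupancy, dtype=float).reindex(self.members)
        a = self.occupancy.to_numpy()
        if np.isnan(a).any():
            missing = self.occupancy.index[np.isnan(a)].tolist()
            raise ValueError(f"site {self.site_id!r}: missing occupancy for {missing}")
        if not np.isfinite(a).all() or (a <= 0).any() or (a > 1).any():
            raise ValueError(f"site {self.site_id!r}: occupancies must lie in (0, 1]")


@dataclasses.dataclass
class ExtirpationRecord:
    """Recently extirpated species of one site (disjoint from its members)."""

    site_id: str
    extirpated: list[str]


@dataclasses.dataclass
class FDResult:
    site_id: str
    region: str
    fdis_weighted: float
    fdis_unweighted_realized: float
    fdis_unweighted_pool: float
    fric: float
    pool_fric: float
    fric_with_extirpated: float
    delta_fric: float
    percent_loss: float
    m_axes: int
    flags: str = ""


def weighted_dispersion(coords: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted mean distance to the weighted centroid.

    ``coords`` is an (n, m) array; ``weights`` need only be relative
    (they are normalized internally).  A single point has dispersion 0.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if weights is None:
        weights = np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must align with coordinate rows")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    w = w / w.sum()
    centroid = w @ coords
    dist = np.linalg.norm(coords - centroid, axis=1)
    return float(w @ dist)


def functional_dispersion(
    space: OrdinationSpace, community: Community, use_weights: bool = True
) -> float:
    """FDis of a community over all retained ordination axes."""
    coords = space.coords_for(community.members)
    if len(community.members) == 1:
        warnings.warn(
            f"site {community.site_id!r}: single-member community has FDis 0", stacklevel=2
        )
        return 0.0
    w = community.occupancy.to_numpy() if use_weights else None
    return weighted_dispersion(coords, w)


def hull_volume(coords: np.ndarray) -> float:
    """Convex-hull volume of an (n, m) point set; 0 for degenerate sets."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    try:
        return float(ConvexHull(coords).volume)
    except QhullError:
        warnings.warn("degenerate (flat) point set; hull volume reported as 0", stacklevel=2)
        return 0.0


def functional_richness(
    space: OrdinationSpace, members: Sequence[str], m: int | None = None
) -> float:
    """FRic: convex-hull volume of ``members`` on the first ``m`` axes.

    Exact duplicate coordinates are collapsed before the hull is built;
    fewer than m+1 distinct points cannot span an m-volume and raise an
    error instructing the caller to lower ``m``.
    """
    m = space.m_fric if m is None else m
    coords = space.coords_for(list(dict.fromkeys(members)), m=m)
    coords = np.unique(coords, axis=0)
    if len(coords) <= m:
        raise ValueError(
            f"functional richness on {m} axes needs at least {m + 1} distinct species "
            f"(got {len(coords)}); lower m"
        )
    return hull_volume(coords)


def species_pool_richness(
    space: OrdinationSpace, pool_members: Sequence[str], m: int | None = None
) -> float:
    """FRic of the species pool (same computation as the realized community)."""
    return functional_richness(space, pool_members, m=m)


def extinction_impact(
    space: OrdinationSpace,
    community: Community,
    extirpation: ExtirpationRecord,
    m: int | None = None,
) -> tuple[float, float]:
    """Hull-volume loss attributable to recent local extinctions.

    Returns ``(delta_fric, percent_loss)`` where ``delta_fric`` is
    FRic(members + extirpated) - FRic(members) (clipped at 0 against
    rounding) and ``percent_loss`` expresses it as a percentage of the
    pre-extirpation volume.  Sites with no recorded extirpations score
    (0, 0); extirpated species strictly inside the current hull
    contribute nothing (functional redundancy).
    """
    if extirpation.site_id != community.site_id:
        raise ValueError(
            f"site mismatch: community {community.site_id!r} vs "
            f"extirpation record {extirpation.site_id!r}"
        )
    overlap = set(extirpation.extirpated) & set(community.members)
    if overlap:
        raise ValueError(
            f"site {community.site_id!r}: extirpated species still listed as "
            f"members: {sorted(overlap)}"
        )
    if not extirpation.extirpated:
        return 0.0, 0.0
    fric_now = functional_richness(space, community.members, m=m)
    fric_whole = functional_richness(
        space, list(community.members) + list(extirpation.extirpated), m=m
    )
    delta = max(fric_whole - fric_now, 0.0)
    percent = 100.0 * delta / fric_whole if fric_whole > 0 else 0.0
    return delta, percent


def unweighted_dispersion_variants(
    space: OrdinationSpace, community: Community, pool_members: Sequence[str]
) -> tuple[float, float]:
    """Presence-only FDis of the realized community and of its species pool."""
    fdis_realized = functional_dispersion(space, community, use_weights=False)
    pool = list(dict.fromkeys(pool_members))
    if len(pool) == 1:
        warnings.warn(f"site {community.site_id!r}: single-species pool has FDis 0", stacklevel=2)
        fdis_pool = 0.0
    else:
        fdis_pool = weighted_dispersion(space.coords_for(pool))
    return fdis_realized, fdis_pool


def fd_table(
    space: OrdinationSpace,
    communities: Sequence[Community],
    pools: dict[str, Sequence[str]],
    extirpations: Sequence[ExtirpationRecord] = (),
    m: int | None = None,
) -> pd.DataFrame:
    """Per-site functional-diversity table for downstream regression.

    Columns: region, weighted and presence-only FDis (realized and pool),
    FRic, pool FRic, pre-extirpation FRic, delta FRic, percent loss,
    number of hull axes, and a flags field noting degenerate hulls.
    """
    m = space.m_fric if m is None else m
    ext_by_site = {e.site_id: e for e in extirpations}
    rows = []
    for comm in communities:
        if comm.site_id not in pools:
            raise KeyError(f"no species pool for site {comm.site_id!r}")
        pool = list(pools[comm.site_id])
        if not set(comm.members) <= set(pool):
            extra = sorted(set(comm.members) - set(pool))
            raise ValueError(f"site {comm.site_id!r}: members outside the pool: {extra}")
        ext = ext_by_site.get(comm.site_id, ExtirpationRecord(comm.site_id, []))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fdis_w = functional_dispersion(space, comm, use_weights=True)
            fdis_r, fdis_p = unweighted_dispersion_variants(space, comm, pool)
            fric = functional_richness(space, comm.members, m=m)
            pool_fric = species_pool_richness(space, pool, m=m)
            delta, percent = extinction_impact(space, comm, ext, m=m)
        flags = ";".join(sorted({str(w.message) for w in caught}))
        rows.append(
            FDResult(
                site_id=comm.site_id,
                region=comm.region,
                fdis_weighted=fdis_w,
                fdis_unweighted_realized=fdis_r,
                fdis_unweighted_pool=fdis_p,
                fric=fric,
                pool_fric=pool_fric,
                fric_with_extirpated=fric + delta,
                delta_fric=delta,
                percent_loss=percent,
                m_axes=m,
                flags=flags,
            )
        )
    out = pd.DataFrame([dataclasses.asdict(r) for r in rows]).set_index("site_id")
    return out
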