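"""Functional-trait coding for terrestrial mammal communities.

Species are described by six trait groups — body mass, diet composition,
sociality, substrate use, activity period, litter size — encoded into a
13-column mixed continuous/binary matrix:

* ``mass`` (kg, continuous, > 0)
* five diet binaries (graze, browse, fruit/seed, invertebrates,
  vertebrates), 1 iff the category exceeds 25% of the average diet
* ``social`` (1 if social, 0 if found solitarily or in pairs)
* ``substrate`` (1 if able to climb, 0 if strictly terrestrial)
* three activity-period binaries (diurnal, crepuscular, nocturnal),
  1 iff the species is consistently active in that period
* ``litter_size`` (continuous, >= 0)

Column weights for the Gower dissimilarity are assigned per group so that
each of the six groups contributes equally (weight 1/6 split evenly over a
group's columns), or uniformly per column as a sensitivity variant.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DIET_CATEGORIES: tuple[str, ...] = (
    "graze",
    "browse",
    "fruit_seed",
    "invertebrates",
    "vertebrates",
)
ACTIVITY_PERIODS: tuple[str, ...] = ("diurnal", "crepuscular", "nocturnal")

#: Diet binaries are 1 strictly above this percentage of the average diet.
DIET_THRESHOLD_PCT: float = 25.0

TRAIT_GROUPS: dict[str, str] = {
    "mass": "mass",
    **{f"diet_{c}": "diet" for c in DIET_CATEGORIES},
    "social": "social",
    "substrate": "substrate",
    **{f"activity_{p}": "activity" for p in ACTIVITY_PERIODS},
    "litter_size": "litter",
}
TRAIT_COLUMNS: tuple[str, ...] = tuple(TRAIT_GROUPS)
GROUPS: tuple[str, ...] = ("mass", "diet", "social", "substrate", "activity", "litter")
CONTINUOUS_COLUMNS: tuple[str, ...] = ("mass", "litter_size")
BINARY_COLUMNS: tuple[str, ...] = tuple(
    c for c in TRAIT_COLUMNS if c not in CONTINUOUS_COLUMNS
)

_SOCIAL_TRUE = {"social", "group", "gregarious", "group-living"}
_SOCIAL_FALSE = {"solitary", "pairs", "solitary_or_pairs", "solitarily or in pairs", "asocial"}
_CLIMB_TRUE = {"scansorial", "climbs", "climber", "semi-arboreal"}
_CLIMB_FALSE = {"terrestrial", "ground", "ground-dwelling"}


class TraitValidationError(ValueError):
    """Raised when a trait record or table violates the coding contract."""


@dataclasses.dataclass
class TraitTable:
    """Encoded species-by-trait matrix with group metadata.

    ``data`` is indexed by unique ``species_id`` and holds exactly the 13
    columns of :data:`TRAIT_COLUMNS`; binary columns take values in {0, 1},
    mass is finite and positive, litter size finite and non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.validate()

    @property
    def species(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        df = self.data
        missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
        if missing:
            raise TraitValidationError(f"missing trait columns: {missing}")
        self.data = df = df.loc[:, list(TRAIT_COLUMNS)].astype(float)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TraitValidationError(f"duplicate species_id values: {dups}")
        if not np.isfinite(df.to_numpy()).all():
            raise TraitValidationError("trait values must be finite")
        for col in BINARY_COLUMNS:
            if not df[col].isin([0.0, 1.0]).all():
                raise TraitValidationError(f"binary column {col!r} has values outside {{0,1}}")
        if (df["mass"] <= 0).any():
            bad = df.index[df["mass"] <= 0].tolist()
            raise TraitValidationError(f"non-positive body mass for species: {bad}")
        if (df["litter_size"] < 0).any():
            bad = df.index[df["litter_size"] < 0].tolist()
            raise TraitValidationError(f"negative litter size for species: {bad}")

    def subset(self, species: Iterable[str]) -> "TraitTable":
        species = list(species)
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise KeyError(f"species absent from trait table: {missing}")
        return TraitTable(self.data.loc[species])


def concat_trait_tables(*tables: TraitTable) -> TraitTable:
    """Union of trait tables deduplicated by species_id.

    Species appearing in several tables must carry identical trait rows;
    conflicting duplicates are an error listing the offending species.
    """
    frames = [t.data for t in tables]
    merged = pd.concat(frames)
    conflicts = []
    for sp, grp in merged.groupby(level=0, sort=False):
        if len(grp) > 1 and not (grp.nunique(axis=0) == 1).all():
            conflicts.append(sp)
    if conflicts:
        raise TraitValidationError(
            f"conflicting trait rows for duplicated species_id: {conflicts}"
        )
    return TraitTable(merged[~merged.index.duplicated(keep="first")])


def _coerce_binary(value, true_set: set[str], false_set: set[str], field: str, species) -> float:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in true_set:
            return 1.0
        if v in false_set:
            return 0.0
        raise TraitValidationError(
            f"species {species!r}: unrecognized {field} descriptor {value!r}"
        )
    if pd.isna(value):
        raise TraitValidationError(f"species {species!r}: missing field {field!r}")
    v = float(value)
    if v not in (0.0, 1.0):
        raise TraitValidationError(f"species {species!r}: {field} must be 0/1, got {value!r}")
    return v


def encode_traits(raw: pd.DataFrame) -> TraitTable:
    """Encode raw per-species records into a :class:`TraitTable`.

    Expected raw columns (``species_id`` as column or index): ``mass``,
    ``diet_<category>`` percentages in [0, 100] for the five categories,
    ``social`` and ``substrate`` (0/1 or text descriptors),
    ``activity_<period>`` indicators, ``litter_size``.

    Diet binaries follow the strict >25% rule; a category sitting exactly
    at 25% is encoded 0 with a warning (the 1-rule requires a strict
    excess).
    """
    raw = raw.copy()
    if "species_id" in raw.columns:
        raw = raw.set_index("species_id")
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise TraitValidationError(f"duplicate species_id values: {dups}")

    required = (
        ["mass", "litter_size", "social", "substrate"]
        + [f"diet_{c}" for c in DIET_CATEGORIES]
        + [f"activity_{p}" for p in ACTIVITY_PERIODS]
    )
    out = {}
    for sp, rec in raw.iterrows():
        for field in required:
            if field not in rec.index or pd.isna(rec[field]):
                raise TraitValidationError(f"species {sp!r}: missing field {field!r}")
        row = {"mass": float(rec["mass"]), "litter_size": float(rec["litter_size"])}
        for cat in DIET_CATEGORIES:
            pct = float(rec[f"diet_{cat}"])
            if not 0.0 <= pct <= 100.0:
                raise TraitValidationError(
                    f"species {sp!r}: diet_{cat} percentage {pct} outside [0, 100]"
                )
            if pct == DIET_THRESHOLD_PCT:
                warnings.warn(
                    f"species {sp!r}: diet_{cat} is exactly {DIET_THRESHOLD_PCT}%;"
                    " encoded 0 (strict >25% rule)",
                    stacklevel=2,
                )
            row[f"diet_{cat}"] = float(pct > DIET_THRESHOLD_PCT)
        row["social"] = _coerce_binary(rec["social"], _SOCIAL_TRUE, _SOCIAL_FALSE, "social", sp)
        row["substrate"] = _coerce_binary(
            rec["substrate"], _CLIMB_TRUE, _CLIMB_FALSE, "substrate", sp
        )
        for p in ACTIVITY_PERIODS:
            row[f"activity_{p}"] = _coerce_binary(
                rec[f"activity_{p}"], {"yes", "active"}, {"no", "inactive"}, f"activity_{p}", sp
            )
        out[sp] = row
    encoded = pd.DataFrame.from_dict(out, orient="index").loc[:, list(TRAIT_COLUMNS)]
    encoded.index.name = "species_id"
    return TraitTable(encoded)


def equal_group_weights(table: TraitTable | pd.DataFrame, equalize: bool = True) -> pd.Series:
    """Per-column Gower weights.

    With ``equalize`` each of the six trait groups receives total weight
    1/6 split evenly across its columns (diet columns 1/30 each, activity
    columns 1/18 each, singletons 1/6); otherwise every column gets the
    uniform weight 1/13 (the trait-weighting sensitivity variant).
    Weights always sum to 1.
    """
    cols = list(TRAIT_COLUMNS)
    if equalize:
        counts = pd.Series(TRAIT_GROUPS).value_counts()
        w = pd.Series(
            {c: 1.0 / (len(GROUPS) * counts[TRAIT_GROUPS[c]]) for c in cols}, name="weight"
        )
    else:
        w = pd.Series(1.0 / len(cols), index=cols, name="weight")
    return w.loc[cols]


class TraitEncoder(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer wrapping :func:`encode_traits`.

    ``transform`` maps a raw record DataFrame to the encoded 13-column
    trait matrix (the ``.data`` of a :class:`TraitTable`).
    """

    def fit(self, X: pd.DataFrame, y=None) -> "TraitEncoder":
        encode_traits(X)  # validation only
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return encode_traits(X).data

    def get_feature_names_out(self, input_features=None):
        return np.asarray(TRAIT_COLUMNS, dtype=object)
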