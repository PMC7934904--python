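"""Per-site predictor assembly: habitat heterogeneity, standardization,
collinearity screening.

The regression design combines species-pool functional richness, Shannon
habitat heterogeneity (landcover-class diversity around the camera
grid), NDVI (productivity), human population density and the local
extinction impact, plus a biogeographic-region factor with the
Neotropics as reference level.  Continuous predictors are centred and
scaled (sample sd, n-1) so coefficients are standardized; pairwise
Pearson correlations are screened with a warning above |r| = 0.6.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diversity import REGIONS

CONTINUOUS_PREDICTORS = ("pool_fric", "habitat_H", "ndvi", "human_density", "extinction_delta")
CORRELATION_THRESHOLD = 0.6


def shannon_heterogeneity(class_freqs, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_k log p_k of landcover classes.

    ``class_freqs`` maps class labels to counts or proportions (any
    positive scale; normalized internally); zero-frequency classes are
    ignored.  Natural log by default (nats); pass ``base`` to change.
    """
    freqs = pd.Series(class_freqs, dtype=float)
    if len(freqs) == 0:
        raise ValueError("need at least one landcover class")
    if (freqs < 0).any():
        bad = freqs.index[freqs < 0].tolist()
        raise ValueError(f"negative class frequencies: {bad}")
    total = freqs.sum()
    if total == 0:
        raise ValueError("all class frequencies are zero")
    p = (freqs / total).to_numpy()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def standardize(
    table: pd.DataFrame, columns=CONTINUOUS_PREDICTORS
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Centre and scale continuous columns to mean 0, sd 1 (sample sd).

    Returns the standardized table and per-column scaling metadata
    (``{"mean": ..., "sd": ...}``) sufficient to invert the transform.
    Non-listed columns (e.g. the region factor) pass through untouched.
    """
    if len(table) < 2:
        raise ValueError("standardization needs at least 2 sites")
    out = table.copy()
    scaling: dict[str, dict[str, float]] = {}
    for col in columns:
        if col not in table.columns:
            raise KeyError(f"missing predictor column {col!r}")
        x = table[col].astype(float)
        if not np.isfinite(x).all():
            raise ValueError(f"non-finite values in predictor {col!r}")
        mean, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0:
            raise ValueError(f"zero-variance predictor column: {col!r}")
        out[col] = (x - mean) / sd
        scaling[col] = {"mean": mean, "sd": sd}
    return out, scaling


def unstandardize(table: pd.DataFrame, scaling: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Invert :func:`standardize` using its scaling metadata."""
    out = table.copy()
    for col, ms in scaling.items():
        out[col] = out[col].astype(float) * ms["sd"] + ms["mean"]
    return out


def correlation_screen(
    table: pd.DataFrame,
    columns=CONTINUOUS_PREDICTORS,
    threshold: float = CORRELATION_THRESHOLD,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations among continuous predictors.

    Pairs with |r| >= ``threshold`` are returned and warned about (they
    do not fail the run — collinearity widens posteriors rather than
    invalidating them).
    """
    cols = [c for c in columns if c in table.columns]
    corr = table[cols].astype(float).corr(method="pearson")
    flagged = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = float(corr.loc[a, b])
            if abs(r) >= threshold:
                flagged.append((a, b, r))
                warnings.warn(
                    f"predictors {a!r} and {b!r} are highly correlated (r = {r:.2f})",
                    stacklevel=2,
                )
    return corr, flagged


def assemble_covariates(
    fd: pd.DataFrame,
    site_covariates: pd.DataFrame,
    landcover: pd.DataFrame | None = None,
    shannon_base: float | None = None,
) -> pd.DataFrame:
    """Join FD-derived predictors with external site covariates.

    ``fd`` is the per-site table from :func:`traitdiv.diversity.fd_table`
    (supplies ``pool_fric`` and ``extinction_delta`` = delta FRic);
    ``site_covariates`` is indexed by site with ``ndvi``,
    ``human_density`` and ``region`` columns (plus optionally a
    precomputed ``habitat_H``); ``landcover`` is a long table
    (site_id, class_code, count) from which habitat heterogeneity is
    computed when given.
    """
    cov = site_covariates.copy()
    if "site_id" in cov.columns:
        cov = cov.set_index("site_id")
    missing_sites = fd.index.difference(cov.index)
    if len(missing_sites):
        raise KeyError(f"covariates missing for sites: {missing_sites.tolist()}")
    cov = cov.loc[fd.index]

    if landcover is not None:
        h = landcover.groupby("site_id").apply(
            lambda g: shannon_heterogeneity(
                pd.Series(g["count"].to_numpy(), index=g["class_code"]), base=shannon_base
            ),
            include_groups=False,
        )
        cov["habitat_H"] = h.reindex(fd.index)
    if "habitat_H" not in cov.columns or cov["habitat_H"].isna().any():
        raise ValueError("habitat_H missing for some sites (provide landcover or habitat_H)")

    for col in ("ndvi", "human_density", "region"):
        if col not in cov.columns:
            raise KeyError(f"missing site covariate {col!r}")
    bad_regions = sorted(set(cov["region"]) - set(REGIONS))
    if bad_regions:
        raise ValueError(f"unknown regions in covariates: {bad_regions}")

    out = pd.DataFrame(
        {
            "pool_fric": fd["pool_fric"],
            "habitat_H": cov["habitat_H"].astype(float),
            "ndvi": cov["ndvi"].astype(float),
            "human_density": cov["human_density"].astype(float),
            "extinction_delta": fd["delta_fric"],
            "region": pd.Categorical(cov["region"], categories=list(REGIONS)),
        },
        index=fd.index,
    )
    return out


def build_design(covariates: pd.DataFrame, reference: str = "Neotropics") -> pd.DataFrame:
    """Numeric design matrix: continuous predictors + region dummy columns.

    The reference region is absorbed into the intercept; the remaining
    regions appear as 0/1 ``region_<name>`` columns.
    """
    cont = covariates[list(CONTINUOUS_PREDICTORS)].astype(float)
    region = covariates["region"].astype(str)
    bad = sorted(set(region) - set(REGIONS))
    if bad:
        raise ValueError(f"unknown regions: {bad}")
    dummies = {}
    for r in REGIONS:
        if r == reference:
            continue
        dummies[f"region_{r}"] = (region == r).astype(float)
    return pd.concat([cont, pd.DataFrame(dummies, index=covariates.index)], axis=1)
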