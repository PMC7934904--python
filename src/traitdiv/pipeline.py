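"""End-to-end orchestration: typed CSV I/O, configuration, manifests.

The pipeline binds the stages together the way the analysis is run on
real study data: encode traits, build the single shared trait space over
the union of all realized, pool and extirpated species, compute per-site
functional diversity, assemble and standardize covariates, and fit one
Bayesian Weibull regression per response (occupancy-weighted FDis, two
presence-only FDis variants, FRic).  All randomness flows from a single
top-level seed through named substreams; a machine-readable manifest
(config hash, seed, versions) suffices to reproduce a run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import (
    CONTINUOUS_PREDICTORS,
    assemble_covariates,
    build_design,
    correlation_screen,
    standardize,
)
from .diversity import Community, ExtirpationRecord, fd_table
from .ordination import build_shared_space
from .regression import WeibullGLM, posterior_predictive_check
from .simulate import RESPONSES, SyntheticStudy, simulate_study
from .traits import TraitTable, encode_traits


class PipelineError(RuntimeError):
    """Stage failure with the stage name and offending item in the message."""


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to re-execute a run (YAML round-trippable)."""

    traits_csv: str | None = None
    communities_csv: str | None = None
    pools_csv: str | None = None
    extirpations_csv: str | None = None
    covariates_csv: str | None = None
    landcover_csv: str | None = None
    encode: bool = False  # traits_csv holds raw records needing encoding
    simulate: bool = False  # generate a synthetic study instead of reading CSVs
    n_sites: int = 15
    n_species: int = 120
    equalize_traits: bool = True
    gower_binary: str = "symmetric"
    correction: str = "sqrt"
    m_fric: int = 3
    log_mass: bool = False
    shannon_base: float | None = None
    responses: tuple[str, ...] = RESPONSES
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    out_dir: str = "traitdiv_run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis definition (the output directory is not
        part of the analysis identity)."""
        payload = {**dataclasses.asdict(self), "responses": list(self.responses)}
        payload.pop("out_dir")
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Typed CSV readers/writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_trait_csv(path, encode: bool = False) -> TraitTable:
    df = pd.read_csv(path)
    _require_columns(df, ["species_id"], path)
    if encode:
        return encode_traits(df)
    return TraitTable(df.set_index("species_id"))


def read_community_csv(path) -> list[Community]:
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "species_id", "occupancy", "region"], path)
    dup = df.duplicated(["site_id", "species_id"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based incl. header
        raise ValueError(f"{path}: duplicate (site_id, species_id) at rows {rows}")
    bad = ~(
        pd.to_numeric(df["occupancy"], errors="coerce").between(0, 1, inclusive="right")
    )
    if bad.any():
        rows = (df.index[bad] + 2).tolist()
        raise ValueError(f"{path}: occupancy outside (0, 1] at rows {rows}")
    out = []
    for site_id, grp in df.groupby("site_id", sort=True):
        regions = grp["region"].unique()
        if len(regions) != 1:
            raise ValueError(f"{path}: site {site_id!r} has conflicting regions {list(regions)}")
        occ = pd.Series(grp["occupancy"].to_numpy(float), index=grp["species_id"])
        out.append(
            Community(
                site_id=str(site_id),
                members=list(grp["species_id"]),
                occupancy=occ,
                region=str(regions[0]),
            )
        )
    return out


def read_pool_csv(path) -> dict[str, list[str]]:
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "species_id"], path)
    return {
        str(site): list(dict.fromkeys(grp["species_id"]))
        for site, grp in df.groupby("site_id", sort=True)
    }


def read_extirpation_csv(path) -> list[ExtirpationRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "species_id"], path)
    return [
        ExtirpationRecord(site_id=str(site), extirpated=list(dict.fromkeys(grp["species_id"])))
        for site, grp in df.groupby("site_id", sort=True)
    ]


def write_study_bundle(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """Write a synthetic study as the CSV bundle the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    traits = study.traits.data.reset_index()
    paths["traits_csv"] = str(out / "traits.csv")
    traits.to_csv(paths["traits_csv"], index=False)

    comm_rows = [
        {
            "site_id": c.site_id,
            "species_id": sp,
            "occupancy": float(c.occupancy[sp]),
            "region": c.region,
        }
        for c in study.communities
        for sp in c.members
    ]
    paths["communities_csv"] = str(out / "communities.csv")
    pd.DataFrame(comm_rows).to_csv(paths["communities_csv"], index=False)

    pool_rows = [
        {"site_id": site, "species_id": sp} for site, pool in study.pools.items() for sp in pool
    ]
    paths["pools_csv"] = str(out / "pools.csv")
    pd.DataFrame(pool_rows).to_csv(paths["pools_csv"], index=False)

    ext_rows = [
        {"site_id": e.site_id, "species_id": sp}
        for e in study.extirpations
        for sp in e.extirpated
    ]
    paths["extirpations_csv"] = str(out / "extirpations.csv")
    pd.DataFrame(ext_rows, columns=["site_id", "species_id"]).to_csv(
        paths["extirpations_csv"], index=False
    )

    cov = study.covariates.drop(columns=["pool_fric", "extinction_delta"]).reset_index()
    paths["covariates_csv"] = str(out / "covariates.csv")
    cov.to_csv(paths["covariates_csv"], index=False)

    paths["responses_csv"] = str(out / "responses.csv")
    study.responses.reset_index(names="site_id").to_csv(paths["responses_csv"], index=False)

    paths["truth_json"] = str(out / "truth.json")
    Path(paths["truth_json"]).write_text(json.dumps(study.truth, indent=2, sort_keys=True))
    return paths


def _write_ordination_csv(space, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# correction={space.correction}\n")
        fh.write(f"# m_fric={space.m_fric}\n")
        eigs = ",".join(repr(float(e)) for e in space.eigenvalues)
        fh.write(f"# eigenvalues={eigs}\n")
        space.coordinates.reset_index(names="species_id").to_csv(fh, index=False)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the result bundle.

    Outputs under ``config.out_dir``: ordination CSV (with eigenvalue
    header block), per-site FD CSV, standardized design CSV + scaling
    JSON, per-response regression summary JSONs, draws CSVs, credible
    interval and posterior-predictive plots, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    # -- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            study = simulate_study(
                n_sites=config.n_sites,
                n_species=config.n_species,
                seed=config.seed,
                equalize_traits=config.equalize_traits,
                correction=config.correction,
                m_fric=config.m_fric,
            )
            traits = study.traits
            communities, pools, extirpations = (
                study.communities,
                study.pools,
                study.extirpations,
            )
            site_cov = study.covariates.drop(columns=["pool_fric", "extinction_delta"])
            landcover = None
        else:
            if not (config.traits_csv and config.communities_csv and config.pools_csv):
                raise PipelineError(
                    "stage inputs: traits_csv, communities_csv and pools_csv are required "
                    "(or set simulate: true)"
                )
            traits = read_trait_csv(config.traits_csv, encode=config.encode)
            communities = read_community_csv(config.communities_csv)
            pools = read_pool_csv(config.pools_csv)
            extirpations = (
                read_extirpation_csv(config.extirpations_csv)
                if config.extirpations_csv
                else []
            )
            site_cov = pd.read_csv(config.covariates_csv)
            landcover = pd.read_csv(config.landcover_csv) if config.landcover_csv else None

        stage = "trait_space"
        needed = set()
        for c in communities:
            needed |= set(c.members)
        for pool in pools.values():
            needed |= set(pool)
        for e in extirpations:
            needed |= set(e.extirpated)
        missing = sorted(needed - set(traits.species))
        if missing:
            raise PipelineError(f"stage trait_space: species missing from traits: {missing}")
        space = build_shared_space(
            traits.subset(sorted(needed)),
            equalize_traits=config.equalize_traits,
            binary=config.gower_binary,
            correction=config.correction,
            m_fric=config.m_fric,
            log_mass=config.log_mass,
        )
        written["ordination_csv"] = str(out / "ordination.csv")
        _write_ordination_csv(space, written["ordination_csv"])

        stage = "diversity"
        fd = fd_table(space, communities, pools, extirpations)
        written["fd_csv"] = str(out / "fd.csv")
        fd.to_csv(written["fd_csv"])

        stage = "covariates"
        covariates = assemble_covariates(
            fd, site_cov, landcover, shannon_base=config.shannon_base
        )
        std, scaling = standardize(covariates, CONTINUOUS_PREDICTORS)
        corr, flagged = correlation_screen(std)
        design = build_design(std)
        written["design_csv"] = str(out / "design.csv")
        design.to_csv(written["design_csv"])
        written["scaling_json"] = str(out / "scaling.json")
        Path(written["scaling_json"]).write_text(
            json.dumps({"scaling": scaling, "high_correlations": flagged}, indent=2, sort_keys=True)
        )

        stage = "regression"
        summaries = {}
        fit_seeds = np.random.SeedSequence(config.seed).generate_state(len(config.responses) + 1)
        for j, response in enumerate(config.responses):
            if response not in fd.columns:
                raise PipelineError(f"stage regression: unknown response {response!r}")
            y = fd[response].astype(float)
            if (y <= 0).any():
                bad = y.index[y <= 0].tolist()
                raise PipelineError(
                    f"stage regression: non-positive {response} at sites {bad}"
                )
            model = WeibullGLM(
                chains=config.chains,
                draws=config.draws,
                warmup=config.warmup,
                random_state=int(fit_seeds[j] % (2**31)),
            ).fit(design, y)
            summaries[response] = json.loads(
                model.summary().to_json(orient="index", double_precision=15)
            )
            summaries[response]["_converged"] = model.converged_
            flat = pd.DataFrame(
                {name: model.posterior_[name].ravel() for name in model.parameter_names_}
            )
            draws_path = out / f"draws_{response}.csv"
            flat.to_csv(draws_path, index=False)
            written[f"draws_{response}"] = str(draws_path)
            ppc = posterior_predictive_check(
                model,
                design,
                y,
                n_rep=200,
                random_state=int(fit_seeds[-1] % (2**31)),
                plot_path=str(out / f"ppc_{response}.svg"),
            )
            summaries[response]["_ppc"] = ppc
            written[f"ppc_{response}"] = str(out / f"ppc_{response}.svg")
            _credible_interval_plot(model, out / f"ci_{response}.svg")
            written[f"ci_{response}"] = str(out / f"ci_{response}.svg")

        written["summary_json"] = str(out / "summary.json")
        Path(written["summary_json"]).write_text(
            json.dumps(summaries, indent=2, sort_keys=True, default=_json_default)
        )
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest = {
        "package": "traitdiv",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "outputs": sorted(written.values()),
    }
    written["manifest_json"] = str(out / "manifest.json")
    Path(written["manifest_json"]).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return {"outputs": written, "summaries": summaries, "fd": fd, "manifest": manifest}


def _credible_interval_plot(model: WeibullGLM, path) -> None:
    """Forest plot of posterior medians with 50% and 95% intervals."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = model.summary()
    rows = [n for n in s.index if n != "shape"]
    fig, ax = plt.subplots(figsize=(5, 0.4 * len(rows) + 1.2))
    ypos = np.arange(len(rows))[::-1]
    for yv, name in zip(ypos, rows):
        r = s.loc[name]
        color = "0.2" if r.get("significant") is True else "0.6"
        ax.plot([r["ci95_low"], r["ci95_high"]], [yv, yv], color="k", lw=0.8)
        ax.plot([r["ci50_low"], r["ci50_high"]], [yv, yv], color="k", lw=2.5)
        ax.plot(r["median"], yv, "o", color=color, ms=5)
    ax.axvline(0.0, color="0.7", lw=0.8, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(rows)
    ax.set_xlabel("standardized effect (log mean)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
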