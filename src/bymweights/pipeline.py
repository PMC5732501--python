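"""Study orchestration: many weights specifications × many data sets.

`run_study` reproduces the full comparison workflow: for each data set it
computes observed-data Moran's I p-values under a handful of weight
specifications, builds each requested weights matrix, fits the BYM model (or
the no-smoothing benchmark "B"), rebalances the random effects, evaluates
DIC3 and residual Moran's I, and writes comparison tables, neighbour
profiles and per-area posterior summaries to an output directory.  The whole
study is a pure function of (config, master seed): sub-seeds are derived by
hashing the master seed with the dataset and spec labels, so adding a spec
never perturbs the other fits.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (FitEvaluation, compare_models, dic3, morans_p,
                         posterior_rhats, residual_autocorrelation)
from .geometry import ArealGeometry, grid_lattice, write_geojson
from .model import AreaDataset, BYMConfig, PosteriorSample, excess_variation, fit_bym, rebalance
from .synthetic import GeneratorConfig, generate_dataset
from .weights import SPEC_LABELS, build_weights, neighbour_profile, row_standardise

__all__ = ["StudyConfig", "run_study", "posterior_map_summaries",
           "load_area_csv", "subseed", "fit_and_evaluate"]

logger = logging.getLogger(__name__)

#: specifications used for the observed-data Moran's I table
OBSERVED_MORAN_SPECS = ("A1", "A2", "D2", "C3", "H5")


def subseed(master_seed: int, *labels: str) -> int:
    """Deterministic sub-seed from the master seed and a label path."""
    h = zlib.crc32(":".join(map(str, labels)).encode())
    return (master_seed * 1000003 + h) % (2 ** 31)


@dataclass
class StudyConfig:
    """Configuration of one full comparison study."""

    datasets: list  # (label, regime-or-path, GeneratorConfig-or-column-map)
    specs: tuple = SPEC_LABELS + ("B",)
    bym: BYMConfig = field(default_factory=BYMConfig)
    n_perm: int = 9_999
    profile_thresholds: tuple = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2)
    rhat_limit: float = 1.1
    master_seed: int = 0


def load_area_csv(path, id_col: str = "area_id", y_col: str = "y",
                  e_col: str = "E", p_col: str = "P", x_col: str = "x",
                  covariate_divisor: float = 1.0) -> AreaDataset:
    """Load an areal attribute table.

    Needs id, y and either expected counts E or populations P (internal
    standardisation is applied when only P is present).  The covariate is
    divided by ``covariate_divisor`` (10 reproduces the classic lip-cancer
    scaling of the percentage covariate).
    """
    df = pd.read_csv(path)
    for col in (id_col, y_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if e_col not in df.columns and p_col not in df.columns:
        raise ValueError(f"{path}: need either {e_col!r} or {p_col!r}")
    ids = df[id_col].tolist()
    dupes = df[id_col][df[id_col].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate area id(s) {dupes}")
    y_raw = df[y_col].to_numpy()
    if np.any(y_raw != np.round(y_raw)):
        bad = df.index[y_raw != np.round(y_raw)].tolist()
        raise ValueError(f"{path}: non-integer counts in rows {bad}")
    x = None
    if x_col in df.columns:
        x = df[x_col].to_numpy(dtype=float) / covariate_divisor
    return AreaDataset(
        area_ids=ids, y=y_raw.astype(np.int64),
        E=df[e_col].to_numpy(dtype=float) if e_col in df.columns else None,
        P=df[p_col].to_numpy(dtype=float) if p_col in df.columns else None,
        x=x)


def posterior_map_summaries(posterior: PosteriorSample, data: AreaDataset
                            ) -> pd.DataFrame:
    """Per-area posterior means of γ, ε, βx, η and the relative risk exp(η)."""
    gamma = posterior.gamma.mean(axis=(0, 1))
    eps = posterior.eps.mean(axis=(0, 1))
    beta_mean = posterior.beta.mean()
    eta = posterior.eta()
    eta_mean = eta.mean(axis=(0, 1))
    rr = np.exp(eta).mean(axis=(0, 1))
    return pd.DataFrame({
        "area_id": data.area_ids,
        "gamma_mean": gamma,
        "eps_mean": eps,
        "covariate_effect": beta_mean * posterior.x,
        "eta_mean": eta_mean,
        "relative_risk": rr,
    })


def fit_and_evaluate(data: AreaDataset, geom: ArealGeometry, spec_label: str,
                     dataset_label: str, bym_config: BYMConfig,
                     a1=None, n_perm: int = 9_999, seed: int | None = None
                     ) -> tuple[FitEvaluation, PosteriorSample]:
    """Build weights for one spec, fit, rebalance and evaluate one model."""
    from dataclasses import replace as _replace

    if a1 is None:
        a1 = build_weights("A1", geom)
    if seed is None:
        seed = bym_config.seed
    if spec_label.upper() == "B":
        cfg = _replace(bym_config, include_structured=False, seed=seed)
        post = fit_bym(data, None, cfg)
    else:
        wm = build_weights(spec_label, geom, data.x)
        cfg = _replace(bym_config, include_structured=True, seed=seed)
        post = fit_bym(data, wm, cfg)
        post = rebalance(post, excess_variation(post).psi)
    d3, mdev = dic3(data.y, data.E, post)
    mi, mp = residual_autocorrelation(post, a1, n_perm=n_perm,
                                      seed=subseed(seed, "resid", spec_label))
    rhats = posterior_rhats(post)
    ev = FitEvaluation(spec_label=spec_label.upper(), dataset_label=dataset_label,
                       dic3=d3, mean_deviance=mdev, morans_I=mi, morans_p=mp,
                       gelman_rubin=rhats)
    return ev, post


def _resolve_dataset(entry, master_seed: int):
    """One dataset entry -> (label, AreaDataset, geometry)."""
    from dataclasses import replace as _replace

    label, source = entry[0], entry[1]
    extra = entry[2] if len(entry) > 2 else None
    if source in ("noise", "smooth", "clusters"):
        gc = extra or GeneratorConfig()
        gc = _replace(gc, seed=subseed(master_seed, "data", label))
        data, comps, geom = generate_dataset(source, gc)
        return label, data, geom
    data = load_area_csv(source, **(extra or {}))
    raise_if_no_geom = ("dataset entries backed by files must carry a geometry "
                        "in the third tuple slot")
    if not isinstance(extra, dict) or "geometry" not in extra:
        raise ValueError(raise_if_no_geom)
    return label, data, extra["geometry"]


def run_study(config: StudyConfig, out_dir=None) -> dict:
    """Run the full study; returns a report dict, optionally writing artefacts.

    Report keys per dataset: ``observed_moran`` (Moran p of the observed
    counts under A1, A2, D2, C3, H5), ``comparison`` (DIC3 table),
    ``profiles`` (neighbour-count-vs-threshold), ``summaries`` (per-area
    posterior means per model), ``flags`` (non-converged models).
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    for entry in config.datasets:
        label, data, geom = _resolve_dataset(entry, config.master_seed)
        a1 = build_weights("A1", geom)
        obs_rows = []
        for spec in OBSERVED_MORAN_SPECS:
            wm = build_weights(spec, geom, data.x)
            p = morans_p(data.y.astype(float), wm, n_perm=config.n_perm,
                         seed=subseed(config.master_seed, "obs", label, spec))
            obs_rows.append({"spec": spec, "morans_p": p})
        observed = pd.DataFrame(obs_rows)

        evals, summaries, profiles, flags = [], {}, {}, []
        for spec in config.specs:
            ev, post = fit_and_evaluate(
                data, geom, spec, label, config.bym, a1=a1, n_perm=config.n_perm,
                seed=subseed(config.master_seed, "fit", label, spec))
            evals.append(ev)
            summaries[spec] = posterior_map_summaries(post, data)
            if spec.upper() != "B":
                wm = build_weights(spec, geom, data.x)
                profiles[spec] = neighbour_profile(
                    row_standardise(wm), config.profile_thresholds)
            max_rhat = max(ev.gelman_rubin.values())
            if max_rhat > config.rhat_limit:
                flags.append({"model": spec, "max_rhat": max_rhat})
                logger.warning("dataset %s model %s: max R-hat %.3f exceeds %.2f",
                               label, spec, max_rhat, config.rhat_limit)
        comparison = compare_models(evals)
        report[label] = {"observed_moran": observed, "comparison": comparison,
                         "profiles": profiles, "summaries": summaries,
                         "flags": flags}
        if out is not None:
            ddir = out / label
            ddir.mkdir(exist_ok=True)
            observed.to_csv(ddir / "observed_moran.csv", index=False)
            comparison.to_csv(ddir / "comparison.csv", index=False)
            pd.DataFrame(profiles, index=list(config.profile_thresholds)
                         ).to_csv(ddir / "neighbour_profiles.csv")
            for spec, summ in summaries.items():
                summ.to_csv(ddir / f"summary_{spec}.csv", index=False)
            if geom.shapes is not None:
                best = comparison["model"].iloc[0]
                cols = summaries[best]
                write_geojson(geom, ddir / f"map_{best}.geojson",
                              properties={c: cols[c].tolist()
                                          for c in cols.columns if c != "area_id"})
    return report
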