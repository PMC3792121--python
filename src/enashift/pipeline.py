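"""End-to-end orchestration: forcing -> simulation -> indicators -> shifts.

:func:`run_pipeline` performs the three analyses an integrated regime-shift
assessment chains together:

i.   abrupt-change screening of the forcing series themselves (per-series
     STARS, PCA pressure index + STARS on its scores, chronological
     clustering, traffic-light table);
ii.  the same battery on the simulated biomass series (longer STARS
     cut-off, since biomass integrates forcing);
iii. yearly ecological-network indicators with STARS, chronological
     clustering and per-regime coefficients of variation.

All outputs are delimited text plus a JSON manifest carrying the seed and
a hash of the configuration; identical config + seed reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .dynamics import DynamicParams, ForcingSet, calibrate
from .ena import indicator_table
from .foodweb import FoodWeb, solve_missing_ee
from .shifts import (
    CcConfig,
    StarsConfig,
    chronological_clustering,
    coefficient_of_variation,
    pca_index,
    stars,
    stars_on_scores,
    traffic_light,
)
from .synth import BALTIC_EXCLUDE, make_baltic_fixture

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With ``web_basic``/``web_diet`` left unset the bundled Baltic-like
    fixture is used.  ``forcing`` must point to a forcing table (see
    :mod:`enashift.io`).  STARS cut-offs default to 5 years for forcing and
    indicator series and 10 years for biomass; CV periods are closed year
    intervals.  One seed drives every stochastic stage.
    """

    forcing: str | None = None
    web_basic: str | None = None
    web_diet: str | None = None
    web_vulnerability: str | None = None
    stars_alpha: float = 0.05
    stars_cutoff_fast: int = 5  # forcing and indicator series
    stars_cutoff_biomass: int = 10
    stars_huber: float = 3.0
    cc_alpha: float = 0.01
    cc_connectedness: float = 0.5
    cc_permutations: int = 999
    cv_periods: list[tuple[int, int]] = field(default_factory=list)
    exclude_groups: list[str] = field(default_factory=lambda: list(BALTIC_EXCLUDE))
    seed: int = 0
    dt: float = 1.0 / 12.0
    make_figures: bool = False
    outdir: str = "enashift_out"


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    if "cv_periods" in raw:
        raw["cv_periods"] = [tuple(p) for p in raw["cv_periods"]]
    return RunConfig(**raw)


def _config_hash(cfg: RunConfig) -> str:
    d = dataclasses.asdict(cfg)
    d.pop("outdir", None)  # analysis identity is independent of output location
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _varying(df: pd.DataFrame, rel: float = 1e-9) -> list:
    """Columns with variation beyond floating-point jitter."""
    out = []
    for c in df.columns:
        col = df[c]
        if col.std(ddof=1) > rel * max(abs(float(col.mean())), 1e-12):
            out.append(c)
    return out


def _shift_table(results: dict[str, "object"]) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "series": name,
                "shift_years": ";".join(str(y) for y in r.shift_years),
                "confirmed_years": ";".join(str(y) for y in r.confirmed_years),
                "rsi": ";".join(f"{r.rsi[y]:.4f}" for y in r.shift_years),
                "regime_means": ";".join(f"{m:.6g}" for m in r.regime_means),
            }
        )
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path, header: str, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, **kw)


def _analyse_block(
    matrix: pd.DataFrame,
    scfg: StarsConfig,
    ccfg: CcConfig,
    outdir: Path,
    tag: str,
    make_figures: bool,
) -> dict:
    """STARS per series + PCA + STARS on PC1 + CC + traffic light for one
    year x variable block."""
    per_series = {c: stars(matrix[c], scfg) for c in matrix.columns}
    pca = pca_index(matrix)
    pc1 = stars_on_scores(pca, 1, scfg)
    part = chronological_clustering(matrix, ccfg)
    tlp = traffic_light(matrix, ordering=pca.loadings["PC1"])

    _write(_shift_table(per_series), outdir / f"shifts_{tag}.csv",
           f"STARS shifts per {tag} series (years; RSI dimensionless)", index=False)
    _write(pca.loadings, outdir / f"pca_loadings_{tag}.csv",
           "PCA loadings (correlation matrix, ln(x+1) transform)", index_label="variable")
    _write(pca.scores, outdir / f"pca_scores_{tag}.csv",
           "PCA scores per year", index_label="year")
    _write(_shift_table({"PC1": pc1}), outdir / f"shifts_{tag}_pc1.csv",
           "STARS shifts on PC1 scores", index=False)
    _write(pd.DataFrame({"segment_start": [s for s, _ in part.segments],
                         "segment_end": [e for _, e in part.segments]}),
           outdir / f"cc_{tag}.csv", "chronological clustering segments (closed years)",
           index=False)
    _write(tlp.categories, outdir / f"traffic_light_{tag}.csv",
           "traffic-light quintile categories 1 (low) .. 5 (high), rows by PC1 loading",
           index_label="variable")
    if make_figures:
        ax = tlp.plot()
        ax.figure.savefig(outdir / f"traffic_light_{tag}.png", dpi=150,
                          bbox_inches="tight")
        import matplotlib.pyplot as plt

        plt.close(ax.figure)
    return {
        "stars": per_series,
        "pca": pca,
        "stars_pc1": pc1,
        "cc": part,
        "traffic_light": tlp,
    }


def run_pipeline(
    cfg: RunConfig,
    web: FoodWeb | None = None,
    params: DynamicParams | None = None,
    forcing: ForcingSet | None = None,
) -> dict:
    """Run the three analyses and write the result bundle to ``cfg.outdir``.

    ``web``/``params``/``forcing`` may be passed directly (they override the
    config paths); otherwise they are loaded from the configured files or
    fall back to the bundled fixture.  Returns the in-memory result bundle;
    partial outputs are retained on stage failure, and the raised error
    names the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if web is None:
            if cfg.web_basic:
                web, vuln = eio.read_web(cfg.web_basic, cfg.web_diet, cfg.web_vulnerability)
                web = solve_missing_ee(web)
                if params is None:
                    params = DynamicParams(vulnerability=vuln if vuln is not None else 2.0)
            else:
                web, fix_params = make_baltic_fixture()
                if params is None:
                    params = fix_params
        if params is None:
            params = DynamicParams()
        if forcing is None:
            if not cfg.forcing:
                raise ValueError("no forcing given (config path or argument)")
            forcing = eio.read_forcing(cfg.forcing)

        fast = StarsConfig(cfg.stars_alpha, cfg.stars_cutoff_fast, cfg.stars_huber)
        slow = StarsConfig(cfg.stars_alpha, cfg.stars_cutoff_biomass, cfg.stars_huber)
        ccfg = CcConfig(cfg.cc_alpha, cfg.cc_connectedness, cfg.cc_permutations, cfg.seed)
        results: dict = {}
        years = forcing.years

        stage = "forcing-analysis"
        fmat = pd.DataFrame(index=pd.Index(years, name="year"))
        for name, series in forcing.F.items():
            fmat[f"F:{name}"] = series
        if np.ptp(forcing.pp_multiplier) > 0:
            fmat["pp_multiplier"] = forcing.pp_multiplier
        varying = _varying(fmat)
        if len(varying) >= 2:
            results["forcing"] = _analyse_block(
                fmat[varying], fast, ccfg, outdir, "forcing", cfg.make_figures
            )
        else:
            results["forcing"] = None  # neutral forcing: nothing to screen

        stage = "simulation"
        model = calibrate(web, params)
        traj = model.simulate(forcing, dt=cfg.dt)
        eio.write_trajectory(traj, web.names, outdir / "biomass.csv")
        results["trajectory"] = traj

        stage = "biomass-analysis"
        bmat = pd.DataFrame(traj.B, index=pd.Index(years, name="year"), columns=web.names)
        keep = [c for c in bmat.columns if c not in set(cfg.exclude_groups)]
        bmat = bmat[keep]
        bvarying = _varying(bmat)
        if len(bvarying) >= 2:
            results["biomass"] = _analyse_block(
                bmat[bvarying], slow, ccfg, outdir, "biomass", cfg.make_figures
            )
        else:
            results["biomass"] = None

        stage = "indicators"
        nets = model.annual_flow_snapshots(traj)
        itab = indicator_table(nets, web, years=years)
        eio.write_indicators(itab, outdir / "indicators.csv")
        results["indicators"] = itab

        stage = "indicator-analysis"
        usable = [c for c in _varying(itab) if itab[c].notna().all()]
        ind_stars = {c: stars(itab[c], fast) for c in usable}
        _write(_shift_table(ind_stars), outdir / "shifts_indices.csv",
               "STARS shifts per indicator series", index=False)
        ind_cc = chronological_clustering(itab[usable], ccfg) if len(usable) >= 2 else None
        if ind_cc is not None:
            _write(pd.DataFrame({"segment_start": [s for s, _ in ind_cc.segments],
                                 "segment_end": [e for _, e in ind_cc.segments]}),
                   outdir / "cc_indices.csv", "chronological clustering of indicators",
                   index=False)
        periods = cfg.cv_periods or [(int(years[0]), int(years[len(years) // 2 - 1])),
                                     (int(years[len(years) // 2]), int(years[-1])),
                                     (int(years[0]), int(years[-1]))]
        cv_rows = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for c in itab.columns:
                cvs = coefficient_of_variation(itab[c].dropna(), periods) \
                    if itab[c].notna().all() else {p: np.nan for p in periods}
                cv_rows[c] = {f"{a}-{b}": v for (a, b), v in cvs.items()}
        cv_table = pd.DataFrame(cv_rows).T
        _write(cv_table, outdir / "cv_indices.csv",
               "coefficient of variation (sample SD / |mean|) per period",
               index_label="index")
        results["indicator_stars"] = ind_stars
        results["indicator_cc"] = ind_cc
        results["cv"] = cv_table

        stage = "manifest"
        manifest = {
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "years": [int(years[0]), int(years[-1])],
            "n_groups": web.n,
            "outputs": sorted(
                {p.name for p in outdir.iterdir() if p.is_file()} | {"manifest.json"}
            ),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        results["manifest"] = manifest
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
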