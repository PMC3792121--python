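"""Delimited-text readers and writers for every object in the pipeline.

Formats (all UTF-8, comma-separated, decimal point, one header row; lines
starting with ``#`` carry units and are skipped on read):

* food web: a *basic* table (one row per group: role, B, P/B, Q/B, EE, GS,
  detritus share, landings per fleet), a *diet* matrix (prey rows x
  predator columns, including an ``import`` row) and an optional
  *vulnerability* matrix of the same shape;
* forcing: one row per year, columns ``F:<group>``, ``pp_multiplier`` and
  ``env:<prey>|<pred>``;
* trajectory and indicator tables: year-indexed frames;
* flow networks: the SCOR exchange format (compartment list, then
  input/export/respiration/internal-flow sections each terminated by -1)
  for interoperability with existing ENA software.

Every writer/reader pair round-trips exactly on the data model.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ForcingSet, Trajectory
from .foodweb import IMPORT_KEY, FlowNetwork, FoodWeb, GroupSpec

__all__ = [
    "write_web",
    "read_web",
    "write_forcing",
    "read_forcing",
    "write_trajectory",
    "write_indicators",
    "read_indicators",
    "write_scor",
    "read_scor",
]


class FormatError(ValueError):
    """Malformed input file; message carries the file and offending item."""


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", **kw)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


# -- food web -----------------------------------------------------------------


def write_web(web: FoodWeb, basic_path: str | Path, diet_path: str | Path,
              vulnerability: np.ndarray | None = None,
              vulnerability_path: str | Path | None = None) -> None:
    """Write the basic-input table and diet matrix (and optional vulnerabilities)."""
    rows = []
    for g in web.groups:
        row = {
            "name": g.name, "role": g.role, "B": g.B, "PB": g.PB, "QB": g.QB,
            "EE": "" if g.EE is None else g.EE, "GS": g.GS,
            "detritus_share": web.detritus_routing.get(g.name, ""),
        }
        for f in web.fleets:
            row[f"landings:{f}"] = g.landings.get(f, 0.0)
        rows.append(row)
    with open(basic_path, "w") as fh:
        fh.write("# basic input: B t/km2 wet weight; PB, QB 1/yr; EE, GS, "
                 "detritus_share proportions; landings t/km2/yr\n")
        pd.DataFrame(rows).to_csv(fh, index=False)

    names = web.names
    diet = pd.DataFrame(0.0, index=names + [IMPORT_KEY], columns=names)
    for g in web.groups:
        for prey, frac in g.diet.items():
            diet.loc[prey, g.name] = frac
    with open(diet_path, "w") as fh:
        fh.write("# diet composition: prey rows x predator columns, proportions\n")
        diet.to_csv(fh, index_label="prey")

    if vulnerability is not None:
        if vulnerability_path is None:
            raise ValueError("vulnerability_path required when writing vulnerabilities")
        v = pd.DataFrame(vulnerability, index=names, columns=names)
        with open(vulnerability_path, "w") as fh:
            fh.write("# vulnerability multipliers: prey rows x predator columns, dimensionless\n")
            v.to_csv(fh, index_label="prey")


def read_web(basic_path: str | Path, diet_path: str | Path,
             vulnerability_path: str | Path | None = None
             ) -> tuple[FoodWeb, np.ndarray | None]:
    """Read the tables written by :func:`write_web`."""
    basic = _read_csv(basic_path)
    required = {"name", "role", "B", "PB", "QB", "EE", "GS"}
    missing = required - set(basic.columns)
    if missing:
        raise FormatError(f"{basic_path}: missing columns {sorted(missing)}")
    diet = _read_csv(diet_path, index_col="prey")
    fleets = [c.split(":", 1)[1] for c in basic.columns if c.startswith("landings:")]
    groups = []
    for _, r in basic.iterrows():
        name = str(r["name"])
        if name not in diet.columns:
            raise FormatError(f"{diet_path}: missing diet column for group {name!r}")
        dcol = diet[name]
        d = {str(p): float(v) for p, v in dcol.items() if float(v) != 0.0}
        landings = {
            f: float(r[f"landings:{f}"])
            for f in fleets
            if float(r.get(f"landings:{f}", 0.0) or 0.0) != 0.0
        }
        groups.append(GroupSpec(
            name=name, role=str(r["role"]), B=float(r["B"]), PB=float(r["PB"]),
            QB=float(r["QB"]), EE=None if pd.isna(r["EE"]) else float(r["EE"]),
            GS=float(r["GS"]), diet=d, landings=landings,
        ))
    routing = {
        str(r["name"]): float(r["detritus_share"])
        for _, r in basic.iterrows()
        if str(r["role"]) == "detritus" and not pd.isna(r.get("detritus_share"))
    }
    web = FoodWeb(groups, fleets=fleets, detritus_routing=routing)
    vuln = None
    if vulnerability_path is not None:
        v = _read_csv(vulnerability_path, index_col="prey")
        vuln = v.loc[web.names, web.names].to_numpy(dtype=float)
    return web, vuln


# -- forcing ------------------------------------------------------------------


def write_forcing(forcing: ForcingSet, path: str | Path) -> None:
    df = pd.DataFrame({"year": forcing.years})
    for name, s in forcing.F.items():
        df[f"F:{name}"] = s
    df["pp_multiplier"] = forcing.pp_multiplier
    for (prey, pred), s in forcing.env_multiplier.items():
        df[f"env:{prey}|{pred}"] = s
    with open(path, "w") as fh:
        fh.write("# forcing: F 1/yr; pp_multiplier and env multipliers dimensionless (1 = baseline)\n")
        df.to_csv(fh, index=False)


def read_forcing(path: str | Path) -> ForcingSet:
    df = _read_csv(path)
    if "year" not in df.columns:
        raise FormatError(f"{path}: mandatory 'year' column missing")
    F, env, pp = {}, {}, None
    for c in df.columns:
        if c == "year":
            continue
        if c == "pp_multiplier":
            pp = df[c].to_numpy(dtype=float)
        elif c.startswith("F:"):
            F[c[2:]] = df[c].to_numpy(dtype=float)
        elif c.startswith("env:"):
            prey, pred = c[4:].split("|", 1)
            env[(prey, pred)] = df[c].to_numpy(dtype=float)
        else:
            raise FormatError(f"{path}: unrecognised column {c!r}")
    return ForcingSet(years=df["year"].to_numpy(dtype=int), F=F,
                      pp_multiplier=pp, env_multiplier=env)


# -- trajectory / indicators --------------------------------------------------


def write_trajectory(traj: Trajectory, names: list[str], path: str | Path) -> None:
    """Year x group biomass table, t/km^2."""
    df = pd.DataFrame(traj.B, index=traj.years, columns=names)
    with open(path, "w") as fh:
        fh.write("# yearly mean biomass, t/km2 wet weight\n")
        df.to_csv(fh, index_label="year")


def write_indicators(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# yearly indicators: TST, TotC t/km2/yr; A, C, R flow-bits; "
                 "AMI, H bits; R_pct_C %; remaining indices dimensionless\n")
        table.to_csv(fh, index_label="year")


def read_indicators(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, index_col="year")


# -- SCOR flow-network exchange ----------------------------------------------


def write_scor(net: FlowNetwork, path: str | Path, title: str = "enashift network") -> None:
    """SCOR-format export: compartments, biomasses, then input / export /
    respiration / internal-flow sections, each terminated by ``-1``."""
    n = net.n
    with open(path, "w") as fh:
        fh.write(f"{title}\n")
        fh.write(f"{n} {int(net.living.sum())}\n")
        for lab in net.labels:
            fh.write(f"{lab}\n")
        bio = net.biomass if net.biomass is not None else np.zeros(n)
        for i in range(n):
            fh.write(f"{i + 1} {bio[i]:.10g}\n")
        fh.write("-1\n")
        for vec in (net.imports, net.exports, net.respiration):
            for i in range(n):
                if vec[i] > 0:
                    fh.write(f"{i + 1} {vec[i]:.10g}\n")
            fh.write("-1\n")
        internal = net.internal
        for i in range(n):
            for j in range(n):
                if internal[i, j] > 0:
                    fh.write(f"{i + 1} {j + 1} {internal[i, j]:.10g}\n")
        fh.write("-1\n")


def read_scor(path: str | Path) -> FlowNetwork:
    """Re-import a SCOR file written by :func:`write_scor`.

    Living/detritus flags follow the SCOR convention that the first
    ``n_living`` compartments are living.
    """
    lines = Path(path).read_text().splitlines()
    it = iter(enumerate(lines, start=1))

    def next_line():
        try:
            return next(it)
        except StopIteration:
            raise FormatError(f"{path}: truncated file") from None

    next_line()  # title
    ln, header = next_line()
    try:
        n, n_living = (int(v) for v in header.split())
    except ValueError:
        raise FormatError(f"{path}:{ln}: expected 'n n_living'") from None
    labels = [next_line()[1].strip() for _ in range(n)]
    bio = np.zeros(n)
    T = np.zeros((n + 3, n + 3))

    def read_section(ncols):
        out = []
        while True:
            ln_, line = next_line()
            parts = line.split()
            if parts[:1] == ["-1"]:
                return out
            if len(parts) != ncols:
                raise FormatError(f"{path}:{ln_}: expected {ncols} fields")
            out.append((ln_, parts))

    for _, p in read_section(2):
        bio[int(p[0]) - 1] = float(p[1])
    for _, p in read_section(2):
        T[n + 0, int(p[0]) - 1] = float(p[1])  # imports
    for _, p in read_section(2):
        T[int(p[0]) - 1, n + 1] = float(p[1])  # exports
    for _, p in read_section(2):
        T[int(p[0]) - 1, n + 2] = float(p[1])  # respiration
    for _, p in read_section(3):
        T[int(p[0]) - 1, int(p[1]) - 1] = float(p[2])
    living = np.arange(n) < n_living
    return FlowNetwork(T=T, labels=labels, living=living, detritus=~living, biomass=bio)
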