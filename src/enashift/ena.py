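"""Ecological network analysis and ecosystem indicators on a flow network.

Fifteen indicators are computed per year, following the canonical
information-theoretic decomposition of Ulanowicz and the Finn cycling
framework:

* size: total system throughput ``TST`` (sum of every flow, boundary
  included);
* organisation: average mutual information ``AMI``, flow diversity ``H``
  (Shannon form, bits, log base 2), ascendency ``A = TST*AMI``, development
  capacity ``C = TST*H``, relative ascendency ``A/C``, and redundancy ``R``
  -- the overhead on internal flows, reported both in flow-bits and as a
  percentage of ``C`` (the resilience proxy used for regime comparison);
* cycling and routing: Finn cycle index ``FCI``, predatory cycle index
  ``PCI`` (cycling after removing the detritus pools), mean path length
  ``MPL``, proportional flow to detritus ``PFD``;
* ecosystem metabolism: ``TPP/TR``, ``ToTP/ToTB``;
* fisheries: total catch, catch-weighted mean trophic level ``mTLc``, and
  primary production required to sustain the catch per unit primary
  production ``PPR/PP``;
* biodiversity: Kempton Q over upper-trophic-level groups.

All information indices use log base 2 and are reported in bits; flow
units are t/km^2/yr throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .foodweb import FlowNetwork, FoodWeb, trophic_levels

__all__ = [
    "IndicatorSet",
    "INDICATOR_NAMES",
    "total_system_throughput",
    "information_decomposition",
    "finn_cycle_index",
    "mean_path_length",
    "flow_to_detritus_fraction",
    "ecosystem_ratios",
    "fisheries_indices",
    "kempton_q",
    "compute_all",
    "indicator_table",
]

#: the 15 indicators summarised per regime (column order of the yearly table)
INDICATOR_NAMES = [
    "TST",
    "AC_ratio",
    "R",
    "AMI",
    "H",
    "FCI",
    "PCI",
    "MPL",
    "PFD",
    "ToTP_ToTB",
    "TPP_TR",
    "TotC",
    "PPR_PP",
    "mTLc",
    "KemptonQ",
]


@dataclass
class IndicatorSet:
    """One year's indicator values; unavailable entries are NaN."""

    year: int
    TST: float = np.nan  # t/km^2/yr
    A: float = np.nan  # flow-bits
    C: float = np.nan  # flow-bits
    AC_ratio: float = np.nan
    AMI: float = np.nan  # bits
    H: float = np.nan  # bits
    R: float = np.nan  # flow-bits
    R_pct_C: float = np.nan  # % of capacity
    FCI: float = np.nan
    PCI: float = np.nan
    MPL: float = np.nan
    PFD: float = np.nan
    TPP_TR: float = np.nan
    ToTP_ToTB: float = np.nan  # 1/yr
    TotC: float = np.nan  # t/km^2/yr
    PPR_PP: float = np.nan
    mTLc: float = np.nan
    KemptonQ: float = np.nan

    def as_series(self) -> pd.Series:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        year = d.pop("year")
        return pd.Series(d, name=year)


def total_system_throughput(net: FlowNetwork) -> float:
    """Sum of every flow, imports, exports and dissipation included."""
    return float(net.T.sum())


def information_decomposition(net: FlowNetwork) -> dict[str, float]:
    """Ulanowicz information decomposition of the flow matrix.

    Returns AMI and H (bits), ascendency ``A`` and capacity ``C``
    (flow-bits), relative ascendency, redundancy ``R`` (the overhead
    restricted to internal compartment-to-compartment flows) in flow-bits
    and as % of C, plus the boundary overhead components.  The identity
    ``A + ov_import + ov_export + ov_dissipation + R = C`` holds exactly.
    """
    tst = total_system_throughput(net)
    if tst <= 0:
        raise ValueError("information decomposition undefined for TST = 0")
    T = net.T
    rows = T.sum(axis=1)
    cols = T.sum(axis=0)
    nz = T > 0
    i, j = np.nonzero(nz)
    t = T[i, j]
    ami_terms = (t / tst) * np.log2(t * tst / (rows[i] * cols[j]))
    h_terms = -(t / tst) * np.log2(t / tst)
    ami = float(ami_terms.sum())
    h = float(h_terms.sum())
    A = tst * ami
    C = tst * h
    ov_terms = -t * np.log2(t * t / (rows[i] * cols[j]))  # flow-bits per link
    n = net.n
    internal = (i < n) & (j < n)
    is_import = i >= n
    is_export = (j == n + 1)
    is_resp = (j == n + 2)
    R = float(ov_terms[internal].sum())
    out = {
        "AMI": ami,
        "H": h,
        "A": A,
        "C": C,
        "AC_ratio": A / C if C > 0 else np.nan,
        "R": R,
        "R_pct_C": 100.0 * R / C if C > 0 else np.nan,
        "ov_import": float(ov_terms[is_import].sum()),
        "ov_export": float(ov_terms[is_export].sum()),
        "ov_dissipation": float(ov_terms[is_resp].sum()),
    }
    return out


def _cycled_fraction(net: FlowNetwork) -> float:
    """Finn's cycled fraction of TST via the structure matrix N = (I-G)^-1."""
    n = net.n
    tst = total_system_throughput(net)
    if tst <= 0:
        return 0.0
    Tf = net.throughflow()
    G = np.zeros((n, n))
    active = Tf > 0
    # G[i, j]: fraction of j's throughflow received directly from i
    G[:, active] = net.internal[:, active] / Tf[active]
    try:
        N = np.linalg.inv(np.eye(n) - G)
    except np.linalg.LinAlgError as exc:
        bad = net.labels[int(np.argmax(np.abs(G).sum(axis=0)))]
        raise ValueError(
            f"singular structure matrix (perfect recycling around {bad!r})"
        ) from exc
    diag = np.diag(N)
    cycled = np.where(diag > 0, (diag - 1.0) / np.where(diag > 0, diag, 1.0), 0.0) * Tf
    return float(cycled.sum() / tst)


def finn_cycle_index(net: FlowNetwork, include_detritus: bool = True) -> float:
    """Fraction of throughflow travelling in cycles.

    With ``include_detritus=False`` the detritus pools and every flow
    touching them are removed first, yielding the predatory cycle index
    (recycling through living compartments only).
    """
    if include_detritus:
        return _cycled_fraction(net)
    return _cycled_fraction(net.subnetwork(~net.detritus))


def mean_path_length(net: FlowNetwork) -> float:
    """TST divided by total boundary input (Finn's convention).

    Primary production enters through the import node, so the denominator
    is simply the import row sum.
    """
    tst = total_system_throughput(net)
    boundary_in = float(net.imports.sum())
    if boundary_in <= 0:
        raise ValueError("mean path length undefined without boundary input")
    return tst / boundary_in


def flow_to_detritus_fraction(net: FlowNetwork) -> float:
    """Share of TST flowing into the detritus pools."""
    tst = total_system_throughput(net)
    if tst <= 0:
        return 0.0
    det_cols = np.flatnonzero(net.detritus)
    return float(net.T[:, det_cols].sum() / tst)


def ecosystem_ratios(net: FlowNetwork, web: FoodWeb | None = None) -> dict[str, float]:
    """Production/respiration, turnover and total catch.

    TPP = summed producer production; TR = summed dissipation; ToTP = all
    (living) production; ToTB = total living biomass; TotC = landings.
    Uses the per-compartment metadata the network carries.
    """
    if net.production is None or net.biomass is None:
        raise ValueError("network lacks production/biomass metadata")
    producer = net.living & (net.imports > 0) & ~net.detritus
    if web is not None:
        producer = web.role_mask("producer")
    TPP = float(net.production[producer].sum())
    TR = float(net.respiration.sum())
    ToTP = float(net.production.sum())
    ToTB = float(net.biomass[net.living].sum())
    TotC = float(net.catch.sum()) if net.catch is not None else 0.0
    if TR <= 0:
        raise ValueError("total respiration is zero; TPP/TR undefined")
    if ToTB <= 0:
        raise ValueError("total biomass is zero; turnover undefined")
    return {"TPP_TR": TPP / TR, "ToTP_ToTB": ToTP / ToTB, "TotC": TotC}


def fisheries_indices(
    net: FlowNetwork, web: FoodWeb, TL: np.ndarray | None = None
) -> dict[str, float]:
    """Catch-weighted mean trophic level and PPR/PP.

    The primary production required (PPR) back-traces each caught unit to
    the primary sources through the diet-proportioned flow graph: a unit
    of group i's production requires ``1/g_i`` units of prey production,
    apportioned by diet.  Producers and detritus count as primary sources
    (requirement 1), imported food as external (requirement 0); cycles are
    handled by solving the linear system.  The result is normalised by
    total primary production.
    """
    if TL is None:
        TL = trophic_levels(web)
    Y = net.catch if net.catch is not None else web.catches()
    totY = float(Y.sum())
    mtlc = float((Y * TL).sum() / totY) if totY > 0 else np.nan
    if totY <= 0:
        warnings.warn("zero total catch: mTLc undefined", stacklevel=2)

    n = web.n
    D, _imp = web.diet_matrix()
    g = np.zeros(n)
    consumer = web.role_mask("consumer")
    PB, QB = web.array("PB"), web.array("QB")
    with np.errstate(divide="ignore", invalid="ignore"):
        g[consumer] = (PB / np.where(QB > 0, QB, 1))[consumer]
    # r_i: primary production required per unit production of group i
    A = np.eye(n)
    b = np.ones(n)
    for i in range(n):
        if consumer[i]:
            if g[i] <= 0:
                raise ValueError(f"consumer {web.names[i]!r} has non-positive g")
            A[i, :] -= D[:, i] / g[i]
            b[i] = 0.0
    r = np.linalg.solve(A, b)
    ppr = float((Y * r).sum())
    producer = web.role_mask("producer")
    TPP = float((web.array("B") * PB)[producer].sum())
    if net.production is not None:
        TPP = float(net.production[producer].sum())
    return {"mTLc": mtlc, "PPR_PP": ppr / TPP if TPP > 0 else np.nan, "PPR": ppr}


def kempton_q(
    biomasses: np.ndarray, TL: np.ndarray, tl_threshold: float = 3.0
) -> float:
    """Kempton's Q biodiversity index over upper-trophic-level groups.

    Groups with TL >= ``tl_threshold`` are ranked by descending biomass;
    Q = (S/2) / log10(B_25 / B_75) with B_25/B_75 the biomasses at the
    inter-quartile positions of the dominance curve (log-interpolated).
    Larger Q means a more even upper food web.  Returns NaN when fewer
    than two groups qualify or the quartile biomasses coincide.
    """
    biomasses = np.asarray(biomasses, dtype=float)
    sel = (np.asarray(TL) >= tl_threshold) & (biomasses > 0)
    S = int(sel.sum())
    if S < 2:
        return np.nan
    logb = np.sort(np.log10(biomasses[sel]))[::-1]
    pos = np.arange(S)
    b25 = np.interp(0.25 * (S - 1), pos, logb)
    b75 = np.interp(0.75 * (S - 1), pos, logb)
    if b25 - b75 <= 0:
        return np.nan
    return float((S / 2.0) / (b25 - b75))


def compute_all(
    net: FlowNetwork,
    web: FoodWeb,
    biomasses: np.ndarray | None = None,
    year: int = 0,
    tl_threshold: float = 3.0,
) -> IndicatorSet:
    """Assemble the 15-indicator set for one year's network.

    Individual failures (undefined ratios, zero catch, ...) propagate as
    NaN in the corresponding fields rather than aborting the year.
    """
    out = IndicatorSet(year=year)
    B = biomasses if biomasses is not None else net.biomass
    try:
        out.TST = total_system_throughput(net)
    except Exception:
        pass
    try:
        info = information_decomposition(net)
        out.A, out.C, out.AC_ratio = info["A"], info["C"], info["AC_ratio"]
        out.AMI, out.H = info["AMI"], info["H"]
        out.R, out.R_pct_C = info["R"], info["R_pct_C"]
    except Exception:
        pass
    for name, flag in (("FCI", True), ("PCI", False)):
        try:
            setattr(out, name, finn_cycle_index(net, include_detritus=flag))
        except Exception:
            pass
    try:
        out.MPL = mean_path_length(net)
    except Exception:
        pass
    try:
        out.PFD = flow_to_detritus_fraction(net)
    except Exception:
        pass
    try:
        ratios = ecosystem_ratios(net, web)
        out.TPP_TR, out.ToTP_ToTB = ratios["TPP_TR"], ratios["ToTP_ToTB"]
        out.TotC = ratios["TotC"]
    except Exception:
        pass
    try:
        tl = trophic_levels(web)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fish = fisheries_indices(net, web, tl)
        out.mTLc, out.PPR_PP = fish["mTLc"], fish["PPR_PP"]
        if B is not None:
            out.KemptonQ = kempton_q(B, tl, tl_threshold=tl_threshold)
    except Exception:
        pass
    return out


def indicator_table(
    nets: list[FlowNetwork],
    web: FoodWeb,
    years: np.ndarray | list[int] | None = None,
    tl_threshold: float = 3.0,
) -> pd.DataFrame:
    """Yearly indicator table (rows = years, 15 indicator columns + R % of C)."""
    if years is None:
        years = list(range(len(nets)))
    rows = [
        compute_all(net, web, year=int(y), tl_threshold=tl_threshold).as_series()
        for net, y in zip(nets, years)
    ]
    df = pd.DataFrame(rows)
    df.index.name = "year"
    return df[INDICATOR_NAMES + ["R_pct_C", "A", "C"]]
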