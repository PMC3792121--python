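"""Synthetic inputs: random balanced webs, the Baltic-like fixture,
forcing scenarios with planted step changes, and multivariate block series.

Everything the pipeline consumes can be generated here, deterministically
per seed, so the full analysis runs without any external data.

The fixture returned by :func:`make_baltic_fixture` reproduces the *shape*
of a Central Baltic food-web model -- 21 functional groups (two primary
producers, two detritus pools, multi-stanza cod/sprat/herring, seals) and
three fleets -- but its biomasses, rates, diets and vulnerabilities are
SYNTHETIC placeholder values chosen to satisfy mass balance and plausible
trophic structure.  They are not a calibrated model of the Baltic Sea.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DynamicParams, ForcingSet
from .foodweb import FoodWeb, GroupSpec, solve_missing_ee

__all__ = [
    "ScenarioSpec",
    "make_random_web",
    "make_baltic_fixture",
    "make_forcing_scenario",
    "make_block_series",
    "BALTIC_GROUPS",
    "BALTIC_EXCLUDE",
]


def make_random_web(
    n_groups: int = 12,
    n_producers: int = 3,
    n_detritus: int = 2,
    connectance: float = 0.3,
    seed: int = 0,
    with_fleet: bool = False,
) -> FoodWeb:
    """Random cascade-ordered balanced food web.

    Producers occupy the lowest indices, detritus the highest; each
    consumer eats a random subset of lower-indexed groups (plus possibly
    detritus) with Dirichlet-distributed fractions.  Demand on any prey is
    capped at 90% of its production by shaving diet fractions into an
    import term, so the solved ecotrophic efficiencies are guaranteed to be
    within [0, 1].  Deterministic per seed.
    """
    if n_producers < 1 or n_detritus < 1:
        raise ValueError("need at least one producer and one detritus group")
    if not 0 < connectance <= 1:
        raise ValueError("connectance must be in (0, 1]")
    n_cons = n_groups - n_producers - n_detritus
    if n_cons < 1:
        raise ValueError("need at least one consumer")
    rng = np.random.default_rng(seed)

    names = (
        [f"prod{i + 1}" for i in range(n_producers)]
        + [f"cons{i + 1}" for i in range(n_cons)]
        + [f"det{i + 1}" for i in range(n_detritus)]
    )
    n_liv = n_producers + n_cons
    B = np.empty(n_groups)
    PB = np.empty(n_groups)
    QB = np.zeros(n_groups)
    GS = np.zeros(n_groups)
    for i in range(n_groups):
        level = i / max(n_liv - 1, 1)
        B[i] = 10.0 ** rng.uniform(-0.5, 1.0) * (1.0 - 0.6 * min(level, 1.0))
        if i < n_producers:
            PB[i] = rng.uniform(30.0, 120.0)
        elif i < n_liv:
            PB[i] = rng.uniform(0.5, 8.0) * (1.0 - 0.5 * level) + 0.2
            QB[i] = PB[i] / rng.uniform(0.15, 0.3)
            GS[i] = rng.uniform(0.15, 0.3)
        else:
            B[i] = 10.0 ** rng.uniform(0.5, 1.5)
            PB[i] = 0.0

    # cascade diets over lower-indexed prey (detritus allowed for all)
    D = np.zeros((n_groups, n_groups))
    for j in range(n_producers, n_liv):
        prey_pool = list(range(j)) + list(range(n_liv, n_groups))
        picks = [p for p in prey_pool if rng.random() < connectance]
        if not picks:
            picks = [int(rng.integers(0, j))]
        fr = rng.dirichlet(np.ones(len(picks)))
        for p, f in zip(picks, fr):
            D[p, j] += f

    # cap demand at 90% of production, shaving excess into the import term
    Q = B * QB
    imp = np.zeros(n_groups)
    prod = B * PB
    for i in range(n_liv):
        demand = float((D[i, :] * Q).sum())
        cap = 0.9 * prod[i]
        if demand > cap > 0:
            f = cap / demand
            imp += D[i, :] * (1.0 - f)
            D[i, :] *= f
        elif demand > 0 and cap == 0:
            imp += D[i, :]
            D[i, :] = 0.0

    fleets = ["fleet1"] if with_fleet else []
    groups = []
    for i, name in enumerate(names):
        role = "producer" if i < n_producers else "consumer" if i < n_liv else "detritus"
        diet = {}
        if role == "consumer":
            diet = {names[p]: float(D[p, i]) for p in range(n_groups) if D[p, i] > 0}
            if imp[i] > 0:
                diet["import"] = float(imp[i])
        landings = {}
        if with_fleet and i == n_liv - 1:
            landings = {"fleet1": float(0.05 * prod[i])}
        groups.append(
            GroupSpec(
                name=name,
                role=role,
                B=float(B[i]),
                PB=float(PB[i]),
                QB=float(QB[i]),
                GS=float(GS[i]),
                diet=diet,
                landings=landings,
            )
        )
    web = FoodWeb(groups, fleets=fleets)
    return solve_missing_ee(web)


# -- the Baltic-like fixture --------------------------------------------------

BALTIC_GROUPS = [
    "Cyanobacteria",
    "Phytoplankton",
    "Microzooplankton",
    "Temora sp.",
    "Acartia sp.",
    "Pseudocalanus sp.",
    "Mesozooplankton",
    "Mysids",
    "Meiozoobenthos",
    "Macrozoobenthos",
    "Juvenile Sprat",
    "Adult Sprat",
    "Juvenile Herring",
    "Adult Herring",
    "Cod larvae",
    "Juvenile Cod",
    "Small Cod",
    "Adult Cod",
    "Seals",
    "Detritus (s)",
    "Detritus (w)",
]

#: groups excluded from the biomass shift analysis: seals (used as forcing in
#: the source system) and the detritus pools (collinear with production)
BALTIC_EXCLUDE = ["Seals", "Detritus (s)", "Detritus (w)"]

# name, role, B (t/km^2), PB (1/yr), QB (1/yr), GS, diet, landings
_BALTIC_SPEC = [
    ("Cyanobacteria", "producer", 2.0, 120.0, 0.0, 0.0, {}, {}),
    ("Phytoplankton", "producer", 8.0, 180.0, 0.0, 0.0, {}, {}),
    (
        "Microzooplankton",
        "consumer",
        3.0,
        35.0,
        120.0,
        0.30,
        {"Phytoplankton": 0.85, "Cyanobacteria": 0.15},
        {},
    ),
    (
        "Temora sp.",
        "consumer",
        1.2,
        18.0,
        60.0,
        0.30,
        # the small cannibalism term keeps a living (detritus-free) cycle in
        # the web, so predatory cycling is non-degenerate
        {"Phytoplankton": 0.50, "Microzooplankton": 0.35, "Cyanobacteria": 0.10, "Temora sp.": 0.05},
        {},
    ),
    (
        "Acartia sp.",
        "consumer",
        1.0,
        20.0,
        67.0,
        0.30,
        {"Phytoplankton": 0.50, "Microzooplankton": 0.40, "Cyanobacteria": 0.10},
        {},
    ),
    (
        "Pseudocalanus sp.",
        "consumer",
        1.5,
        15.0,
        50.0,
        0.30,
        {"Phytoplankton": 0.70, "Microzooplankton": 0.30},
        {},
    ),
    (
        "Mesozooplankton",
        "consumer",
        1.0,
        12.0,
        40.0,
        0.30,
        {"Phytoplankton": 0.50, "Microzooplankton": 0.50},
        {},
    ),
    (
        "Mysids",
        "consumer",
        1.2,
        4.0,
        16.0,
        0.25,
        {
            "Temora sp.": 0.20,
            "Acartia sp.": 0.20,
            "Pseudocalanus sp.": 0.20,
            "Mesozooplankton": 0.20,
            "Detritus (w)": 0.20,
        },
        {},
    ),
    (
        "Meiozoobenthos",
        "consumer",
        1.5,
        8.0,
        40.0,
        0.30,
        {"Detritus (s)": 0.90, "Phytoplankton": 0.10},
        {},
    ),
    (
        "Macrozoobenthos",
        "consumer",
        4.0,
        2.5,
        12.0,
        0.30,
        {"Detritus (s)": 0.75, "Meiozoobenthos": 0.20, "Phytoplankton": 0.05},
        {},
    ),
    (
        "Juvenile Sprat",
        "consumer",
        0.9,
        1.5,
        12.0,
        0.25,
        {
            "Temora sp.": 0.30,
            "Acartia sp.": 0.35,
            "Pseudocalanus sp.": 0.15,
            "Mesozooplankton": 0.20,
        },
        {"sprat": 0.05},
    ),
    (
        "Adult Sprat",
        "consumer",
        3.5,
        0.9,
        5.5,
        0.20,
        {
            "Temora sp.": 0.30,
            "Acartia sp.": 0.30,
            "Pseudocalanus sp.": 0.25,
            "Mesozooplankton": 0.15,
        },
        {"sprat": 0.9},
    ),
    (
        "Juvenile Herring",
        "consumer",
        0.7,
        1.2,
        8.0,
        0.25,
        {
            "Temora sp.": 0.25,
            "Acartia sp.": 0.30,
            "Pseudocalanus sp.": 0.20,
            "Mesozooplankton": 0.15,
            "Mysids": 0.10,
        },
        {"herring": 0.03},
    ),
    (
        "Adult Herring",
        "consumer",
        2.8,
        0.7,
        4.2,
        0.20,
        {
            "Temora sp.": 0.15,
            "Acartia sp.": 0.15,
            "Pseudocalanus sp.": 0.30,
            "Mysids": 0.20,
            "Mesozooplankton": 0.10,
            "Macrozoobenthos": 0.10,
        },
        {"herring": 0.45},
    ),
    (
        "Cod larvae",
        "consumer",
        0.02,
        5.0,
        25.0,
        0.25,
        {
            "Temora sp.": 0.30,
            "Acartia sp.": 0.30,
            "Pseudocalanus sp.": 0.20,
            "Mesozooplankton": 0.20,
        },
        {},
    ),
    (
        "Juvenile Cod",
        "consumer",
        0.15,
        2.2,
        9.0,
        0.20,
        {
            "Mysids": 0.30,
            "Pseudocalanus sp.": 0.10,
            "Meiozoobenthos": 0.10,
            "Macrozoobenthos": 0.30,
            "Juvenile Sprat": 0.10,
            "Juvenile Herring": 0.10,
        },
        {},
    ),
    (
        "Small Cod",
        "consumer",
        0.6,
        1.3,
        5.5,
        0.20,
        {
            "Macrozoobenthos": 0.40,
            "Mysids": 0.10,
            "Juvenile Sprat": 0.15,
            "Adult Sprat": 0.15,
            "Juvenile Herring": 0.10,
            "Adult Herring": 0.10,
        },
        {"cod": 0.15},
    ),
    (
        "Adult Cod",
        "consumer",
        1.1,
        0.75,
        3.2,
        0.20,
        {
            "Adult Sprat": 0.35,
            "Adult Herring": 0.25,
            "Small Cod": 0.08,
            "Juvenile Sprat": 0.05,
            "Juvenile Herring": 0.05,
            "Macrozoobenthos": 0.12,
            "Mysids": 0.05,
            "import": 0.05,
        },
        {"cod": 0.25},
    ),
    (
        "Seals",
        "consumer",
        0.03,
        0.08,
        12.0,
        0.15,
        {"Adult Cod": 0.30, "Small Cod": 0.10, "Adult Herring": 0.35, "Adult Sprat": 0.25},
        {},
    ),
    ("Detritus (s)", "detritus", 50.0, 0.0, 0.0, 0.0, {}, {}),
    ("Detritus (w)", "detritus", 10.0, 0.0, 0.0, 0.0, {}, {}),
]

#: stanza graduation links (source, sink, rate 1/yr)
_BALTIC_STANZAS = [
    ("Cod larvae", "Juvenile Cod", 2.0),
    ("Juvenile Cod", "Small Cod", 0.8),
    ("Small Cod", "Adult Cod", 0.4),
    ("Juvenile Sprat", "Adult Sprat", 0.3),
    ("Juvenile Herring", "Adult Herring", 0.2),
]


def make_baltic_fixture() -> tuple[FoodWeb, DynamicParams]:
    """Central-Baltic-shaped fixture: 21 groups, 3 fleets, 2 detritus pools.

    Multi-stanza fish (cod larvae -> juvenile -> small -> adult; juvenile ->
    adult sprat and herring) are linked by fixed graduation rates.  All
    parameter values are synthetic placeholders (see module docstring);
    ecotrophic efficiencies are solved from the balance and guaranteed to
    lie in [0, 1].  Construction is seed-free and bit-stable.
    """
    groups = [
        GroupSpec(name=n, role=r, B=b, PB=pb, QB=qb, GS=gs, diet=dict(d), landings=dict(l))
        for n, r, b, pb, qb, gs, d, l in _BALTIC_SPEC
    ]
    web = FoodWeb(
        groups,
        fleets=["cod", "sprat", "herring"],
        detritus_routing={"Detritus (s)": 0.5, "Detritus (w)": 0.5},
    )
    web = solve_missing_ee(web)
    n = web.n
    # vulnerability multipliers: top-down-sensitive cod links above baseline
    k = np.full((n, n), 2.0)
    for pred in ("Small Cod", "Adult Cod"):
        k[:, web.index(pred)] = 3.0
    params = DynamicParams(vulnerability=k, stanza_links=list(_BALTIC_STANZAS))
    return web, params


# -- forcing scenarios --------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Piecewise-constant forcing levels with AR(1) noise.

    ``series`` maps a target name to its level per segment: the name
    ``"pp_multiplier"`` drives primary production, any other name is a
    group's fishing mortality series.  ``shift_years`` are the first years
    of the later segments (len(levels) = len(shift_years) + 1).  Noise is a
    stationary AR(1) with marginal SD ``noise_sd`` (absolute units) applied
    additively to each series.
    """

    n_years: int = 33
    start_year: int = 1974
    shift_years: list[int] = field(default_factory=list)
    series: dict[str, list[float]] = field(default_factory=dict)
    noise_sd: float = 0.0
    ar1_coefficient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        years = range(self.start_year, self.start_year + self.n_years)
        if any(y not in years for y in self.shift_years):
            raise ValueError("shift_years must fall within the simulated span")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("|ar1_coefficient| must be < 1")
        for name, levels in self.series.items():
            if len(levels) != len(self.shift_years) + 1:
                raise ValueError(
                    f"series {name!r}: need {len(self.shift_years) + 1} levels, got {len(levels)}"
                )


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    eps_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0.0, eps_sd)
    return x


def make_forcing_scenario(spec: ScenarioSpec) -> ForcingSet:
    """Build a :class:`ForcingSet` from a scenario (steps + AR(1) noise).

    Multiplier series are floored at a small positive value so noise cannot
    push them non-positive.
    """
    rng = np.random.default_rng(spec.seed)
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    edges = [spec.start_year] + sorted(spec.shift_years) + [spec.start_year + spec.n_years]
    F: dict[str, np.ndarray] = {}
    pp = None
    for name, levels in spec.series.items():
        base = np.empty(spec.n_years, dtype=float)
        for lev, a, b in zip(levels, edges[:-1], edges[1:]):
            base[(years >= a) & (years < b)] = lev
        x = base + _ar1(rng, spec.n_years, spec.ar1_coefficient, spec.noise_sd)
        if name == "pp_multiplier":
            pp = np.clip(x, 1e-3, None)
        else:
            F[name] = np.clip(x, 0.0, None)
    return ForcingSet(years=years, F=F, pp_multiplier=pp)


def make_block_series(
    n1: int = 10,
    n2: int = 10,
    mean_shift: float = 5.0,
    n_vars: int = 4,
    noise_sd: float = 1.0,
    seed: int = 0,
    start_year: int = 1974,
) -> pd.DataFrame:
    """Two multivariate Gaussian blocks (years x variables).

    The first ``n1`` years have mean 0, the following ``n2`` years mean
    ``mean_shift``, in every variable; i.i.d. noise with SD ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    means = np.concatenate([np.zeros(n1), np.full(n2, mean_shift)])
    X = means[:, None] + rng.normal(0.0, noise_sd, size=(n1 + n2, n_vars))
    years = np.arange(start_year, start_year + n1 + n2)
    return pd.DataFrame(X, index=years, columns=[f"var{i + 1}" for i in range(n_vars)])
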