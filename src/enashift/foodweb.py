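"""Mass-balanced food-web data model and its conversion to an annual flow network.

The static description follows the Ecopath bookkeeping convention: each
functional group i carries a biomass ``B`` (t/km^2 wet weight), annual
production/biomass ``PB`` and consumption/biomass ``QB`` ratios (1/yr), an
ecotrophic efficiency ``EE`` (the fraction of production consumed by
predation or removed by the fishery inside the system), an unassimilated
fraction ``GS`` of consumption, a diet-composition column and per-fleet
landings.  The balance identity for every living group is

    B_i * PB_i * EE_i = sum_j B_j * QB_j * DC_ij + Y_i

with DC_ij the fraction of predator j's diet made up of prey i and Y_i the
total catch.  ``check_mass_balance`` reports the residual of this identity,
``solve_missing_ee`` inverts it for EE, and ``to_flow_network`` expands the
balanced web into a compartment-to-compartment flow matrix with explicit
import, export and dissipation (respiration) boundary nodes -- the object
all ecological network analysis indices consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GroupSpec",
    "FoodWeb",
    "FlowNetwork",
    "UnbalancedWebError",
    "MissingEEError",
    "check_mass_balance",
    "solve_missing_ee",
    "trophic_levels",
    "to_flow_network",
]

#: diet key reserved for consumption imported from outside the system
IMPORT_KEY = "import"

ROLES = ("producer", "consumer", "detritus")


class UnbalancedWebError(ValueError):
    """Raised when a web cannot satisfy the mass-balance identity (EE outside [0, 1])."""


class MissingEEError(ValueError):
    """Raised when an operation needs ecotrophic efficiencies that are not set."""


@dataclass
class GroupSpec:
    """One functional group of the web.

    Parameters
    ----------
    name : str
        Unique identifier.
    role : {"producer", "consumer", "detritus"}
    B : float
        Biomass, t/km^2 wet weight.
    PB : float
        Production/biomass ratio, 1/yr (0 for detritus).
    QB : float
        Consumption/biomass ratio, 1/yr; 0 for producers and detritus.
    EE : float or None
        Ecotrophic efficiency in [0, 1]; ``None`` means unknown (to be
        solved from the balance).
    GS : float
        Unassimilated fraction of consumption in [0, 1).
    diet : dict
        prey-name -> fraction; may include an ``"import"`` entry.  Sums to 1
        for consumers, empty for producers and detritus.
    landings : dict
        fleet-name -> catch, t/km^2/yr.
    """

    name: str
    role: str
    B: float
    PB: float
    QB: float = 0.0
    EE: float | None = None
    GS: float = 0.0
    diet: dict[str, float] = field(default_factory=dict)
    landings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"group {self.name!r}: unknown role {self.role!r}")
        if self.B < 0 or self.PB < 0 or self.QB < 0:
            raise ValueError(f"group {self.name!r}: B, PB, QB must be non-negative")
        if not 0.0 <= self.GS < 1.0:
            raise ValueError(f"group {self.name!r}: GS must be in [0, 1)")
        if self.EE is not None and not 0.0 <= self.EE <= 1.0:
            raise ValueError(f"group {self.name!r}: EE must be in [0, 1] or None")
        if self.role == "consumer":
            if self.QB <= 0:
                raise ValueError(f"consumer {self.name!r} needs QB > 0")
            total = sum(self.diet.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"consumer {self.name!r}: diet fractions sum to {total:g}, expected 1"
                )
            if any(v < 0 for v in self.diet.values()):
                raise ValueError(f"consumer {self.name!r}: negative diet fraction")
        else:
            if self.diet:
                raise ValueError(f"{self.role} {self.name!r} must have an empty diet")
        if any(v < 0 for v in self.landings.values()):
            raise ValueError(f"group {self.name!r}: negative landings")

    @property
    def is_living(self) -> bool:
        return self.role != "detritus"


@dataclass
class FoodWeb:
    """Ordered collection of groups plus fleet list and detritus routing.

    ``detritus_routing`` maps each detritus group to its share of every
    detrital inflow (egestion and non-predation mortality); shares sum to 1.
    """

    groups: list[GroupSpec]
    fleets: list[str] = field(default_factory=list)
    detritus_routing: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        det = [g.name for g in self.groups if g.role == "detritus"]
        if not det:
            raise ValueError("a food web needs at least one detritus group")
        if not self.detritus_routing:
            self.detritus_routing = {d: 1.0 / len(det) for d in det}
        if set(self.detritus_routing) != set(det):
            raise ValueError("detritus_routing keys must be exactly the detritus groups")
        if abs(sum(self.detritus_routing.values()) - 1.0) > 1e-9:
            raise ValueError("detritus_routing shares must sum to 1")
        known = set(names) | {IMPORT_KEY}
        for g in self.groups:
            bad = set(g.diet) - known
            if bad:
                raise ValueError(f"group {g.name!r}: unresolved diet entries {sorted(bad)}")
            badf = set(g.landings) - set(self.fleets)
            if badf:
                raise ValueError(f"group {g.name!r}: unresolved fleets {sorted(badf)}")

    # -- convenience accessors ------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def role_mask(self, role: str) -> np.ndarray:
        return np.array([g.role == role for g in self.groups])

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(g, attr) for g in self.groups], dtype=float)

    def diet_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(D, imp)``: D[i, j] is the fraction of predator j's diet on
        prey i; ``imp[j]`` the import fraction."""
        n = self.n
        idx = {nm: i for i, nm in enumerate(self.names)}
        D = np.zeros((n, n))
        imp = np.zeros(n)
        for j, g in enumerate(self.groups):
            for prey, frac in g.diet.items():
                if prey == IMPORT_KEY:
                    imp[j] = frac
                else:
                    D[idx[prey], j] = frac
        return D, imp

    def consumption(self, B: np.ndarray | None = None) -> np.ndarray:
        """Total consumption per group, t/km^2/yr (B_j * QB_j)."""
        b = self.array("B") if B is None else np.asarray(B, dtype=float)
        return b * self.array("QB")

    def predation(self, B: np.ndarray | None = None) -> np.ndarray:
        """Predation mortality flow onto each group, t/km^2/yr."""
        D, _ = self.diet_matrix()
        return D @ self.consumption(B)

    def catches(self) -> np.ndarray:
        return np.array([sum(g.landings.values()) for g in self.groups], dtype=float)


# boundary node offsets in the flow matrix (relative to compartment count n)
IMPORT, EXPORT, RESPIRATION = 0, 1, 2


@dataclass
class FlowNetwork:
    """Compartment flow matrix with boundary nodes.

    ``T`` is an ``(n+3, n+3)`` non-negative matrix, t/km^2/yr.  Rows are
    donors, columns receivers; indices ``0..n-1`` are compartments and the
    last three are import (row n), export (column n+1) and dissipation /
    respiration (column n+2).  No flow leaves export or dissipation and
    none enters import.  For a balanced web every living compartment's
    inflow equals its outflow.

    ``biomass``, ``production`` and ``catch`` are per-compartment metadata
    (t/km^2 and t/km^2/yr) used by the ecosystem-level ratio indices.
    """

    T: np.ndarray
    labels: list[str]
    living: np.ndarray
    detritus: np.ndarray
    biomass: np.ndarray | None = None
    production: np.ndarray | None = None
    catch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        n = self.n
        if self.T.shape != (n + 3, n + 3):
            raise ValueError("T must be (n+3) x (n+3)")
        if (self.T < -1e-12).any():
            raise ValueError("negative flow in network")
        self.T[self.T < 0] = 0.0
        if self.T[:, n + IMPORT].any():
            raise ValueError("no flow may enter the import node")
        if self.T[n + EXPORT, :].any() or self.T[n + RESPIRATION, :].any():
            raise ValueError("no flow may leave export or dissipation nodes")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def imports(self) -> np.ndarray:
        """Boundary inflow per compartment (import row)."""
        return self.T[self.n + IMPORT, : self.n]

    @property
    def exports(self) -> np.ndarray:
        return self.T[: self.n, self.n + EXPORT]

    @property
    def respiration(self) -> np.ndarray:
        return self.T[: self.n, self.n + RESPIRATION]

    @property
    def internal(self) -> np.ndarray:
        """Compartment-to-compartment flow block (n x n)."""
        return self.T[: self.n, : self.n]

    def inflow(self) -> np.ndarray:
        return self.T[:, : self.n].sum(axis=0)

    def outflow(self) -> np.ndarray:
        return self.T[: self.n, :].sum(axis=1)

    def throughflow(self) -> np.ndarray:
        """Per-compartment throughflow: max(inflow, outflow), robust to small
        storage imbalance."""
        return np.maximum(self.inflow(), self.outflow())

    def balance_residuals(self) -> np.ndarray:
        """inflow - outflow per compartment (zero at steady state)."""
        return self.inflow() - self.outflow()

    def subnetwork(self, keep: np.ndarray) -> "FlowNetwork":
        """Network restricted to compartments where ``keep`` is True; flows
        touching dropped compartments are removed."""
        keep = np.asarray(keep, dtype=bool)
        idx = np.concatenate([np.flatnonzero(keep), self.n + np.arange(3)])
        return FlowNetwork(
            T=self.T[np.ix_(idx, idx)].copy(),
            labels=[l for l, k in zip(self.labels, keep) if k],
            living=self.living[keep],
            detritus=self.detritus[keep],
            biomass=None if self.biomass is None else self.biomass[keep],
            production=None if self.production is None else self.production[keep],
            catch=None if self.catch is None else self.catch[keep],
        )


def _require_ee(web: FoodWeb) -> np.ndarray:
    ee = [g.EE for g in web.groups]
    missing = [g.name for g, e in zip(web.groups, ee) if e is None and g.is_living]
    if missing:
        raise MissingEEError(f"cannot check balance: EE unknown for {missing}")
    return np.array([0.0 if e is None else e for e in ee], dtype=float)


def check_mass_balance(web: FoodWeb) -> np.ndarray:
    """Residual of the Ecopath balance identity per group, t/km^2/yr.

    residual_i = B_i*PB_i*EE_i - (predation_i + catch_i); zero for a
    balanced web, negative where allocated production (predation plus
    catch) exceeds the available production.  Detritus groups have no
    production term and report 0.
    """
    ee = _require_ee(web)
    living = ~web.role_mask("detritus")
    res = web.array("B") * web.array("PB") * ee - web.predation() - web.catches()
    res[~living] = 0.0
    return res


def solve_missing_ee(web: FoodWeb, atol: float = 1e-9) -> FoodWeb:
    """Return a copy of the web with unknown EEs solved from the balance.

    EE_i = (predation_i + catch_i) / (B_i * PB_i).  Groups that are neither
    eaten nor caught get EE = 0.  Raises :class:`UnbalancedWebError` naming
    the first group whose solved EE exceeds 1.
    """
    demand = web.predation() + web.catches()
    prod = web.array("B") * web.array("PB")
    groups = []
    for i, g in enumerate(web.groups):
        if g.role == "detritus" or g.EE is not None:
            groups.append(replace(g, diet=dict(g.diet), landings=dict(g.landings)))
            continue
        if prod[i] <= 0:
            if demand[i] > atol:
                raise UnbalancedWebError(
                    f"group {g.name!r}: positive demand {demand[i]:g} but zero production"
                )
            ee = 0.0
        else:
            ee = demand[i] / prod[i]
        if ee > 1.0 + 1e-9:
            raise UnbalancedWebError(
                f"unbalanced web: group {g.name!r} has EE = {ee:.4f} > 1 "
                f"(predation + catch {demand[i]:g} exceeds production {prod[i]:g})"
            )
        groups.append(
            replace(g, EE=min(ee, 1.0), diet=dict(g.diet), landings=dict(g.landings))
        )
    return FoodWeb(groups, list(web.fleets), dict(web.detritus_routing))


def trophic_levels(web: FoodWeb) -> np.ndarray:
    """Fractional trophic levels: TL_i = 1 + sum_j DC_ji * TL_j.

    Producers, detritus and imported food sit at TL 1; consumer levels
    solve the linear system over the diet matrix.
    """
    n = web.n
    D, imp = web.diet_matrix()
    A = np.eye(n)
    b = np.ones(n)
    consumer = web.role_mask("consumer")
    for i in range(n):
        if consumer[i]:
            A[i, :] -= D[:, i]
            b[i] = 1.0 + imp[i]  # imported food counts as TL-1 material
    try:
        tl = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological diets
        raise ValueError(f"trophic-level system is singular: {exc}") from exc
    if not np.all(np.isfinite(tl)) or (tl < 1 - 1e-9).any():
        raise ValueError("trophic-level solution invalid (check diet matrix)")
    return tl


def to_flow_network(
    web: FoodWeb, biomass_override: np.ndarray | None = None
) -> FlowNetwork:
    """Expand a balanced web into the steady-state flow network.

    Flows, all t/km^2/yr:

    * consumption prey->pred = B_pred * QB_pred * DC
    * primary production enters producers from the import node
    * import-diet share of consumption enters from the import node
    * egestion GS*Q plus non-predation deaths (1-EE)*B*PB go to the
      detritus pools via ``detritus_routing``
    * respiration = (1-GS)*Q - B*PB per consumer, floored at 0 with a
      warning when inputs imply negative respiration
    * landings leave via the export node; detritus surplus (deficit) is
      balanced against export (import)

    ``biomass_override`` rescales consumption/production with alternative
    biomasses while keeping the web's rate ratios.
    """
    ee = _require_ee(web)
    n = web.n
    B = web.array("B") if biomass_override is None else np.asarray(biomass_override, float)
    if (B < 0).any():
        raise ValueError("negative biomass")
    PB, GS = web.array("PB"), web.array("GS")
    D, imp = web.diet_matrix()
    Q = B * web.array("QB")  # total consumption per predator
    catch = web.catches()
    producer = web.role_mask("producer")
    consumer = web.role_mask("consumer")
    det_mask = web.role_mask("detritus")

    T = np.zeros((n + 3, n + 3))
    iIMP, iEXP, iRSP = n + IMPORT, n + EXPORT, n + RESPIRATION

    T[:n, :n] = D * Q[None, :]  # prey -> predator
    T[iIMP, :n] += imp * Q  # imported food
    T[iIMP, np.flatnonzero(producer)] += (B * PB)[producer]  # primary production
    T[:n, iEXP] += catch

    # flows to detritus: egestion + non-predation mortality
    to_det = GS * Q + (1.0 - ee) * B * PB
    to_det[det_mask] = GS[det_mask] * Q[det_mask]  # detritus neither produces nor dies
    det_idx = {web.index(name): share for name, share in web.detritus_routing.items()}
    for d, share in det_idx.items():
        T[:n, d] += share * to_det

    # respiration (consumers only; producer P/B is net of respiration here)
    resp = (1.0 - GS) * Q - B * PB
    resp[~consumer] = 0.0
    if (resp < -1e-9).any():
        bad = [web.names[i] for i in np.flatnonzero(resp < -1e-9)]
        warnings.warn(
            f"negative respiration floored at 0 for {bad}; "
            "P/B exceeds assimilated consumption -- web flagged unbalanced",
            stacklevel=2,
        )
    T[:n, iRSP] = np.clip(resp, 0.0, None)

    # balance each detritus pool against the boundary
    for d in det_idx:
        surplus = T[:, d].sum() - T[d, : n].sum() - T[d, iEXP]
        if surplus >= 0:
            T[d, iEXP] += surplus
        else:
            T[iIMP, d] += -surplus

    production = B * PB
    production[det_mask] = 0.0
    return FlowNetwork(
        T=T,
        labels=list(web.names),
        living=~det_mask,
        detritus=det_mask,
        biomass=B.copy(),
        production=production,
        catch=catch,
    )
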