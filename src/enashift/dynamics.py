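"""Biomass dynamics of a balanced food web under annual forcing.

The state equation for each consumer group is the Ecosim-style master
equation

    dB_i/dt = g_i * sum_j Q_ji  -  sum_j Q_ij  -  (M0_i + F_i(t) + e_i) B_i  +  I_i

with ``g_i`` the net growth efficiency (production/consumption), ``Q_ji``
the consumption of prey j by i, ``M0_i`` the non-predation natural
mortality, ``F_i(t)`` the (forced) fishing mortality, and ``e_i``/``I_i``
emigration rate and immigration flow.  Producers replace the consumption
gain by a saturating primary-production term scaled by the forcing's
primary-production multiplier; detritus pools follow donor bookkeeping
(egestion plus natural deaths in, consumption and burial/export out).

Consumption follows the foraging-arena closure

    Q_ij = a_ij * v_ij * B_i * B_j / (2 v_ij + a_ij B_j)

in which prey shuttle between vulnerable and invulnerable states; ``v_ij``
is the vulnerability exchange rate and ``a_ij`` the effective search rate.
Both are back-solved from the baseline (Ecopath) flows and a dimensionless
vulnerability multiplier k >= 1, chosen so that the predation mortality
exerted by predator j saturates at ``2 k`` times its baseline value as the
predator grows.  With the baseline biomasses and forcing at 1, every
derivative is zero by construction: M0 (and the detritus burial rate) are
calibrated so the Ecopath state is an equilibrium of the dynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .foodweb import IMPORT, EXPORT, RESPIRATION, FlowNetwork, FoodWeb, to_flow_network

__all__ = [
    "DynamicParams",
    "ForcingSet",
    "Trajectory",
    "CalibratedModel",
    "calibrate",
    "consumption_matrix",
    "derivative",
    "simulate",
    "annual_flow_snapshots",
    "neutral_forcing",
]

#: relative biomass floor applied during integration
B_FLOOR_REL = 1e-9


@dataclass
class DynamicParams:
    """Rate parameters of the dynamic model.

    ``vulnerability`` is the dimensionless foraging-arena multiplier per
    trophic link (prey x predator), >= 1; scalar broadcast allowed.
    ``stanza_links`` are (source, sink, graduation-rate 1/yr) triples moving
    biomass between life stages of a split group.  ``M0`` is normally left
    ``None`` and calibrated; ``g`` defaults to PB/QB from the web.
    """

    g: np.ndarray | None = None
    M0: np.ndarray | None = None
    e: np.ndarray | None = None
    I: np.ndarray | None = None
    vulnerability: np.ndarray | float = 2.0
    stanza_links: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class ForcingSet:
    """Annual forcing series sharing one year axis.

    ``F`` maps group name -> fishing mortality series (1/yr, absolute);
    groups absent from ``F`` keep their baseline mortality.
    ``pp_multiplier`` scales primary production (1 = baseline).
    ``env_multiplier`` maps (prey-name, pred-name) -> multiplier series on
    the link's search rate (1 = baseline); the wiring of environmental
    drivers onto links is deliberately explicit per run.
    """

    years: np.ndarray
    F: dict[str, np.ndarray] = field(default_factory=dict)
    pp_multiplier: np.ndarray | None = None
    env_multiplier: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        ny = len(self.years)
        if self.pp_multiplier is None:
            self.pp_multiplier = np.ones(ny)
        self.pp_multiplier = np.asarray(self.pp_multiplier, dtype=float)
        for name, s in {**self.F}.items():
            self.F[name] = np.asarray(s, dtype=float)
            if len(self.F[name]) != ny:
                raise ValueError(f"forcing series {name!r} length mismatch")
        if len(self.pp_multiplier) != ny or (self.pp_multiplier <= 0).any():
            raise ValueError("pp_multiplier must be positive and match the year axis")
        for key, s in {**self.env_multiplier}.items():
            s = np.asarray(s, dtype=float)
            if len(s) != ny or (s <= 0).any():
                raise ValueError(f"env multiplier {key} invalid")
            self.env_multiplier[key] = s

    @property
    def n_years(self) -> int:
        return len(self.years)


def neutral_forcing(web: FoodWeb, years: np.ndarray | list[int]) -> ForcingSet:
    """Forcing that holds every driver at its baseline over ``years``."""
    return ForcingSet(years=np.asarray(years, dtype=int))


@dataclass
class Trajectory:
    """Yearly output of the integration.

    ``B`` is the within-year mean biomass (years x groups, t/km^2); ``Q``
    the accumulated prey->predator consumption (years x n x n, t/km^2/yr);
    ``Q_import``, ``production``, ``deaths`` (non-predation mortality flow),
    ``Y`` (catch) are years x groups; ``stanza_flow`` follows the order of
    ``params.stanza_links``.
    """

    years: np.ndarray
    B: np.ndarray
    Q: np.ndarray
    Q_import: np.ndarray
    production: np.ndarray
    deaths: np.ndarray
    Y: np.ndarray
    stanza_flow: np.ndarray


class CalibratedModel:
    """Web + params with all rate constants back-solved from baseline flows."""

    def __init__(self, web: FoodWeb, params: DynamicParams):
        self.web = web
        self.params = params
        n = web.n
        self.n = n
        base = to_flow_network(web)
        self.baseline_net = base
        self.B0 = web.array("B")
        self.PB = web.array("PB")
        self.GS = web.array("GS")
        self.producer = web.role_mask("producer")
        self.consumer = web.role_mask("consumer")
        self.det = web.role_mask("detritus")
        D, imp = web.diet_matrix()
        Qtot0 = web.consumption()
        self.Q0 = D * Qtot0[None, :]  # prey x predator baseline flows
        self.Qimp0 = imp * Qtot0

        g = params.g
        if g is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                g = np.where(Qtot0 > 0, self.B0 * self.PB / np.where(Qtot0 > 0, Qtot0, 1), 0.0)
        self.g = np.asarray(g, dtype=float)
        if ((self.g[self.consumer] <= 0) | (self.g[self.consumer] > 1)).any():
            raise ValueError("net growth efficiency g must lie in (0, 1] for consumers")
        if ((self.g + self.GS)[self.consumer] > 1 + 1e-9).any():
            raise ValueError("g + GS > 1 implies negative respiration")

        self.e = np.zeros(n) if params.e is None else np.asarray(params.e, float)
        self.I = np.zeros(n) if params.I is None else np.asarray(params.I, float)
        if (self.e < 0).any() or (self.I < 0).any():
            raise ValueError("e and I must be non-negative")

        k = np.broadcast_to(np.asarray(params.vulnerability, float), (n, n)).copy()
        if (k[self.Q0 > 0] < 1.0).any():
            raise ValueError("vulnerability multipliers must be >= 1")
        self.k = k
        # foraging-arena constants from the baseline identity
        active = self.Q0 > 0
        self.v_rate = np.zeros((n, n))
        self.a = np.zeros((n, n))
        Bi = self.B0[:, None]
        Bj = self.B0[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(active & (Bi > 0), 2.0 * k * self.Q0 / np.where(Bi > 0, Bi, 1), 0.0)
            a = np.where(
                active & (Bj > 0),
                2.0 * v / (np.where(Bj > 0, Bj, 1) * (2.0 * k - 1.0)),
                0.0,
            )
        self.v_rate, self.a = v, a

        # stanza graduation: source index, sink index, rate
        idx = {nm: i for i, nm in enumerate(web.names)}
        self.stanzas = [(idx[s], idx[d], float(r)) for s, d, r in params.stanza_links]

        # baseline fishing mortality from landings
        catch = web.catches()
        with np.errstate(divide="ignore", invalid="ignore"):
            self.F0 = np.where(self.B0 > 0, catch / np.where(self.B0 > 0, self.B0, 1), 0.0)

        # producer saturation: P(B) = p*B / (1 + B/B0), p = 2*PB at baseline
        self.p_rate = np.where(self.producer, 2.0 * self.PB, 0.0)

        # non-predation mortality M0 back-solved so derivative(baseline) = 0
        if params.M0 is not None:
            self.M0 = np.asarray(params.M0, float)
        else:
            gain = np.zeros(n)
            gain[self.consumer] = (self.g * (self.Q0.sum(axis=0) + self.Qimp0))[self.consumer]
            gain[self.producer] = (self.B0 * self.PB)[self.producer]
            stanza_net = np.zeros(n)
            for s, d, r in self.stanzas:
                stanza_net[s] -= r * self.B0[s]
                stanza_net[d] += r * self.B0[s]
            loss_pred = self.Q0.sum(axis=1)  # predation on each group
            num = gain + self.I + stanza_net - loss_pred - (self.F0 + self.e) * self.B0
            with np.errstate(divide="ignore", invalid="ignore"):
                M0 = np.where(self.B0 > 0, num / np.where(self.B0 > 0, self.B0, 1), 0.0)
            M0[self.det] = 0.0
            if (M0 < -1e-9).any():
                bad = [web.names[i] for i in np.flatnonzero(M0 < -1e-9)]
                raise ValueError(
                    f"calibrated M0 negative for {bad}: baseline losses exceed production"
                )
            self.M0 = np.clip(M0, 0.0, None)

        # detritus burial/export rate (or import) closing the detritus budget
        det_in = np.zeros(n)
        deaths0 = self.M0 * self.B0  # equals (1-EE)*B*PB for plain groups
        eges0 = self.GS * (self.Q0.sum(axis=0) + self.Qimp0)
        routing = {web.index(nm): sh for nm, sh in web.detritus_routing.items()}
        for d_i, share in routing.items():
            det_in[d_i] = share * float((deaths0 + eges0).sum())
        self.s_det = np.zeros(n)
        self.I_det = np.zeros(n)
        for d_i in routing:
            surplus = det_in[d_i] - self.Q0[d_i, :].sum()
            if surplus >= 0 and self.B0[d_i] > 0:
                self.s_det[d_i] = surplus / self.B0[d_i]
            else:
                self.I_det[d_i] = max(-surplus, 0.0)
        self.routing = routing

    # -- forcing lookup -------------------------------------------------------

    def _year_index(self, forcing: ForcingSet, t: float) -> int:
        i = int(np.floor(t))
        return min(max(i, 0), forcing.n_years - 1)

    def forcing_at(self, forcing: ForcingSet, t: float):
        """Stepwise-constant within-year forcing: (F vector, pp mult, env a-scale)."""
        yi = self._year_index(forcing, t)
        F = self.F0.copy()
        idx = {nm: i for i, nm in enumerate(self.web.names)}
        for name, series in forcing.F.items():
            F[idx[name]] = series[yi]
        env = np.ones((self.n, self.n))
        for (prey, pred), series in forcing.env_multiplier.items():
            env[idx[prey], idx[pred]] = series[yi]
        return F, float(forcing.pp_multiplier[yi]), env

    # -- core terms -----------------------------------------------------------

    def consumption(self, B: np.ndarray, env: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Foraging-arena consumption (prey x predator) and import consumption."""
        B = np.asarray(B, dtype=float)
        if (B < 0).any():
            raise ValueError("negative biomass")
        a = self.a if env is None else self.a * env
        num = a * self.v_rate * B[:, None] * B[None, :]
        den = 2.0 * self.v_rate + a * B[None, :]
        Q = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            Qimp = np.where(self.B0 > 0, self.Qimp0 * B / np.where(self.B0 > 0, self.B0, 1), 0.0)
        return Q, Qimp

    def production_rate(self, B: np.ndarray, pp_mult: float) -> np.ndarray:
        """Saturating primary production per producer, t/km^2/yr."""
        with np.errstate(divide="ignore", invalid="ignore"):
            sat = np.where(self.B0 > 0, 1.0 + B / np.where(self.B0 > 0, self.B0, 1), 1.0)
        P = pp_mult * self.p_rate * B / sat
        P[~self.producer] = 0.0
        return P

    def derivative(self, B: np.ndarray, t: float, forcing: ForcingSet) -> np.ndarray:
        F, pp, env = self.forcing_at(forcing, t)
        return self._derivative(B, F, pp, env)[0]

    def _derivative(self, B, F, pp, env):
        Q, Qimp = self.consumption(B, env)
        Qin = Q.sum(axis=0) + Qimp
        Qout = Q.sum(axis=1)
        P = self.production_rate(B, pp)
        dB = np.zeros(self.n)
        c, pr, dt_ = self.consumer, self.producer, self.det
        dB[c] = (self.g * Qin - Qout - (self.M0 + F + self.e) * B + self.I)[c]
        dB[pr] = (P - Qout - (self.M0 + F + self.e) * B + self.I)[pr]
        # detritus: egestion + deaths in, consumption + burial out
        deaths = self.M0 * B
        eges = self.GS * Qin
        pool_in = float((deaths + eges).sum())
        for d_i, share in self.routing.items():
            dB[d_i] = share * pool_in - Qout[d_i] - self.s_det[d_i] * B[d_i] + self.I_det[d_i]
        for s, d, r in self.stanzas:
            dB[s] -= r * B[s]
            dB[d] += r * B[s]
        return dB, Q, Qimp, P, deaths, F

    # -- integration ----------------------------------------------------------

    def _stability_steps(self, forcing: ForcingSet) -> int:
        """Sub-steps per year keeping RK4 inside its stability region.

        The fastest per-capita rate in the system (plankton production and
        consumption reach O(100)/yr) bounds the stiffest eigenvalue; the
        step count scales with it so fast groups do not blow up numerically.
        """
        pp_max = float(np.max(forcing.pp_multiplier))
        env_max = 1.0
        for s in forcing.env_multiplier.values():
            env_max = max(env_max, float(np.max(s)))
        F_max = self.F0.copy()
        idx = {nm: i for i, nm in enumerate(self.web.names)}
        for name, s in forcing.F.items():
            F_max[idx[name]] = float(np.max(s))
        rate = (
            self.PB * pp_max
            + self.web.array("QB") * env_max
            + self.M0
            + F_max
            + self.e
            + self.s_det
        )
        for s, _, r in self.stanzas:
            rate[s] += r
        return int(np.ceil(1.2 * max(float(rate.max()), 12.0)))

    def simulate(self, forcing: ForcingSet, dt: float = 1.0 / 12.0) -> Trajectory:
        """RK4 integration over the forcing years.

        ``dt`` sets the requested step (at most monthly); the effective
        step is shortened further whenever the web's rate constants demand
        it for numerical stability (see :meth:`_stability_steps`).  Yearly
        biomass is the mean over within-year sub-steps; yearly flows
        (consumption, production, deaths, catch, stanza graduation) are
        accumulated left-rectangle integrals, t/km^2/yr.
        """
        if dt > 1.0 / 12.0 + 1e-12:
            raise ValueError("dt must be at most one month (1/12 yr)")
        ny, n = forcing.n_years, self.n
        steps = max(int(round(1.0 / dt)), self._stability_steps(forcing))
        dt = 1.0 / steps
        B = self.B0.copy()
        floor = B_FLOOR_REL * np.where(self.B0 > 0, self.B0, 1.0)
        out_B = np.zeros((ny, n))
        out_Q = np.zeros((ny, n, n))
        out_Qimp = np.zeros((ny, n))
        out_P = np.zeros((ny, n))
        out_death = np.zeros((ny, n))
        out_Y = np.zeros((ny, n))
        out_stanza = np.zeros((ny, len(self.stanzas)))
        floored = False
        for y in range(ny):
            F, pp, env = self.forcing_at(forcing, y + 0.5)

            def accumulate(weight, Bval, Q, Qimp, P, deaths):
                # trapezoid weights over the year's sub-step nodes
                w = weight * dt
                out_B[y] += weight * Bval / steps
                out_Q[y] += Q * w
                out_Qimp[y] += Qimp * w
                out_P[y] += P * w
                out_death[y] += deaths * w
                out_Y[y] += F * Bval * w
                for li, (src, _, r) in enumerate(self.stanzas):
                    out_stanza[y, li] += r * Bval[src] * w

            for s in range(steps):
                d1, Q, Qimp, P, deaths, _ = self._derivative(B, F, pp, env)
                accumulate(0.5 if s == 0 else 1.0, B, Q, Qimp, P, deaths)
                d2 = self._derivative(np.clip(B + 0.5 * dt * d1, floor, None), F, pp, env)[0]
                d3 = self._derivative(np.clip(B + 0.5 * dt * d2, floor, None), F, pp, env)[0]
                d4 = self._derivative(np.clip(B + dt * d3, floor, None), F, pp, env)[0]
                B = B + (dt / 6.0) * (d1 + 2 * d2 + 2 * d3 + d4)
                if not np.all(np.isfinite(B)):
                    bad = int(np.flatnonzero(~np.isfinite(B))[0])
                    raise FloatingPointError(
                        f"non-finite biomass for group {self.web.names[bad]!r} "
                        f"at year {forcing.years[y]}, sub-step {s}"
                    )
                if (B < floor).any():
                    floored = True
                    B = np.maximum(B, floor)
            # closing node of the year's trapezoid, at this year's forcing
            _, Q, Qimp, P, deaths, _ = self._derivative(B, F, pp, env)
            accumulate(0.5, B, Q, Qimp, P, deaths)
        if floored:
            import warnings

            warnings.warn("biomass floored at epsilon during integration", stacklevel=2)
        return Trajectory(
            years=forcing.years.copy(),
            B=out_B,
            Q=out_Q,
            Q_import=out_Qimp,
            production=out_P,
            deaths=out_death,
            Y=out_Y,
            stanza_flow=out_stanza,
        )

    # -- snapshots ------------------------------------------------------------

    def annual_flow_snapshots(self, traj: Trajectory) -> list[FlowNetwork]:
        """One flow network per simulated year, built from realized flows.

        Layout matches :func:`enashift.foodweb.to_flow_network`, with stanza
        graduation flows added as internal source->sink transfers and the
        calibrated detritus burial rate feeding the export column.  Small
        within-year storage changes leave transient compartments slightly
        unbalanced; this is expected away from equilibrium.
        """
        nets = []
        n = self.n
        iIMP, iEXP, iRSP = n + IMPORT, n + EXPORT, n + RESPIRATION
        for y in range(len(traj.years)):
            T = np.zeros((n + 3, n + 3))
            Qin = traj.Q[y].sum(axis=0) + traj.Q_import[y]
            T[:n, :n] = traj.Q[y]
            T[iIMP, :n] += traj.Q_import[y]
            T[iIMP, np.flatnonzero(self.producer)] += traj.production[y][self.producer]
            T[:n, iEXP] += traj.Y[y]
            to_det = self.GS * Qin + traj.deaths[y]
            for d_i, share in self.routing.items():
                T[:n, d_i] += share * to_det
            prod_cons = np.where(self.consumer, self.g * Qin, traj.production[y])
            resp = (1.0 - self.GS) * Qin - prod_cons
            resp[~self.consumer] = 0.0
            T[:n, iRSP] = np.clip(resp, 0.0, None)
            for li, (src, dst, _) in enumerate(self.stanzas):
                T[src, dst] += traj.stanza_flow[y, li]
            for d_i in self.routing:
                T[d_i, iEXP] += self.s_det[d_i] * traj.B[y, d_i]
                T[iIMP, d_i] += self.I_det[d_i]
            production = prod_cons.copy()
            production[self.det] = 0.0
            nets.append(
                FlowNetwork(
                    T=T,
                    labels=list(self.web.names),
                    living=~self.det,
                    detritus=self.det,
                    biomass=traj.B[y].copy(),
                    production=production,
                    catch=traj.Y[y].copy(),
                )
            )
        return nets


# -- functional facade ---------------------------------------------------------


def calibrate(web: FoodWeb, params: DynamicParams | None = None) -> CalibratedModel:
    """Back-solve all rate constants so the balanced web is an equilibrium."""
    return CalibratedModel(web, params or DynamicParams())


def consumption_matrix(
    B: np.ndarray,
    web: FoodWeb,
    params: DynamicParams | None = None,
    multipliers: np.ndarray | None = None,
    model: CalibratedModel | None = None,
) -> np.ndarray:
    """Foraging-arena consumption flows (prey x predator) at biomass ``B``."""
    m = model or calibrate(web, params)
    return m.consumption(B, multipliers)[0]


def derivative(
    B: np.ndarray,
    t: float,
    web: FoodWeb,
    params: DynamicParams | None = None,
    forcing: ForcingSet | None = None,
    model: CalibratedModel | None = None,
) -> np.ndarray:
    """dB/dt (t/km^2/yr) at state ``B`` and time ``t`` (years from series start)."""
    m = model or calibrate(web, params)
    if forcing is None:
        forcing = neutral_forcing(web, [0])
    return m.derivative(np.asarray(B, float), t, forcing)


def simulate(
    web: FoodWeb,
    params: DynamicParams | None = None,
    forcing: ForcingSet | None = None,
    dt: float = 1.0 / 12.0,
    model: CalibratedModel | None = None,
) -> Trajectory:
    """Integrate the master equation over the forcing years (RK4, monthly default)."""
    m = model or calibrate(web, params)
    if forcing is None:
        raise ValueError("forcing is required (use neutral_forcing for a baseline run)")
    return m.simulate(forcing, dt=dt)


def annual_flow_snapshots(
    traj: Trajectory,
    web: FoodWeb,
    params: DynamicParams | None = None,
    model: CalibratedModel | None = None,
) -> list[FlowNetwork]:
    """Yearly flow networks from a simulated trajectory."""
    m = model or calibrate(web, params)
    return m.annual_flow_snapshots(traj)
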