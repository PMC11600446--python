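"""Reduced-order whole-body cardiorenal model.

A ~15-state daily-stepped model of long-term blood pressure and renal
function: sodium balance sets extracellular volume, volume drives cardiac
output and (through whole-body autoregulation) arterial pressure, pressure
and hormones set renal vascular tone, glomerular pressure and filtration,
and filtration closes the loop through pressure natriuresis.  Slow states
(body sodium, left-ventricular mass, nephron number, delayed glomerular
damage) are integrated with a one-day outer step; circulatory and hormonal
variables are treated as quasi-steady within the day and solved by a damped
fixed-point iteration.

Everything is vectorized over patients: parameters and state variables are
arrays of shape ``(n,)`` so an entire virtual population advances through
the simulator at once.

Units: pressures mmHg; renal flows mL/min; cardiac output L/min; sodium
mEq; volumes L; hormone units as reported clinically; time days.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy.special import expit

from .damage import DamageState
from .params import ParameterSet

__all__ = [
    "CardiorenalModel",
    "CardiorenalState",
    "HemodynamicOutputs",
    "Outputs",
    "Interventions",
    "ModelError",
    "ConvergenceError",
    "DegenerateKidneyError",
]


class ModelError(RuntimeError):
    """Base class for simulation failures."""


class ConvergenceError(ModelError):
    """Quasi-steady or steady-state solve failed; names the worst variable."""


class DegenerateKidneyError(ModelError):
    """No functional nephrons: GFR is 0 and Pc is undefined."""


@dataclass
class Interventions:
    """Active interventions for one integration interval.

    ``ccb_conc`` is the plasma amlodipine concentration (ng/mL, scalar or
    per-patient array) applied over the interval; ``ras_fraction`` scales
    every angiotensin-II effect channel by ``1 - fraction``;
    ``salt_override`` (mEq/day) replaces the patient's own salt intake.
    """

    ccb_conc: float | np.ndarray = 0.0
    ras_fraction: float = 0.0
    salt_override: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= float(self.ras_fraction) <= 1.0):
            raise ValueError("ras_fraction must be in [0, 1]")
        if np.any(np.asarray(self.ccb_conc) < 0):
            raise ValueError("ccb concentration must be non-negative")
        if self.salt_override is not None and np.any(
            np.asarray(self.salt_override) <= 0
        ):
            raise ValueError("salt intake must be positive")


@dataclass
class Outputs:
    """Quasi-steady circulatory/hormonal solution at one time point."""

    map: np.ndarray
    co: np.ndarray
    rnr: np.ndarray
    q_kidney: np.ndarray
    rbf: np.ndarray
    ra: np.ndarray
    re: np.ndarray
    pc: np.ndarray
    sngfr: np.ndarray
    gfr: np.ndarray
    md_na: np.ndarray
    tgf: np.ndarray
    renin: np.ndarray
    ang2: np.ndarray
    ang2_eff: np.ndarray
    aldosterone: np.ndarray
    anp: np.ndarray
    sympathetic: np.ndarray
    fp: np.ndarray
    fd: np.ndarray
    una: np.ndarray  # mEq/min
    ecfv: np.ndarray
    converged: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass(frozen=True)
class HemodynamicOutputs:
    """Renal pressure/flow summary (spec contract of renal_hemodynamics)."""

    pc: np.ndarray
    sngfr: np.ndarray
    gfr: np.ndarray
    rbf: np.ndarray
    md_na: np.ndarray


@dataclass
class CardiorenalState:
    """Slow states of one (vectorized) patient batch."""

    na_total: np.ndarray
    lv_mass: np.ndarray
    n_structural: np.ndarray
    damage: DamageState
    time_days: float = 0.0
    warm: dict | None = None
    outputs: Outputs | None = None
    failed: np.ndarray | None = None
    day_intake: np.ndarray | None = None
    day_excretion: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.failed is None:
            self.failed = np.zeros(self.na_total.shape, dtype=bool)

    @property
    def ecfv(self) -> np.ndarray:
        return self.na_total / 140.0

    @property
    def nonfiltering(self) -> np.ndarray:
        return self.damage.nonfiltering

    def n_functional(self, floor: float = 0.0) -> np.ndarray:
        return np.maximum(self.n_structural - self.damage.nonfiltering, floor)

    def copy(self) -> "CardiorenalState":
        return CardiorenalState(
            na_total=self.na_total.copy(),
            lv_mass=self.lv_mass.copy(),
            n_structural=self.n_structural.copy(),
            damage=self.damage.copy(),
            time_days=self.time_days,
            warm={k: v.copy() for k, v in self.warm.items()} if self.warm else None,
            outputs=self.outputs,
            failed=self.failed.copy(),
        )


class _NormSig:
    """Logistic curve normalized to unity at a reference input.

    Holds per-patient parameter arrays so slope perturbations change the
    *response* around the operating point without moving the point itself.
    """

    __slots__ = ("b", "A", "m", "s", "sign", "ref")

    def __init__(self, shape: dict, x_ref: float, s_scale=1.0):
        self.b = float(shape["b"])
        self.A = float(shape["A"])
        self.m = float(shape["m"])
        self.s = float(shape["s"]) * np.asarray(s_scale, dtype=float)
        if np.any(self.s <= 0):
            raise ValueError("sigmoid slope scale must be positive")
        self.sign = 1.0 if shape.get("direction", "increasing") == "increasing" else -1.0
        self.ref = self.raw(x_ref)

    def raw(self, x):
        return self.b + self.A * expit(self.sign * (np.asarray(x, dtype=float) - self.m) / self.s)

    def __call__(self, x):
        return self.raw(x) / self.ref


class CardiorenalModel:
    """Vectorized reduced-order engine for a batch of patients.

    The unperturbed model is normalized so that the configured operating
    point (MAP 94, GFR 129, Pc 52, RBF 1100, ECFV 15, AngII 12, ...) is an
    exact algebraic fixed point with sodium excretion equal to intake.
    """

    def __init__(self, params: ParameterSet | None = None, config: dict | None = None):
        if params is None:
            params = ParameterSet.nominal(1, config=config)
        self.params = params
        self.cfg = config if config is not None else params.config
        self.n = params.n
        op = self.cfg["operating_point"]
        cst = self.cfg["constants"]
        m = params.mult

        self.na_conc = op["na_conc"]
        self.pv = op["venous_pressure"]
        self.plasma_frac = op["plasma_fraction"]
        self.n0_star = op["nephron_number"]
        self.nephron_floor = cst["nephron_floor"]
        self.map_star = op["map"]
        self.co_star = op["co"]
        self.ecfv_star = op["ecfv"]
        self.sbp_factor = cst["sbp_factor"]
        self.lv_tau = cst["lv_tau_days"]
        self.max_fd = cst["max_fd"]
        self.g_auto = cst["autoreg_exponent"]

        q_star = op["rbf"] / 2.0
        gfr_k_star = op["gfr"] / 2.0
        sngfr_star = op["gfr"] * 1e6 / self.n0_star

        # Series network anchors (per kidney); derived so the operating point
        # closes exactly: MAP -> (renal artery) -> Ra -> glomerulus -> Re -> vein.
        r_art_star = (op["map"] - op["pc"]) / q_star - op["ra"]
        if r_art_star <= 0:
            raise ValueError("operating point inconsistent: pre-afferent resistance <= 0")
        re_star = (op["pc"] - self.pv) / (q_star - gfr_k_star)
        self.r_art = r_art_star * m("r_artery")
        self.ra_star = op["ra"] * m("renal_resistance")
        self.re_star = re_star * m("renal_resistance") * m("efferent_resistance")

        # Filtration: saturating single-nephron curve with a fixed ceiling
        # (filtration-equilibrium limit): snGFR = c (1 - exp(-Kf (Pc-Popp)/c))
        # with Kf derived so snGFR(Pc*) = GFR*/N0.
        self.sngfr_max = cst["sngfr_max"] * m("sngfr_max")
        self.p_opp = cst["p_opposing"] * m("p_opposing")
        c_star = cst["sngfr_max"]
        x_star = -c_star * np.log1p(-sngfr_star / c_star)
        self.kf = x_star / (op["pc"] - cst["p_opposing"]) * m("kf")

        # Tubule anchors: proximal fraction fp0; distal fraction derived so
        # excretion equals the nominal intake at the operating point.
        filtered_star = op["gfr"] * self.na_conc / 1000.0
        self.fp0 = cst["fp0"] * m("proximal_reabsorption")
        md_star = filtered_star * (1.0 - cst["fp0"])
        una_star = op["salt_intake"] / 1440.0
        self.fd0 = (1.0 - una_star / md_star) * m("distal_reabsorption")
        self.md_star = md_star

        # Systemic circulation anchors.
        self.rnr_star = (op["map"] - self.pv) / (op["co"] - op["rbf"] / 1000.0) * m(
            "nonrenal_resistance"
        )
        self.co_gain = m("co_gain") * m("heart_rate")

        # Hormone gains.
        self.renin_gain = m("renin_gain")
        self.ang_gain = m("ang_gain")
        self.ang_star = op["ang2"] * m("ang_gain") * m("renin_gain")
        self.aldo_star = op["aldosterone"] * m("aldo_gain")
        self.anp_star = op["anp"] * m("anp_gain")
        self.sym_tone = m("sympathetic_tone")
        self.lv_star = op["lv_mass"] * m("lv_gain")
        self.salt_base = op["salt_intake"] * m("salt_intake")
        self.n0_patient = self.n0_star * m("nephron_number")

        # PD (amlodipine) per patient.
        pd = self.cfg["pd"]
        self.emax_aff = np.minimum(pd["emax_afferent"] * m("emax_afferent"), 0.95)
        self.emax_sys = np.minimum(pd["emax_systemic"] * m("emax_systemic"), 0.95)
        self.emax_tgf = np.minimum(pd["emax_tgf"] * m("emax_tgf"), 0.95)
        self.emax_natri = np.minimum(pd["emax_natriuresis"] * m("emax_natriuresis"), 0.95)
        self.ec50 = pd["ec50_ng_ml"] * m("ec50_ccb")

        # Regulatory curves, normalized per patient at the operating point.
        sg = self.cfg["sigmoids"]

        def ns(name, x_ref, gain=1.0):
            return _NormSig(sg[name], x_ref, s_scale=m(f"s_{name}") / gain)

        self.s_co = ns("co_volume", op["ecfv"])
        self.s_anp = ns("anp_release", op["ecfv"])
        self.s_baro = ns("baroreflex", op["map"], gain=m("baroreceptor_gain"))
        self.s_myo = ns("myogenic", op["map"], gain=m("myogenic_gain"))
        self.s_tgf_del = ns("tgf_delivery", md_star)
        self.s_tgf_ang = ns("tgf_ang2", op["ang2"])
        self.s_ang_ra = ns("ang_afferent", op["ang2"])
        self.s_ang_re = ns("ang_efferent", op["ang2"])
        self.s_ang_v = ns("ang_systemic", op["ang2"])
        self.s_ren_md = ns("renin_delivery", md_star)
        self.s_ren_p = ns("renin_pressure", op["map"])
        self.s_aldo = ns("aldo_release", op["ang2"])
        self.s_pn = ns("pressure_natriuresis", op["map"])
        self.s_ald_fd = ns("aldo_reabs", op["aldosterone"])
        self.s_anp_fd = ns("anp_reabs", op["anp"])
        self.s_ang_fp = ns("ang_proximal", op["ang2"])
        self.s_lv = ns("lv_target", op["map"] * self.sbp_factor)

        dmg = self.cfg["damage"]
        self.damage_threshold = dmg["threshold_mmhg"] * m("damage_threshold")
        self.damage_gain = dmg["gain"] * m("damage_gain")
        self.damage_delay = int(dmg["delay_days"])

    # ------------------------------------------------------------------ #
    # construction helpers

    def initial_state(self) -> CardiorenalState:
        ones = np.ones(self.n)
        return CardiorenalState(
            na_total=self.ecfv_star * self.na_conc * ones,
            lv_mass=self.lv_star * ones,
            n_structural=self.n0_patient * ones,
            damage=DamageState.fresh(
                self.n,
                threshold=self.damage_threshold,
                delay=self.damage_delay,
                gain=self.damage_gain,
                excess_cap=self.cfg["damage"].get("excess_cap_mmhg", 10.0),
                supra_cap_slope=self.cfg["damage"].get("supra_cap_slope", 0.05),
            ),
        )

    def salt_intake_day(self, iv: Interventions) -> np.ndarray:
        if iv.salt_override is not None:
            return np.broadcast_to(
                np.asarray(iv.salt_override, dtype=float), (self.n,)
            ).copy()
        return self.salt_base * np.ones(self.n)

    def set_damage_gain(self, gain: float) -> None:
        """Rescale the damage gain (nephrons/day/mmHg) keeping per-patient
        perturbation multipliers."""
        self.damage_gain = gain * self.params.mult("damage_gain")

    # ------------------------------------------------------------------ #
    # spec operations exposed piecewise (used by the solver below)

    def ccb_multipliers(self, conc):
        """Emax drug effects: multipliers on (systemic resistance, afferent
        resistance, TGF signal, distal reabsorption)."""
        c = np.asarray(conc, dtype=float)
        if np.any(c < 0):
            raise ValueError("negative amlodipine concentration")
        frac = c / (c + self.ec50)
        return (
            1.0 - self.emax_sys * frac,
            1.0 - self.emax_aff * frac,
            1.0 - self.emax_tgf * frac,
            1.0 - self.emax_natri * frac,
        )

    def tgf_signal(self, md_na, ang2) -> np.ndarray:
        """TGF multiplier on afferent tone (x normal); increasing in both
        macula densa sodium delivery and angiotensin II."""
        if np.any(np.asarray(md_na) < 0) or np.any(np.asarray(ang2) < 0):
            raise ValueError("tgf inputs must be non-negative")
        return self.s_tgf_del(md_na) * self.s_tgf_ang(ang2)

    def hormones(self, md_na, map_, ecfv, ras_fraction=0.0):
        """Renin-driven AngII, aldosterone and volume-driven ANP."""
        renin = self.renin_gain * self.s_ren_md(md_na) * self.s_ren_p(map_)
        ang2 = self.cfg["operating_point"]["ang2"] * self.ang_gain * renin
        aldo = self.aldo_star * self.s_aldo(ang2 * (1.0 - ras_fraction))
        anp = self.anp_star * self.s_anp(ecfv)
        return ang2, aldo, anp

    def renal_hemodynamics(
        self, map_, n_func, ra, re, fp=None, q_init=None, iters: int = 60
    ) -> HemodynamicOutputs:
        """Solve the renal series network at fixed resistances.

        Per-kidney flow satisfies
        ``(MAP - Pv) = (R_art + Ra) q + Re (q - GFR/2)`` with the
        single-nephron filtration curve closing the loop.
        """
        map_ = np.asarray(map_, dtype=float)
        n_func = np.asarray(n_func, dtype=float)
        if np.any(n_func <= 0):
            raise DegenerateKidneyError("no functional nephrons: GFR=0, Pc undefined")
        if np.any(map_ <= self.pv):
            raise ModelError("MAP must exceed venous pressure")
        q = np.full(np.broadcast_shapes(map_.shape, n_func.shape), 500.0) \
            if q_init is None else np.asarray(q_init, dtype=float).copy()
        fp = self.fp0 if fp is None else fp
        pc = sngfr = gfr = None
        for _ in range(iters):
            pc = map_ - (self.r_art + ra) * q
            sngfr = self._sngfr(pc, q, n_func)
            gfr = sngfr * n_func * 1e-6
            q_new = (map_ - self.pv + re * gfr / 2.0) / (self.r_art + ra + re)
            q_new = np.maximum(q_new, 1.0)
            if np.max(np.abs(q_new - q) / np.maximum(q, 1.0)) < 1e-12:
                q = q_new
                break
            q = q_new
        pc = map_ - (self.r_art + ra) * q
        sngfr = self._sngfr(pc, q, n_func)
        gfr = sngfr * n_func * 1e-6
        md = gfr * self.na_conc / 1000.0 * (1.0 - fp)
        return HemodynamicOutputs(pc=pc, sngfr=sngfr, gfr=gfr, rbf=2.0 * q, md_na=md)

    def _sngfr(self, pc, q, n_func):
        c = self.sngfr_max
        x = self.kf * (pc - self.p_opp)
        with np.errstate(over="ignore"):
            val = c * (-np.expm1(-np.maximum(x, 0.0) / c))
        return np.where(x > 0.0, val, 0.0)

    # ------------------------------------------------------------------ #
    # quasi-steady solve

    def algebraic(
        self,
        na_total,
        n_func,
        iv: Interventions,
        warm: dict | None = None,
        tol: float = 1e-9,
        max_iter: int = 300,
        strict: bool = False,
        active: np.ndarray | None = None,
    ) -> Outputs:
        """Damped fixed-point solve of the within-day circulatory state.

        ``active`` masks the patients whose convergence is required; already
        failed patients are carried along but do not hold up the iteration.
        """
        na_total = np.asarray(na_total, dtype=float)
        n_func = np.maximum(np.asarray(n_func, dtype=float), self.nephron_floor)
        ecfv = na_total / self.na_conc
        ras = float(iv.ras_fraction)

        co = self.co_star * self.co_gain * self.s_co(ecfv)
        anp = self.anp_star * self.s_anp(ecfv)
        ccb_sys, ccb_aff, ccb_tgf, ccb_natri = self.ccb_multipliers(iv.ccb_conc)

        if warm is not None:
            map_ = warm["map"].copy()
            q = warm["q"].copy()
            ang2 = warm["ang2"].copy()
            md = warm["md"].copy()
        else:
            ones = np.ones(self.n)
            map_, q, ang2, md = (
                self.map_star * ones,
                550.0 * ones,
                self.ang_star * np.ones(self.n),
                self.md_star * ones,
            )

        struct = self.n0_star / n_func
        err = np.inf
        last = {}
        damp = np.full(self.n, 0.5)
        err_prev = np.full(self.n, np.inf)
        for _ in range(max_iter):
            ang_eff = ang2 * (1.0 - ras)
            aldo = self.aldo_star * self.s_aldo(ang_eff)
            sym = self.sym_tone * self.s_baro(map_)
            tgf = self.s_tgf_del(md) * self.s_tgf_ang(ang_eff) * ccb_tgf
            ra = (
                self.ra_star * struct * tgf * self.s_myo(map_)
                * self.s_ang_ra(ang_eff) * ccb_aff
            )
            re = self.re_star * struct * self.s_ang_re(ang_eff)

            pc = map_ - (self.r_art + ra) * q
            sngfr = self._sngfr(pc, q, n_func)
            gfr = sngfr * n_func * 1e-6
            q_new = (map_ - self.pv + re * gfr / 2.0) / (self.r_art + ra + re)
            q_new = np.maximum(q_new, 1.0)

            filtered = gfr * self.na_conc / 1000.0
            fp = np.clip(self.fp0 * self.s_ang_fp(ang_eff), 0.5, 0.99)
            md_new = filtered * (1.0 - fp)
            fd = np.clip(
                self.fd0 * self.s_pn(map_) * self.s_ald_fd(aldo)
                * self.s_anp_fd(anp) * ccb_natri,
                0.0,
                self.max_fd,
            )
            una = md_new * (1.0 - fd)

            renin = self.renin_gain * self.s_ren_md(md_new) * self.s_ren_p(map_)
            ang_new = self.cfg["operating_point"]["ang2"] * self.ang_gain * renin

            rnr = (
                self.rnr_star * self.s_ang_v(ang_eff) * sym * ccb_sys
                * (co / self.co_star) ** self.g_auto
            )
            resid_flow = co - (map_ - self.pv) / rnr - 2.0 * q / 1000.0
            dmap = resid_flow * rnr

            dq = q_new - q
            dang = ang_new - ang2
            err_vec = {
                "MAP": np.abs(dmap) / self.map_star,
                "renal_flow": np.abs(dq) / np.maximum(q, 1.0),
                "ang2": np.abs(dang) / (np.abs(ang2) + 1.0),
                "md_na": np.abs(md_new - md) / (np.abs(md) + 1e-3),
            }
            err_now = np.maximum.reduce(list(err_vec.values()))
            # per-patient adaptive damping: back off when the residual grows
            damp = np.where(err_now > err_prev, damp * 0.5, np.minimum(damp * 1.2, 0.6))
            damp = np.maximum(damp, 0.02)
            err_prev = err_now

            map_ = np.clip(map_ + damp * dmap, 20.0, 280.0)
            q = q + np.minimum(1.3 * damp, 0.9) * dq
            ang2 = ang2 + damp * dang
            md = md + np.minimum(1.6 * damp, 1.0) * (md_new - md)
            err = float(np.max(err_now[active])) if active is not None else float(np.max(err_now))
            last = dict(
                aldo=aldo, sym=sym, tgf=tgf, ra=ra, re=re, pc=pc, sngfr=sngfr,
                gfr=gfr, fp=fp, fd=fd, una=una, renin=renin, rnr=rnr,
                ang_eff=ang_eff,
            )
            if err < tol:
                break

        converged_vec = {k: np.asarray(v) < 1e-6 for k, v in err_vec.items()}
        converged = np.ones(self.n, dtype=bool)
        for v in converged_vec.values():
            converged &= v
        if strict and not bool(np.all(converged)):
            worst = max(err_vec, key=lambda k: float(np.max(err_vec[k])))
            raise ConvergenceError(
                f"quasi-steady solve did not converge; worst residual in "
                f"{worst!r} ({float(np.max(err_vec[worst])):.3e})"
            )

        return Outputs(
            map=map_, co=co, rnr=last["rnr"], q_kidney=q, rbf=2.0 * q,
            ra=last["ra"], re=last["re"], pc=last["pc"], sngfr=last["sngfr"],
            gfr=last["gfr"], md_na=md, tgf=last["tgf"], renin=last["renin"],
            ang2=ang2, ang2_eff=last["ang_eff"], aldosterone=last["aldo"],
            anp=anp, sympathetic=last["sym"], fp=last["fp"], fd=last["fd"],
            una=last["una"], ecfv=ecfv, converged=converged,
        )

    # ------------------------------------------------------------------ #
    # time stepping

    def advance_day(
        self,
        state: CardiorenalState,
        iv: Interventions | None = None,
        n_sub: int = 3,
        hourly_conc: np.ndarray | None = None,
    ) -> CardiorenalState:
        """Advance the slow states by one day.

        Sodium is integrated with an exponential (locally-linearized) rule
        over ``n_sub`` sub-steps so the stiff pressure-natriuresis loop is
        unconditionally stable; LV mass relaxes first-order toward its
        load-dependent target; supra-threshold glomerular pressure accrues
        delayed damage.  Daily sodium balance is exact by construction:
        the recorded excretion equals intake minus the change in body sodium.
        """
        iv = iv if iv is not None else Interventions()
        intake = self.salt_intake_day(iv)  # mEq/day
        na = state.na_total.copy()
        nf = state.n_functional(self.nephron_floor)
        warm = state.warm

        if hourly_conc is not None:
            steps = [(1.0 / 24.0, hourly_conc[h]) for h in range(24)]
        else:
            steps = [(1.0 / n_sub, iv.ccb_conc)] * n_sub

        active = ~state.failed
        pc_acc = np.zeros(self.n)
        out = None
        lam = None
        delta = 0.5  # mEq probe for the local natriuresis slope
        for k, (dt, conc) in enumerate(steps):
            sub_iv = Interventions(
                ccb_conc=conc, ras_fraction=iv.ras_fraction,
                salt_override=iv.salt_override,
            )
            out = self.algebraic(na, nf, sub_iv, warm=warm, active=active)
            warm = {"map": out.map, "q": out.q_kidney, "ang2": out.ang2, "md": out.md_na}
            if k == 0:
                # local linearization of the natriuresis curve, reused over
                # the day's sub-steps (it varies slowly within a day)
                out2 = self.algebraic(na + delta, nf, sub_iv, warm=warm, active=active)
                lam = np.maximum((out2.una - out.una) * 1440.0 / delta, 1e-8)
            una1 = out.una * 1440.0
            na_ss = na + (intake - una1) / lam
            na = na_ss + (na - na_ss) * np.exp(-lam * dt)
            pc_acc += out.pc * dt

        excreted = intake - (na - state.na_total)

        # slow states
        sbp = self.sbp_factor * out.map
        lv_target = self.lv_star * self.s_lv(sbp)
        lv = state.lv_mass + (lv_target - state.lv_mass) * (-np.expm1(-1.0 / self.lv_tau))

        damage = state.damage
        # per-nephron hazard: the configured gain applies at full nephron
        # endowment and scales with the currently exposed (functional) count
        damage.gain = self.damage_gain * (nf / self.n0_star)
        damage.accrue(pc_acc, 1.0)
        np.minimum(damage.nonfiltering, state.n_structural, out=damage.nonfiltering)

        new = CardiorenalState(
            na_total=na,
            lv_mass=lv,
            n_structural=state.n_structural.copy(),
            damage=damage,
            time_days=state.time_days + 1.0,
            warm=warm,
            outputs=out,
            failed=state.failed | ~out.converged,
        )
        new.day_intake = intake
        new.day_excretion = excreted
        return new

    def steady_state(
        self,
        iv: Interventions | None = None,
        state_template: CardiorenalState | None = None,
        n_iter: int = 70,
        verify: bool = True,
        drift_tol: float = 1e-3,
    ) -> CardiorenalState:
        """Chronic steady state: body sodium solved by bisection on the
        sodium-balance residual (excretion is monotone in body sodium),
        then verified to drift < ``drift_tol`` per day.
        """
        iv = iv if iv is not None else Interventions()
        template = state_template if state_template is not None else self.initial_state()
        nf = template.n_functional(self.nephron_floor)
        intake = self.salt_intake_day(iv)

        lo = np.full(self.n, 600.0)
        hi = np.full(self.n, 8000.0)
        warm = None

        active = ~template.failed

        def residual(na):
            nonlocal warm
            out = self.algebraic(na, nf, iv, warm=warm, active=active)
            warm = {"map": out.map, "q": out.q_kidney, "ang2": out.ang2, "md": out.md_na}
            return intake - out.una * 1440.0, out

        g_lo, _ = residual(lo)
        g_hi, _ = residual(hi)
        invalid = (g_lo < 0) | (g_hi > 0)
        out = None
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            g, out = residual(mid)
            take_lo = g > 0
            lo = np.where(take_lo, mid, lo)
            hi = np.where(take_lo, hi, mid)
        na = 0.5 * (lo + hi)
        _, out = residual(na)

        sbp = self.sbp_factor * out.map
        state = CardiorenalState(
            na_total=na,
            lv_mass=self.lv_star * self.s_lv(sbp),
            n_structural=template.n_structural.copy(),
            damage=template.damage.copy(),
            time_days=template.time_days,
            warm=warm,
            outputs=out,
            failed=template.failed | invalid | ~out.converged,
        )
        if verify:
            probe = self.advance_day(state.copy(), iv)
            drifts = {
                "na_total": np.abs(probe.na_total - state.na_total)
                / np.maximum(state.na_total, 1.0),
                "MAP": np.abs(probe.outputs.map - out.map) / np.maximum(out.map, 1.0),
            }
            bad = np.zeros(self.n, dtype=bool)
            for v in drifts.values():
                bad |= v > drift_tol
            state.failed |= bad
            if self.n == 1 and bool(state.failed[0]):
                worst = max(drifts, key=lambda k: float(np.max(drifts[k])))
                raise ConvergenceError(
                    f"steady state not reached; worst residual in {worst!r} "
                    f"({float(np.max(drifts[worst])):.3e}/day)"
                )
        return state
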