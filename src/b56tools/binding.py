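"""Quantitative 1:1 binding models: BLI kinetics, ITC isotherm, competition.

Biolayer interferometry traces are modelled with the standard 1:1 Langmuir
scheme.  During association at analyte concentration C the sensor response
follows

    R(t) = Rmax * C / (C + KD) * (1 - exp(-(kon*C + koff) * t)),

and during dissociation R(t) = R_end * exp(-koff * t), with KD = koff/kon a
derived (never free) parameter.  ITC injections are fitted with the
single-site Wiseman isotherm with dilution-corrected totals.  The
competitive-displacement model solves the two-ligand one-site equilibrium
by mass balance on free receptor, yielding the fraction of reporter bound
as a function of competitor concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import FitError, ParameterError

ASSOCIATION = "association"
DISSOCIATION = "dissociation"


@dataclass
class BindingTrace:
    """One sensor phase: times (s, strictly increasing, phase-local),
    responses (sensor units) at a fixed analyte concentration (M)."""

    time: np.ndarray
    response: np.ndarray
    concentration: float
    phase: str

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.response = np.asarray(self.response, float)
        if self.phase not in (ASSOCIATION, DISSOCIATION):
            raise ParameterError(f"unknown phase {self.phase!r}")
        if self.concentration < 0:
            raise ParameterError("analyte concentration must be >= 0")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")


@dataclass
class KineticFit:
    kon: float  # 1/(M*s)
    koff: float  # 1/s
    Rmax: float  # sensor units
    residual_norm: float
    stderr: dict[str, float] = field(default_factory=dict)

    @property
    def KD(self) -> float:
        return self.koff / self.kon


@dataclass
class ITCFit:
    Ka: float  # 1/M
    dH: float  # cal/mol
    n: float  # stoichiometry
    residual_norm: float
    degenerate: bool = False

    @property
    def Kd(self) -> float:
        return 1.0 / self.Ka


@dataclass
class CompetitionCurve:
    competitor: np.ndarray  # M
    fraction_bound: np.ndarray  # of reporter
    KD_reporter: float
    KD_competitor: float
    receptor_total: float
    reporter_total: float


def bli_forward(
    kon: float,
    koff: float,
    Rmax: float,
    concentration: float,
    t: np.ndarray | float,
    phase: str = ASSOCIATION,
    r_start: float | None = None,
) -> np.ndarray | float:
    """1:1 model response at time(s) ``t`` (phase-local, starting at 0).

    For dissociation, ``r_start`` is the response at the end of the
    preceding association step (defaults to the association plateau).
    """
    if kon <= 0 or koff <= 0 or Rmax <= 0:
        raise ParameterError("kon, koff, Rmax must be positive")
    if concentration < 0:
        raise ParameterError("concentration must be >= 0")
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ParameterError("time must be >= 0")
    kd = koff / kon
    if phase == ASSOCIATION:
        if concentration == 0:
            return np.zeros_like(t)
        req = Rmax * concentration / (concentration + kd)
        return req * (1.0 - np.exp(-(kon * concentration + koff) * t))
    if phase == DISSOCIATION:
        if r_start is None:
            r_start = Rmax * concentration / (concentration + kd)
        return r_start * np.exp(-koff * t)
    raise ParameterError(f"unknown phase {phase!r}")


def _subtract_blank(traces: list[BindingTrace]) -> list[BindingTrace]:
    blanks = {
        tr.phase: tr for tr in traces if tr.concentration == 0.0
    }
    if not blanks:
        return [tr for tr in traces]
    out = []
    for tr in traces:
        if tr.concentration == 0.0:
            continue
        blank = blanks.get(tr.phase)
        if blank is None:
            out.append(tr)
            continue
        ref = np.interp(tr.time, blank.time, blank.response)
        out.append(
            BindingTrace(tr.time, tr.response - ref, tr.concentration, tr.phase)
        )
    return out


def fit_bli(traces: list[BindingTrace], t_assoc: float | None = None) -> KineticFit:
    """Global 1:1 fit of kon, koff, Rmax over all traces.

    All concentrations share the three parameters; a zero-concentration
    trace, if present, is used as a reference blank and subtracted.
    ``t_assoc`` is the association duration used to seed each dissociation
    (defaults to the last association time point).  Initialisation is a
    multi-start over a log-spaced (kon, koff) grid; parameters are kept
    positive by fitting in log space.
    """
    traces = _subtract_blank(traces)
    concs = sorted({tr.concentration for tr in traces})
    if len(concs) < 2:
        warnings.warn("single analyte concentration: kon/koff weakly identifiable")
    if not any(tr.phase == ASSOCIATION for tr in traces) or not any(
        tr.phase == DISSOCIATION for tr in traces
    ):
        raise ParameterError("both association and dissociation phases required")
    if t_assoc is None:
        t_assoc = max(
            tr.time[-1] for tr in traces if tr.phase == ASSOCIATION
        )

    def residuals(logp: np.ndarray) -> np.ndarray:
        kon, koff, rmax = np.exp(logp)
        res = []
        for tr in traces:
            if tr.phase == ASSOCIATION:
                model = bli_forward(kon, koff, rmax, tr.concentration, tr.time)
            else:
                r0 = bli_forward(kon, koff, rmax, tr.concentration, t_assoc)
                model = bli_forward(
                    kon, koff, rmax, tr.concentration, tr.time,
                    DISSOCIATION, r_start=float(r0),
                )
            res.append(model - tr.response)
        return np.concatenate(res)

    rmax0 = max(float(np.max(tr.response)) for tr in traces)
    rmax0 = max(rmax0, 1e-6)
    best = None
    for kon0 in np.logspace(3, 7, 3):
        for koff0 in np.logspace(-4, -1, 3):
            try:
                sol = optimize.least_squares(
                    residuals,
                    np.log([kon0, koff0, rmax0]),
                    method="lm",
                    max_nfev=2000,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("BLI global fit failed to converge")
    kon, koff, rmax = np.exp(best.x)
    # parameter standard errors via the Jacobian (log-scale, delta method)
    stderr: dict[str, float] = {}
    try:
        jtj = best.jac.T @ best.jac
        dof = max(best.fun.size - 3, 1)
        cov = np.linalg.inv(jtj) * (2 * best.cost / dof)
        sd_log = np.sqrt(np.diag(cov))
        stderr = {
            "kon": kon * sd_log[0],
            "koff": koff * sd_log[1],
            "Rmax": rmax * sd_log[2],
        }
    except np.linalg.LinAlgError:
        pass
    return KineticFit(
        kon=float(kon),
        koff=float(koff),
        Rmax=float(rmax),
        residual_norm=float(np.sqrt(2 * best.cost)),
        stderr=stderr,
    )


def itc_forward(
    Ka: float,
    dH: float,
    n: float,
    cell_conc: float,
    syringe_conc: float,
    injection_volumes: np.ndarray,
    cell_volume: float = 1.4e-3,
) -> np.ndarray:
    """Per-injection heats (cal) of a single-site Wiseman isotherm.

    Totals are dilution-corrected with the standard perfusion expressions
    for an overfilled cell: after cumulative injected volume dV the
    macromolecule total is ``M0*(1-dV/2V0)/(1+dV/2V0)`` and the ligand
    total ``X0*(dV/V0)/(1+dV/2V0)``.
    """
    if Ka <= 0 or n <= 0:
        raise ParameterError("Ka and n must be positive")
    vol = np.asarray(injection_volumes, float)
    dv = np.cumsum(vol)
    mt = cell_conc * (1 - dv / (2 * cell_volume)) / (1 + dv / (2 * cell_volume))
    xt = syringe_conc * (dv / cell_volume) / (1 + dv / (2 * cell_volume))
    r = xt / (n * mt)
    inv_c = 1.0 / (n * Ka * mt)
    with np.errstate(over="ignore", invalid="ignore"):
        disc = np.sqrt((1 + r + inv_c) ** 2 - 4 * r)
        q = n * mt * dH * cell_volume / 2 * (1 + r + inv_c - disc)
        q_prev = np.concatenate([[0.0], q[:-1]])
        return q - q_prev + (vol / cell_volume) * (q + q_prev) / 2


def fit_itc(
    heats: np.ndarray,
    cell_conc: float,
    syringe_conc: float,
    injection_volumes: np.ndarray,
    cell_volume: float = 1.4e-3,
    fix_n: float | None = None,
) -> ITCFit:
    """Least-squares single-site fit of (Ka, dH, n) to injection heats.

    For low-c titrations (c = n*Ka*[cell] below ~10) the stoichiometry and
    Ka are poorly separable; passing ``fix_n`` holds n at a known value
    (usually 1) and fits only Ka and dH, the standard practice for weak
    binders.
    """
    heats = np.asarray(heats, float)
    vol = np.asarray(injection_volumes, float)
    if heats.size < 10:
        raise ParameterError("need at least 10 injections")
    if cell_conc <= 0 or syringe_conc <= 0 or np.any(vol <= 0):
        raise ParameterError("concentrations and volumes must be positive")
    scale = float(np.max(np.abs(heats)))
    if scale == 0.0:
        return ITCFit(Ka=1.0, dH=0.0, n=1.0, residual_norm=0.0, degenerate=True)

    def residuals(p: np.ndarray) -> np.ndarray:
        ka, dh = np.exp(p[0]), p[1]
        n = fix_n if fix_n is not None else np.exp(p[2])
        model = itc_forward(ka, dh, n, cell_conc, syringe_conc, vol, cell_volume)
        return np.nan_to_num(model - heats, nan=1e3 * scale, posinf=1e3 * scale,
                             neginf=-1e3 * scale)

    dh0 = float(np.sum(heats) / (cell_conc * cell_volume))
    x0_tail = [] if fix_n is not None else [0.0]
    best = None
    for ka0 in np.logspace(3, 7, 5):
        sol = optimize.least_squares(
            residuals,
            np.array([np.log(ka0), dh0, *x0_tail]),
            method="lm",
            max_nfev=5000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("ITC fit failed to converge")
    ka, dh = float(np.exp(best.x[0])), float(best.x[1])
    n = float(fix_n) if fix_n is not None else float(np.exp(best.x[2]))
    c_value = n * ka * cell_conc
    if not 1.0 <= c_value <= 1000.0:
        warnings.warn(
            f"c-value {c_value:.3g} outside [1, 1000]: Ka weakly determined"
        )
    return ITCFit(
        Ka=ka, dH=dh, n=n, residual_norm=float(np.sqrt(2 * best.cost))
    )


def _free_receptor(
    p_total: float, l_total: float, c_total: float, kd_l: float, kd_c: float
) -> float:
    """Root of the two-ligand mass balance for free receptor."""
    def balance(x: float) -> float:
        return (
            x
            + x * l_total / (kd_l + x)
            + x * c_total / (kd_c + x)
            - p_total
        )

    if p_total == 0:
        return 0.0
    return optimize.brentq(balance, 0.0, p_total, xtol=1e-18, rtol=1e-14)


def competition_curve(
    KD_reporter: float,
    KD_competitor: float,
    receptor_total: float,
    reporter_total: float,
    competitor_grid: np.ndarray,
) -> CompetitionCurve:
    """Reporter bound fraction versus competitor concentration.

    Solves, for each competitor total C, the one-site two-ligand
    equilibrium by bracketed root-finding on the free receptor
    concentration and returns the fraction of reporter in complex,
    ``[free receptor]/(KD_reporter + [free receptor])``.
    """
    if KD_reporter <= 0 or KD_competitor <= 0:
        raise ParameterError("dissociation constants must be positive")
    grid = np.asarray(competitor_grid, float)
    if receptor_total < 0 or reporter_total < 0 or np.any(grid < 0):
        raise ParameterError("concentrations must be >= 0")
    fractions = np.empty(grid.size)
    for i, c in enumerate(grid):
        x = _free_receptor(
            receptor_total, reporter_total, float(c), KD_reporter, KD_competitor
        )
        fractions[i] = x / (KD_reporter + x)
    return CompetitionCurve(
        competitor=grid,
        fraction_bound=fractions,
        KD_reporter=KD_reporter,
        KD_competitor=KD_competitor,
        receptor_total=receptor_total,
        reporter_total=reporter_total,
    )
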