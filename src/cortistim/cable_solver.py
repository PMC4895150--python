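"""Multi-compartment cable integration under extracellular potential forcing.

The membrane model is a reduced Hodgkin-Huxley-family scheme (fast Na+,
delayed-rectifier K+, slow non-inactivating K+) with kinetics of the
published cat-cortex pyramidal lineage; densities live in a versioned YAML
configuration because the source protocol prints none of them.  Dendrites
are passive by default.

Numerics: semi-implicit backward-Euler step with Rush-Larsen gate updates —
the stiff passive operator (capacitance/dt + leak + axial Laplacian) is
constant, factorized once and solved implicitly, while channel currents are
evaluated at the previous voltage (their time constants are >> dt).  One
sparse triangular solve per step covers an entire batch of neurons sharing a
discretization.

Units: mV, ms, nA, uS, nF; compartment geometry um; extracellular
potentials mV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import yaml

from .errors import InputError, IntegrationError, ParameterError
from .neuron_morphology import CompartmentSet

__all__ = [
    "MembraneParameters",
    "PulseSpec",
    "MembraneTrace",
    "APEvent",
    "CableModel",
    "simulate",
    "simulate_batch",
    "detect_ap",
    "classify_initiation",
]

INITIATION_CATEGORIES = ("initial segment", "axon terminal", "GM/WM boundary",
                         "axon bend", "soma", "other")


@dataclass
class PulseSpec:
    """Monophasic rectangular pulse."""

    width_us: float = 100.0
    onset_ms: float = 0.1
    shape: str = "monophasic_rectangular"

    def __post_init__(self) -> None:
        if self.width_us <= 0.0:
            raise ParameterError("pulse width must be positive")
        if self.shape != "monophasic_rectangular":
            raise ParameterError("only monophasic rectangular pulses are supported")

    def active(self, t_ms: float) -> bool:
        return self.onset_ms <= t_ms < self.onset_ms + self.width_us * 1e-3


_DEFAULT_MEMBRANE = {
    "global": {
        "ra_ohm_cm": 150.0,
        "celsius": 36.0,
        "v_init": -70.0,
        "e_na": 60.0,
        "e_k": -90.0,
        "q10": 2.3,
        "kinetics_t_ref": 23.0,
    },
    # per section type: cm uF/cm^2, conductances S/cm^2
    "soma": {"cm": 1.0, "g_pas": 3.3e-5, "gbar_na": 0.05, "gbar_kv": 0.01,
             "gbar_km": 3e-4},
    "apical": {"cm": 1.0, "g_pas": 3.3e-5, "gbar_na": 0.12, "gbar_kv": 0.012,
               "gbar_km": 0.0},
    "basal": {"cm": 1.0, "g_pas": 3.3e-5, "gbar_na": 0.01, "gbar_kv": 0.001,
              "gbar_km": 0.0},
    "initial_segment": {"cm": 1.0, "g_pas": 3.3e-5, "gbar_na": 3.0,
                        "gbar_kv": 0.1, "gbar_km": 0.0},
    "node": {"cm": 1.0, "g_pas": 0.02, "gbar_na": 3.0, "gbar_kv": 0.1,
             "gbar_km": 0.0},
    "axon": {"cm": 0.04, "g_pas": 1e-6, "gbar_na": 0.0, "gbar_kv": 0.0,
             "gbar_km": 0.0},  # myelinated internode
}


@dataclass
class MembraneParameters:
    """Per-section-type densities plus global electrical constants."""

    table: dict = field(default_factory=lambda: _DEFAULT_MEMBRANE)

    def __post_init__(self) -> None:
        for stype, row in self.table.items():
            if stype == "global":
                continue
            for key, val in row.items():
                if key.startswith(("g", "cm")) and val < 0.0:
                    raise ParameterError(f"{stype}.{key} must be >= 0")

    @property
    def glob(self) -> dict:
        return self.table["global"]

    def row(self, stype: str) -> dict:
        try:
            return self.table[stype]
        except KeyError as exc:
            raise ParameterError(f"no membrane parameters for section type "
                                 f"{stype!r}") from exc

    @classmethod
    def from_yaml(cls, path: str) -> "MembraneParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        table = {k: dict(v) for k, v in _DEFAULT_MEMBRANE.items()}
        for k, v in (data.get("membrane", data) or {}).items():
            table.setdefault(k, {}).update(v)
        return cls(table)

    @classmethod
    def default(cls) -> "MembraneParameters":
        try:
            ref = (importlib.resources.files("cortistim")
                   / "data" / "membrane_default.yaml")
            return cls.from_yaml(str(ref))
        except (FileNotFoundError, ModuleNotFoundError):
            return cls()


@dataclass
class MembraneTrace:
    """Membrane potential time series, compartments x time."""

    times: np.ndarray  # (T,) ms
    v: np.ndarray  # (n_comp, T) mV
    dt_us: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.v).all():
            raise IntegrationError("membrane trace contains non-finite values")


@dataclass
class APEvent:
    """Outcome of action-potential detection on one neuron."""

    fired: bool
    crossing_times: np.ndarray  # (n_comp,) ms, nan where never crossed
    initiation_compartment: int = -1
    initiation_time: float = np.nan
    category: str = ""


# -- channel kinetics -------------------------------------------------------


def _ratef(v, th, a, q):
    x = (v - th) / q
    out = np.where(np.abs(x) > 1e-6, a * (v - th) / (1.0 - np.exp(-x)), a * q)
    return out


def _rater(v, th, a, q):
    x = (v - th) / q
    out = np.where(np.abs(x) > 1e-6, -a * (v - th) / (1.0 - np.exp(x)), a * q)
    return out


def _na_rates(v, tadj):
    am = _ratef(v, -35.0, 0.182, 9.0)
    bm = _rater(v, -35.0, 0.124, 9.0)
    minf = am / (am + bm)
    taum = 1.0 / ((am + bm) * tadj)
    ah = _ratef(v, -50.0, 0.024, 5.0)
    bh = _rater(v, -75.0, 0.0091, 5.0)
    hinf = 1.0 / (1.0 + np.exp((v + 65.0) / 6.2))
    tauh = 1.0 / ((ah + bh) * tadj)
    return minf, taum, hinf, tauh


def _kv_rates(v, tadj):
    an = _ratef(v, 25.0, 0.02, 9.0)
    bn = _rater(v, 25.0, 0.002, 9.0)
    return an / (an + bn), 1.0 / ((an + bn) * tadj)


def _km_rates(v, tadj):
    an = _ratef(v, -30.0, 0.001, 9.0)
    bn = _rater(v, -30.0, 0.001, 9.0)
    return an / (an + bn), 1.0 / ((an + bn) * tadj)


# -- model assembly ---------------------------------------------------------


class CableModel:
    """Discretized electrical model of one morphology (shareable by a batch)."""

    def __init__(self, comp: CompartmentSet, mem: MembraneParameters | None = None):
        mem = mem or MembraneParameters.default()
        self.comp = comp
        self.mem = mem
        g = mem.glob
        self.v_init = float(g["v_init"])
        self.e_na = float(g["e_na"])
        self.e_k = float(g["e_k"])
        self.tadj = float(g["q10"]) ** ((g["celsius"] - g["kinetics_t_ref"]) / 10.0)
        ra = float(g["ra_ohm_cm"])

        n = comp.n
        L_cm = comp.lengths * 1e-4
        d_cm = comp.diameters * 1e-4
        area = np.pi * d_cm * L_cm  # cm^2
        xsec = 0.25 * np.pi * d_cm**2

        self.cm_nf = np.empty(n)
        self.g_pas = np.empty(n)
        gbar_na = np.empty(n)
        gbar_kv = np.empty(n)
        gbar_km = np.empty(n)
        for i, st in enumerate(comp.stypes):
            row = mem.row(str(st))
            self.cm_nf[i] = row["cm"] * area[i] * 1e3
            self.g_pas[i] = row["g_pas"] * area[i] * 1e6  # uS
            gbar_na[i] = row["gbar_na"] * area[i] * 1e6
            gbar_kv[i] = row["gbar_kv"] * area[i] * 1e6
            gbar_km[i] = row["gbar_km"] * area[i] * 1e6

        # axial conductances (uS) between each compartment and its parent
        g_ax = np.zeros(n)
        par = comp.parent
        for i in range(1, n):
            p = par[i]
            if p < 0:
                continue
            r = ra * (0.5 * L_cm[i] / xsec[i] + 0.5 * L_cm[p] / xsec[p])
            g_ax[i] = 1e6 / r
        self.g_ax = g_ax

        rows, cols, vals = [], [], []
        for i in range(1, n):
            p = par[i]
            if p < 0:
                continue
            rows += [i, p, i, p]
            cols += [i, p, p, i]
            vals += [g_ax[i], g_ax[i], -g_ax[i], -g_ax[i]]
        self.lap = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

        # active compartments carry voltage-dependent conductances
        self.active = np.flatnonzero((gbar_na > 0) | (gbar_kv > 0) | (gbar_km > 0))
        self.gbar_na = gbar_na[self.active]
        self.gbar_kv = gbar_kv[self.active]
        self.gbar_km = gbar_km[self.active]

        # leak reversal balancing: rest is an exact fixed point at v_init
        self.e_pas = np.full(n, self.v_init)
        v0 = np.full(len(self.active), self.v_init)
        minf, _, hinf, _ = _na_rates(v0, self.tadj)
        ninf, _ = _kv_rates(v0, self.tadj)
        kinf, _ = _km_rates(v0, self.tadj)
        i_rest = (self.gbar_na * minf**3 * hinf * (self.v_init - self.e_na)
                  + self.gbar_kv * ninf * (self.v_init - self.e_k)
                  + self.gbar_km * kinf * (self.v_init - self.e_k))
        gp = self.g_pas[self.active]
        if (gp <= 0).any():
            raise ParameterError("active compartments need g_pas > 0 for "
                                 "resting balance")
        self.e_pas[self.active] = self.v_init + i_rest / gp

        self._lu_cache: dict[float, tuple] = {}

    def _factorize(self, dt_ms: float):
        key = round(dt_ms, 9)
        if key not in self._lu_cache:
            A0 = (sp.diags(self.cm_nf / dt_ms + self.g_pas) + self.lap).tocsc()
            self._lu_cache[key] = spla.splu(A0)
        return self._lu_cache[key]


def _gate_init(model: CableModel, batch: int):
    v0 = np.full((batch, len(model.active)), model.v_init)
    minf, _, hinf, _ = _na_rates(v0, model.tadj)
    ninf, _ = _kv_rates(v0, model.tadj)
    kinf, _ = _km_rates(v0, model.tadj)
    return minf, hinf, ninf, kinf


def _integrate(model: CableModel, phi_unit: np.ndarray, amplitudes: np.ndarray,
               pulse: PulseSpec, dt_us: float, duration_ms: float,
               record: bool, threshold_mv: float = 0.0,
               stop_when_all_fired: bool = False,
               detect_mask: np.ndarray | None = None):
    """Shared implicit integrator. phi_unit (B, n) mV per mA, amplitudes (B,) mA."""
    comp = model.comp
    n = comp.n
    phi_unit = np.atleast_2d(np.asarray(phi_unit, float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, float))
    B = len(amplitudes)
    if phi_unit.shape != (B, n):
        raise InputError(
            f"phi_unit shape {phi_unit.shape} does not match "
            f"(batch {B}, compartments {n})"
        )
    if dt_us <= 0.0 or duration_ms <= 0.0:
        raise InputError("dt and duration must be positive")
    dt_ms = dt_us * 1e-3
    steps = int(round(duration_ms / dt_ms))

    lu = model._factorize(dt_ms)
    act = model.active
    v = np.full((B, n), model.v_init)
    m, h, nk, km = _gate_init(model, B)

    phi_scaled = phi_unit * amplitudes[:, None]  # (B, n) mV at the drive
    lap = model.lap
    cmdt = model.cm_nf / dt_ms
    g_pas = model.g_pas
    e_pas = model.e_pas

    first_cross = np.full((B, n), np.nan)
    v_peak = np.full((B, n), model.v_init)
    traces = np.empty((B, n, steps + 1)) if record else None
    if record:
        traces[:, :, 0] = v
    times = np.arange(steps + 1) * dt_ms

    for k in range(1, steps + 1):
        t = k * dt_ms
        va = v[:, act]
        minf, taum, hinf, tauh = _na_rates(va, model.tadj)
        ninf, taun = _kv_rates(va, model.tadj)
        kinf, tauk = _km_rates(va, model.tadj)
        m += (minf - m) * (1.0 - np.exp(-dt_ms / taum))
        h += (hinf - h) * (1.0 - np.exp(-dt_ms / tauh))
        nk += (ninf - nk) * (1.0 - np.exp(-dt_ms / taun))
        km += (kinf - km) * (1.0 - np.exp(-dt_ms / tauk))

        # channel currents explicit in v (their tau >> dt)
        g_na = model.gbar_na * m**3 * h
        g_k = model.gbar_kv * nk + model.gbar_km * km
        b = cmdt * v + g_pas * e_pas
        b[:, act] -= g_na * (va - model.e_na) + g_k * (va - model.e_k)
        if pulse.active(t):
            b -= (lap @ phi_scaled.T).T
        v_new = lu.solve(b.T).T

        if not np.isfinite(v_new).all():
            raise IntegrationError(f"cable integration diverged at dt={dt_us} us")
        newly = (v_new >= threshold_mv) & (v < threshold_mv) & np.isnan(first_cross)
        if detect_mask is not None:
            newly &= detect_mask[None, :]
        if newly.any():
            first_cross[newly] = t
        np.maximum(v_peak, v_new, out=v_peak)
        v = v_new
        if record:
            traces[:, :, k] = v
        if stop_when_all_fired and np.isfinite(first_cross).any(axis=1).all():
            if record:
                traces = traces[:, :, : k + 1]
                times = times[: k + 1]
            break

    return times, traces, first_cross, v_peak


def simulate(comp: CompartmentSet, mem: MembraneParameters,
             phi_unit: np.ndarray, pulse: PulseSpec, amplitude: float,
             dt_us: float = 5.0, duration_ms: float = 5.0) -> MembraneTrace:
    """Integrate one neuron and return the full membrane trace."""
    model = comp if isinstance(comp, CableModel) else CableModel(comp, mem)
    times, traces, _, _ = _integrate(
        model, np.atleast_2d(phi_unit), np.array([amplitude]), pulse,
        dt_us, duration_ms, record=True)
    return MembraneTrace(times=times, v=traces[0], dt_us=dt_us)


@dataclass
class BatchResult:
    """Summary of a batched integration (no full traces)."""

    first_cross: np.ndarray  # (B, n_comp) ms
    v_peak: np.ndarray  # (B, n_comp) mV

    @property
    def fired(self) -> np.ndarray:
        return np.isfinite(self.first_cross).any(axis=1)


def simulate_batch(model: CableModel, phi_unit: np.ndarray,
                   amplitudes: np.ndarray, pulse: PulseSpec,
                   dt_us: float = 5.0, duration_ms: float = 5.0,
                   threshold_mv: float = 0.0,
                   detect_active_only: bool = True) -> BatchResult:
    """Integrate a batch of neurons sharing one discretization.

    By default, crossings are only counted on somatic/axonal compartments: a
    dendritic depolarization must propagate there to count as an action
    potential, so bulk passive polarization of the dendrites is never
    mistaken for one.
    """
    mask = None
    if detect_active_only:
        mask = np.isin(model.comp.stypes.astype(str),
                       ("soma", "initial_segment", "node"))
    _, _, first_cross, v_peak = _integrate(
        model, phi_unit, amplitudes, pulse, dt_us, duration_ms,
        record=False, threshold_mv=threshold_mv, detect_mask=mask)
    return BatchResult(first_cross=first_cross, v_peak=v_peak)


def detect_ap(trace: MembraneTrace, threshold_mv: float = 0.0) -> APEvent:
    """Fired iff any compartment crosses the detection level with + slope."""
    v = trace.v
    above = v >= threshold_mv
    rising = above[:, 1:] & ~above[:, :-1]
    crossing = np.full(v.shape[0], np.nan)
    for i in range(v.shape[0]):
        idx = np.flatnonzero(rising[i])
        if len(idx):
            crossing[i] = trace.times[idx[0] + 1]
    fired = np.isfinite(crossing).any()
    if not fired:
        return APEvent(False, crossing)
    init = int(np.nanargmin(crossing))
    return APEvent(True, crossing, initiation_compartment=init,
                   initiation_time=float(crossing[init]))


def classify_initiation(event: APEvent, comp: CompartmentSet,
                        depth_at_compartments: np.ndarray,
                        gm_thickness: float,
                        bend_range: tuple | None = None,
                        boundary_tol: float = 0.3) -> str:
    """Initiation-site category from compartment type and position.

    Order of precedence: axon terminal (last axonal compartment), GM/WM
    boundary (axonal compartment within ``boundary_tol`` mm of the
    interface), initial segment, axon bend, soma, other.  The terminal takes
    precedence so that a terminal that happens to stop near the boundary
    (L3 cells) is still reported as a terminal.
    """
    if not event.fired:
        return ""
    i = event.initiation_compartment
    st = str(comp.stypes[i])
    axonal = st in ("axon", "node", "initial_segment")
    if axonal and i == comp.last_axon_compartment():
        return "axon terminal"
    if axonal and st != "initial_segment" and np.isfinite(
            depth_at_compartments[i]) and abs(
            depth_at_compartments[i] - gm_thickness) <= boundary_tol:
        return "GM/WM boundary"
    if st == "initial_segment":
        return "initial segment"
    if axonal and bend_range is not None and np.isfinite(comp.axon_arc[i]) \
            and bend_range[0] <= comp.axon_arc[i] <= bend_range[1]:
        return "axon bend"
    if st == "soma":
        return "soma"
    return "other"
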