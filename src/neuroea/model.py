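"""Reduced conductance-based compartmental neuron model.

The simulator integrates a small tree of cylindrical compartments (soma with
optional attached axon and dendrite) carrying classic Hodgkin-Huxley sodium
(m^3 h) and delayed-rectifier potassium (n^4) currents, a first-order M-type
potassium current providing spike-frequency adaptation, and a passive leak.
Free parameters (maximal conductance densities per compartment plus the
global passive properties) are described by a :class:`ParameterSpec` and
bound to the model by :func:`build_default_model`.

Numerics: gating variables advance by exponential Euler with the voltage
frozen over the step; the voltage advances by implicit (backward) Euler on
the conductance-linearised cable equation, solved directly on the tree
(Hines elimination).  This scheme is unconditionally stable at the default
``dt`` = 0.025 ms.

Units follow common electrophysiology practice: mV, ms, nA, S/cm**2 for
conductance densities, uF/cm**2 for specific capacitance, ohm*cm for axial
resistivity, um for geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ConfigurationError, IntegrationError

__all__ = [
    "ParameterSpec",
    "ParameterEntry",
    "Individual",
    "Population",
    "Compartment",
    "CellModel",
    "Trace",
    "default_parameter_spec",
    "build_default_model",
    "simulate",
    "DEFAULT_DT",
    "E_NA",
    "E_K",
    "SETTLE_MS",
    "BLOWUP_MV",
]

DEFAULT_DT = 0.025     # ms
SETTLE_MS = 100.0      # unrecorded settling period before t = 0
BLOWUP_MV = 1000.0     # |v| beyond this is an integration failure
E_NA = 50.0            # mV, sodium reversal
E_K = -77.0            # mV, potassium reversal (shared by K-dr and I_M)

# ---------------------------------------------------------------------------
# Parameter specification
# ---------------------------------------------------------------------------

_COMPARTMENTS = ("soma", "axon", "dend")
_DENSITY_BASES = {"gNabar": "gnabar", "gKbar": "gkbar",
                  "gMbar": "gmbar", "g_pas": "g_pas"}
_GLOBAL_NAMES = {"e_pas": "e_pas", "cm": "cm", "Ra": "ra",
                 "tau_max": "tau_max"}


@dataclass(frozen=True)
class ParameterEntry:
    name: str
    compartment: str      # soma | axon | dend | global
    lower: float
    upper: float
    units: str

    def __post_init__(self):
        if self.compartment not in _COMPARTMENTS + ("global",):
            raise ConfigurationError(
                f"entry {self.name!r}: unknown compartment "
                f"{self.compartment!r}"
            )
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"entry {self.name!r}: lower bound {self.lower} must be "
                f"< upper bound {self.upper}"
            )


@dataclass(frozen=True)
class ParameterSpec:
    """Ordered list of free parameters with box bounds."""

    entries: tuple[ParameterEntry, ...]

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ConfigurationError("parameter names must be unique")

    @property
    def count(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def lower(self) -> np.ndarray:
        return np.array([e.lower for e in self.entries])

    @property
    def upper(self) -> np.ndarray:
        return np.array([e.upper for e in self.entries])

    def subset(self, names) -> "ParameterSpec":
        """Spec restricted to ``names``, preserving this spec's order."""
        names = set(names)
        unknown = names - set(self.names)
        if unknown:
            raise ConfigurationError(f"unknown parameter names: {sorted(unknown)}")
        return ParameterSpec(tuple(e for e in self.entries if e.name in names))

    def check_bounds(self, values) -> bool:
        v = np.asarray(values, dtype=float)
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))


def default_parameter_spec() -> ParameterSpec:
    """The shipped 13-parameter specification.

    Maximal Na/K-dr/M conductance densities split between soma and axon,
    a passive leak density per compartment, and the four global passive
    parameters.  Bounds bracket the canonical squid values and give the
    default stimulus grid a sub- to supra-threshold span.
    """
    s_cm2 = "S/cm^2"
    rows = [
        ("gNabar_soma", "soma", 0.05, 0.4, s_cm2),
        ("gNabar_axon", "axon", 0.05, 0.4, s_cm2),
        ("gKbar_soma", "soma", 0.005, 0.06, s_cm2),
        ("gKbar_axon", "axon", 0.005, 0.06, s_cm2),
        ("gMbar_soma", "soma", 1e-5, 2e-4, s_cm2),
        ("gMbar_axon", "axon", 1e-5, 2e-4, s_cm2),
        ("g_pas_soma", "soma", 1e-5, 8e-5, s_cm2),
        ("g_pas_axon", "axon", 1e-5, 8e-5, s_cm2),
        ("g_pas_dend", "dend", 1e-5, 8e-5, s_cm2),
        ("e_pas", "global", -80.0, -60.0, "mV"),
        ("cm", "global", 0.5, 1.5, "uF/cm^2"),
        ("Ra", "global", 50.0, 200.0, "ohm*cm"),
        ("tau_max", "global", 200.0, 2000.0, "ms"),
    ]
    return ParameterSpec(tuple(ParameterEntry(*r) for r in rows))


# ---------------------------------------------------------------------------
# Individuals and populations
# ---------------------------------------------------------------------------

@dataclass
class Individual:
    """One candidate parameter vector, optionally carrying its scores."""

    values: np.ndarray
    scores: np.ndarray | None = None     # ScoreRow, length S*F
    fitness: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def total_score(self) -> float:
        if self.scores is None:
            raise ValueError("individual has not been scored")
        return float(np.sum(self.scores))

    def copy(self) -> "Individual":
        return Individual(self.values.copy(),
                          None if self.scores is None else self.scores.copy(),
                          self.fitness)


@dataclass
class Population:
    individuals: list[Individual] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.individuals)

    def __len__(self):
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, i):
        return self.individuals[i]

    def values_matrix(self) -> np.ndarray:
        return np.array([ind.values for ind in self.individuals])


# ---------------------------------------------------------------------------
# Cell model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compartment:
    name: str
    length_um: float
    diameter_um: float
    parent: str | None   # None only for the root (soma)

    def __post_init__(self):
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ConfigurationError(
                f"compartment {self.name!r}: dimensions must be positive"
            )

    @property
    def area_cm2(self) -> float:
        # lateral surface of a cylinder
        return math.pi * self.diameter_um * self.length_um * 1e-8


# geometry defaults: smallest model with a soma/axon/dend parameter split;
# the soma area is ~1e-4 cm^2
DEFAULT_GEOMETRY = {
    "soma": (56.42, 56.42, None),
    "axon": (60.0, 1.0, "soma"),
    "dend": (600.0, 2.0, "soma"),
}

# per-compartment mechanism defaults (S/cm^2) used for parameters a spec
# does not bind; the dendrite is passive by default
_DENSITY_DEFAULTS = {
    "gnabar": {"soma": 0.12, "axon": 0.12, "dend": 0.0},
    "gkbar": {"soma": 0.036, "axon": 0.036, "dend": 0.0},
    "gmbar": {"soma": 4e-4, "axon": 4e-4, "dend": 0.0},
    "g_pas": {"soma": 5e-5, "axon": 5e-5, "dend": 5e-5},
}
_GLOBAL_DEFAULTS = {"e_pas": -70.0, "cm": 1.0, "ra": 150.0, "tau_max": 1000.0}


@dataclass
class CellModel:
    """Compartment tree plus base mechanism values and spec bindings.

    ``bindings`` maps each spec entry index either to
    ``("density", field, compartment_index)`` or ``("global", field)``;
    :func:`simulate` overlays the individual's values onto the base values
    through these bindings.
    """

    compartments: list[Compartment]
    spec: ParameterSpec
    base_density: dict          # field -> ndarray over compartments (S/cm^2)
    base_global: dict           # e_pas, cm, ra, tau_max
    bindings: list[tuple]
    settle_ms: float = SETTLE_MS

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def compartment_names(self) -> list[str]:
        return [c.name for c in self.compartments]

    def parent_indices(self) -> np.ndarray:
        names = self.compartment_names
        out = np.empty(len(names), dtype=np.int64)
        for i, c in enumerate(self.compartments):
            if c.parent is None:
                out[i] = -1
            else:
                out[i] = names.index(c.parent)
                if out[i] >= i:
                    raise ConfigurationError(
                        "compartments must be ordered parent-before-child"
                    )
        return out

    def resolve(self, values) -> tuple[dict, dict]:
        """Base values with an individual's free values overlaid."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.spec.count,):
            raise ConfigurationError(
                f"expected {self.spec.count} parameter values, "
                f"got {values.shape}"
            )
        dens = {k: v.copy() for k, v in self.base_density.items()}
        glob = dict(self.base_global)
        for val, binding in zip(values, self.bindings):
            if binding[0] == "density":
                _, fld, ci = binding
                dens[fld][ci] = val
            else:
                glob[binding[1]] = val
        return dens, glob


def _parse_entry(entry: ParameterEntry) -> tuple:
    """Map a spec entry name onto a mechanism field, or raise."""
    if entry.compartment == "global":
        if entry.name not in _GLOBAL_NAMES:
            raise ConfigurationError(
                f"unknown global parameter {entry.name!r}; "
                f"known: {sorted(_GLOBAL_NAMES)}"
            )
        return ("global", _GLOBAL_NAMES[entry.name])
    for base, fld in _DENSITY_BASES.items():
        if entry.name == f"{base}_{entry.compartment}":
            return ("density", fld, entry.compartment)
    raise ConfigurationError(
        f"parameter {entry.name!r} does not match any mechanism of "
        f"compartment {entry.compartment!r} "
        f"(known bases: {sorted(_DENSITY_BASES)})"
    )


def build_default_model(
    spec: ParameterSpec,
    *,
    geometry: dict | None = None,
    base_density: dict | None = None,
    base_global: dict | None = None,
    settle_ms: float = SETTLE_MS,
) -> CellModel:
    """Build the compartment tree implied by ``spec`` and wire its entries.

    Compartments are the ones the spec references (the soma is always
    present); a spec touching only somatic parameters therefore yields a
    single-compartment model.  ``base_density`` / ``base_global`` override
    the shipped defaults for parameters the spec leaves fixed — the
    synthetic-problem generator uses this to pin non-free parameters at
    their ground-truth values.
    """
    geometry = dict(DEFAULT_GEOMETRY if geometry is None else geometry)

    parsed = [_parse_entry(e) for e in spec.entries]

    wanted = {"soma"} | {b[2] for b in parsed if b[0] == "density"}
    comp_names = [c for c in _COMPARTMENTS if c in wanted]
    compartments = []
    for name in comp_names:
        length, diam, parent = geometry[name]
        if parent is not None and parent not in comp_names:
            parent = "soma"
        compartments.append(Compartment(name, length, diam, parent))

    dens = {}
    for fld in ("gnabar", "gkbar", "gmbar", "g_pas"):
        defaults = _DENSITY_DEFAULTS[fld]
        over = (base_density or {}).get(fld, {})
        dens[fld] = np.array(
            [float(over.get(n, defaults[n])) for n in comp_names]
        )
    glob = dict(_GLOBAL_DEFAULTS)
    glob.update(base_global or {})

    comp_index = {n: i for i, n in enumerate(comp_names)}
    bindings = []
    for b in parsed:
        if b[0] == "density":
            bindings.append(("density", b[1], comp_index[b[2]]))
        else:
            bindings.append(b)

    return CellModel(compartments, spec, dens, glob, bindings,
                     settle_ms=settle_ms)


# ---------------------------------------------------------------------------
# Voltage trace
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Somatic membrane potential on a uniform time grid."""

    t: np.ndarray          # ms
    v: np.ndarray          # mV
    stimulus_id: str

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ConfigurationError("time and voltage arrays differ in length")
        if len(self.t) < 2 or self.dt <= 0:
            raise ConfigurationError("trace needs >= 2 samples with dt > 0")
        if not np.all(np.isfinite(self.v)):
            raise ConfigurationError("trace contains non-finite voltages")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


# ---------------------------------------------------------------------------
# Integration kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _safe_rate(u):
    # u / (1 - exp(-u)) with the removable singularity at u = 0
    if abs(u) < 1e-7:
        return 1.0 + 0.5 * u
    return u / (1.0 - math.exp(-u))


@njit(cache=True)
def _steady_gates(v, tau_max):
    am = _safe_rate((v + 40.0) / 10.0)
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    an = 0.1 * _safe_rate((v + 55.0) / 10.0)
    bn = 0.125 * math.exp(-(v + 65.0) / 80.0)
    m = am / (am + bm)
    h = ah / (ah + bh)
    n = an / (an + bn)
    p = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    return m, h, n, p


# rate-table layout (one row per tabulated quantity on the voltage grid):
# steady states and per-step exponential decay factors exp(-dt/tau) of the
# four gates
_TAB_VMIN = -120.0
_TAB_VMAX = 80.0
_TAB_N = 4001


@njit(cache=True)
def _build_rate_table(dt, tau_max):
    """Tabulate gate steady states and step factors on a 0.05 mV grid.

    Lookup with linear interpolation replaces ~13 exp evaluations per
    active compartment per step; the grid is fine enough that the
    interpolation error is far below the integration error.
    """
    tab = np.empty((_TAB_N, 8))
    step = (_TAB_VMAX - _TAB_VMIN) / (_TAB_N - 1)
    for j in range(_TAB_N):
        vj = _TAB_VMIN + j * step
        am = _safe_rate((vj + 40.0) / 10.0)
        bm = 4.0 * math.exp(-(vj + 65.0) / 18.0)
        ah = 0.07 * math.exp(-(vj + 65.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-(vj + 35.0) / 10.0))
        an = 0.1 * _safe_rate((vj + 55.0) / 10.0)
        bn = 0.125 * math.exp(-(vj + 65.0) / 80.0)
        tm = 1.0 / (am + bm)
        th = 1.0 / (ah + bh)
        tn = 1.0 / (an + bn)
        tab[j, 0] = am * tm
        tab[j, 1] = math.exp(-dt / tm)
        tab[j, 2] = ah * th
        tab[j, 3] = math.exp(-dt / th)
        tab[j, 4] = an * tn
        tab[j, 5] = math.exp(-dt / tn)
        tab[j, 6] = 1.0 / (1.0 + math.exp(-(vj + 35.0) / 10.0))
        tp = tau_max / (3.3 * math.exp((vj + 35.0) / 20.0)
                        + math.exp(-(vj + 35.0) / 20.0))
        tab[j, 7] = math.exp(-dt / tp)
    return tab


@njit(cache=True)
def _integrate(parent, c_nf, g_ax_us, gna_us, gk_us, gm_us, gpas_us,
               e_pas, tau_max, v_init, dt, n_settle, i_inj, v_out):
    """Settle, then record the soma on the output grid.

    One fused loop: exponential-Euler gate updates via rate-table lookup,
    then the implicit-Euler voltage solve on the tree (Hines elimination).
    ``i_inj[k]`` is the somatic current (nA) over step k -> k+1.  Returns
    +inf on success, otherwise the time (ms, negative during settling) of
    the first blown-up step.
    """
    n = parent.shape[0]
    n_out = i_inj.shape[0]
    e_na = E_NA
    e_k = E_K
    inv_step = (_TAB_N - 1) / (_TAB_VMAX - _TAB_VMIN)
    tab = _build_rate_table(dt, tau_max)

    v = np.empty(n)
    m = np.empty(n)
    h = np.empty(n)
    ng = np.empty(n)
    p = np.empty(n)
    cdt = np.empty(n)
    active = np.empty(n, dtype=np.bool_)
    for i in range(n):
        v[i] = v_init
        mi, hi, ni, pi = _steady_gates(v_init, tau_max)
        m[i] = mi
        h[i] = hi
        ng[i] = ni
        p[i] = pi
        cdt[i] = c_nf[i] / dt
        active[i] = gna_us[i] + gk_us[i] + gm_us[i] > 0.0
    d = np.empty(n)
    rhs = np.empty(n)

    total = n_settle + n_out - 1
    v_out[0] = v_init
    for step in range(total):
        recording = step >= n_settle
        inj = i_inj[step - n_settle] if recording else 0.0

        # gate update with V frozen over the step (skipped in passive
        # compartments, where the gates are never read)
        for i in range(n):
            if not active[i]:
                continue
            x = (v[i] - _TAB_VMIN) * inv_step
            if x < 0.0:
                x = 0.0
            elif x > _TAB_N - 1.001:
                x = _TAB_N - 1.001
            j = int(x)
            w = x - j
            m_inf = tab[j, 0] + (tab[j + 1, 0] - tab[j, 0]) * w
            em = tab[j, 1] + (tab[j + 1, 1] - tab[j, 1]) * w
            h_inf = tab[j, 2] + (tab[j + 1, 2] - tab[j, 2]) * w
            eh = tab[j, 3] + (tab[j + 1, 3] - tab[j, 3]) * w
            n_inf = tab[j, 4] + (tab[j + 1, 4] - tab[j, 4]) * w
            en = tab[j, 5] + (tab[j + 1, 5] - tab[j, 5]) * w
            p_inf = tab[j, 6] + (tab[j + 1, 6] - tab[j, 6]) * w
            ep = tab[j, 7] + (tab[j + 1, 7] - tab[j, 7]) * w
            m[i] = m_inf + (m[i] - m_inf) * em
            h[i] = h_inf + (h[i] - h_inf) * eh
            ng[i] = n_inf + (ng[i] - n_inf) * en
            p[i] = p_inf + (p[i] - p_inf) * ep

        # conductance-linearised implicit system
        for i in range(n):
            gna = gna_us[i] * m[i] * m[i] * m[i] * h[i]
            gk = gk_us[i] * ng[i] * ng[i] * ng[i] * ng[i]
            gm = gm_us[i] * p[i]
            gtot = gna + gk + gm + gpas_us[i]
            ie = gna * e_na + gk * e_k + gm * e_k + gpas_us[i] * e_pas
            d[i] = cdt[i] + gtot + g_ax_us[i]
            rhs[i] = cdt[i] * v[i] + ie
        for i in range(1, n):
            d[parent[i]] += g_ax_us[i]
        rhs[0] += inj

        # Hines solve (parents precede children)
        for i in range(n - 1, 0, -1):
            f = g_ax_us[i] / d[i]
            d[parent[i]] -= f * g_ax_us[i]
            rhs[parent[i]] += f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_ax_us[i] * v[parent[i]]) / d[i]

        bad = False
        for i in range(n):
            if not math.isfinite(v[i]) or abs(v[i]) > BLOWUP_MV:
                bad = True
        if bad:
            if recording:
                return (step - n_settle + 1) * dt
            return (step + 1) * dt - n_settle * dt
        if recording:
            v_out[step - n_settle + 1] = v[0]
        elif step == n_settle - 1:
            v_out[0] = v[0]
    return math.inf


def simulate(
    model: CellModel,
    values,
    stimulus,
    dt: float = DEFAULT_DT,
    v_init: float | None = None,
) -> Trace:
    """Integrate the model under one stimulus and return the somatic trace.

    Deterministic for fixed inputs and independent of any other individual
    or stimulus.  ``v_init`` defaults to the (possibly free) leak reversal
    ``e_pas``; an unrecorded settling period of ``model.settle_ms`` precedes
    t = 0.  Numerical blow-up raises :class:`IntegrationError`.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    dens, glob = model.resolve(values)

    areas = np.array([c.area_cm2 for c in model.compartments])
    parent = model.parent_indices()
    c_nf = glob["cm"] * areas * 1e3                       # nF
    g_ax_us = np.zeros(model.n_compartments)
    for i, c in enumerate(model.compartments):
        if c.parent is not None:
            a_cross_cm2 = math.pi * (c.diameter_um * 1e-4) ** 2 / 4.0
            g_ax_us[i] = a_cross_cm2 / (glob["ra"] * c.length_um * 1e-4) * 1e6

    to_us = areas * 1e6
    gna = dens["gnabar"] * to_us
    gk = dens["gkbar"] * to_us
    gm = dens["gmbar"] * to_us
    gpas = dens["g_pas"] * to_us

    if v_init is None:
        v_init = glob["e_pas"]

    i_inj = stimulus.samples(dt)
    n_settle = int(round(model.settle_ms / dt))
    v_out = np.empty_like(i_inj)

    t_fail = _integrate(parent, c_nf, g_ax_us, gna, gk, gm, gpas,
                        glob["e_pas"], glob["tau_max"], float(v_init),
                        float(dt), n_settle, i_inj, v_out)
    if not math.isinf(t_fail):
        raise IntegrationError(t_fail)

    t = np.arange(len(i_inj)) * dt
    return Trace(t, v_out, stimulus_id=stimulus.id)
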