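"""A reduced one-dimensional enamel-knot patterning model of tooth rows.

Cusps of mammalian teeth are positioned by secondary enamel knots:
signalling centres that form reiteratively wherever existing knots'
inhibition has faded enough on a growing epithelium. This module implements
a deliberately minimal 1D surrogate of that process. A tooth is a growing
interval; knots sit at fixed positions and emit exponentially decaying
inhibition; a new knot nucleates at the grid point where total inhibition
first drops below a threshold. Three parameters carry the species
differences:

* ``inh`` — inhibition strength, the spatial reach of knot inhibition;
  larger values space cusps further apart and reduce cusp number.
* ``egr`` — epithelial growth rate; scales both domain growth and cusp
  height, making cusps taller and pointier (smaller top-cusp angle).
* ``abi`` — anterior bias, the fraction of elongation allocated to the
  anterior end, controlling anteroposterior asymmetry of the cusp row.

Lateral biases (``lbi``, ``bbi``) exist in the full 3D developmental model
but are held constant for laterally compressed seal-like teeth and have no
effect in one dimension; they are carried only for interface completeness.

Tooth rows arise from constant per-tooth parameter changes along the jaw,
and hybridization is modelled by combining the two parents' parameters —
averaging, shifting 10% towards a parent, or inheriting a parameter
outright — independently for each of the three parameters.

The model is fully deterministic; all compared simulations must use the
same number of iterations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dental
from .errors import ParameterError

HYBRID_MODES = ("average", "shift_to_a_10pct", "shift_to_b_10pct", "take_a", "take_b")
PARAM_NAMES = ("inh", "egr", "abi")


@dataclass(frozen=True)
class DevParams:
    """The three species-differentiating developmental parameters."""

    inh: float  # inhibition strength (> 0), sets cusp spacing/number
    egr: float  # epithelial growth rate (> 0), sets cusp height/pointedness
    abi: float  # anterior bias in [0, 1], fraction of growth placed anteriorly
    n_iter: int = 1000
    lbi: float = 1.0  # lateral biases: constant, inert in the 1D model
    bbi: float = 1.0

    def __post_init__(self) -> None:
        if not (self.inh > 0 and np.isfinite(self.inh)):
            raise ParameterError(f"inh must be > 0, got {self.inh}")
        if not (self.egr > 0 and np.isfinite(self.egr)):
            raise ParameterError(f"egr must be > 0, got {self.egr}")
        if not 0.0 <= self.abi <= 1.0:
            raise ParameterError(f"abi must be in [0, 1], got {self.abi}")
        if self.n_iter < 1:
            raise ParameterError("n_iter must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Fixed numerical constants of the surrogate model.

    ``g0`` is the elongation per iteration per unit ``egr``; ``lambda0`` the
    inhibition length scale per unit ``inh``; ``delta`` the nucleation grid
    spacing; ``theta_nuc`` the inhibition level below which a knot forms;
    ``L0`` the initial domain length and ``h0`` the height unit.
    """

    g0: float = 0.0008
    lambda0: float = 0.25
    delta: float = 0.01
    theta_nuc: float = 0.35
    L0: float = 0.3
    h0: float = 0.5

    def __post_init__(self) -> None:
        if min(self.g0, self.lambda0, self.delta, self.theta_nuc, self.L0, self.h0) <= 0:
            raise ParameterError("all simulation constants must be positive")


DEFAULT_CONFIG = SimConfig()


@dataclass
class SimulatedTooth:
    """Knots (cusp precursors) and final domain of one simulated tooth."""

    knots: pd.DataFrame  # columns: x, step, height; includes the primary knot
    domain: tuple[float, float]
    params: DevParams

    @property
    def cusp_count(self) -> int:
        return len(self.knots)

    def geometry(self) -> dental.ToothGeometry:
        tips = self.knots.sort_values("x")[["x", "height"]].to_numpy(float)
        a, p = self.domain
        return dental.ToothGeometry(tips, np.array([a, 0.0]), np.array([p, 0.0]))

    @property
    def top_cusp_angle(self) -> float:
        return dental.top_cusp_angle(self.geometry())


def simulate_tooth(p: DevParams, config: SimConfig = DEFAULT_CONFIG) -> SimulatedTooth:
    """Run the 1D enamel-knot simulation for one tooth.

    The domain starts as [-L0/2, +L0/2] with the primary knot at 0. Each
    iteration the anterior (negative) end extends by g*abi and the posterior
    end by g*(1-abi), with g = g0*egr. Total inhibition
    h(x) = sum_k exp(-|x - x_k| / (lambda0*inh)) is evaluated on a fixed
    global grid of spacing delta; a knot nucleates at the grid point
    minimising h whenever that minimum falls below theta_nuc (ties resolved
    to the most anterior point). Knot k nucleated at step t_k ends with tip
    height (1 + (n_iter - t_k)/n_iter) * h0 * egr, so earlier cusps are
    taller; crown-base endpoints sit at the final domain edges at height 0.
    """
    lam = config.lambda0 * p.inh
    g = config.g0 * p.egr
    n = p.n_iter

    # Fixed global grid (multiples of delta) covering the final domain, so
    # that refining delta only inserts points rather than shifting them.
    a_final = -config.L0 / 2 - g * p.abi * n
    p_final = config.L0 / 2 + g * (1 - p.abi) * n
    i_lo = int(np.floor(a_final / config.delta)) - 1
    i_hi = int(np.ceil(p_final / config.delta)) + 1
    grid = np.arange(i_lo, i_hi + 1) * config.delta

    knot_x = [0.0]
    knot_t = [0]
    field_h = np.exp(-np.abs(grid) / lam)  # inhibition from the primary knot

    a_end, p_end = -config.L0 / 2, config.L0 / 2
    for t in range(1, n + 1):
        a_end -= g * p.abi
        p_end += g * (1 - p.abi)
        active = (grid >= a_end) & (grid <= p_end)
        h_active = field_h[active]
        if h_active.size == 0:
            continue
        j = int(np.argmin(h_active))  # first minimum = most anterior tie
        if h_active[j] < config.theta_nuc:
            x_new = grid[active][j]
            knot_x.append(float(x_new))
            knot_t.append(t)
            field_h += np.exp(-np.abs(grid - x_new) / lam)

    heights = [(1.0 + (n - t) / n) * config.h0 * p.egr for t in knot_t]
    knots = pd.DataFrame({"x": knot_x, "step": knot_t, "height": heights})
    return SimulatedTooth(knots, (a_end, p_end), p)


@dataclass(frozen=True)
class RowSpec:
    """A five-tooth row: base parameters plus constant per-tooth deltas."""

    base: DevParams
    delta_inh: float = 0.0
    delta_egr: float = 0.0
    delta_abi: float = 0.0
    n_teeth: int = 5
    label: str = ""

    def params_at(self, position: int) -> DevParams:
        """Parameters of the tooth at 0-based position along the jaw."""
        try:
            return replace(
                self.base,
                inh=self.base.inh + position * self.delta_inh,
                egr=self.base.egr + position * self.delta_egr,
                abi=self.base.abi + position * self.delta_abi,
            )
        except ParameterError as exc:
            raise ParameterError(f"invalid parameters at position P{position + 1}: {exc}")


def simulate_tooth_row(
    spec: RowSpec, config: SimConfig = DEFAULT_CONFIG
) -> list[SimulatedTooth]:
    """Simulate the five teeth of a row under constant parameter gradients."""
    return [simulate_tooth(spec.params_at(i), config) for i in range(spec.n_teeth)]


def row_summary(teeth: Sequence[SimulatedTooth], label: str = "") -> pd.DataFrame:
    rows = []
    for i, tooth in enumerate(teeth):
        rows.append({
            "row_label": label,
            "position": f"P{i + 1}",
            "cusp_count": tooth.cusp_count,
            "angle_deg": tooth.top_cusp_angle,
        })
    return pd.DataFrame(rows)


# Packaged species rows: calibration choices of this package, set so that the
# ringed-type row develops several subequal cusps at every position while the
# grey-type row has few cusps anteriorly with a dominant central cusp, and a
# cusp-number gradient along the jaw driven by its inh gradient.
RINGED_SEAL_ROW = RowSpec(
    base=DevParams(inh=1.0, egr=1.0, abi=0.5),
    delta_egr=0.05,
    label="ringed",
)
GREY_SEAL_ROW = RowSpec(
    base=DevParams(inh=2.2, egr=1.6, abi=0.35),
    delta_egr=0.05,
    delta_inh=-0.2,
    label="grey",
)


def _combine(x_a: float, x_b: float, mode: str) -> float:
    mid = (x_a + x_b) / 2.0
    if mode == "average":
        return mid
    if mode == "shift_to_a_10pct":  # == 0.55*a + 0.45*b
        return mid + 0.1 * (x_a - mid)
    if mode == "shift_to_b_10pct":
        return mid + 0.1 * (x_b - mid)
    if mode == "take_a":
        return x_a
    if mode == "take_b":
        return x_b
    raise ParameterError(f"unknown hybrid mode {mode!r}; choose from {HYBRID_MODES}")


def make_hybrid_params(
    a: DevParams, b: DevParams, modes: str | dict[str, str] = "average"
) -> DevParams:
    """Combine two parents' parameters under per-parameter inheritance modes.

    ``modes`` is one mode applied to all three parameters, or a dict keyed by
    'inh'/'egr'/'abi'. The 10% shifts move the midpoint one tenth of the
    half-range towards the named parent (equivalently a 0.55/0.45 weighted
    mean), representing weak dominance.
    """
    if a.n_iter != b.n_iter:
        raise ParameterError(
            f"parents differ in n_iter ({a.n_iter} vs {b.n_iter}); "
            "all compared simulations must run the same number of iterations"
        )
    if isinstance(modes, str):
        modes = {name: modes for name in PARAM_NAMES}
    unknown = set(modes) - set(PARAM_NAMES)
    if unknown:
        raise ParameterError(f"unknown parameter names in modes: {sorted(unknown)}")
    values = {
        name: _combine(getattr(a, name), getattr(b, name), modes.get(name, "average"))
        for name in PARAM_NAMES
    }
    return DevParams(n_iter=a.n_iter, **values)


def make_hybrid_row_spec(
    a: RowSpec, b: RowSpec, modes: str | dict[str, str] = "average", label: str = "hybrid"
) -> RowSpec:
    """Hybrid row: base and per-tooth deltas combined per-parameter.

    Because every inheritance mode is affine, combining base and delta
    separately equals combining the two parents' per-tooth parameters at
    each position.
    """
    if a.n_teeth != b.n_teeth:
        raise ParameterError("parent rows differ in number of teeth")
    if isinstance(modes, str):
        modes = {name: modes for name in PARAM_NAMES}
    base = make_hybrid_params(a.base, b.base, modes)
    deltas = {
        f"delta_{name}": _combine(
            getattr(a, f"delta_{name}"), getattr(b, f"delta_{name}"), modes.get(name, "average")
        )
        for name in PARAM_NAMES
    }
    return RowSpec(base=base, n_teeth=a.n_teeth, label=label, **deltas)


def hybrid_combination_grid(
    a: RowSpec, b: RowSpec, config: SimConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Simulate every per-parameter parental combination of a hybrid row.

    Enumerates all 27 assignments of {average, take_a, take_b} to the three
    parameters plus the two whole-genotype 10%-shift rows, simulates each
    resulting row, and reports per-tooth cusp counts and angles in a tidy
    table with the mode assignment attached.
    """
    frames = []
    for combo in itertools.product(("average", "take_a", "take_b"), repeat=3):
        modes = dict(zip(PARAM_NAMES, combo))
        label = ",".join(f"{k}={v}" for k, v in modes.items())
        spec = make_hybrid_row_spec(a, b, modes, label=label)
        summary = row_summary(simulate_tooth_row(spec, config), label)
        for name in PARAM_NAMES:
            summary[f"mode_{name}"] = modes[name]
        frames.append(summary)
    for shift in ("shift_to_a_10pct", "shift_to_b_10pct"):
        spec = make_hybrid_row_spec(a, b, shift, label=f"all_{shift}")
        summary = row_summary(simulate_tooth_row(spec, config), f"all_{shift}")
        for name in PARAM_NAMES:
            summary[f"mode_{name}"] = shift
        frames.append(summary)
    return pd.concat(frames, ignore_index=True)


def params_to_yaml(p: DevParams) -> str:
    return yaml.safe_dump({k: getattr(p, k) for k in ("inh", "egr", "abi", "n_iter")})


def params_from_yaml(text: str) -> DevParams:
    data = yaml.safe_load(text)
    return DevParams(**data)


def row_spec_from_yaml(text: str) -> RowSpec:
    data = yaml.safe_load(text)
    base = DevParams(**data.pop("base"))
    return RowSpec(base=base, **data)
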