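"""Mass-action chemical reaction networks and a deterministic ODE simulator.

This module is the substrate every other stage compiles into: species,
elementary reactions with mass-action kinetics, initial concentrations, and a
stiff-capable integrator with steady-state detection.  Units throughout are
nM for concentrations, seconds for time, and nM^(1-order)·s^-1 for rate
constants (so a bimolecular constant of 1e-4 nM^-1 s^-1 is ~1e5 M^-1 s^-1,
typical of toehold-mediated strand displacement).

Species roles are informational tags only; the integrator treats every
species identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Reaction",
    "ConservationLaw",
    "ReactionNetwork",
    "KineticsTrace",
    "ValidationError",
    "IntegrationFailure",
    "SteadyStateWarning",
    "simulate",
    "check_conservation",
    "endpoint_concentration",
    "DEFAULT_BIMOLECULAR_K",
]

#: Default bimolecular rate constant (nM^-1 s^-1); ~1e5 M^-1 s^-1.
DEFAULT_BIMOLECULAR_K = 1e-4

ROLES = frozenset(
    {
        "input",
        "amplifier",
        "inhibitor",
        "output_pos",
        "output_neg",
        "annihilator",
        "reporter",
        "fluorophore",
        "waste",
        "other",
    }
)


class ValidationError(ValueError):
    """A network, reaction, or argument violates a structural invariant."""


class IntegrationFailure(RuntimeError):
    """The ODE solver produced a non-finite state or failed to advance."""


class SteadyStateWarning(UserWarning):
    """Endpoint requested from a trace that has not reached steady state."""


@dataclass(frozen=True)
class Species:
    id: str
    role: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("species id must be non-empty")
        if self.role not in ROLES:
            raise ValidationError(f"unknown species role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """An elementary reaction with mass-action kinetics.

    ``reactants`` and ``products`` are tuples of species ids counted with
    multiplicity; reaction order (len of reactants) must be 1-3.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if not 1 <= len(self.reactants) <= 3:
            raise ValidationError(
                f"reaction order must be 1-3, got {len(self.reactants)}"
            )
        if len(self.products) > 3:
            raise ValidationError("at most 3 products per reaction")
        if not (np.isfinite(self.rate_constant) and self.rate_constant > 0):
            raise ValidationError(
                f"rate constant must be positive, got {self.rate_constant}"
            )

    @property
    def order(self) -> int:
        return len(self.reactants)


@dataclass(frozen=True)
class ConservationLaw:
    """A linear combination sum_i c_i·[s_i] expected to be constant in time."""

    coefficients: dict[str, float]
    expected: float
    label: str = ""


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    initial: dict[str, float]
    conservation_laws: list[ConservationLaw] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            raise ValidationError("species ids must be unique")
        known = set(ids)
        for rxn in self.reactions:
            for sid in (*rxn.reactants, *rxn.products):
                if sid not in known:
                    raise ValidationError(
                        f"reaction references undeclared species {sid!r}"
                    )
        for sid, conc in self.initial.items():
            if sid not in known:
                raise ValidationError(f"initial concentration for unknown species {sid!r}")
            if conc < 0:
                raise ValidationError(
                    f"initial concentration of {sid!r} is negative ({conc})"
                )

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def initial_vector(self) -> np.ndarray:
        return np.array([self.initial.get(s.id, 0.0) for s in self.species], float)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "species": [{"id": s.id, "role": s.role} for s in self.species],
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "rate_constant": r.rate_constant,
                }
                for r in self.reactions
            ],
            "initial": dict(self.initial),
            "conservation_laws": [
                {
                    "coefficients": dict(law.coefficients),
                    "expected": law.expected,
                    "label": law.label,
                }
                for law in self.conservation_laws
            ],
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        return cls(
            species=[Species(s["id"], s.get("role", "other")) for s in d["species"]],
            reactions=[
                Reaction(
                    tuple(r["reactants"]), tuple(r["products"]), r["rate_constant"]
                )
                for r in d["reactions"]
            ],
            initial={k: float(v) for k, v in d.get("initial", {}).items()},
            conservation_laws=[
                ConservationLaw(
                    {k: float(v) for k, v in law["coefficients"].items()},
                    float(law["expected"]),
                    law.get("label", ""),
                )
                for law in d.get("conservation_laws", [])
            ],
        )

    @classmethod
    def from_json(cls, source) -> "ReactionNetwork":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)


@dataclass
class KineticsTrace:
    """Time course of a simulation: times (s) × species concentrations (nM)."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_times, n_species)
    species_ids: list[str]
    steady_state_reached: bool
    endpoint: dict[str, float]
    max_clip: float = 0.0

    def __getitem__(self, species_id: str) -> np.ndarray:
        return self.concentrations[:, self._index(species_id)]

    def _index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise KeyError(f"species {species_id!r} not in trace") from None

    def to_tsv(self, path) -> None:
        header = "time\t" + "\t".join(self.species_ids)
        data = np.column_stack([self.times, self.concentrations])
        np.savetxt(path, data, delimiter="\t", header=header, comments="")

    def plot(self, species=None, ax=None):
        """Plot concentration time courses (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sid in species or self.species_ids:
            ax.plot(self.times, self[sid], label=sid)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("concentration (nM)")
        ax.legend(fontsize="small")
        return ax


def _rhs_factory(network: ReactionNetwork):
    """Build a vectorized mass-action right-hand side f(t, y)."""
    index = {sid: i for i, sid in enumerate(network.species_ids)}
    n_s, n_r = len(network.species), len(network.reactions)
    stoich = np.zeros((n_s, n_r))
    rates = np.empty(n_r)
    reactant_idx: list[np.ndarray] = []
    for j, rxn in enumerate(network.reactions):
        rates[j] = rxn.rate_constant
        idx = np.array([index[s] for s in rxn.reactants], int)
        reactant_idx.append(idx)
        for s in rxn.reactants:
            stoich[index[s], j] -= 1.0
        for s in rxn.products:
            stoich[index[s], j] += 1.0

    def rhs(_t, y):
        flux = rates.copy()
        for j, idx in enumerate(reactant_idx):
            flux[j] *= np.prod(y[idx])
        return stoich @ flux

    return rhs


def simulate(
    network: ReactionNetwork,
    t_end: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
    steady_tol: float = 1e-6,
    auto_extend: bool = True,
    max_extensions: int = 3,
    neg_tol: float = 1e-9,
) -> KineticsTrace:
    """Integrate the mass-action ODEs d[s]/dt = Σ_r ν_{s,r} k_r Π[reactants].

    Steady state is declared when max |d[s]/dt| < ``steady_tol`` (nM/s) at the
    final time.  If not reached and ``auto_extend`` is set, the horizon is
    doubled up to ``max_extensions`` times (8× total by default) — endpoint
    quantities in this system are t→∞ limits, so reliable convergence matters
    more than the nominal horizon.
    """
    network.validate()
    if not t_end > 0:
        raise ValidationError(f"t_end must be positive, got {t_end}")

    sids = network.species_ids
    if not sids:
        times = np.array([0.0, float(t_end)])
        return KineticsTrace(times, np.zeros((2, 0)), [], True, {})

    rhs = _rhs_factory(network)
    y0 = network.initial_vector()

    times_parts = [np.array([0.0])]
    conc_parts = [y0[None, :]]
    t0, y = 0.0, y0
    horizon = float(t_end)
    steady = False
    extensions = 0
    while True:
        sol = solve_ivp(rhs, (t0, horizon), y, method=method, rtol=rtol, atol=atol)
        y_arr = sol.y.T
        if not np.all(np.isfinite(y_arr)):
            bad_t, bad_s = np.argwhere(~np.isfinite(y_arr))[0]
            raise IntegrationFailure(
                f"non-finite concentration for species {sids[bad_s]!r} "
                f"near t={sol.t[bad_t]:.3g} s (rate blow-up?)"
            )
        if not sol.success:
            raise IntegrationFailure(f"ODE solver failed: {sol.message}")
        times_parts.append(sol.t[1:])
        conc_parts.append(y_arr[1:])
        t0, y = sol.t[-1], y_arr[-1]
        steady = bool(np.max(np.abs(rhs(t0, y))) < steady_tol)
        if steady or not auto_extend or extensions >= max_extensions:
            break
        extensions += 1
        horizon *= 2.0

    times = np.concatenate(times_parts)
    conc = np.vstack(conc_parts)
    max_clip = float(max(0.0, -conc.min())) if conc.size else 0.0
    if max_clip > 1e-6:
        warnings.warn(
            f"large negative excursion ({-max_clip:.3g} nM) clipped; "
            "consider tightening solver tolerances",
            RuntimeWarning,
            stacklevel=2,
        )
    conc = np.clip(conc, 0.0, None)
    endpoint = {sid: float(conc[-1, i]) for i, sid in enumerate(sids)}
    return KineticsTrace(times, conc, list(sids), steady, endpoint, max_clip)


def check_conservation(
    network: ReactionNetwork, trace: KineticsTrace
) -> list[tuple[ConservationLaw, float]]:
    """Max over time of |Σ c_i [s_i](t) − expected| for each declared law."""
    if not network.conservation_laws:
        raise ValidationError("network declares no conservation laws")
    known = set(trace.species_ids)
    out = []
    for law in network.conservation_laws:
        unknown = set(law.coefficients) - known
        if unknown:
            raise ValidationError(
                f"conservation law references unknown species {sorted(unknown)}"
            )
        total = np.zeros(len(trace.times))
        for sid, coef in law.coefficients.items():
            total += coef * trace[sid]
        violation = float(np.max(np.abs(total - law.expected))) if len(total) else 0.0
        out.append((law, violation))
    return out


def endpoint_concentration(trace: KineticsTrace, species_id: str) -> float:
    """Final-time concentration; warns if the trace is not at steady state."""
    value = trace.endpoint[species_id] if species_id in trace.endpoint else None
    if value is None:
        raise KeyError(f"species {species_id!r} not in trace")
    if not trace.steady_state_reached:
        warnings.warn(
            f"endpoint of {species_id!r} taken from a trace that has not "
            "reached steady state",
            SteadyStateWarning,
            stacklevel=2,
        )
    return value
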