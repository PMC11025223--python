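"""Independent reference integrators used as oracles.

Deliberately written from scratch (dict-based stoichiometry, Radau at
rtol 1e-10) so they share no code path with molclass.crn.simulate.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def reference_endpoint(
    species: list[str],
    reactions: list[tuple[tuple[str, ...], tuple[str, ...], float]],
    initial: dict[str, float],
    t_end: float,
) -> dict[str, float]:
    """Tight-tolerance Radau integration of a mass-action system.

    ``reactions`` are (reactants, products, k) triples over species names.
    """
    idx = {s: i for i, s in enumerate(species)}
    y0 = np.array([initial.get(s, 0.0) for s in species], float)

    def rhs(_t, y):
        dy = np.zeros_like(y)
        for reactants, products, k in reactions:
            flux = k
            for s in reactants:
                flux *= y[idx[s]]
            for s in reactants:
                dy[idx[s]] -= flux
            for s in products:
                dy[idx[s]] += flux
        return dy

    sol = solve_ivp(rhs, (0.0, t_end), y0, method="Radau", rtol=1e-10, atol=1e-12)
    assert sol.success
    return {s: float(sol.y[idx[s], -1]) for s in species}


def competitive_inhibition_endpoint(
    input0: float, amplifier0: float, inhibitor0: float, k: float, t_end: float
) -> float:
    """Reference Output endpoint for the two-reaction weighting scheme."""
    out = reference_endpoint(
        ["I", "A", "Z", "O", "W"],
        [
            (("I", "A"), ("I", "O"), k),
            (("I", "Z"), ("W",), k),
        ],
        {"I": input0, "A": amplifier0, "Z": inhibitor0},
        t_end,
    )
    return out["O"]
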