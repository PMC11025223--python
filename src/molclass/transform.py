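"""Associative strand-displacement conversion of ssDNA into classifier inputs.

The converter complex ("two splitting modules") recognizes the PCR-produced
ssDNA and releases the universal input strand the classifier circuitry
expects, decoupling the RNA sequence from the downstream chemistry.  The
two-splint association and the toehold-mediated displacement are collapsed
into a single effective bimolecular step at the concentration level; the
sequence-level split-position/junction optimizations enter only through a
yield fraction γ and a zeroth-order leak rate λ.

Below saturation (ssDNA < converter), the endpoint input concentration is
γ·ssDNA + λ·t, i.e. linear in the ssDNA amount — which composes with the
log-linear PCR front-end to give inputs linear in log2 of the initial miRNA
concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from . import crn
from .crn import ReactionNetwork, Reaction, Species, ValidationError

__all__ = ["ConverterSpec", "SaturationWarning", "convert", "transform_panel"]


class SaturationWarning(UserWarning):
    """ssDNA exceeds the converter supply; conversion is no longer linear."""


@dataclass(frozen=True)
class ConverterSpec:
    """One feature's conversion unit.

    converter0 : nM of converter complex; sets the saturation ceiling.
    yield_fraction : γ, fraction of consumed ssDNA emitted as input strand.
    leak_rate : λ, zeroth-order leak (nM/s) of input strand release.
    rate_constant : effective bimolecular displacement constant (nM^-1 s^-1).
    """

    target_id: str
    input_id: str
    converter0: float = 2000.0
    yield_fraction: float = 1.0
    leak_rate: float = 0.0
    rate_constant: float = crn.DEFAULT_BIMOLECULAR_K

    def __post_init__(self) -> None:
        if not self.converter0 > 0:
            raise ValidationError("converter0 must be positive")
        if not 0 < self.yield_fraction <= 1:
            raise ValidationError("yield fraction must be in (0, 1]")
        if self.leak_rate < 0:
            raise ValidationError("leak rate must be >= 0")
        if not self.rate_constant > 0:
            raise ValidationError("rate constant must be positive")

    def network(self, ssdna: float) -> ReactionNetwork:
        """CRN realizing ssDNA + Converter -> γ·Input (+ waste)."""
        g = self.yield_fraction
        species = [
            Species(self.target_id, "input"),
            Species("converter", "other"),
            Species(self.input_id, "input"),
            Species("waste", "waste"),
        ]
        reactions = [
            Reaction(
                (self.target_id, "converter"),
                (self.input_id, "waste"),
                g * self.rate_constant,
            )
        ]
        if g < 1.0:
            # unproductive branch: consumed but no input released
            reactions.append(
                Reaction(
                    (self.target_id, "converter"),
                    ("waste",),
                    (1.0 - g) * self.rate_constant,
                )
            )
        return ReactionNetwork(
            species=species,
            reactions=reactions,
            initial={self.target_id: ssdna, "converter": self.converter0},
        )


def convert(spec: ConverterSpec, ssdna: float, t_end: float = 1e5) -> float:
    """Endpoint input concentration (nM) for one ssDNA amount.

    Runs the converter CRN to steady state; the zeroth-order leak term
    λ·t_end is added to the endpoint analytically (the reaction-network
    representation is restricted to order 1-3 elementary steps).
    """
    if ssdna < 0:
        raise ValidationError("ssDNA concentration must be >= 0")
    if ssdna > spec.converter0:
        warnings.warn(
            f"ssDNA ({ssdna:.3g} nM) exceeds converter supply "
            f"({spec.converter0:.3g} nM): conversion saturates",
            SaturationWarning,
            stacklevel=2,
        )
    leak = spec.leak_rate * t_end
    if ssdna == 0:
        return leak
    trace = crn.simulate(spec.network(ssdna), t_end)
    return trace.endpoint[spec.input_id] + leak


def transform_panel(
    specs: dict[str, ConverterSpec], ssdna: dict[str, float], t_end: float = 1e5
) -> dict[str, float]:
    """Elementwise :func:`convert` over a feature panel."""
    missing = set(ssdna) - set(specs)
    if missing:
        raise ValidationError(f"no converter spec for features {sorted(missing)}")
    return {feat: convert(specs[feat], value, t_end) for feat, value in ssdna.items()}
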