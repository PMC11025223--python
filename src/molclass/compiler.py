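"""Compile a linear classifier into a strand-displacement reaction network.

A trained linear classifier  score = Σ_i W_i·x_i + b  is realized in
chemistry as:

* one *competitive-inhibition weight unit* per feature — a catalytic
  amplifier (Input + Amplifier → Input + Output, rate k) running in parallel
  with an inhibitor sink (Input + Inhibitor → Waste, same k).  Integrating
  the mass-action ODEs gives the exact endpoint
  [Output]∞ = [Input]0 · [Amplifier]0 / [Inhibitor]0, so the weight is set
  purely by initial concentrations: Inhibitor0 = Amplifier0 / |W|;

* *summation* for free: all positive-weight units release the same shared
  output strand, all negative-weight units the other, so the two output
  totals are Σ_pos W_i·x_i and Σ_neg |W_i|·x_i;

* an *annihilator* implementing winner-take-all subtraction: a cooperative-
  hybridization complex binds the negative output reversibly and collapses
  irreversibly once the positive output joins, consuming the two channels
  1:1 so only the majority survives;

* two *reporters* (HEX for the positive class, ROX for the negative) that
  convert the surviving output into fluorophore, read out against a linear
  standard curve.

The bias is realized as a constant auxiliary input of |b| nM on a weight-1
unit routed to the sign(b) side — the molecular realization of the SVM
threshold is a model commitment of this compiler (the underlying chemistry
literature does not prescribe one).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import crn
from .crn import (
    ConservationLaw,
    Reaction,
    ReactionNetwork,
    Species,
    ValidationError,
)

__all__ = [
    "InputScale",
    "LinearClassifierSpec",
    "WeightUnit",
    "AnnihilatorSpec",
    "ReporterSpec",
    "CompiledClassifier",
    "LinearRegimeWarning",
    "compile_classifier",
    "closed_form_output",
    "closed_form_signal",
    "build_annihilator",
    "build_weight_unit_network",
    "evaluate_in_silico",
    "INDETERMINATE",
]

INDETERMINATE = "indeterminate"

# Annihilation must out-compete reporting so strands destined for mutual
# cancellation are consumed, not reported: the collapse step runs ~5000x
# faster than reporter displacement (long annihilator toehold, short
# reporter toehold).  Near-tie inputs then leave both channels dark instead
# of leaking the transiently unpaired majority into its fluorophore.
DEFAULT_ANNIHILATOR_K_ON = 1e-2  # nM^-1 s^-1
DEFAULT_ANNIHILATOR_K_OFF = 1e-2  # s^-1
DEFAULT_ANNIHILATOR_K_COLLAPSE = 5e-2  # nM^-1 s^-1
DEFAULT_REPORTER_K = 1e-5  # nM^-1 s^-1


class LinearRegimeWarning(UserWarning):
    """An input may exceed its inhibitor: Eq-3 weighting leaves its linear regime."""


def _check_one_decimal(w: float) -> None:
    if abs(w * 10 - round(w * 10)) > 1e-9:
        raise ValidationError(
            f"weights are stored at one-decimal resolution; got {w!r}"
        )


@dataclass(frozen=True)
class InputScale:
    """Affine map from raw feature values to the classifier input range (nM).

    Stored with the classifier so the in-silico score (computed on mapped
    values) and the molecular margin are on the same nM scale.
    """

    x_min: float
    x_max: float
    u_min: float = 1.0
    u_max: float = 6.0

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValidationError("require x_max > x_min")
        if not self.u_max > self.u_min > 0:
            raise ValidationError("require u_max > u_min > 0")

    @property
    def slope(self) -> float:
        return (self.u_max - self.u_min) / (self.x_max - self.x_min)

    @property
    def intercept(self) -> float:
        return self.u_min - self.slope * self.x_min

    def to_nM(self, x):
        return self.slope * np.asarray(x, float) + self.intercept

    def to_raw(self, u):
        return (np.asarray(u, float) - self.intercept) / self.slope


@dataclass(frozen=True)
class LinearClassifierSpec:
    """Feature names, signed one-decimal weights (nM-space), bias and labels."""

    features: tuple[str, ...]
    weights: tuple[float, ...]
    bias: float
    positive_class: str = "HCC"
    negative_class: str = "healthy"
    input_scale: InputScale | None = None
    amplifier0: float = 100.0
    rate_constant: float = crn.DEFAULT_BIMOLECULAR_K
    converters: dict = field(default_factory=dict)  # feature -> ConverterSpec kwargs
    calibration_table: dict = field(default_factory=dict)  # |weight| -> inhibitor0 nM

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(self.features) != len(self.weights):
            raise ValidationError("features and weights must align")
        if len(set(self.features)) != len(self.features):
            raise ValidationError("feature names must be unique")
        for w in self.weights:
            _check_one_decimal(w)
            if w == 0:
                raise ValidationError("zero-weight features must be dropped upstream")

    @property
    def weight_map(self) -> dict[str, float]:
        return dict(zip(self.features, self.weights))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "format_version": 1,
            "features": list(self.features),
            "weights": list(self.weights),
            "bias": self.bias,
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
            "amplifier0": self.amplifier0,
            "rate_constant": self.rate_constant,
            "converters": {k: dict(v) for k, v in self.converters.items()},
            "calibration_table": dict(self.calibration_table),
        }
        if self.input_scale is not None:
            s = self.input_scale
            d["input_scale"] = {
                "x_min": s.x_min, "x_max": s.x_max,
                "u_min": s.u_min, "u_max": s.u_max,
            }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "LinearClassifierSpec":
        scale = None
        if d.get("input_scale"):
            scale = InputScale(**d["input_scale"])
        return cls(
            features=tuple(d["features"]),
            weights=tuple(d["weights"]),
            bias=float(d["bias"]),
            positive_class=d.get("positive_class", "HCC"),
            negative_class=d.get("negative_class", "healthy"),
            input_scale=scale,
            amplifier0=float(d.get("amplifier0", 100.0)),
            rate_constant=float(d.get("rate_constant", crn.DEFAULT_BIMOLECULAR_K)),
            converters={k: dict(v) for k, v in d.get("converters", {}).items()},
            calibration_table={
                float(k): float(v) for k, v in d.get("calibration_table", {}).items()
            },
        )

    @classmethod
    def from_json(cls, source) -> "LinearClassifierSpec":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))

    def with_input_scale(self, scale: InputScale) -> "LinearClassifierSpec":
        return replace(self, input_scale=scale)


@dataclass(frozen=True)
class WeightUnit:
    """One feature's amplifier/inhibitor pair: |W| = amplifier0/inhibitor0."""

    feature: str
    amplifier0: float
    inhibitor0: float
    sign: int
    output_species: str
    rate_constant: float

    @property
    def weight(self) -> float:
        return self.sign * self.amplifier0 / self.inhibitor0


@dataclass(frozen=True)
class AnnihilatorSpec:
    annihilator0: float
    k_on: float = DEFAULT_ANNIHILATOR_K_ON
    k_off: float = DEFAULT_ANNIHILATOR_K_OFF
    k_collapse: float = DEFAULT_ANNIHILATOR_K_COLLAPSE


@dataclass(frozen=True)
class ReporterSpec:
    channel: str  # "HEX" | "ROX"
    reporter0: float
    rate_constant: float = DEFAULT_REPORTER_K
    standard_curve: tuple[float, float] = (200.0, 50.0)  # (slope a.u./nM, intercept)

    def __post_init__(self) -> None:
        if self.channel not in ("HEX", "ROX"):
            raise ValidationError("channel must be HEX or ROX")
        if not self.standard_curve[0] > 0:
            raise ValidationError("standard-curve slope must be positive")


# ---------------------------------------------------------------------------
# closed forms (used as oracles for the compiled chemistry)
# ---------------------------------------------------------------------------


def closed_form_output(input0: float, amplifier0: float, inhibitor0: float) -> float:
    """Ideal endpoint of one weight unit: Input0 · Amplifier0 / Inhibitor0.

    Valid in the linear regime Input0 <= Inhibitor0; beyond it the inhibitor
    is exhausted and the catalytic amplifier saturates toward Amplifier0.
    """
    if input0 < 0 or amplifier0 <= 0 or inhibitor0 <= 0:
        raise ValidationError("concentrations must be non-negative (amp/inh positive)")
    if input0 > inhibitor0:
        raise ValidationError(
            f"input ({input0} nM) exceeds inhibitor ({inhibitor0} nM): "
            "closed form invalid outside the linear regime"
        )
    return input0 * amplifier0 / inhibitor0


def closed_form_signal(weights, inputs) -> tuple[float, float]:
    """Pre-annihilation channel totals (positive_sum, negative_sum) in nM."""
    weights = np.asarray(weights, float)
    inputs = np.asarray(inputs, float)
    if weights.shape != inputs.shape:
        raise ValidationError("weights and inputs must align")
    contrib = weights * inputs
    pos = float(contrib[contrib > 0].sum())
    neg = float(-contrib[contrib < 0].sum())
    return pos, neg


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def build_weight_unit_network(
    weight: float,
    input0: float,
    amplifier0: float = 100.0,
    k: float = crn.DEFAULT_BIMOLECULAR_K,
    output_id: str = "output",
) -> ReactionNetwork:
    """Standalone competitive-inhibition unit for a single unsigned weight."""
    if weight <= 0:
        raise ValidationError("standalone unit takes |W| > 0")
    inhibitor0 = amplifier0 / weight
    species = [
        Species("input", "input"),
        Species("amplifier", "amplifier"),
        Species("inhibitor", "inhibitor"),
        Species(output_id, "output_pos"),
        Species("waste", "waste"),
    ]
    reactions = [
        Reaction(("input", "amplifier"), ("input", output_id), k),
        Reaction(("input", "inhibitor"), ("waste",), k),
    ]
    laws = [
        ConservationLaw(
            {"amplifier": 1.0, output_id: 1.0}, amplifier0, "amplifier+output"
        ),
        ConservationLaw(
            {"inhibitor": 1.0, "input": -1.0},
            inhibitor0 - input0,
            "inhibitor-input (1:1 consumption)",
        ),
    ]
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        initial={"input": input0, "amplifier": amplifier0, "inhibitor": inhibitor0},
        conservation_laws=laws,
    )


def build_annihilator(
    spec: AnnihilatorSpec,
    pos_id: str = "out_pos",
    neg_id: str = "out_neg",
) -> list[Reaction]:
    """Two-step cooperative-hybridization annihilation.

    OutNeg + Annihilator <-> Intermediate;  Intermediate + OutPos -> 2 Waste.
    Consumes the two output strands at a stoichiometric 1:1 ratio.
    """
    return [
        Reaction((neg_id, "annihilator"), ("ann_intermediate",), spec.k_on),
        Reaction(("ann_intermediate",), (neg_id, "annihilator"), spec.k_off),
        Reaction(("ann_intermediate", pos_id), ("waste", "waste"), spec.k_collapse),
    ]


@dataclass
class CompiledClassifier:
    """A classifier spec lowered onto a reaction network."""

    spec: LinearClassifierSpec
    network: ReactionNetwork
    weight_units: list[WeightUnit]
    annihilator: AnnihilatorSpec
    reporters: dict[str, ReporterSpec]
    input_max: float
    bias_input0: float

    @property
    def capacity(self) -> float:
        """Total input capacity: Σ|W_i|·input_max + |bias| (nM)."""
        return (
            sum(abs(w) for w in self.spec.weights) * self.input_max + self.bias_input0
        )

    def delta(self, fraction: float = 0.05) -> float:
        """Indeterminate-call margin: ``fraction`` of the input capacity."""
        return fraction * self.capacity

    def with_inputs(self, values: dict[str, float]) -> ReactionNetwork:
        """Network copy with per-feature input concentrations (nM) set."""
        missing = set(self.spec.features) - set(values)
        if missing:
            raise ValidationError(f"missing input values for {sorted(missing)}")
        initial = dict(self.network.initial)
        for unit in self.weight_units:
            if unit.feature == "bias":  # preset to |bias| nM at compile time
                continue
            value = float(values[unit.feature])
            if value < 0:
                raise ValidationError(f"negative input for {unit.feature!r}")
            if value > 0.8 * unit.inhibitor0:
                warnings.warn(
                    f"input for {unit.feature!r} ({value:.3g} nM) approaches its "
                    f"inhibitor ({unit.inhibitor0:.3g} nM); weighting leaves the "
                    "linear regime",
                    LinearRegimeWarning,
                    stacklevel=2,
                )
            initial[f"in_{unit.feature}"] = value
        net = ReactionNetwork(
            species=self.network.species,
            reactions=self.network.reactions,
            initial=initial,
            conservation_laws=self.network.conservation_laws,
        )
        return net

    def simulate(self, values: dict[str, float], t_end: float = 2e5, **kwargs):
        return crn.simulate(self.with_inputs(values), t_end, **kwargs)


def compile_classifier(
    spec: LinearClassifierSpec,
    amplifier0_default: float | None = None,
    k: float | None = None,
    input_max: float | None = None,
    annihilator: AnnihilatorSpec | None = None,
    reporters: dict[str, ReporterSpec] | None = None,
) -> CompiledClassifier:
    """Lower a linear classifier onto a full reaction network.

    Ideal mapping per feature: inhibitor0 = amplifier0 / |W_i| (a
    user-supplied calibration table |W| -> inhibitor0 overrides it, never
    defaulted).  The sign of W_i routes the unit's output onto the shared
    positive or negative output strand; the bias becomes an auxiliary
    weight-1 unit fed |bias| nM on the sign(bias) side.  An annihilator in
    2x excess of the larger channel capacity and one reporter per channel
    complete the network.
    """
    amplifier0 = spec.amplifier0 if amplifier0_default is None else amplifier0_default
    if amplifier0 <= 0:
        raise ValidationError("amplifier0 must be positive")
    k = spec.rate_constant if k is None else k
    if input_max is None:
        input_max = spec.input_scale.u_max if spec.input_scale else 6.0

    species = [
        Species("out_pos", "output_pos"),
        Species("out_neg", "output_neg"),
        Species("waste", "waste"),
    ]
    reactions: list[Reaction] = []
    units: list[WeightUnit] = []

    def add_unit(feature: str, weight: float, input0: float = 0.0) -> None:
        sign = 1 if weight > 0 else -1
        mag = abs(weight)
        inhibitor0 = spec.calibration_table.get(mag, amplifier0 / mag)
        out = "out_pos" if sign > 0 else "out_neg"
        if inhibitor0 <= input_max:
            warnings.warn(
                f"inhibitor for {feature!r} ({inhibitor0:.3g} nM) is below the "
                f"expected input range (<= {input_max:.3g} nM): linear-regime "
                "guard violated",
                LinearRegimeWarning,
                stacklevel=3,
            )
        species.extend(
            [
                Species(f"in_{feature}", "input"),
                Species(f"amp_{feature}", "amplifier"),
                Species(f"inh_{feature}", "inhibitor"),
            ]
        )
        reactions.append(
            Reaction((f"in_{feature}", f"amp_{feature}"), (f"in_{feature}", out), k)
        )
        reactions.append(Reaction((f"in_{feature}", f"inh_{feature}"), ("waste",), k))
        initial[f"in_{feature}"] = input0
        initial[f"amp_{feature}"] = amplifier0
        initial[f"inh_{feature}"] = inhibitor0
        units.append(WeightUnit(feature, amplifier0, inhibitor0, sign, out, k))

    initial: dict[str, float] = {}
    for feature, weight in zip(spec.features, spec.weights):
        if weight == 0:
            warnings.warn(f"zero-weight feature {feature!r} rejected", UserWarning)
            continue
        add_unit(feature, weight)

    bias_input0 = abs(spec.bias)
    if bias_input0 > 0:
        add_unit("bias", 1.0 if spec.bias > 0 else -1.0, input0=bias_input0)

    cap_pos = sum(u.amplifier0 / u.inhibitor0 * input_max for u in units if u.sign > 0)
    cap_neg = sum(u.amplifier0 / u.inhibitor0 * input_max for u in units if u.sign < 0)
    if bias_input0 > 0:  # bias unit holds a fixed input, not input_max
        if spec.bias > 0:
            cap_pos += bias_input0 - input_max
        else:
            cap_neg += bias_input0 - input_max

    if annihilator is None:
        annihilator = AnnihilatorSpec(annihilator0=2.0 * max(cap_pos, cap_neg, 1.0))
    if reporters is None:
        reporters = {
            "HEX": ReporterSpec("HEX", reporter0=1.5 * max(cap_pos, 1.0)),
            "ROX": ReporterSpec("ROX", reporter0=1.5 * max(cap_neg, 1.0)),
        }

    species.extend(
        [
            Species("annihilator", "annihilator"),
            Species("ann_intermediate", "other"),
            Species("rep_hex", "reporter"),
            Species("rep_rox", "reporter"),
            Species("fluor_hex", "fluorophore"),
            Species("fluor_rox", "fluorophore"),
        ]
    )
    reactions.extend(build_annihilator(annihilator))
    hx, rx = reporters["HEX"], reporters["ROX"]
    reactions.append(
        Reaction(("out_pos", "rep_hex"), ("fluor_hex", "waste"), hx.rate_constant)
    )
    reactions.append(
        Reaction(("out_neg", "rep_rox"), ("fluor_rox", "waste"), rx.rate_constant)
    )
    initial.update(
        {
            "annihilator": annihilator.annihilator0,
            "rep_hex": hx.reporter0,
            "rep_rox": rx.reporter0,
        }
    )

    network = ReactionNetwork(species=species, reactions=reactions, initial=initial)
    return CompiledClassifier(
        spec=spec,
        network=network,
        weight_units=units,
        annihilator=annihilator,
        reporters=reporters,
        input_max=input_max,
        bias_input0=bias_input0,
    )


# ---------------------------------------------------------------------------
# in-silico evaluation
# ---------------------------------------------------------------------------


def evaluate_in_silico(
    spec: LinearClassifierSpec,
    feature_values: dict[str, float],
    *,
    space: str = "input",
) -> float:
    """Score = Σ W_i·u_i + bias on the classifier's input (nM) scale.

    ``space="raw"`` maps values through the stored affine input scale first.
    """
    missing = set(spec.features) - set(feature_values)
    if missing:
        raise ValidationError(f"missing feature values for {sorted(missing)}")
    if space not in ("input", "raw"):
        raise ValidationError("space must be 'input' or 'raw'")
    values = np.array([feature_values[f] for f in spec.features], float)
    if space == "raw":
        if spec.input_scale is None:
            raise ValidationError("classifier stores no input scale for raw values")
        values = spec.input_scale.to_nM(values)
    return float(np.dot(spec.weights, values) + spec.bias)


def predict_in_silico(spec: LinearClassifierSpec, feature_values, **kwargs) -> str:
    """Class label from the score sign; exactly zero is 'indeterminate'."""
    score = evaluate_in_silico(spec, feature_values, **kwargs)
    if score > 0:
        return spec.positive_class
    if score < 0:
        return spec.negative_class
    return INDETERMINATE
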