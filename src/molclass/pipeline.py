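"""End-to-end orchestration: sample -> PCR -> conversion -> classifier CRN -> call.

One synthetic patient is processed exactly as a bench sample would be: each
panel miRNA concentration runs through the asymmetric-PCR recurrence, the
resulting ssDNA through the strand-displacement converter, the recovered
input concentrations (calibrated against a simulated dilution standard, the
in-silico analogue of the reporter standard curve) are loaded into the
compiled classifier network, and the mass-action ODEs are integrated to the
dual-channel fluorophore endpoints.  The HEX−ROX margin against the
indeterminate threshold δ yields the diagnostic call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np

from . import crn, pcr, transform
from .compiler import (
    INDETERMINATE,
    CompiledClassifier,
    LinearClassifierSpec,
    compile_classifier,
    evaluate_in_silico,
)
from .crn import ValidationError
from .pcr import PCRConfig
from .synth import StandardCurve, generate_standard_curve
from .transform import ConverterSpec

__all__ = [
    "ClassificationResult",
    "ConfusionSummary",
    "TransformationCalibration",
    "calibrate_transformation",
    "run_sample",
    "run_cohort",
    "normalize_fluorescence",
    "confusion_stats",
]

log = logging.getLogger("molclass.pipeline")

DELTA_FRACTION = 0.05  # indeterminate margin as a fraction of input capacity


@dataclass
class ClassificationResult:
    sample_id: str
    raw_hex_nM: float
    raw_rox_nM: float
    hex_au: float
    rox_au: float
    normalized_hex_nM: float
    normalized_rox_nM: float
    margin_nM: float  # HEX − ROX after normalization
    call: str
    delta_nM: float
    insilico_score: float | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = (
            INDETERMINATE
            if abs(self.margin_nM) < self.delta_nM
            else None
        )
        if expected == INDETERMINATE and self.call != INDETERMINATE:
            raise ValidationError("call inconsistent with margin and delta")


@dataclass(frozen=True)
class ConfusionSummary:
    """Exact-rational confusion statistics for a binary diagnostic panel."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> Fraction:
        return Fraction(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Fraction:
        return Fraction(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> Fraction:
        return Fraction(self.tp + self.tn, self.total)

    @staticmethod
    def _pct(x: Fraction) -> float:
        """Percentage with one decimal, round half up (85.7%-style)."""
        pct = Decimal(x.numerator) * 100 / Decimal(x.denominator)
        return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    @property
    def sensitivity_pct(self) -> float:
        return self._pct(self.sensitivity)

    @property
    def specificity_pct(self) -> float:
        return self._pct(self.specificity)

    @property
    def accuracy_pct(self) -> float:
        return self._pct(self.accuracy)

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "TP": self.tp,
            "FN": self.fn,
            "TN": self.tn,
            "FP": self.fp,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
        }


# ---------------------------------------------------------------------------
# transformation calibration (dilution standard for the PCR+converter chain)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransformationCalibration:
    """OLS line v = slope·log2(conc_pM) + intercept for the front-end chain."""

    slope: float
    intercept: float

    def to_log2_pM(self, v):
        return (np.asarray(v, float) - self.intercept) / self.slope


def calibrate_transformation(
    pcr_config: PCRConfig,
    converter: ConverterSpec,
    conc_range_pM: tuple[float, float] = (0.1, 10.0),
    n_points: int = 7,
) -> TransformationCalibration:
    """Fit the front-end response on a simulated dilution standard.

    Mirrors the bench practice of normalizing against a standard curve: the
    same PCR + conversion model is run on known concentrations and the
    resulting line is used to read unknowns back onto the log2 scale.
    """
    concs = np.geomspace(*conc_range_pM, n_points)
    v = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # plateau warnings expected at range edge
        for c in concs:
            trace = pcr.simulate_pcr(pcr_config, float(c))
            v.append(transform.convert(converter, pcr.ssdna_at_readout(trace)))
    slope, intercept, r2 = pcr.fit_loglinear(concs, v)
    if slope <= 0:
        raise ValidationError("transformation calibration has non-positive slope")
    log.debug("transformation calibration: slope=%.3f intercept=%.3f R2=%.5f",
              slope, intercept, r2)
    return TransformationCalibration(slope, intercept)


# ---------------------------------------------------------------------------
# per-sample pipeline
# ---------------------------------------------------------------------------


def normalize_fluorescence(raw_au: float, standard_curve) -> float:
    """(raw − intercept)/slope, clipped at 0 nM.

    ``standard_curve`` may be a StandardCurve or a (slope, intercept) pair.
    """
    if isinstance(standard_curve, StandardCurve):
        slope, intercept = standard_curve.slope, standard_curve.intercept
    else:
        slope, intercept = standard_curve
    if not slope > 0:
        raise ValidationError("standard-curve slope must be positive")
    return max(0.0, (raw_au - intercept) / slope)


def _default_curves(seed: int) -> dict[str, StandardCurve]:
    rng = np.random.default_rng(seed)
    return {
        "HEX": generate_standard_curve("HEX", int(rng.integers(0, 2**31 - 1))),
        "ROX": generate_standard_curve("ROX", int(rng.integers(0, 2**31 - 1))),
    }


def run_sample(
    panel: dict[str, float],
    spec: LinearClassifierSpec,
    *,
    pcr_config: PCRConfig | None = None,
    converter: ConverterSpec | None = None,
    compiled: CompiledClassifier | None = None,
    calibration: TransformationCalibration | None = None,
    standard_curves: dict[str, StandardCurve] | None = None,
    seed: int = 0,
    sample_id: str = "sample",
    t_end: float = 2e5,
    delta_fraction: float = DELTA_FRACTION,
) -> ClassificationResult:
    """Classify one concentration panel (pM per classifier feature).

    The stages compose deterministically: PCR recurrence per feature →
    converter CRN → calibrated log2 recovery → affine input scale →
    compiled classifier CRN → reporter standard curves → margin call.
    Reusable stage objects (compiled network, calibration, curves) may be
    passed in to amortize across a cohort.
    """
    missing = set(spec.features) - set(panel)
    if missing:
        raise ValidationError(f"panel lacks classifier features {sorted(missing)}")
    if spec.input_scale is None:
        raise ValidationError("classifier spec lacks an input scale")
    if pcr_config is None:
        pcr_config = PCRConfig()
    if converter is None:
        converter = ConverterSpec("ssdna", "input")
    if compiled is None:
        compiled = compile_classifier(spec)
    if calibration is None:
        calibration = calibrate_transformation(
            pcr_config,
            converter,
            conc_range_pM=(2.0**spec.input_scale.x_min, 2.0**spec.input_scale.x_max),
        )
    if standard_curves is None:
        standard_curves = _default_curves(seed)

    notes: list[str] = []
    inputs_nM: dict[str, float] = {}
    for feature in spec.features:
        conc = float(panel[feature])
        stage = f"pcr[{feature}]"
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                trace = pcr.simulate_pcr(pcr_config, conc)
                ss = pcr.ssdna_at_readout(trace)
            for w in caught:
                notes.append(f"{stage}: {w.message}")
            stage = f"convert[{feature}]"
            v = transform.convert(converter, ss)
        except Exception as exc:
            raise type(exc)(f"stage {stage}: {exc}") from exc
        z_hat = float(calibration.to_log2_pM(v))
        inputs_nM[feature] = float(spec.input_scale.to_nM(z_hat))
    log.debug("%s: recovered inputs %s", sample_id, inputs_nM)

    try:
        trace = compiled.simulate(inputs_nM, t_end=t_end)
    except crn.IntegrationFailure as exc:
        raise crn.IntegrationFailure(f"stage classifier-crn: {exc}") from exc
    raw_hex = trace.endpoint["fluor_hex"]
    raw_rox = trace.endpoint["fluor_rox"]

    hex_au = float(standard_curves["HEX"].to_au(raw_hex))
    rox_au = float(standard_curves["ROX"].to_au(raw_rox))
    norm_hex = normalize_fluorescence(hex_au, standard_curves["HEX"])
    norm_rox = normalize_fluorescence(rox_au, standard_curves["ROX"])

    margin = norm_hex - norm_rox
    delta = compiled.delta(delta_fraction)
    if margin >= delta:
        call = spec.positive_class
    elif margin <= -delta:
        call = spec.negative_class
    else:
        call = INDETERMINATE

    score = evaluate_in_silico(
        spec, {f: float(spec.input_scale.to_nM(np.log2(panel[f]))) for f in spec.features}
    )
    return ClassificationResult(
        sample_id=sample_id,
        raw_hex_nM=raw_hex,
        raw_rox_nM=raw_rox,
        hex_au=hex_au,
        rox_au=rox_au,
        normalized_hex_nM=norm_hex,
        normalized_rox_nM=norm_rox,
        margin_nM=margin,
        call=call,
        delta_nM=delta,
        insilico_score=score,
        warnings=tuple(notes),
    )


def run_cohort(
    panels,
    spec: LinearClassifierSpec,
    *,
    seed: int = 0,
    **kwargs,
) -> list[ClassificationResult]:
    """Run :func:`run_sample` over a cohort with shared stage objects."""
    pcr_config = kwargs.pop("pcr_config", None) or PCRConfig()
    converter = kwargs.pop("converter", None) or ConverterSpec("ssdna", "input")
    compiled = kwargs.pop("compiled", None) or compile_classifier(spec)
    calibration = kwargs.pop("calibration", None) or calibrate_transformation(
        pcr_config,
        converter,
        conc_range_pM=(2.0**spec.input_scale.x_min, 2.0**spec.input_scale.x_max),
    )
    curves = kwargs.pop("standard_curves", None) or _default_curves(seed)
    results = []
    for p in panels:
        panel_dict = p.concentrations if hasattr(p, "concentrations") else dict(p)
        sid = getattr(p, "sample_id", f"sample_{len(results):03d}")
        results.append(
            run_sample(
                panel_dict,
                spec,
                pcr_config=pcr_config,
                converter=converter,
                compiled=compiled,
                calibration=calibration,
                standard_curves=curves,
                seed=seed,
                sample_id=sid,
                **kwargs,
            )
        )
        log.info("%s: call=%s margin=%.2f nM", sid, results[-1].call,
                 results[-1].margin_nM)
    return results


def confusion_stats(calls, true_labels, positive_class: str, negative_class: str) -> ConfusionSummary:
    """Counts and exact-rational sensitivity/specificity/accuracy.

    Indeterminate calls count as misclassifications (conservative: the
    clinical table this emulates has no indeterminate category).
    """
    calls = list(calls)
    true_labels = list(true_labels)
    if len(calls) != len(true_labels):
        raise ValidationError("calls and labels differ in length")
    bad = set(true_labels) - {positive_class, negative_class}
    if bad:
        raise ValidationError(f"non-binary true labels {sorted(bad)}")
    tp = fn = tn = fp = 0
    for call, truth in zip(calls, true_labels):
        if truth == positive_class:
            tp += call == positive_class
            fn += call != positive_class
        else:
            tn += call == negative_class
            fp += call != negative_class
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)
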