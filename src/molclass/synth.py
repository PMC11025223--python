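"""Synthetic data: expression matrices, patient panels, standard curves.

The expression generator emulates the structure of a serum-miRNA case/
control cohort (345 cancer vs 958 healthy samples, a few hundred features,
a handful of informative miRNAs whose between-class difference exceeds the
fourfold screen, log-normal within-class variation — i.e. Gaussian on the
log2 scale).  Ground truth (which features are informative and their true
effects) is returned alongside every matrix so recovery can be scored.

Patient panels emulate the study's validation cohort: per-feature plasma
concentrations inside the PCR model's linear range (0.1–10 pM), drawn so
the in-silico score is confidently class-consistent (the study replicated
in vitro only patients its classifier called correctly); a borderline mode
produces near-tie panels for indeterminate-call testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compiler import LinearClassifierSpec, evaluate_in_silico
from .crn import ValidationError
from .training import ExpressionMatrix

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PatientPanel",
    "StandardCurve",
    "generate_expression",
    "generate_patient_panel",
    "generate_cohort",
    "generate_standard_curve",
]

#: Default planted effects (log2 units): all comfortably beyond the fourfold
#: screen (so threshold-edge sampling noise cannot drop a planted feature),
#: 4–8-fold magnitudes, mixed directions like a real up/down signature.
DEFAULT_EFFECTS = (2.3, 2.6, -2.4, -2.8, -3.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shape parameters for the synthetic cohort.

    Sample counts default to the emulated cohort (345 positive / 958
    negative); ``informative_effects`` are log2 between-class differences
    (|effect| >= 2 to qualify as informative under the fourfold screen);
    ``noise_sigma`` is the within-class log2 SD; baselines are drawn
    uniformly over ``baseline_range`` (log2 abundance).
    """

    seed: int
    n_positive: int = 345
    n_negative: int = 958
    n_features: int = 250
    informative_effects: tuple[float, ...] = DEFAULT_EFFECTS
    noise_sigma: float = 1.2
    baseline_range: tuple[float, float] = (4.0, 12.0)
    concentration_range_pM: tuple[float, float] = (0.1, 10.0)
    positive_class: str = "HCC"
    negative_class: str = "healthy"

    def __post_init__(self) -> None:
        for e in self.informative_effects:
            if abs(e) < 2.0:
                raise ValidationError(
                    "informative effects must satisfy |log2 effect| >= 2 "
                    "(the fourfold screen)"
                )
        if self.n_features < len(self.informative_effects):
            raise ValidationError("more informative features than features")
        if self.noise_sigma <= 0:
            raise ValidationError("noise sigma must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Which features were planted informative, and with what effect."""

    effects: dict[str, float]  # feature -> log2 effect (positive = up in cases)

    @property
    def features(self) -> list[str]:
        return list(self.effects)


def _feature_names(n: int) -> list[str]:
    return [f"miR-{i:03d}" for i in range(1, n + 1)]


def generate_expression(
    config: GeneratorConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Two-class log2 expression matrix with planted fold changes."""
    rng = np.random.default_rng(config.seed)
    names = _feature_names(config.n_features)
    baselines = rng.uniform(*config.baseline_range, size=config.n_features)
    informative_idx = rng.choice(
        config.n_features, size=len(config.informative_effects), replace=False
    )
    effects = np.zeros(config.n_features)
    effects[informative_idx] = config.informative_effects

    n_pos, n_neg = config.n_positive, config.n_negative
    mean_pos = baselines + effects / 2.0
    mean_neg = baselines - effects / 2.0
    X_pos = mean_pos + rng.normal(0.0, config.noise_sigma, (n_pos, config.n_features))
    X_neg = mean_neg + rng.normal(0.0, config.noise_sigma, (n_neg, config.n_features))

    samples = [f"case_{i:04d}" for i in range(n_pos)] + [
        f"ctrl_{i:04d}" for i in range(n_neg)
    ]
    values = pd.DataFrame(np.vstack([X_pos, X_neg]), index=samples, columns=names)
    labels = pd.Series(
        [config.positive_class] * n_pos + [config.negative_class] * n_neg,
        index=samples,
        name="label",
    )
    truth = GroundTruth(
        {names[i]: float(effects[i]) for i in sorted(informative_idx)}
    )
    matrix = ExpressionMatrix(
        values, labels, config.positive_class, config.negative_class
    )
    return matrix, truth


@dataclass
class PatientPanel:
    """Per-feature plasma miRNA concentrations (pM) for one synthetic patient."""

    sample_id: str
    true_class: str
    concentrations: dict[str, float]
    insilico_score: float
    borderline: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mirna_id": list(self.concentrations), "concentration_pM": list(self.concentrations.values())}
        )


def _score_scale(spec: LinearClassifierSpec) -> float:
    """Half-range of achievable scores over the input box (nM)."""
    scale = spec.input_scale
    u_min, u_max = (scale.u_min, scale.u_max) if scale else (1.0, 6.0)
    return sum(abs(w) for w in spec.weights) * (u_max - u_min) / 2.0


def generate_patient_panel(
    spec: LinearClassifierSpec,
    true_class: str,
    seed: int,
    *,
    margin_fraction: float = 0.3,
    borderline: bool = False,
    sample_id: str = "sample",
    max_tries: int = 200,
) -> PatientPanel:
    """Draw one class-consistent concentration panel.

    Non-borderline panels are resampled until the in-silico score is on the
    correct side with |score| >= ``margin_fraction`` × the classifier's score
    scale; borderline panels target |score| below 20% of that margin and are
    flagged for indeterminate-call testing.
    """
    if spec.input_scale is None:
        raise ValidationError("classifier needs an input scale over log2 pM")
    if true_class not in (spec.positive_class, spec.negative_class):
        raise ValidationError(f"unknown class {true_class!r}")
    rng = np.random.default_rng(seed)
    scale = spec.input_scale
    z_lo, z_hi = scale.x_min, scale.x_max
    z_mid = 0.5 * (z_lo + z_hi)
    class_sign = 1.0 if true_class == spec.positive_class else -1.0
    target = margin_fraction * _score_scale(spec)

    best = None
    for _ in range(max_tries):
        z = np.empty(len(spec.features))
        for i, w in enumerate(spec.weights):
            shift = class_sign * np.sign(w) * rng.uniform(0.8, 2.2)
            z[i] = np.clip(z_mid + shift + rng.normal(0.0, 0.35), z_lo, z_hi)
        values = dict(zip(spec.features, scale.to_nM(z)))
        score = evaluate_in_silico(spec, values)
        if borderline:
            if abs(score) <= 0.2 * target:
                best = (z, score)
                break
            if best is None or abs(score) < abs(best[1]):
                best = (z, score)
        else:
            if class_sign * score >= target:
                best = (z, score)
                break
            if best is None or class_sign * score > class_sign * best[1]:
                best = (z, score)
    z, score = best
    concentrations = {
        f: float(2.0**zi) for f, zi in zip(spec.features, z)
    }  # z is log2 concentration in pM
    return PatientPanel(sample_id, true_class, concentrations, score, borderline)


def generate_cohort(
    spec: LinearClassifierSpec,
    seed: int,
    n_per_class: int = 10,
    **panel_kwargs,
) -> list[PatientPanel]:
    """A balanced synthetic cohort (default 10 + 10) of class-consistent panels."""
    rng = np.random.default_rng(seed)
    panels = []
    for cls, tag in ((spec.positive_class, "pos"), (spec.negative_class, "neg")):
        for i in range(n_per_class):
            panels.append(
                generate_patient_panel(
                    spec,
                    cls,
                    int(rng.integers(0, 2**31 - 1)),
                    sample_id=f"{tag}_{i:02d}",
                    **panel_kwargs,
                )
            )
    return panels


def cohort_to_frame(panels: list[PatientPanel]) -> pd.DataFrame:
    """Wide CSV layout: sample_id, label, one column per miRNA (pM)."""
    rows = []
    for p in panels:
        row = {"sample_id": p.sample_id, "label": p.true_class}
        row.update(p.concentrations)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class StandardCurve:
    """Linear fluorescence standard curve: a.u. = slope·nM + intercept."""

    channel: str
    slope: float
    intercept: float
    points: tuple = ()  # ((conc_nM, fluorescence_au), ...)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValidationError("standard-curve slope must be positive")

    def to_au(self, conc_nM):
        return self.slope * np.asarray(conc_nM, float) + self.intercept

    def to_nM(self, au):
        return np.clip((np.asarray(au, float) - self.intercept) / self.slope, 0.0, None)


def generate_standard_curve(
    channel: str,
    seed: int,
    noise_fraction: float = 0.0,
    n_points: int = 6,
    conc_max_nM: float = 50.0,
) -> StandardCurve:
    """Reporter calibration: noisy points around a seeded linear a.u./nM map."""
    rng = np.random.default_rng(seed)
    slope = float(rng.uniform(150.0, 250.0))
    intercept = float(rng.uniform(20.0, 60.0))
    concs = np.linspace(0.0, conc_max_nM, n_points)
    au = slope * concs + intercept
    if noise_fraction > 0:
        au = au + rng.normal(0.0, noise_fraction * au.max(), size=au.shape)
    return StandardCurve(
        channel=channel,
        slope=slope,
        intercept=intercept,
        points=tuple((float(c), float(a)) for c, a in zip(concs, au)),
    )
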