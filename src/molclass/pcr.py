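"""Cycle-by-cycle model of reverse transcription + asymmetric PCR.

Asymmetric PCR uses unequal primer amounts: a low-concentration universal
("limiting") primer and a high-concentration specific ("excess") primer.
The reaction first amplifies exponentially, building double-stranded
amplicons until the limiting primer is exhausted; thereafter every cycle
extends only the excess primer on the accumulated templates, so
single-stranded DNA grows linearly per cycle.  Because the number of
exponential cycles needed to exhaust the limiting primer is ~log2 of the
initial template amount, the ssDNA present at a fixed readout cycle is
approximately linear in log2 of the initial miRNA concentration — the
transform the downstream classifier relies on.

The model is a discrete per-cycle recurrence over concentrations
(fractional strand amounts are allowed).  The reverse-transcription product
is single-stranded cDNA, so the first thermal cycle can only synthesize the
complementary strand (consuming an excess primer); exponential duplication
with both primers starts at cycle 2.  Templates already double-stranded
(``initial_template="dsdna"``) duplicate from cycle 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crn import ValidationError

__all__ = ["PCRConfig", "PCRTrace", "simulate_pcr", "ssdna_at_readout", "fit_loglinear"]

PM_TO_NM = 1e-3


@dataclass(frozen=True)
class PCRConfig:
    """Primer amounts (nM), per-cycle efficiency and readout cycle.

    Defaults follow the bench protocol this model abstracts: 25 nM limiting
    (universal) primer, 1 µM excess (specific) primer, readout at cycle 52,
    ideal per-cycle efficiency E=1 and unit RT yield.
    """

    efficiency: float = 1.0
    limiting_primer: float = 25.0
    excess_primer: float = 1000.0
    n_cycles: int = 52
    readout_cycle: int = 52
    rt_yield: float = 1.0
    initial_template: str = "cdna"  # "cdna" | "dsdna"
    fluorescence_gain: float = 1.0  # a.u. per nM ssDNA (Taqman readout)

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1:
            raise ValidationError("efficiency must be in (0, 1]")
        if not self.excess_primer > self.limiting_primer > 0:
            raise ValidationError("require excess_primer > limiting_primer > 0")
        if not 1 <= self.readout_cycle <= self.n_cycles:
            raise ValidationError("require 1 <= readout_cycle <= n_cycles")
        if not 0 < self.rt_yield <= 1:
            raise ValidationError("rt_yield must be in (0, 1]")
        if self.initial_template not in ("cdna", "dsdna"):
            raise ValidationError("initial_template must be 'cdna' or 'dsdna'")


@dataclass
class PCRTrace:
    """Per-cycle amounts (nM); index 0 is the pre-PCR state."""

    config: PCRConfig
    cycles: np.ndarray
    ds: np.ndarray
    ss: np.ndarray
    limiting: np.ndarray
    excess: np.ndarray
    exhaustion_cycle: int | None = None
    initial_mirna_pM: float = field(default=np.nan)

    def to_tsv(self, path) -> None:
        header = "cycle\tds\tss\tlimiting_primer\texcess_primer"
        data = np.column_stack([self.cycles, self.ds, self.ss, self.limiting, self.excess])
        np.savetxt(path, data, delimiter="\t", header=header, comments="")


def simulate_pcr(config: PCRConfig, initial_mirna: float) -> PCRTrace:
    """Run the asymmetric-PCR recurrence for one miRNA species.

    Parameters
    ----------
    config : PCRConfig
    initial_mirna : float
        Initial miRNA concentration in pM (carried through RT at
        ``rt_yield`` into cDNA; concentrations, not molecule counts).
    """
    if not initial_mirna > 0:
        raise ValidationError("initial miRNA concentration must be positive")
    n0 = config.rt_yield * initial_mirna * PM_TO_NM
    if n0 > config.limiting_primer:
        raise ValidationError(
            "initial template exceeds the limiting primer; the two-phase "
            "model assumes the limiting primer bounds the exponential phase"
        )

    E = config.efficiency
    if config.initial_template == "cdna":
        cdna, ds = n0, 0.0
    else:
        cdna, ds = 0.0, n0
    lim, exc, ss = config.limiting_primer, config.excess_primer, 0.0
    templates: float | None = None
    exhaustion_cycle: int | None = None
    eps = 1e-15

    n = config.n_cycles
    ds_a = np.empty(n + 1)
    ss_a = np.empty(n + 1)
    lim_a = np.empty(n + 1)
    exc_a = np.empty(n + 1)
    ds_a[0], ss_a[0], lim_a[0], exc_a[0] = ds, ss, lim, exc

    for c in range(1, n + 1):
        if templates is not None:
            # linear phase: only excess-primer strands are synthesized
            gain = min(E * templates, exc)
            ss += gain
            exc -= gain
        else:
            ds0, cd0 = ds, cdna
            # second-strand synthesis on free cDNA (excess primer only)
            conv = min(E * cd0, exc)
            cdna -= conv
            ds += conv
            exc -= conv
            # exponential duplication: each new duplex takes one limiting
            # and one excess primer
            dup = min(E * ds0, lim, exc)
            ds += dup
            lim -= dup
            exc -= dup
            if lim <= eps:
                lim = 0.0
                exhaustion_cycle = c
                templates = ds
        ds_a[c], ss_a[c], lim_a[c], exc_a[c] = ds, ss, lim, exc

    return PCRTrace(
        config=config,
        cycles=np.arange(n + 1),
        ds=ds_a,
        ss=ss_a,
        limiting=lim_a,
        excess=exc_a,
        exhaustion_cycle=exhaustion_cycle,
        initial_mirna_pM=initial_mirna,
    )


def ssdna_at_readout(trace: PCRTrace) -> float:
    """ssDNA amount (nM) at the configured readout cycle."""
    if trace.excess[trace.config.readout_cycle] <= 1e-12:
        warnings.warn(
            "excess primer exhausted at readout: ssDNA has plateaued",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(trace.ss[trace.config.readout_cycle])


def fit_loglinear(concs, ss_values) -> tuple[float, float, float]:
    """OLS of ssDNA readout on log2(concentration): (slope, intercept, R²).

    Constant responses get the degenerate convention slope 0, R² = 0.
    """
    concs = np.asarray(concs, float)
    y = np.asarray(ss_values, float)
    if concs.shape != y.shape or concs.size < 3:
        raise ValidationError("need >= 3 matching (concentration, ssDNA) points")
    if np.any(concs <= 0):
        raise ValidationError("concentrations must be positive")
    x = np.log2(concs)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0, float(y.mean()), 0.0
    A = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return float(coef[0]), float(coef[1]), r2
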