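"""Absolute dating of Ks peaks and cross-lineage synonymous-rate correction.

Dating assumes synonymous substitutions accumulate linearly with time, so
a duplication with synonymous age Ks maps to an absolute date

    date = Ks / (2 r)

with r the lineage's synonymous substitution rate per site per year (the
factor 2 because both duplicates accumulate substitutions).  Dates are
reported in millions of years (Mya); larger Mya means earlier.

When lineages differ in synonymous rate, the Ks of a slow lineage
understates its age on the reference lineage's scale.  The correction
chain rescales a target lineage onto the reference scale through a bridge
species that shares a datable duplication peak with the reference:

    C_bridge          = Ks_ref_peak / Ks_bridge_peak
    C_b(bridge, ref)  = (C_bridge + C_ref) / 2         with C_ref = 1
    Ks'(bridge, ref)  = C_b(bridge, ref) * Ks(bridge, ref ortholog peak)
    C_b(bridge, tgt)  = Ks'(bridge, ref) / Ks(bridge, tgt ortholog peak)
    C_target          = 2 C_b(bridge, tgt) - C_bridge
    Ks'_target        = C_target * Ks_target

The reference species' own coefficient is fixed at 1: the chain aligns
every lineage onto the reference peak scale, which is only consistent if
the anchor itself is unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "RateConstant", "DatingResult", "TimeWindow", "CorrectionChain",
    "date_from_ks", "compare_to_window", "correction_coefficient",
    "correct_target_ks",
]


@dataclass(frozen=True)
class RateConstant:
    """Synonymous substitution rate in substitutions per site per year."""

    species: str
    r: float
    provenance: str = ""

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("rate must be > 0")


@dataclass(frozen=True)
class DatingResult:
    ks: float
    rate: RateConstant
    date_mya: float


@dataclass(frozen=True)
class TimeWindow:
    lower_mya: float
    upper_mya: float
    label: str = ""

    def __post_init__(self):
        if self.lower_mya > self.upper_mya:
            raise ValueError("window lower bound exceeds upper bound")


def date_from_ks(ks: float, rate: RateConstant) -> DatingResult:
    """date [Mya] = Ks / (2 r) / 1e6, with r per site per year."""
    if ks < 0:
        raise ValueError("ks must be non-negative")
    return DatingResult(ks=ks, rate=rate, date_mya=ks / (2.0 * rate.r) / 1e6)


def compare_to_window(result: DatingResult, window: TimeWindow,
                      tol_mya: float = 0.0) -> str:
    """Classify a date against a closed time window.  Larger Mya = earlier,
    so a date above the upper bound is ``earlier_than`` the window."""
    if result.date_mya > window.upper_mya + tol_mya:
        return "earlier_than"
    if result.date_mya < window.lower_mya - tol_mya:
        return "later_than"
    return "within"


def correction_coefficient(ks_ref_peak: float, ks_other_peak: float) -> float:
    """Rate-correction coefficient of a lineage sharing a duplication peak
    with the reference: the ratio of the two peak Ks values."""
    if ks_ref_peak <= 0 or ks_other_peak <= 0:
        raise ValueError("peak Ks values must be > 0")
    return ks_ref_peak / ks_other_peak


@dataclass
class CorrectionChain:
    """Rate-correction chain reference -> bridge -> target.

    ``ks_ref_peak`` and ``ks_bridge_peak`` are the shared-event peak Ks in
    the reference and bridge species; the two ``_ortho`` values are the
    interspecific ortholog-peak Ks of (bridge, reference) and
    (bridge, target).  All derived coefficients are computed on
    construction; the reference coefficient is fixed at 1."""

    reference_species: str
    bridge_species: str
    target_species: str
    ks_ref_peak: float
    ks_bridge_peak: float
    ks_bridge_ref_ortho: float
    ks_bridge_target_ortho: float
    C_bridge: float = field(init=False)
    C_b_bridge_ref: float = field(init=False)
    ks_bridge_ref_corrected: float = field(init=False)
    C_b_bridge_target: float = field(init=False)
    C_target: float = field(init=False)

    def __post_init__(self):
        for v in (self.ks_ref_peak, self.ks_bridge_peak,
                  self.ks_bridge_ref_ortho, self.ks_bridge_target_ortho):
            if v <= 0:
                raise ValueError("all chain peak Ks values must be > 0")
        self.C_bridge = correction_coefficient(self.ks_ref_peak, self.ks_bridge_peak)
        self.C_b_bridge_ref = (self.C_bridge + 1.0) / 2.0
        self.ks_bridge_ref_corrected = self.C_b_bridge_ref * self.ks_bridge_ref_ortho
        self.C_b_bridge_target = self.ks_bridge_ref_corrected / self.ks_bridge_target_ortho
        self.C_target = 2.0 * self.C_b_bridge_target - self.C_bridge
        if self.C_target <= 0:
            raise ValueError(
                "chain geometry inconsistent: derived target coefficient <= 0"
            )


def correct_target_ks(chain: CorrectionChain, ks_target_values) -> list[float]:
    """Rescale target-lineage Ks values onto the reference scale:
    Ks' = C_target * Ks."""
    return [chain.C_target * float(k) for k in ks_target_values]
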