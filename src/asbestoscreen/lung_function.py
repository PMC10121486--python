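"""Lung-function impairment classing and fusion with the imaging score.

Implements the AMA (American Medical Association) impairment class derived
from spirometry and diffusion capacity, the lung-function eligibility rule
(class >= 2), the simple average fusion of the imaging probability with DLCO,
and the triage rule that routes uncertain cases back to a full panel review.

All lung-function inputs are percentages of the predicted normal value
(e.g. ``dlco_pct=62`` means 62 % of predicted DLCO).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "LungFunctionRecord",
    "FusedScore",
    "ama_class",
    "lf_eligible",
    "simple_combine",
    "triage",
]

# Impairment bands, worst (class 4) first: (lower bound inclusive -> class).
# FVC: >=80 -> 0, 70-79 -> 1, 60-69 -> 2, 50-59 -> 3, <50 -> 4
_FVC_EDGES = (80.0, 70.0, 60.0, 50.0)
# DLCO: >=75 -> 0, 65-74 -> 1, 55-64 -> 2, 45-54 -> 3, <45 -> 4
_DLCO_EDGES = (75.0, 65.0, 55.0, 45.0)

REVIEW_LOW = 0.35
REVIEW_HIGH = 0.60


def _band_class(pct: float, edges: tuple[float, ...]) -> int:
    for cls, edge in enumerate(edges):
        if pct >= edge:
            return cls
    return len(edges)


def ama_class(fvc_pct: float | None = None, dlco_pct: float | None = None) -> int:
    """AMA impairment class (0-4) from FVC and DLCO, worst parameter rule.

    Each available parameter is converted to a per-parameter class via its
    band table; the case class is the maximum (most impaired).  At least one
    parameter must be present.
    """
    classes = []
    if fvc_pct is not None and not (isinstance(fvc_pct, float) and math.isnan(fvc_pct)):
        if fvc_pct <= 0:
            raise ValueError("fvc_pct must be positive")
        classes.append(_band_class(float(fvc_pct), _FVC_EDGES))
    if dlco_pct is not None and not (isinstance(dlco_pct, float) and math.isnan(dlco_pct)):
        if dlco_pct <= 0:
            raise ValueError("dlco_pct must be positive")
        classes.append(_band_class(float(dlco_pct), _DLCO_EDGES))
    if not classes:
        raise ValueError("at least one of fvc_pct/dlco_pct is required")
    return max(classes)


def lf_eligible(ama: int) -> bool:
    """Lung-function criterion for financial support: AMA class >= 2."""
    if ama not in (0, 1, 2, 3, 4):
        raise ValueError(f"AMA class must be in 0..4, got {ama}")
    return ama >= 2


@dataclass
class LungFunctionRecord:
    """VC/FVC/DLCO in percent of predicted, with the derived AMA class.

    Any parameter may be missing (``None``).  VC is recorded but does not
    enter the AMA class, which uses only FVC and DLCO.
    """

    vc_pct: float | None = None
    fvc_pct: float | None = None
    dlco_pct: float | None = None

    @property
    def ama_class(self) -> int:
        return ama_class(self.fvc_pct, self.dlco_pct)

    @property
    def eligible(self) -> bool:
        return lf_eligible(self.ama_class)


@dataclass
class FusedScore:
    """Imaging probability fused with DLCO, plus the triage decision."""

    ai: float
    dlco_frac: float | None
    combined: float
    triage: str  # "clear" | "review"


def triage(p: float, low: float = REVIEW_LOW, high: float = REVIEW_HIGH) -> str:
    """Route a probability to ``"review"`` if it falls in [low, high], else ``"clear"``.

    The review band is closed on both ends — a case sitting exactly on a
    boundary gets the extra panel attention — and the comparison carries a
    tiny tolerance so round-off from upstream arithmetic (e.g. a fused
    score that is 0.6 up to floating point) cannot push a boundary case
    out of review.
    """
    if low > high:
        raise ValueError(f"triage bounds inverted: low={low} > high={high}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of [0, 1]: {p}")
    tol = 1e-9
    return "review" if (low - tol) <= p <= (high + tol) else "clear"


def simple_combine(
    ai: float,
    dlco_pct: float | None,
    low: float = REVIEW_LOW,
    high: float = REVIEW_HIGH,
) -> FusedScore:
    """Average of the imaging probability and the DLCO deficit.

    ``combined = ((1 - DLCO) + AI) / 2`` with DLCO as a fraction of predicted
    (``dlco_pct / 100``, clipped to [0, 1]), so the fused score stays in
    [0, 1].  A missing DLCO falls back to the imaging probability alone with
    a warning.
    """
    if not 0.0 <= ai <= 1.0:
        raise ValueError(f"ai probability out of [0, 1]: {ai}")
    if dlco_pct is None or (isinstance(dlco_pct, float) and math.isnan(dlco_pct)):
        warnings.warn("DLCO missing; fused score falls back to the imaging probability", stacklevel=2)
        return FusedScore(ai=ai, dlco_frac=None, combined=ai, triage=triage(ai, low, high))
    if dlco_pct <= 0:
        raise ValueError("dlco_pct must be positive")
    dlco_frac = min(max(dlco_pct / 100.0, 0.0), 1.0)
    combined = ((1.0 - dlco_frac) + ai) / 2.0
    return FusedScore(ai=ai, dlco_frac=dlco_frac, combined=combined, triage=triage(combined, low, high))
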