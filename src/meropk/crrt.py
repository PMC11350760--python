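"""Extracorporeal meropenem clearance during CVVH.

Clearance across the hemofilter from paired pre-/post-filter plasma
concentrations and the circuit flow settings:

    CL_CVVH (L/h) = (Cti - Cto) / Cti * (QT - QF) + QF

where Cti/Cto are the concentrations entering/leaving the filter, QF the
filtration (effluent) flow and QT the total flow term.  QT is taken as the
blood flow QB converted to L/h (150 mL/min -> 9 L/h) unless overridden;
see docs/methods.md for the caveats around this convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = ["FlowSettings", "FilterSamplePair", "cl_cvvh", "cl_cvvh_patient"]


@dataclass(frozen=True)
class FlowSettings:
    """CVVH circuit flows, normalized to L/h."""

    qf_l_h: float
    qt_l_h: float

    def __post_init__(self) -> None:
        if self.qf_l_h <= 0 or self.qt_l_h <= 0:
            raise ValueError("flows must be positive")
        if self.qt_l_h < self.qf_l_h:
            raise ValueError("QT must be >= QF")

    @classmethod
    def from_clinical(
        cls,
        qb_ml_min: float = 150.0,
        qf_ml_h: float = 1000.0,
        qt_l_h: Optional[float] = None,
    ) -> "FlowSettings":
        """Build from bedside units: QB in mL/min, QF in mL/h.

        QT defaults to QB expressed in L/h.
        """
        if qt_l_h is None:
            qt_l_h = qb_ml_min * 60.0 / 1000.0
        return cls(qf_l_h=qf_ml_h / 1000.0, qt_l_h=qt_l_h)


@dataclass(frozen=True)
class FilterSamplePair:
    """Pre-/post-filter concentration pair at one sampling time."""

    cti: float  # mg/L, entering the filter
    cto: float  # mg/L, leaving the filter
    time: float  # h

    def __post_init__(self) -> None:
        if self.cti <= 0:
            raise ValueError("cti must be positive")
        if self.cto < 0:
            raise ValueError("cto must be non-negative")
        if self.cto > self.cti:
            warnings.warn(
                f"post-filter concentration {self.cto} exceeds pre-filter "
                f"{self.cti}; pair kept but extraction is negative",
                stacklevel=2,
            )


def cl_cvvh(pair: FilterSamplePair, flows: FlowSettings) -> float:
    """Hemofilter clearance (L/h) from one sample pair.

    Bounded in [QF, QT] while 0 <= Cto <= Cti; a negative result (only
    possible with Cto far above Cti) is flagged with a warning, not raised.
    """
    extraction = (pair.cti - pair.cto) / pair.cti
    cl = extraction * (flows.qt_l_h - flows.qf_l_h) + flows.qf_l_h
    if cl < 0:
        warnings.warn(f"negative CVVH clearance {cl:.3g} L/h", stacklevel=2)
    return cl


def cl_cvvh_patient(
    pairs: Sequence[FilterSamplePair], flows: FlowSettings
) -> float:
    """Per-patient CVVH clearance: mean over the available sample pairs."""
    if len(pairs) == 0:
        raise ValueError("need at least one sample pair")
    return sum(cl_cvvh(p, flows) for p in pairs) / len(pairs)
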