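"""Standard CT dose estimators.

Effective diameter from patient AP/lateral dimensions, size-specific dose
estimate (SSDE) from CTDIvol and a size conversion factor, and effective
dose from the dose-length product via a tissue-weighting coefficient k
(mSv per mGy·cm; 0.014 is the conventional adult-chest value). The SSDE and
effective-dose chains are independent: effective dose is derived from DLP,
never from SSDE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import ParameterError

__all__ = [
    "DoseInputs",
    "DoseReport",
    "effective_diameter",
    "ssde",
    "effective_dose",
    "dose_report",
]


@dataclass(frozen=True)
class DoseInputs:
    """Scan/dose parameters for one acquisition.

    If ``dlp`` is given it is used as-is (scanners report DLP including
    overranging); otherwise it is ctdi_vol × scan_length.
    """

    ctdi_vol: float  # mGy
    ap: float  # cm
    lat: float  # cm
    f_size: float = 1.3  # dimensionless, 32-cm phantom conversion factor
    scan_length: Optional[float] = None  # cm
    dlp: Optional[float] = None  # mGy·cm
    k_factor: float = 0.014  # mSv/(mGy·cm)

    def __post_init__(self) -> None:
        for name in ("ctdi_vol", "ap", "lat", "f_size", "k_factor"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("scan_length", "dlp"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ParameterError(f"{name} must be positive when provided")
        if self.dlp is None and self.scan_length is None:
            raise ParameterError("provide either dlp or scan_length")


@dataclass(frozen=True)
class DoseReport:
    effective_diameter: float  # cm
    ssde: float  # mGy
    dlp: float  # mGy·cm
    effective_dose: float  # mSv


def effective_diameter(ap: float, lat: float) -> float:
    """Geometric-mean patient diameter sqrt(AP × LAT), cm."""
    if ap <= 0 or lat <= 0:
        raise ParameterError("ap and lat must be positive")
    return math.sqrt(ap * lat)


def ssde(ctdi_vol: float, f_size: float) -> float:
    """Size-specific dose estimate CTDIvol × f_size, mGy."""
    if ctdi_vol <= 0 or f_size <= 0:
        raise ParameterError("ctdi_vol and f_size must be positive")
    return ctdi_vol * f_size


def effective_dose(dlp: float, k: float = 0.014) -> float:
    """Effective dose DLP × k, mSv."""
    if dlp <= 0 or k <= 0:
        raise ParameterError("dlp and k must be positive")
    return dlp * k


def dose_report(inputs: DoseInputs) -> DoseReport:
    """All dose estimates for one acquisition."""
    dlp = inputs.dlp if inputs.dlp is not None else inputs.ctdi_vol * inputs.scan_length
    return DoseReport(
        effective_diameter=effective_diameter(inputs.ap, inputs.lat),
        ssde=ssde(inputs.ctdi_vol, inputs.f_size),
        dlp=dlp,
        effective_dose=effective_dose(dlp, inputs.k_factor),
    )
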