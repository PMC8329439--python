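"""The 21-measurement record shared by every module of the pipeline.

The column names below are the stable identifiers used in every emitted
table: 8 subthreshold measurements followed by 13 suprathreshold ones
(five f-I rates plus eight AP waveform features).  ``T_1ISI`` may be NaN
("undefined") when a cell fires fewer than two spikes at 250 pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping

__all__ = ["MEASUREMENT_NAMES", "MeasurementRecord"]

MEASUREMENT_NAMES: tuple[str, ...] = (
    "V_RMP",
    "R_in",
    "Sag_pct",
    "S_alpha",
    "Z_max",
    "f_R",
    "Q",
    "Phi_L",
    "f_50",
    "f_100",
    "f_150",
    "f_200",
    "f_250",
    "V_th",
    "V_AP_peak",
    "V_AP",
    "T_APHW",
    "T_1AP",
    "T_1ISI",
    "dVdt_max",
    "dVdt_min",
)

_FIELD_TO_NAME = {
    "v_rmp": "V_RMP",
    "r_in": "R_in",
    "sag_pct": "Sag_pct",
    "s_alpha": "S_alpha",
    "z_max": "Z_max",
    "f_r": "f_R",
    "q": "Q",
    "phi_l": "Phi_L",
    "f_50": "f_50",
    "f_100": "f_100",
    "f_150": "f_150",
    "f_200": "f_200",
    "f_250": "f_250",
    "v_th": "V_th",
    "v_ap_peak": "V_AP_peak",
    "v_ap": "V_AP",
    "t_aphw": "T_APHW",
    "t_1ap": "T_1AP",
    "t_1isi": "T_1ISI",
    "dvdt_max": "dVdt_max",
    "dvdt_min": "dVdt_min",
}


@dataclass
class MeasurementRecord:
    """All 21 intrinsic measurements for one cell under one condition."""

    v_rmp: float
    r_in: float
    sag_pct: float
    s_alpha: float
    z_max: float
    f_r: float
    q: float
    phi_l: float
    f_50: float
    f_100: float
    f_150: float
    f_200: float
    f_250: float
    v_th: float
    v_ap_peak: float
    v_ap: float
    t_aphw: float
    t_1ap: float
    t_1isi: float
    dvdt_max: float
    dvdt_min: float
    r_in_by_voltage: Mapping[float, float] = field(default_factory=dict)
    z_max_by_voltage: Mapping[float, float] = field(default_factory=dict)
    meta: Mapping[str, object] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        """Measurement-name -> value mapping in canonical column order."""
        raw = {f.name: getattr(self, f.name) for f in fields(self)}
        return {name: float(raw[fld]) for fld, name in _FIELD_TO_NAME.items()}

    #: AP waveform features are undefined ("undef") when the cell fires no
    #: spike at 250 pA; T_1ISI additionally needs two spikes.
    _MAY_BE_NAN = frozenset(
        {"v_th", "v_ap_peak", "v_ap", "t_aphw", "t_1ap", "t_1isi", "dvdt_max", "dvdt_min"}
    )

    def __post_init__(self) -> None:
        for fld in _FIELD_TO_NAME:
            val = getattr(self, fld)
            if fld not in self._MAY_BE_NAN and not math.isfinite(float(val)):
                raise ValueError(f"measurement {fld} is not finite: {val}")
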