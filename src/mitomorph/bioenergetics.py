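"""Mitochondrial stress-test decomposition of oxygen consumption traces.

A stress test measures oxygen consumption rate (OCR, pmol O2/min) through
four phases delimited by three sequential injections:

1. *basal* — untreated respiration;
2. *oligomycin* — ATP synthase blocked; remaining mitochondrial OCR is
   proton leak;
3. *FCCP* — uncoupled; the peak is maximal respiration;
4. *rotenone + antimycin A* — electron transport fully inhibited; what
   remains is non-mitochondrial oxygen consumption.

Summary values (all corrected by subtracting the non-mitochondrial floor):

* ``non_mito``  = mean of the rotenone/antimycin phase
* ``basal``     = mean(basal phase) - non_mito
* ``proton_leak`` = min(oligomycin phase) - non_mito
* ``atp_linked``  = basal - proton_leak
* ``maximal``   = max(FCCP phase) - non_mito
* ``reserve``   = maximal - basal

``basal = atp_linked + proton_leak`` and ``reserve = maximal - basal`` hold
exactly by construction, and adding any constant to the whole trace leaves
every summary unchanged. The mean/min/max readout choices per phase are
recorded in ``OcrSummary.method``. A negative corrected basal is reported
with a quality-control flag rather than raised, since it occurs in real
noisy wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "AGENTS",
    "PHASES",
    "OcrSummary",
    "segment_phases",
    "stress_summary",
    "summarize_wells",
]

AGENTS = ("oligomycin", "fccp", "rotenone_antimycin")
PHASES = ("basal", "oligo", "fccp", "rot_aa")

READOUT = {"basal": "mean", "oligo": "min", "fccp": "max", "rot_aa": "mean"}


@dataclass
class OcrSummary:
    non_mito: float
    basal: float
    atp_linked: float
    proton_leak: float
    maximal: float
    reserve: float
    qc_flags: list[str] = field(default_factory=list)
    method: dict = field(default_factory=lambda: dict(READOUT))

    def as_dict(self) -> dict[str, float]:
        return {
            "non_mito": self.non_mito,
            "basal": self.basal,
            "atp_linked": self.atp_linked,
            "proton_leak": self.proton_leak,
            "maximal": self.maximal,
            "reserve": self.reserve,
        }


def _injection_times(injections: pd.DataFrame) -> list[float]:
    if list(injections["agent"]) != list(AGENTS):
        raise ValidationError(
            f"injections must be exactly {AGENTS} in order, got {list(injections['agent'])}"
        )
    times = [float(t) for t in injections["time_min"]]
    if not all(a < b for a, b in zip(times, times[1:])):
        raise ValidationError("injection times must be strictly increasing")
    return times


def segment_phases(times, injections: pd.DataFrame) -> np.ndarray:
    """Assign each measurement time a phase label by injection bracketing.

    A measurement belongs to the phase opened by the latest injection at or
    before its time (measurements exactly at an injection time are assigned
    to the following phase, as the instrument measures after mixing).
    """
    t = np.asarray(times, dtype=float)
    if len(t) == 0:
        raise ValidationError("no measurements to segment")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("measurement times must be strictly increasing per well")
    inj = _injection_times(injections)
    idx = np.searchsorted(inj, t, side="right")  # 0..3
    labels = np.array(PHASES, dtype=object)[idx]
    for phase in PHASES:
        if not (labels == phase).any():
            raise ValidationError(f"phase {phase!r} has no measurements")
    return labels


def stress_summary(trace: pd.DataFrame, injections: pd.DataFrame) -> OcrSummary:
    """Summarize one well's trace (columns ``time_min``, ``ocr``)."""
    for col in ("time_min", "ocr"):
        if col not in trace.columns:
            raise ValidationError(f"trace missing column {col!r}")
    labels = segment_phases(trace["time_min"].to_numpy(), injections)
    ocr = trace["ocr"].to_numpy(dtype=float)
    phase = {p: ocr[labels == p] for p in PHASES}
    non_mito = float(np.mean(phase["rot_aa"]))
    basal = float(np.mean(phase["basal"])) - non_mito
    proton_leak = float(np.min(phase["oligo"])) - non_mito
    atp_linked = basal - proton_leak
    maximal = float(np.max(phase["fccp"])) - non_mito
    reserve = maximal - basal
    flags = []
    if basal < 0:
        flags.append("negative_basal_after_correction")
    if maximal < basal:
        flags.append("maximal_below_basal")
    return OcrSummary(non_mito, basal, atp_linked, proton_leak, maximal, reserve, flags)


def summarize_wells(measurements: pd.DataFrame, injections: pd.DataFrame) -> pd.DataFrame:
    """Per-well summaries from a long table (``well``, ``time_min``, ``ocr``)."""
    for col in ("well", "time_min", "ocr"):
        if col not in measurements.columns:
            raise ValidationError(f"measurements missing column {col!r}")
    rows = []
    for well, sub in measurements.groupby("well", sort=True):
        s = stress_summary(sub.sort_values("time_min"), injections)
        rows.append({"well": well, **s.as_dict(), "qc_flags": ";".join(s.qc_flags)})
    return pd.DataFrame(rows)
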