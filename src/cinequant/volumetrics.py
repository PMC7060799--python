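"""Volume curves, mass, and filling/ejection dynamics from label stacks.

Volumes use Simpson slice summation: per-slice labelled area times the
inter-slice distance (slice thickness + gap).  Curves are smoothed by
periodic Fourier truncation (the cine cycle is periodic), and dV/dt is the
spectral derivative of the smoothed curve, evaluated on a dense grid so
peak rates and their timings are not quantized to the frame raster.

Scalar outputs follow the standard definitions: EDV/ESV are the smoothed
curve extrema, SV = EDV - ESV, EF = 100 SV/EDV, LV mass is myocardial
volume times 1.05 g/ml.  Peak ejection rate (PER) is the largest -dV/dt on
the ejection arc; the E-wave peak is the first local dV/dt maximum after
end-systole and the A-wave peak the last one before the cycle closes;
diastasis is the |dV/dt| minimum between them; atrial contribution
AC = V(end-of-cycle ED) - V(diastasis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .model import LV_MYO, LV_POOL, RV_POOL, LabelledStack, View

MYOCARDIAL_DENSITY_G_PER_ML = 1.05

CHAMBER_LABELS = {"LV": LV_POOL, "RV": RV_POOL}


def bsa_dubois(height_cm: float, weight_kg: float) -> float:
    """DuBois & DuBois body surface area (m^2) from height (cm), weight (kg)."""
    if not (height_cm > 0 and weight_kg > 0):
        raise ValueError("height and weight must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def slice_summation_volume(stack: LabelledStack, label: int, frame: int) -> float:
    """Simpson slice-summation volume (ml) of one label at one frame."""
    if stack.view is not View.SAX:
        raise ValueError("slice summation requires a SAX stack")
    dr, dc = stack.voxel_size
    area_factor = dr * dc  # mm^2 per voxel
    counts = np.count_nonzero(stack.labels[:, :, :, frame] == label)
    return counts * area_factor * stack.slice_spacing / 1000.0


def fourier_smooth(values: np.ndarray, n_harmonics: int = 10) -> np.ndarray:
    """Periodic low-pass: keep the DC term and the first ``n_harmonics``."""
    values = np.asarray(values, dtype=float)
    c = np.fft.rfft(values)
    c[n_harmonics + 1 :] = 0.0
    return np.fft.irfft(c, n=len(values))


def _fourier_dense(values: np.ndarray, period_s: float, n_harmonics: int, n_dense: int):
    """Smoothed curve and its spectral derivative on a dense cyclic grid."""
    n = len(values)
    c = np.fft.rfft(values) / n
    h = min(n_harmonics, len(c) - 1)
    k = np.arange(1, h + 1)
    tau = np.arange(n_dense) / n_dense  # cycle fraction
    phases = np.exp(2j * np.pi * np.outer(tau, k))
    v = np.real(c[0]) + 2.0 * np.real(phases @ c[1 : h + 1])
    dv = 2.0 * np.real(phases @ (c[1 : h + 1] * (2j * np.pi * k / period_s)))
    return tau, v, dv


@dataclass
class VolumeCurve:
    """Per-frame chamber volume (ml) with smoothed companion."""

    values: np.ndarray
    times: np.ndarray
    chamber: str  # "LV" | "RV"
    n_harmonics: int = 10
    smoothed_values: np.ndarray = field(init=False)
    missing_frames: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.values) != len(self.times):
            raise ValueError("values and times length mismatch")
        if np.any(self.values < 0):
            raise ValueError("volumes must be non-negative")
        self.smoothed_values = fourier_smooth(self.values, self.n_harmonics)

    @property
    def period(self) -> float:
        dt = self.times[1] - self.times[0]
        return len(self.times) * dt


def volume_curve(
    stack: LabelledStack, chamber: str = "LV", n_harmonics: int = 10
) -> VolumeCurve:
    """Slice-summation volume at every frame of a SAX stack."""
    label = CHAMBER_LABELS[chamber]
    values = np.array(
        [slice_summation_volume(stack, label, k) for k in range(stack.n_frames)]
    )
    curve = VolumeCurve(
        values=values, times=stack.frame_times.copy(), chamber=chamber, n_harmonics=n_harmonics
    )
    curve.missing_frames = [int(k) for k in np.nonzero(values == 0)[0]]
    return curve


def lv_mass(stack: LabelledStack, frame: Optional[int] = None) -> float:
    """LV myocardial mass (g) at end-diastole (or an explicit frame)."""
    if frame is None:
        pool = [
            np.count_nonzero(stack.labels[:, :, :, k] == LV_POOL)
            for k in range(stack.n_frames)
        ]
        frame = int(np.argmax(pool))
    vol_ml = slice_summation_volume(stack, LV_MYO, frame)
    if vol_ml == 0:
        raise ValueError(f"no myocardium labelled at frame {frame}")
    return vol_ml * MYOCARDIAL_DENSITY_G_PER_ML


@dataclass
class VolumetryReport:
    """Derived scalars for one chamber; rates in ml/s, volumes in ml."""

    chamber: str
    edv: float
    esv: float
    sv: float
    ef: float
    per: Optional[float] = None
    pefr: Optional[float] = None
    pafr: Optional[float] = None
    ac_ml: Optional[float] = None
    ac_pct_sv: Optional[float] = None
    lvm: Optional[float] = None
    bsa: Optional[float] = None
    ed_frame: int = 0
    es_frame: int = 0
    e_peak_frame: Optional[int] = None
    a_peak_frame: Optional[int] = None
    diastasis_frame: Optional[int] = None
    missing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.edv < self.esv:
            raise ValueError("edv must be >= esv")

    @property
    def indexed(self) -> dict:
        """BSA-indexed volumes (ml/m^2) and mass (g/m^2), if BSA known."""
        if not self.bsa:
            return {}
        out = {
            "edv_i": self.edv / self.bsa,
            "esv_i": self.esv / self.bsa,
            "sv_i": self.sv / self.bsa,
        }
        if self.lvm is not None:
            out["lvm_i"] = self.lvm / self.bsa
        return out

    def to_row(self) -> dict:
        """Flat unit-suffixed mapping (one CSV row)."""
        p = self.chamber.lower()
        row = {
            f"{p}_edv_ml": self.edv,
            f"{p}_esv_ml": self.esv,
            f"{p}_sv_ml": self.sv,
            f"{p}_ef_pct": self.ef,
        }
        if self.per is not None:
            row[f"{p}_per_ml_s"] = self.per
        if self.pefr is not None:
            row[f"{p}_pefr_ml_s"] = self.pefr
        if self.pafr is not None:
            row[f"{p}_pafr_ml_s"] = self.pafr
        if self.ac_ml is not None:
            row[f"{p}_ac_ml"] = self.ac_ml
            row[f"{p}_ac_pct_sv"] = self.ac_pct_sv
        if self.lvm is not None:
            row["lvm_g"] = self.lvm
        for k, v in self.indexed.items():
            suffix = "g_m2" if k.startswith("lvm") else "ml_m2"
            row[f"{p}_{k}_{suffix}" if not k.startswith("lvm") else f"{k}_{suffix}"] = v
        return row


def cycle_parameters(
    curve: VolumeCurve,
    bsa: Optional[float] = None,
    n_dense: int = 720,
    peak_prominence_frac: float = 0.05,
) -> VolumetryReport:
    """Measure EDV/ESV/SV/EF and filling/ejection dynamics from a volume curve.

    Works on the Fourier-smoothed periodic curve evaluated densely; local
    dV/dt maxima in diastole with prominence below ``peak_prominence_frac``
    of the global |dV/dt| maximum are treated as ripple, not waves.  A
    missing A-wave (fused E/A) leaves PAFR and AC unset with a reason.
    """
    if len(curve.values) < 20:
        raise ValueError("cycle_parameters needs at least 20 frames")
    n = len(curve.values)
    tau, v, dv = _fourier_dense(curve.values, curve.period, curve.n_harmonics, n_dense)

    ed = int(np.argmax(v))
    es = int(np.argmin(v))
    edv, esv = float(v[ed]), float(v[es])
    sv = edv - esv
    ef = 100.0 * sv / edv if edv > 0 else 0.0

    def to_frame(dense_idx: int) -> int:
        return int(round(dense_idx * n / n_dense)) % n

    report = VolumetryReport(
        chamber=curve.chamber,
        edv=edv,
        esv=esv,
        sv=sv,
        ef=ef,
        bsa=bsa,
        ed_frame=to_frame(ed),
        es_frame=to_frame(es),
    )

    # ejection arc: ED forward (cyclically) to ES
    arc_len = (es - ed) % n_dense
    if arc_len == 0:
        report.missing["dynamics"] = "flat curve"
        return report
    ej = (ed + np.arange(arc_len + 1)) % n_dense
    report.per = float(np.max(-dv[ej]))

    # diastolic arc: ES forward to the next ED
    dlen = (ed - es) % n_dense
    dia = (es + np.arange(dlen + 1)) % n_dense
    dv_dia = dv[dia]
    prom = peak_prominence_frac * np.max(np.abs(dv))
    peaks, _ = find_peaks(dv_dia, prominence=prom)
    if len(peaks) == 0:
        report.missing["pefr"] = "no filling wave detected"
        return report
    e_peak = peaks[0]
    report.pefr = float(dv_dia[e_peak])
    report.e_peak_frame = to_frame(int(dia[e_peak]))
    if len(peaks) < 2:
        report.missing["pafr"] = "no A-wave detected"
        report.missing["ac"] = "no A-wave detected"
        return report
    a_peak = peaks[-1]
    report.pafr = float(dv_dia[a_peak])
    report.a_peak_frame = to_frame(int(dia[a_peak]))
    between = np.arange(e_peak, a_peak + 1)
    dstis = between[int(np.argmin(np.abs(dv_dia[between])))]
    report.diastasis_frame = to_frame(int(dia[dstis]))
    v_dia = v[dia]
    ac = float(v_dia[-1] - v_dia[dstis])  # end-of-cycle ED minus diastasis
    report.ac_ml = ac
    report.ac_pct_sv = 100.0 * ac / sv if sv > 0 else None
    return report
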