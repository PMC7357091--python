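"""Synthetic lumbar-spine cohort and sagittal MR acquisition simulator.

Generates per-disc ground truth (T2, proton density, water fraction) for a
four-group activity cohort with per-disc degeneration grades, rasterizes a
simplified sagittal spine into nucleus/annulus label volumes, and simulates
three acquisitions with known forward models:

* multi-echo spin echo:  S(TE) = PD * exp(-TE / T2), Rician magnitude noise
* single-echo T2w:       same model at one echo time
* dual-echo Dixon:       s(TE) = (W + c(TE) F) * exp(2i pi psi TE),
                         c(TE) = exp(2i pi f_fat TE), complex Gaussian noise

Degeneration grade drives the per-disc parameter means; activity group adds
a calibrated additive offset, so grade and group are independent by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .roi import DiscROI

logger = logging.getLogger(__name__)

GROUPS = ("sedentary", "cyclist", "jogger", "runner")
DEFAULT_LEVELS = ("T12/L1", "L1/L2", "L2/L3", "L3/L4", "L4/L5", "L5/S1")
GRADES = (1, 2, 3, 4)
MEASURES = ("t2", "t2w", "dixon")

FAT_SHIFT_HZ = -434.0       # single-peak fat, 3.4 ppm at 3 T
T2W_ECHO_TIME_MS = 70.0
VERTEBRA_T2_MS = 60.0
VERTEBRA_PD = 400.0
VERTEBRA_WATER_PCT = 50.0

MULTIECHO_TES_MS = (15.75, 36.75, 57.75, 78.75, 99.75, 120.75, 141.75, 162.75)
DIXON_TES_MS = (2.45, 3.67)


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


class GeometryError(ValueError):
    """Disc geometry does not fit or overlaps."""


# ---------------------------------------------------------------------------
# default generator parameter tables (nucleus-level mean/SD per grade, plus
# group-level cells used to calibrate additive activity offsets)

_GRADE_NUCLEUS = {
    "t2": ((166.0, 137.1, 103.9, 89.0), (25.0, 81.8, 37.7, 34.4)),
    "t2w": ((551.0, 492.0, 377.0, 271.0), (72.0, 236.0, 109.0, 99.0)),
    "dixon": ((87.2, 88.1, 84.8, 81.9), (7.9, 25.9, 11.9, 10.9)),
}
_GRADE_RATIO = {
    "t2": ((1.8, 1.5, 1.3, 1.0), (0.3, 0.9, 0.4, 0.4)),
    "t2w": ((3.7, 3.5, 2.7, 2.0), (0.7, 2.3, 1.1, 1.0)),
    "dixon": ((1.00, 1.01, 1.00, 0.99), (0.03, 0.10, 0.05, 0.04)),
}
_GROUP_NUCLEUS = {
    "t2": ((111.4, 137.7, 129.8, 132.6), (3.0, 3.1, 2.7, 2.9)),
    "t2w": ((423.6, 434.0, 426.4, 421.6), (8.9, 9.3, 7.9, 8.7)),
    "dixon": ((87.2, 88.1, 88.1, 89.4), (0.6, 0.7, 0.6, 0.6)),
}
_GROUP_WHOLE = {
    "t2": ((104.4, 121.6, 115.6, 117.9), (1.7, 1.7, 1.5, 1.6)),
    "t2w": ((326.9, 329.7, 317.6, 320.5), (4.9, 5.1, 4.4, 4.8)),
    "dixon": ((86.0, 87.1, 87.1, 88.1), (0.6, 0.7, 0.6, 0.6)),
}
_GROUP_RATIO = {
    "t2": ((1.40, 1.49, 1.48, 1.51), (0.03, 0.03, 0.02, 0.03)),
    "t2w": ((3.31, 3.29, 3.46, 3.27), (0.07, 0.07, 0.06, 0.07)),
    "dixon": ((1.01, 1.00, 1.01, 1.01), (0.004, 0.004, 0.004, 0.004)),
}
_GRADE_CELL_N = (47, 457, 60, 42)
_GROUP_CELL_N = (144, 132, 180, 150)

# validity ranges for truncated draws, per measure: (nucleus range, ratio range)
_RANGES = {
    "t2": ((1.0, 3000.0), (0.1, 20.0)),
    "t2w": ((1.0, 1e5), (0.1, 50.0)),
    "dixon": ((0.0, 100.0), (0.1, 20.0)),
}


@dataclass(frozen=True)
class ParameterTables:
    """Generator distributions: per-grade nucleus and nucleus/annulus-ratio
    cells, and per-group cells used for offset calibration / uniform mode."""

    nucleus_by_grade: Mapping[str, Tuple[Tuple[float, ...], Tuple[float, ...]]]
    ratio_by_grade: Mapping[str, Tuple[Tuple[float, ...], Tuple[float, ...]]]
    nucleus_by_group: Mapping[str, Tuple[Tuple[float, ...], Tuple[float, ...]]]
    whole_by_group: Mapping[str, Tuple[Tuple[float, ...], Tuple[float, ...]]]
    ratio_by_group: Mapping[str, Tuple[Tuple[float, ...], Tuple[float, ...]]]
    grade_cell_n: Tuple[int, ...] = _GRADE_CELL_N
    group_cell_n: Tuple[int, ...] = _GROUP_CELL_N


def default_parameter_tables() -> ParameterTables:
    return ParameterTables(_GRADE_NUCLEUS, _GRADE_RATIO, _GROUP_NUCLEUS, _GROUP_WHOLE, _GROUP_RATIO)


def default_grade_probabilities() -> Tuple[float, ...]:
    total = sum(_GRADE_CELL_N)
    return tuple(n / total for n in _GRADE_CELL_N)


@dataclass
class CohortConfig:
    subjects_per_group: Tuple[int, ...] = (24, 22, 30, 25)
    levels: Tuple[str, ...] = DEFAULT_LEVELS
    grade_probabilities: Optional[Mapping[str, Sequence[float]]] = None
    parameter_tables: ParameterTables = field(default_factory=default_parameter_tables)
    noise_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"multiecho": 0.0, "t2w": 0.0, "dixon": 0.0}
    )
    sd_vs_sem: str = "sd"            # interpret printed dispersions as SD or SEM
    uniform_discs: bool = False      # nucleus == annulus, drawn from whole-disc group cells
    group_effects: bool = True       # additive activity-group offsets
    seed: int = 0
    # simplified geometry (voxels)
    disc_ap_width: float = 36.0
    disc_height: float = 7.0
    disc_row_start: float = 12.0
    disc_row_spacing: float = 14.0
    disc_center_col: float = 32.0
    disc_slice_start: int = 2
    disc_slice_stop: int = 10

    def grade_probs(self, group: str) -> np.ndarray:
        if self.grade_probabilities is None:
            return np.asarray(default_grade_probabilities())
        return np.asarray(self.grade_probabilities[group], dtype=float)


@dataclass
class DiscGroundTruth:
    subject_id: str
    level: str
    group: str
    pfirrmann_grade: int
    t2_nucleus: float
    t2_annulus: float
    pd_nucleus: float
    pd_annulus: float
    water_pct_nucleus: float
    water_pct_annulus: float
    center_row: float
    center_col: float
    ap_width: float
    height: float
    slice_start: int
    slice_stop: int

    @property
    def disc_id(self) -> str:
        return f"{self.subject_id}:{self.level}"


@dataclass
class AcquisitionParams:
    technique: str
    echo_times: Tuple[float, ...]            # ms
    repetition_time: float = 2000.0          # ms
    n_slices: int = 12
    n_rows: int = 96
    n_cols: int = 64
    slice_thickness: float = 3.0             # mm
    slice_gap: float = 1.5                   # mm
    field_of_view: float = 281.0             # mm
    in_plane_resolution: float = 0.366       # mm / pixel

    def __post_init__(self) -> None:
        tes = tuple(float(t) for t in self.echo_times)
        if self.technique == "multiecho":
            if len(tes) != 8 or any(b <= a for a, b in zip(tes, tes[1:])):
                raise ConfigurationError("multiecho needs exactly 8 strictly increasing echo times")
        elif self.technique == "dixon":
            if len(tes) != 2 or tes[1] <= tes[0]:
                raise ConfigurationError("dixon needs exactly 2 echo times with TE1 < TE2")
        elif self.technique != "t2w":
            raise ConfigurationError(f"unknown technique {self.technique!r}")
        self.echo_times = tes

    @property
    def shape(self) -> Tuple[int, int, int]:
        return (self.n_slices, self.n_rows, self.n_cols)

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return (
            self.slice_thickness + self.slice_gap,
            self.in_plane_resolution,
            self.in_plane_resolution,
        )


def multiecho_params(**kw) -> AcquisitionParams:
    return AcquisitionParams("multiecho", MULTIECHO_TES_MS, **kw)


def t2w_params(**kw) -> AcquisitionParams:
    kw.setdefault("repetition_time", 2600.0)
    return AcquisitionParams("t2w", (T2W_ECHO_TIME_MS,), **kw)


def dixon_params(**kw) -> AcquisitionParams:
    kw.setdefault("repetition_time", 5.27)
    kw.setdefault("slice_gap", 0.0)
    return AcquisitionParams("dixon", DIXON_TES_MS, **kw)


@dataclass
class LabelVolume:
    """Integer label grid, axis order (slice, row, column), 0-based."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    compartments: Dict[str, Tuple[int, int]]  # disc_id -> (nucleus, annulus) codes
    vertebra_code: int = 1

    def disc_mask(self, disc_id: str) -> np.ndarray:
        nuc, ann = self.compartments[disc_id]
        return (self.data == nuc) | (self.data == ann)


@dataclass
class FieldMap:
    """Per-voxel off-resonance in Hz."""

    psi_hz: np.ndarray
    smoothness_vox: float = 8.0


@dataclass
class MultiEchoStack:
    volumes: np.ndarray            # (n_echoes, slices, rows, cols) magnitudes
    echo_times: Tuple[float, ...]  # ms
    spacing: Tuple[float, float, float] = (4.5, 0.366, 0.366)

    def __post_init__(self) -> None:
        if len(self.echo_times) < 2:
            raise ConfigurationError("need at least 2 echoes")
        if self.volumes.shape[0] != len(self.echo_times):
            raise ConfigurationError("echo count does not match volume count")


@dataclass
class ScalarVolume:
    data: np.ndarray
    spacing: Tuple[float, float, float] = (4.5, 0.366, 0.366)
    echo_time: float = T2W_ECHO_TIME_MS


@dataclass
class DualEchoComplex:
    echo1: np.ndarray              # complex
    echo2: np.ndarray
    echo_times: Tuple[float, float] = DIXON_TES_MS  # ms
    fat_shift_hz: float = FAT_SHIFT_HZ
    spacing: Tuple[float, float, float] = (3.0, 0.833, 0.833)

    def __post_init__(self) -> None:
        if self.echo1.shape != self.echo2.shape:
            raise ConfigurationError("echo volumes must share a shape")
        if self.echo_times[0] == self.echo_times[1]:
            raise ConfigurationError("echo times must differ")


# ---------------------------------------------------------------------------
# cohort generation


def _truncated_normal(rng, mean, sd, lo, hi, max_tries: int = 1000) -> float:
    if sd < 0:
        raise ConfigurationError("negative SD")
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _effective_sd(printed: float, cell_n: int, sd_vs_sem: str) -> float:
    return printed * np.sqrt(cell_n) if sd_vs_sem == "sem" else printed


def _validate(config: CohortConfig) -> None:
    if len(config.subjects_per_group) != len(GROUPS):
        raise ConfigurationError("need one subject count per group")
    if any(n < 0 for n in config.subjects_per_group):
        raise ConfigurationError("negative subject count")
    if config.sd_vs_sem not in ("sd", "sem"):
        raise ConfigurationError("sd_vs_sem must be 'sd' or 'sem'")
    for group in GROUPS:
        p = config.grade_probs(group)
        if len(p) != len(GRADES):
            raise ConfigurationError("grade probabilities must cover grades 1-4")
        if np.any(p < 0):
            raise ConfigurationError("negative grade probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("grade probabilities must sum to 1")
    tables = config.parameter_tables
    for tab in (tables.nucleus_by_grade, tables.ratio_by_grade, tables.whole_by_group):
        for means, sds in tab.values():
            if any(s < 0 for s in sds):
                raise ConfigurationError("negative SD in parameter table")


def group_offsets(config: CohortConfig) -> Dict[str, Dict[str, float]]:
    """Additive per-group offsets so that group-conditional nucleus means match
    the group-level cells under the grade mixture of each group."""
    tables = config.parameter_tables
    out: Dict[str, Dict[str, float]] = {m: {} for m in MEASURES}
    ratio_out: Dict[str, Dict[str, float]] = {m: {} for m in MEASURES}
    for m in MEASURES:
        grade_means = np.asarray(tables.nucleus_by_grade[m][0])
        grade_ratio_means = np.asarray(tables.ratio_by_grade[m][0])
        for gi, group in enumerate(GROUPS):
            p = config.grade_probs(group)
            mix = float(p @ grade_means)
            mix_ratio = float(p @ grade_ratio_means)
            if config.group_effects:
                out[m][group] = tables.nucleus_by_group[m][0][gi] - mix
                ratio_out[m][group] = tables.ratio_by_group[m][0][gi] - mix_ratio
            else:
                out[m][group] = 0.0
                ratio_out[m][group] = 0.0
    return {"nucleus": out, "ratio": ratio_out}


def build_cohort(config: CohortConfig) -> List[DiscGroundTruth]:
    """Draw one DiscGroundTruth per subject per level; reproducible per seed."""
    _validate(config)
    rng = np.random.default_rng(config.seed)
    tables = config.parameter_tables
    offsets = group_offsets(config)
    discs: List[DiscGroundTruth] = []
    sid = 0
    for gi, group in enumerate(GROUPS):
        probs = config.grade_probs(group)
        for _ in range(config.subjects_per_group[gi]):
            sid += 1
            subject_id = f"S{sid:03d}"
            for li, level in enumerate(config.levels):
                grade = int(rng.choice(len(GRADES), p=probs)) + 1
                g = grade - 1
                draws: Dict[str, Tuple[float, float]] = {}
                for m in MEASURES:
                    (lo, hi), (rlo, rhi) = _RANGES[m]
                    if config.uniform_discs:
                        means, sds = tables.whole_by_group[m]
                        sd = _effective_sd(sds[gi], tables.group_cell_n[gi], config.sd_vs_sem)
                        val = _truncated_normal(rng, means[gi], sd, lo, hi)
                        draws[m] = (val, val)
                    else:
                        nm, ns = tables.nucleus_by_grade[m]
                        rm, rs = tables.ratio_by_grade[m]
                        sd = _effective_sd(ns[g], tables.grade_cell_n[g], config.sd_vs_sem)
                        rsd = _effective_sd(rs[g], tables.grade_cell_n[g], config.sd_vs_sem)
                        nuc = _truncated_normal(rng, nm[g] + offsets["nucleus"][m][group], sd, lo, hi)
                        ratio = _truncated_normal(
                            rng, rm[g] + offsets["ratio"][m][group], rsd, rlo, rhi
                        )
                        ann = float(np.clip(nuc / ratio, lo, hi))
                        draws[m] = (nuc, ann)
                t2n, t2a = draws["t2"]
                sin, sia = draws["t2w"]
                wpn, wpa = draws["dixon"]
                pdn = sin / np.exp(-T2W_ECHO_TIME_MS / t2n)
                pda = sia / np.exp(-T2W_ECHO_TIME_MS / t2a)
                discs.append(
                    DiscGroundTruth(
                        subject_id=subject_id,
                        level=level,
                        group=group,
                        pfirrmann_grade=grade,
                        t2_nucleus=t2n,
                        t2_annulus=t2a,
                        pd_nucleus=float(pdn),
                        pd_annulus=float(pda),
                        water_pct_nucleus=wpn,
                        water_pct_annulus=wpa,
                        center_row=config.disc_row_start + li * config.disc_row_spacing,
                        center_col=config.disc_center_col,
                        ap_width=config.disc_ap_width,
                        height=config.disc_height,
                        slice_start=config.disc_slice_start,
                        slice_stop=config.disc_slice_stop,
                    )
                )
    return discs


def cohort_frame(discs: Sequence[DiscGroundTruth]):
    import pandas as pd

    return pd.DataFrame([vars(d) | {"disc_id": d.disc_id} for d in discs])


# ---------------------------------------------------------------------------
# rasterization


def rasterize_subject(discs: Sequence[DiscGroundTruth], params: AcquisitionParams) -> LabelVolume:
    """Render discs as per-slice ellipses with a central-fifth nucleus band.

    Vertebral bodies fill the gaps between consecutive discs (and one above
    and below the column) with label 1.  Deterministic.
    """
    shape = params.shape
    data = np.zeros(shape, dtype=np.int16)
    rows = np.arange(shape[1])[:, None].astype(float)
    cols = np.arange(shape[2])[None, :].astype(float)
    compartments: Dict[str, Tuple[int, int]] = {}

    ordered = sorted(discs, key=lambda d: d.center_row)
    for i, d in enumerate(ordered):
        a = d.ap_width / 2.0
        b = d.height / 2.0
        if (
            d.center_col - a < 0
            or d.center_col + a > shape[2] - 1
            or d.center_row - b < 0
            or d.center_row + b > shape[1] - 1
            or d.slice_start < 0
            or d.slice_stop > shape[0]
        ):
            raise GeometryError(f"disc {d.disc_id} does not fit in the field of view")
        ellipse = ((cols - d.center_col) / a) ** 2 + ((rows - d.center_row) / b) ** 2 <= 1.0
        nucleus_band = np.abs(cols - d.center_col) <= a / 5.0
        nuc2d = ellipse & nucleus_band
        ann2d = ellipse & ~nucleus_band
        nuc_code, ann_code = 2 + 2 * i, 3 + 2 * i
        for z in range(d.slice_start, d.slice_stop):
            if np.any(data[z][ellipse] != 0):
                raise GeometryError(f"disc {d.disc_id} overlaps another disc")
            data[z][nuc2d] = nuc_code
            data[z][ann2d] = ann_code
        compartments[d.disc_id] = (nuc_code, ann_code)

    # vertebral bodies between/around discs, background voxels only
    if ordered:
        a = ordered[0].ap_width / 2.0
        cc = ordered[0].center_col
        col_band = np.abs(cols - cc) <= a
        z0 = min(d.slice_start for d in ordered)
        z1 = max(d.slice_stop for d in ordered)
        bounds = []
        first, last = ordered[0], ordered[-1]
        bounds.append((first.center_row - first.height / 2 - 5, first.center_row - first.height / 2 - 1))
        for d0, d1 in zip(ordered, ordered[1:]):
            bounds.append((d0.center_row + d0.height / 2 + 1, d1.center_row - d1.height / 2 - 1))
        bounds.append((last.center_row + last.height / 2 + 1, last.center_row + last.height / 2 + 5))
        for lo, hi in bounds:
            lo = max(int(np.ceil(lo)), 0)
            hi = min(int(np.floor(hi)), shape[1] - 1)
            if hi < lo:
                continue
            block = np.zeros(shape[1:], dtype=bool)
            block[lo : hi + 1, :] = col_band[0]
            for z in range(z0, z1):
                sel = block & (data[z] == 0)
                data[z][sel] = 1
    return LabelVolume(data, params.spacing, compartments)


def make_disc_rois(discs: Sequence[DiscGroundTruth], n_vertices: int = 48) -> List[DiscROI]:
    """Per-disc elliptical polygons matching the rasterized geometry,
    anterior vertex first."""
    rois = []
    theta = np.pi + 2 * np.pi * np.arange(n_vertices) / n_vertices
    for d in discs:
        a, b = d.ap_width / 2.0, d.height / 2.0
        verts = np.column_stack(
            [d.center_row + b * np.sin(theta), d.center_col + a * np.cos(theta)]
        )
        rois.append(
            DiscROI(d.disc_id, {z: verts for z in range(d.slice_start, d.slice_stop)})
        )
    return rois


# ---------------------------------------------------------------------------
# simulators


def _lookup_maps(labels: LabelVolume, discs: Sequence[DiscGroundTruth]):
    """Per-voxel (t2, pd, water_pct) volumes from compartment ground truth."""
    max_code = int(labels.data.max())
    t2 = np.zeros(max_code + 1)
    pd_ = np.zeros(max_code + 1)
    wp = np.zeros(max_code + 1)
    t2[labels.vertebra_code] = VERTEBRA_T2_MS
    pd_[labels.vertebra_code] = VERTEBRA_PD
    wp[labels.vertebra_code] = VERTEBRA_WATER_PCT
    by_id = {d.disc_id: d for d in discs}
    for disc_id, (nuc, ann) in labels.compartments.items():
        d = by_id[disc_id]
        t2[nuc], pd_[nuc], wp[nuc] = d.t2_nucleus, d.pd_nucleus, d.water_pct_nucleus
        t2[ann], pd_[ann], wp[ann] = d.t2_annulus, d.pd_annulus, d.water_pct_annulus
    codes = labels.data
    return t2[codes], pd_[codes], wp[codes]


def _noiseless_echo(t2_map: np.ndarray, pd_map: np.ndarray, te_ms: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.where(t2_map > 0, np.exp(-te_ms / np.maximum(t2_map, 1e-12)), 0.0)
    return pd_map * decay


def _rician(signal: np.ndarray, sigma: float, rng) -> np.ndarray:
    if sigma <= 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def simulate_multiecho(
    labels: LabelVolume,
    discs: Sequence[DiscGroundTruth],
    params: AcquisitionParams,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> MultiEchoStack:
    if params.technique != "multiecho":
        raise ConfigurationError("params.technique must be 'multiecho'")
    t2m, pdm, _ = _lookup_maps(labels, discs)
    rng = np.random.default_rng(seed)
    vols = np.stack(
        [_rician(_noiseless_echo(t2m, pdm, te), noise_sigma, rng) for te in params.echo_times]
    )
    return MultiEchoStack(vols, params.echo_times, params.spacing)


def simulate_t2w(
    labels: LabelVolume,
    discs: Sequence[DiscGroundTruth],
    params: AcquisitionParams,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ScalarVolume:
    if params.technique != "t2w":
        raise ConfigurationError("params.technique must be 't2w'")
    t2m, pdm, _ = _lookup_maps(labels, discs)
    rng = np.random.default_rng(seed)
    te = params.echo_times[0]
    return ScalarVolume(_rician(_noiseless_echo(t2m, pdm, te), noise_sigma, rng), params.spacing, te)


def make_fieldmap(
    shape: Tuple[int, int, int],
    max_abs_hz: float = 60.0,
    smoothness_vox: float = 8.0,
    seed: int = 0,
) -> FieldMap:
    """Smooth random off-resonance field scaled to a peak |psi|."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    psi = gaussian_filter(rng.normal(size=shape), smoothness_vox, mode="nearest")
    peak = np.abs(psi).max()
    if peak > 0:
        psi = psi * (max_abs_hz / peak)
    return FieldMap(psi, smoothness_vox)


def simulate_dixon(
    labels: LabelVolume,
    discs: Sequence[DiscGroundTruth],
    fieldmap: FieldMap,
    params: AcquisitionParams,
    noise_sigma: float = 0.0,
    seed: int = 0,
    fat_shift_hz: float = FAT_SHIFT_HZ,
) -> DualEchoComplex:
    if params.technique != "dixon":
        raise ConfigurationError("params.technique must be 'dixon'")
    _, pdm, wpm = _lookup_maps(labels, discs)
    psi = np.asarray(fieldmap.psi_hz, dtype=float)
    if psi.shape != labels.data.shape:
        raise ConfigurationError("field map shape mismatch")
    te_s = np.asarray(params.echo_times) * 1e-3
    alias = 1.0 / (2.0 * (te_s[1] - te_s[0]))
    if np.abs(psi).max() > alias:
        logger.warning(
            "field map |psi| max %.1f Hz exceeds the aliasing bound %.1f Hz",
            np.abs(psi).max(),
            alias,
        )
    water = pdm * wpm / 100.0
    fat = pdm * (1.0 - wpm / 100.0)
    rng = np.random.default_rng(seed)
    echoes = []
    for te in te_s:
        c = np.exp(2j * np.pi * fat_shift_hz * te)
        s = (water + c * fat) * np.exp(2j * np.pi * psi * te)
        if noise_sigma > 0:
            s = s + noise_sigma * (
                rng.normal(size=s.shape) + 1j * rng.normal(size=s.shape)
            )
        echoes.append(s.astype(complex))
    return DualEchoComplex(
        echoes[0], echoes[1], tuple(params.echo_times), fat_shift_hz, params.spacing
    )
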