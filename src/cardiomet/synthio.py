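"""Seeded synthetic-data generators for every input class of the pipeline.

Each generator returns its output together with a ground-truth record of
the injected parameters, so that the downstream estimators (beat
detection, AR spectral analysis, reflex gain, Kitt, stereology, vessel
morphometry) can be validated without any external recordings.

Simulated study conditions follow the published design: conscious rats at
~325 bpm, 30-min-scale arterial-pressure recordings with low-frequency
(~0.4 Hz Mayer-wave) and high-frequency (~1.5 Hz respiratory) systolic
oscillations, insulin-tolerance glucose decays sampled at 0/4/8/12/16 min,
vasoactive-bolus baroreflex trials, stereological tissue fields and
aortic rings, organized as three groups (C / F / FT) of eight animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cardiomet import tables

#: Integer labels used in generated masks.
BACKGROUND_LABEL = 0
OBJECT_LABEL = 10
WALL_LABEL = 1
LAMELLA_LABEL = 2
COLLAGEN_LABEL = 3


# ---------------------------------------------------------------------------
# arterial-pressure waveform
# ---------------------------------------------------------------------------

@dataclass
class APSimParams:
    """Parameters of the pulsatile arterial-pressure simulator.

    The waveform is built beat by beat: a half-sine systolic upstroke to the
    beat's systolic target followed by an exponential diastolic decay back to
    the diastolic level.  Low- and high-frequency oscillations amplitude-
    modulate the per-beat systolic values (the systogram), which is where the
    spectral pipeline operates; the intra-beat morphology is a free choice.
    """

    duration_s: float = 60.0
    fs: float = 500.0
    hr_bpm: float = 325.0
    sap_mmHg: float = 122.0
    dap_mmHg: float = 95.0
    lf_freq_hz: float = 0.4
    lf_sd_mmHg: float = 0.0
    hf_freq_hz: float = 1.5
    hf_sd_mmHg: float = 0.0
    noise_sd_mmHg: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        beat_freq = self.hr_bpm / 60.0
        if self.fs <= 2.0 * beat_freq:
            raise ValueError(
                f"sampling rate {self.fs} Hz too low for {self.hr_bpm} bpm: "
                f"need fs > 2 x beat frequency ({2 * beat_freq:.1f} Hz)"
            )
        if not (self.sap_mmHg > self.dap_mmHg > 0):
            raise ValueError("require sap > dap > 0")
        if min(self.lf_sd_mmHg, self.hf_sd_mmHg, self.noise_sd_mmHg) < 0:
            raise ValueError("oscillation/noise SDs must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass
class APWaveform:
    """Sampled pressure waveform plus the ground truth that generated it."""

    time_s: np.ndarray
    pressure_mmHg: np.ndarray
    fs: float
    truth: dict = field(default_factory=dict)


def gen_ap_waveform(params: APSimParams) -> APWaveform:
    """Simulate a pulsatile arterial-pressure recording.

    Per-beat systolic targets are ``sap + LF + HF + noise`` where LF and HF
    are sinusoids at ``lf_freq_hz`` / ``hf_freq_hz`` with amplitudes chosen
    so their time variance equals ``lf_sd**2`` / ``hf_sd**2``.  The returned
    ground truth records the injected systogram, band variances and rate.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    beat_period = 60.0 / params.hr_bpm
    n_beats = int(round(params.hr_bpm * params.duration_s / 60.0))
    beat_times = np.arange(n_beats) * beat_period

    lf = params.lf_sd_mmHg * math.sqrt(2.0) * np.sin(
        2 * np.pi * params.lf_freq_hz * beat_times
    )
    hf = params.hf_sd_mmHg * math.sqrt(2.0) * np.sin(
        2 * np.pi * params.hf_freq_hz * beat_times + np.pi / 3
    )
    noise = rng.normal(0.0, params.noise_sd_mmHg, n_beats) if params.noise_sd_mmHg else 0.0
    sap_series = params.sap_mmHg + lf + hf + noise

    n_samples = int(round(params.duration_s * params.fs))
    t = np.arange(n_samples) / params.fs
    beat_idx = np.minimum((t / beat_period).astype(int), n_beats - 1)
    u = t / beat_period - beat_idx  # phase within beat, [0, 1)

    amp = sap_series[beat_idx] - params.dap_mmHg
    rise = 0.3   # systolic upstroke fraction of the beat
    tau = 0.12   # diastolic decay constant, beat fractions
    p = np.where(
        u < rise,
        params.dap_mmHg + amp * np.sin(np.pi * u / (2 * rise)),
        params.dap_mmHg + amp * np.exp(-(u - rise) / tau),
    )

    truth = {
        "hr_bpm": params.hr_bpm,
        "n_beats": n_beats,
        "sap_mmHg": params.sap_mmHg,
        "dap_mmHg": params.dap_mmHg,
        "lf_var_mmHg2": params.lf_sd_mmHg ** 2,
        "hf_var_mmHg2": params.hf_sd_mmHg ** 2,
        "noise_var_mmHg2": params.noise_sd_mmHg ** 2,
        "beat_rate_hz": params.hr_bpm / 60.0,
        "beat_times_s": beat_times,
        "sap_series": sap_series,
    }
    return APWaveform(time_s=t, pressure_mmHg=p, fs=params.fs, truth=truth)


# ---------------------------------------------------------------------------
# insulin tolerance test
# ---------------------------------------------------------------------------

def gen_itt(
    g0: float,
    t_half: float,
    noise_sd: float = 0.0,
    times: Sequence[float] = tables.ITT_TIMES_MIN,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential blood-glucose decay ``g0 * 2**(-t/t_half)`` plus noise.

    ``t_half`` may be ``inf`` (no decay).  Readings are clipped at 1 mg/dL.
    Returns ``(times_min, glucose_mg_dl)``.
    """
    times = np.asarray(times, dtype=float)
    if g0 <= 0:
        raise ValueError("g0 must be positive")
    if not t_half > 0:
        raise ValueError("t_half must be positive (may be inf)")
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    decay = np.ones_like(times) if math.isinf(t_half) else 2.0 ** (-times / t_half)
    g = g0 * decay
    if noise_sd:
        g = g + rng.normal(0.0, noise_sd, times.size)
    return times, np.clip(g, 1.0, None)


# ---------------------------------------------------------------------------
# baroreflex trial
# ---------------------------------------------------------------------------

def gen_baro_trial(
    gain: float,
    delta_map_values: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear reflex trial: ``delta_hr = gain * delta_map + noise``."""
    dmap = np.asarray(delta_map_values, dtype=float)
    if dmap.size == 0:
        raise ValueError("need at least one bolus")
    if not math.isfinite(gain):
        raise ValueError("gain must be finite")
    rng = np.random.default_rng(seed)
    dhr = gain * dmap
    if noise_sd:
        dhr = dhr + rng.normal(0.0, noise_sd, dmap.size)
    return dmap, dhr


# ---------------------------------------------------------------------------
# stereological tissue fields
# ---------------------------------------------------------------------------

@dataclass
class TissueField:
    """Labelled mask with calibration and the generating ground truth."""

    mask: np.ndarray          # integer labels, shape (height, width)
    px_per_um: float
    truth: dict = field(default_factory=dict)

    @property
    def area_um2(self) -> float:
        return self.mask.size / self.px_per_um ** 2

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6


def gen_tissue_field(
    width: int,
    height: int,
    fractions: dict[int, float] | None = None,
    object_density_per_mm2: float = 0.0,
    object_radius_um: float = 5.0,
    px_per_um: float = 1.0,
    seed: int = 0,
) -> TissueField:
    """Generate a labelled tissue field with exact area fractions.

    ``fractions`` maps integer labels to requested area percentages of the
    whole field; label assignment is by random pixel selection, which makes
    the realized fraction exact to the pixel and is sufficient for
    point-counting estimators (which are insensitive to spatial texture).
    Round objects (e.g. ANP granules, capillary profiles) are placed as
    non-overlapping disks of label ``OBJECT_LABEL`` at the requested
    density per mm^2.
    """
    fractions = dict(fractions or {})
    if any(f < 0 for f in fractions.values()) or sum(fractions.values()) > 100.0 + 1e-9:
        raise ValueError("fractions must be >= 0 and sum to <= 100%")
    rng = np.random.default_rng(seed)
    mask = np.zeros((height, width), dtype=np.uint8)

    area_mm2 = width * height / (px_per_um * 1e3) ** 2
    n_objects = int(round(object_density_per_mm2 * area_mm2))
    centers: list[tuple[int, int]] = []
    r_px = max(1.0, object_radius_um * px_per_um)
    if n_objects:
        if n_objects * np.pi * r_px ** 2 > 0.4 * mask.size:
            raise ValueError("object density too high for object size (packing)")
        yy, xx = np.mgrid[0:height, 0:width]
        tries = 0
        while len(centers) < n_objects:
            tries += 1
            if tries > 200 * n_objects:
                raise ValueError("could not place objects without overlap (packing)")
            cy = rng.integers(int(r_px), height - int(r_px))
            cx = rng.integers(int(r_px), width - int(r_px))
            if any((cy - y) ** 2 + (cx - x) ** 2 < (2 * r_px + 2) ** 2 for y, x in centers):
                continue
            centers.append((cy, cx))
            mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r_px ** 2] = OBJECT_LABEL

    free = np.flatnonzero(mask.ravel() == BACKGROUND_LABEL)
    free = rng.permutation(free)
    cursor = 0
    realized: dict[int, float] = {}
    for label, frac in fractions.items():
        k = int(round(frac / 100.0 * mask.size))
        if cursor + k > free.size:
            raise ValueError("requested fractions exceed available background")
        mask.ravel()[free[cursor:cursor + k]] = label
        realized[label] = 100.0 * k / mask.size
        cursor += k

    truth = {
        "fractions_pct": realized,
        "requested_pct": fractions,
        "n_objects": len(centers),
        "object_density_per_mm2": len(centers) / area_mm2 if area_mm2 else 0.0,
        "object_radius_um": object_radius_um,
        "object_area_um2": float(np.pi * object_radius_um ** 2),
        "centers": centers,
    }
    return TissueField(mask=mask, px_per_um=px_per_um, truth=truth)


# ---------------------------------------------------------------------------
# aortic ring
# ---------------------------------------------------------------------------

def gen_aorta_ring(
    lumen_d_mm: float,
    imt_um: float,
    n_lamellae: int,
    collagen_fraction: float = 0.0,
    px_per_um: float = 1.0,
    lamella_thickness_um: float = 3.0,
    seed: int = 0,
) -> TissueField:
    """Synthetic transverse aortic ring.

    An annular wall (label ``WALL_LABEL``) of thickness ``imt_um`` around a
    lumen of diameter ``lumen_d_mm`` contains ``n_lamellae`` evenly spaced
    concentric elastic lamellae (label ``LAMELLA_LABEL``) and, optionally,
    randomly scattered collagen pixels (label ``COLLAGEN_LABEL``) at
    ``collagen_fraction`` percent of the wall area.
    """
    if n_lamellae < 1:
        raise ValueError("n_lamellae must be >= 1")
    if not 0 <= collagen_fraction <= 100:
        raise ValueError("collagen_fraction must be in [0, 100]")
    if imt_um >= lumen_d_mm * 500.0:
        raise ValueError("IMT must be smaller than the lumen radius (unit check)")
    wall_px = imt_um * px_per_um
    band_px = lamella_thickness_um * px_per_um
    spacing = wall_px / n_lamellae
    if spacing < 2.0 * band_px:
        raise ValueError(
            f"{n_lamellae} lamellae of {lamella_thickness_um} um do not fit in "
            f"a {imt_um} um wall without overlap"
        )

    rng = np.random.default_rng(seed)
    r_in = lumen_d_mm / 2.0 * 1e3 * px_per_um
    r_out = r_in + wall_px
    half = int(math.ceil(r_out + 4))
    size = 2 * half + 1
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    r = np.hypot(yy, xx)

    mask = np.zeros((size, size), dtype=np.uint8)
    wall = (r >= r_in) & (r < r_out)
    mask[wall] = WALL_LABEL
    for i in range(n_lamellae):
        rc = r_in + (i + 0.5) * spacing
        mask[(r >= rc - band_px / 2) & (r < rc + band_px / 2)] = LAMELLA_LABEL
    if collagen_fraction > 0:
        candidates = np.flatnonzero((mask.ravel() == WALL_LABEL))
        k = int(round(collagen_fraction / 100.0 * wall.sum()))
        k = min(k, candidates.size)
        mask.ravel()[rng.choice(candidates, size=k, replace=False)] = COLLAGEN_LABEL

    truth = {
        "lumen_d_mm": lumen_d_mm,
        "imt_um": imt_um,
        "n_lamellae": n_lamellae,
        "collagen_fraction_pct": collagen_fraction,
        "wall_area_px": int(wall.sum()),
        "center_px": (half, half),
        "r_in_px": r_in,
        "r_out_px": r_out,
    }
    return TissueField(mask=mask, px_per_um=px_per_um, truth=truth)


def add_label_noise(field: TissueField, fraction: float, seed: int = 0) -> TissueField:
    """Return a copy with ``fraction`` of pixels replaced by random labels."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = field.mask.copy()
    labels = np.unique(mask)
    n = int(round(fraction * mask.size))
    idx = rng.choice(mask.size, size=n, replace=False)
    mask.ravel()[idx] = rng.choice(labels, size=n)
    return TissueField(mask=mask, px_per_um=field.px_per_um, truth=dict(field.truth))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Specification of a three-group synthetic cohort.

    Endpoint means/SEMs default to the published group tables; per-animal
    values are drawn as Gaussian with SD = SEM * sqrt(n_reference).  White
    adipose tissue and left-ventricular collagen share a latent factor with
    correlation ``wat_collagen_rho`` to emulate the reported fat-fibrosis
    association.
    """

    n_per_group: int = tables.N_PER_GROUP
    endpoints: dict = field(default_factory=lambda: tables.ENDPOINTS)
    fructose_conc_g_per_l: float = tables.FRUCTOSE_G_PER_L
    insulin_dose_U_per_kg: float = tables.INSULIN_DOSE_U_PER_KG
    wat_collagen_rho: float = 0.89
    include_raw: bool = False
    waveform_duration_s: float = 60.0
    waveform_fs: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for ep, groups in self.endpoints.items():
            for g, (_, sem) in groups.items():
                if sem < 0:
                    raise ValueError(f"negative SEM for {ep}/{g}")


@dataclass
class Animal:
    """One synthetic animal: endpoint draws plus optional raw input bundle."""

    animal_id: str
    group: str
    endpoints: dict[str, float]
    waveform: APWaveform | None = None
    itt: tuple[np.ndarray, np.ndarray] | None = None
    baro_pressor: tuple[np.ndarray, np.ndarray] | None = None
    baro_depressor: tuple[np.ndarray, np.ndarray] | None = None
    lv_field: TissueField | None = None
    atrial_field: TissueField | None = None
    aorta_ring: TissueField | None = None


def _draw_endpoints(spec: CohortSpec, group: str, rng: np.random.Generator) -> dict[str, float]:
    n_ref = tables.N_PER_GROUP
    values: dict[str, float] = {}
    # correlated WAT / LV-collagen pair via a shared latent normal
    z = rng.standard_normal()
    rho = spec.wat_collagen_rho
    e = rng.standard_normal()
    for ep, groups in spec.endpoints.items():
        mean, sem = groups[group]
        sd = sem * math.sqrt(n_ref)
        if ep == "wat":
            values[ep] = mean + sd * z
        elif ep == "lv_vv_collagen":
            values[ep] = mean + sd * (rho * z + math.sqrt(1 - rho ** 2) * e)
        else:
            values[ep] = mean + sd * rng.standard_normal()
    return values


def gen_cohort(spec: CohortSpec | None = None) -> list[Animal]:
    """Generate a complete three-group cohort, optionally with raw inputs.

    With ``include_raw=True`` every animal carries a pressure waveform (SAP /
    DAP / HR and LF band power from its own endpoint draws), an ITT glucose
    series consistent with its Kitt, pressor and depressor baroreflex trials
    with its BR/TR gains, a left-ventricular collagen field, an atrial
    granule field, and an aortic ring — each with retained ground truth.
    """
    spec = spec or CohortSpec()
    spec.validate()
    root = np.random.default_rng(spec.seed)
    animals: list[Animal] = []
    for group in tables.GROUPS:
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(root.integers(2 ** 31))
            ep = _draw_endpoints(spec, group, rng)
            animal = Animal(animal_id=f"{group}{i + 1:02d}", group=group, endpoints=ep)
            if spec.include_raw:
                _attach_raw(animal, spec, rng)
            animals.append(animal)
    return animals


def _attach_raw(animal: Animal, spec: CohortSpec, rng: np.random.Generator) -> None:
    ep = animal.endpoints
    sap = max(ep["sap"], 60.0)
    dap = min(max(ep["dap"], 30.0), sap - 10.0)
    hr = float(np.clip(ep["hr"], 220.0, 480.0))
    total_var = max(ep["sap_var"], 1.0)
    lf_var = float(np.clip(ep["sap_lf"], 0.2, 0.8 * total_var))
    hf_var = max(total_var - lf_var, 0.1)
    animal.waveform = gen_ap_waveform(APSimParams(
        duration_s=spec.waveform_duration_s, fs=spec.waveform_fs,
        hr_bpm=hr, sap_mmHg=sap, dap_mmHg=dap,
        lf_sd_mmHg=math.sqrt(lf_var), hf_sd_mmHg=math.sqrt(hf_var),
        noise_sd_mmHg=0.5, seed=int(rng.integers(2 ** 31)),
    ))
    kitt_val = max(ep["kitt"], 0.5)
    animal.itt = gen_itt(
        g0=max(ep["glycemia"], 40.0), t_half=69.3 / kitt_val,
        noise_sd=2.0, seed=int(rng.integers(2 ** 31)),
    )
    br = min(ep["br"], -0.2)
    tr = max(ep["tr"], 0.2)
    animal.baro_pressor = gen_baro_trial(
        br, [10, 15, 20, 30, 40], noise_sd=1.0, seed=int(rng.integers(2 ** 31)))
    animal.baro_depressor = gen_baro_trial(
        -tr, [-10, -15, -20, -30], noise_sd=1.0, seed=int(rng.integers(2 ** 31)))
    animal.lv_field = gen_tissue_field(
        400, 400, fractions={COLLAGEN_LABEL: float(np.clip(ep["lv_vv_collagen"], 0.5, 60.0))},
        object_density_per_mm2=max(ep["nv_capillaries"], 0.5),
        object_radius_um=4.0, px_per_um=0.1, seed=int(rng.integers(2 ** 31)))
    animal.atrial_field = gen_tissue_field(
        400, 400, fractions={},
        object_density_per_mm2=max(ep["nv_granules"], 1.0),
        object_radius_um=3.0, px_per_um=0.1, seed=int(rng.integers(2 ** 31)))
    animal.aorta_ring = gen_aorta_ring(
        lumen_d_mm=float(np.clip(ep["aorta_diameter"], 0.5, 1.6)),
        imt_um=float(np.clip(ep["imt"], 100.0, 260.0)),
        n_lamellae=int(np.clip(round(ep["elastic_lamellae"]), 1, 20)),
        collagen_fraction=float(np.clip(ep["aorta_vv_collagen"], 0.0, 30.0)),
        px_per_um=1.0, seed=int(rng.integers(2 ** 31)))
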