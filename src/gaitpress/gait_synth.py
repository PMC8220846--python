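"""Synthetic plantar-pressure generator for the four gait classes.

No public recordings of children's insole pressure exist for this problem,
so this module generates labeled stand-ins with the statistical structure
the recognition pipeline assumes:

* an 8x8 spatial template per foot type, built from the published regional
  load shifts — in-toeing amplifies the lateral midfoot/forefoot load by up
  to 61%/49%, out-toeing the medial midfoot/forefoot by up to 72%/52%, and
  flat foot enlarges the midfoot contact area;
* a gait-cycle temporal model for walking: stance (~60% of the cycle) with
  a heel -> midfoot -> forefoot rolling sequence of raised-cosine
  activation bumps, swing with near-zero pressure, cadence ~2 steps/s;
* quasi-constant standing pressure with slow postural sway and a
  per-trial posture perturbation (children rarely stand still naturally);
* between-subject bodyweight variation (features are later unit-normalized
  precisely to cancel it) and truncated-Gaussian sensor noise;
* children's pressure range 0-700 kPa and spectral content confined to
  0-10 Hz.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .recording import CLASS_ORDER, GRID_SHAPE, PressureRecording

REGION_NAMES = (
    "medial_forefoot",
    "lateral_forefoot",
    "medial_midfoot",
    "lateral_midfoot",
    "heel",
    "off_foot",
)

#: Fraction of the gait cycle spent in stance.
STANCE_FRACTION = 0.6

#: Upper end of the children's plantar-pressure range, kPa.
PRESSURE_MAX_KPA = 700.0


@dataclass(frozen=True)
class FootRegionMap:
    """Assignment of every 8x8 cell to an anatomical region.

    ``codes`` holds indices into :data:`REGION_NAMES`.  Row 0 is the heel
    end, row 7 the toes; column 0 is the medial edge, column 7 lateral.
    """

    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        if codes.shape != GRID_SHAPE:
            raise ValueError("region map must be 8x8")
        if codes.min() < 0 or codes.max() >= len(REGION_NAMES):
            raise ValueError("unknown region code")
        object.__setattr__(self, "codes", codes)

    def mask(self, region: str) -> np.ndarray:
        """Boolean 8x8 mask of one region."""
        return self.codes == REGION_NAMES.index(region)

    @property
    def on_foot(self) -> np.ndarray:
        return ~self.mask("off_foot")


def default_region_map() -> FootRegionMap:
    """Foot-shaped default layout: heel rows 0-1, midfoot 2-3, forefoot 4-7."""
    mf, lf, mm, lm, heel, off = range(6)
    codes = np.full(GRID_SHAPE, off, dtype=int)
    codes[0:2, 2:6] = heel
    codes[2:4, 1:4] = mm
    codes[2:4, 4:7] = lm
    codes[4:8, 1:4] = mf
    codes[4:8, 4:7] = lf
    codes[5:7, 0] = mf
    codes[5:7, 7] = lf
    return FootRegionMap(codes)


@dataclass(frozen=True)
class FootTypeTemplate:
    """Spatial load distribution of one foot type (weights sum to 1)."""

    label: str
    spatial_weights: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown gait label {self.label!r}")
        w = np.asarray(self.spatial_weights, dtype=float)
        if w.shape != GRID_SHAPE:
            raise ValueError("spatial_weights must be 8x8")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "spatial_weights", w)


def base_normal_template(region_map: FootRegionMap | None = None) -> FootTypeTemplate:
    """Normal-foot template: heel ~30%, midfoot ~10%, forefoot ~60% of load.

    The medial arch (the two medial-most midfoot columns) carries no load in
    a normally arched foot; the flat template later activates those cells.
    """
    rm = region_map or default_region_map()
    w = np.zeros(GRID_SHAPE)
    w[rm.mask("heel")] = 0.30 / rm.mask("heel").sum()
    # arch: medial midfoot cells in columns 1-2 stay at zero
    mm = rm.mask("medial_midfoot").copy()
    arch = np.zeros(GRID_SHAPE, dtype=bool)
    arch[:, :3] = True
    mm_loaded = mm & ~arch
    w[mm_loaded] = 0.03 / max(mm_loaded.sum(), 1)
    lm = rm.mask("lateral_midfoot")
    w[lm] = 0.07 / lm.sum()
    mf = rm.mask("medial_forefoot")
    w[mf] = 0.32 / mf.sum()
    lf = rm.mask("lateral_forefoot")
    w[lf] = 0.28 / lf.sum()
    return FootTypeTemplate("normal", w / w.sum())


# Regional amplification factors for the pathological templates: in-toeing
# loads the lateral midfoot/forefoot up to 1.61x/1.49x, out-toeing the
# medial midfoot/forefoot up to 1.72x/1.52x.
TOE_IN_FACTORS = {"lateral_midfoot": 1.61, "lateral_forefoot": 1.49}
TOE_OUT_FACTORS = {"medial_midfoot": 1.72, "medial_forefoot": 1.52}


def make_template(
    label: str,
    region_map: FootRegionMap | None = None,
    base: FootTypeTemplate | None = None,
) -> FootTypeTemplate:
    """Build the spatial template for a gait class from the normal base."""
    rm = region_map or default_region_map()
    base = base or base_normal_template(rm)
    if label == "normal":
        return base
    w = base.spatial_weights.copy()
    if label == "toe_in":
        for region, f in TOE_IN_FACTORS.items():
            w[rm.mask(region)] *= f
    elif label == "toe_out":
        for region, f in TOE_OUT_FACTORS.items():
            w[rm.mask(region)] *= f
    elif label == "flat":
        # collapse of the medial arch: previously unloaded midfoot cells
        # come into contact at the mean loaded-midfoot level
        mid = rm.mask("medial_midfoot") | rm.mask("lateral_midfoot")
        loaded = mid & (w > 0)
        newly = mid & (w == 0)
        w[newly] = w[loaded].mean()
        w[mid] *= 1.3  # flat feet also shift load toward the midfoot
    else:
        raise ValueError(f"unknown gait label {label!r}")
    return FootTypeTemplate(label, w / w.sum())


#: Foot-progression-angle band of a normal gait, degrees.
FPA_NORMAL_RANGE = (-3.0, 20.0)


@dataclass(frozen=True)
class SubjectParams:
    """Anthropometrics and diagnosis of one simulated child."""

    subject_id: str
    mass: float  # kg
    cadence: float = 2.0  # steps/s
    fpa: float = 10.0  # foot progression angle, degrees
    diagnosis: str = "normal"

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError("mass must be positive")
        if not self.cadence > 0:
            raise ValueError("cadence must be positive")
        if self.diagnosis not in CLASS_ORDER:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        lo, hi = FPA_NORMAL_RANGE
        ok = {
            "normal": lo <= self.fpa <= hi,
            "toe_in": self.fpa < lo,
            "toe_out": self.fpa > hi,
            "flat": True,  # flat foot is an arch condition, any FPA
        }[self.diagnosis]
        if not ok:
            raise ValueError(
                f"fpa {self.fpa} inconsistent with diagnosis {self.diagnosis}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings shared by the dynamic and static generators.

    noise_sd is i.i.d. truncated-Gaussian sensor noise per on-foot cell per
    frame (kPa).  kpa_per_kg converts body mass to the peak cell pressure
    during stance (default 12 kPa/kg: a 35 kg child peaks around 420 kPa,
    inside the 0-700 kPa children's range).  subject_jitter_sd is a mild
    per-subject multiplicative template perturbation giving each child an
    individual footprint; posture_sd is an additional per-trial regional
    perturbation applied only when standing (children stand unnaturally
    when asked to keep still, which is why the static section is the harder
    one).
    """

    fs: float = 50.0
    duration: float = 12.0
    noise_sd: float = 5.0
    seed: int = 0
    section: str = "dynamic"
    kpa_per_kg: float = 12.0
    subject_jitter_sd: float = 0.05
    posture_sd: float = 0.12
    sway_amp: float = 0.04
    sway_freq: float = 0.3  # Hz

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.section not in ("dynamic", "static"):
            raise ValueError("section must be dynamic or static")


def _subject_template(
    template: FootTypeTemplate, subject: SubjectParams, jitter_sd: float
) -> np.ndarray:
    """Deterministic per-subject footprint: log-normal cell jitter keyed on id."""
    if jitter_sd <= 0:
        return template.spatial_weights
    key = zlib.crc32(subject.subject_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(key)
    w = template.spatial_weights * np.exp(
        rng.normal(0.0, jitter_sd, GRID_SHAPE)
    )
    w[template.spatial_weights == 0] = 0.0
    return w / w.sum()


def _phase_bump(phase: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Raised-cosine activation bump on cycle phase in [0, 1)."""
    d = np.abs(phase - center)
    d = np.minimum(d, 1.0 - d)  # circular distance
    env = np.where(d < half_width, 0.5 * (1.0 + np.cos(np.pi * d / half_width)), 0.0)
    return env


# Stance rolling sequence (cycle-phase centers / half-widths per region);
# heel strikes first, the forefoot pushes off last, all inside the
# STANCE_FRACTION portion of the cycle.
_REGION_TIMING = {
    "heel": (0.13, 0.17),
    "medial_midfoot": (0.30, 0.19),
    "lateral_midfoot": (0.30, 0.19),
    "medial_forefoot": (0.45, 0.17),
    "lateral_forefoot": (0.45, 0.17),
}


def synth_dynamic(
    subject: SubjectParams,
    template: FootTypeTemplate,
    cfg: SimConfig,
    region_map: FootRegionMap | None = None,
) -> PressureRecording:
    """Simulate one walking recording.

    Instantaneous grid = mass-scaled subject template x per-region stance
    envelope + truncated Gaussian noise, clipped to [0, 700] kPa.  With
    zero noise the signal is exactly periodic with period ``fs/cadence``
    frames.
    """
    if cfg.section != "dynamic":
        raise ValueError("cfg.section must be 'dynamic'")
    rm = region_map or default_region_map()
    n = int(round(cfg.duration * cfg.fs))
    if n < cfg.fs / subject.cadence:
        raise ValueError("duration shorter than one gait cycle")
    w = _subject_template(template, subject, cfg.subject_jitter_sd)
    phase = (np.arange(n) / cfg.fs * subject.cadence) % 1.0
    env = np.zeros((n,) + GRID_SHAPE)
    for region, (center, hw) in _REGION_TIMING.items():
        env[:, rm.mask(region)] = _phase_bump(phase, center, hw)[:, None]
    peak = subject.mass * cfg.kpa_per_kg
    frames = peak * (w / w.max())[None] * env
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        noise = rng.normal(0.0, cfg.noise_sd, frames.shape)
        noise[:, ~rm.on_foot] = 0.0
        frames = frames + noise
    frames = np.clip(frames, 0.0, PRESSURE_MAX_KPA)
    return PressureRecording(
        frames,
        cfg.fs,
        subject.subject_id,
        template.label,
        "dynamic",
        meta={"mass": subject.mass, "cadence": subject.cadence, "fpa": subject.fpa},
    )


def synth_static(
    subject: SubjectParams,
    template: FootTypeTemplate,
    cfg: SimConfig,
    region_map: FootRegionMap | None = None,
) -> PressureRecording:
    """Simulate one quiet-standing recording.

    Quasi-constant grid = mass-scaled template (with a per-trial posture
    perturbation) modulated by a slow medial-lateral sway, plus noise.
    With zero noise, zero sway and zero posture perturbation every frame is
    identical.
    """
    if cfg.section != "static":
        raise ValueError("cfg.section must be 'static'")
    rm = region_map or default_region_map()
    n = int(round(cfg.duration * cfg.fs))
    if n < 1:
        raise ValueError("duration too short")
    rng = np.random.default_rng(cfg.seed)
    w = _subject_template(template, subject, cfg.subject_jitter_sd).copy()
    if cfg.posture_sd > 0:
        # per-trial regional weight perturbation (unnatural standing pose)
        for region in REGION_NAMES[:-1]:
            w[rm.mask(region)] *= np.exp(rng.normal(0.0, cfg.posture_sd))
        w /= w.sum()
    # standing load is spread over the whole stance surface; roughly half
    # the walking peak on the loaded cells
    level = 0.5 * subject.mass * cfg.kpa_per_kg
    base = level * (w / max(w.max(), 1e-300))
    t = np.arange(n) / cfg.fs
    lateral = np.linspace(-1.0, 1.0, GRID_SHAPE[1])[None, :].repeat(GRID_SHAPE[0], 0)
    sway = 1.0 + cfg.sway_amp * np.sin(2 * np.pi * cfg.sway_freq * t)[:, None, None] * lateral[None]
    frames = base[None] * sway
    if cfg.noise_sd > 0:
        noise = rng.normal(0.0, cfg.noise_sd, frames.shape)
        noise[:, ~rm.on_foot] = 0.0
        frames = frames + noise
    frames = np.clip(frames, 0.0, PRESSURE_MAX_KPA)
    return PressureRecording(
        frames,
        cfg.fs,
        subject.subject_id,
        template.label,
        "static",
        meta={"mass": subject.mass, "fpa": subject.fpa},
    )


def default_subjects(seed: int = 0) -> list[SubjectParams]:
    """A 17-child roster with the study's diagnosis mix (9 flat, 4 normal,
    2 toe-in, 2 toe-out), masses drawn for ages ~5-10."""
    rng = np.random.default_rng(seed)
    mix = ["flat"] * 9 + ["normal"] * 4 + ["toe_in"] * 2 + ["toe_out"] * 2
    fpa = {"normal": (0.0, 15.0), "toe_in": (-15.0, -5.0), "toe_out": (22.0, 32.0), "flat": (0.0, 15.0)}
    out = []
    for i, diag in enumerate(mix):
        lo, hi = fpa[diag]
        out.append(
            SubjectParams(
                subject_id=f"S{i + 1:02d}",
                mass=float(rng.uniform(18.0, 38.0)),
                cadence=float(rng.uniform(1.8, 2.4)),
                fpa=float(rng.uniform(lo, hi)),
                diagnosis=diag,
            )
        )
    return out


def make_dataset(
    n_per_class: int,
    subjects: list[SubjectParams],
    cfg: SimConfig,
    seed: int | None = None,
    window_width: int = 512,
    window_stride: int = 25,
    segment_length: int = 100,
) -> tuple[list[PressureRecording], dict]:
    """Generate a class-balanced recording collection.

    Durations are computed so that downstream windowing (sliding windows of
    ``window_width`` frames at ``window_stride`` in the dynamic section,
    non-overlapping ``segment_length``-frame segments in the static
    section) yields exactly ``n_per_class`` samples per class.  Recordings
    are split round-robin over the subjects carrying each diagnosis.
    Deterministic under ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seed = cfg.seed if seed is None else seed
    by_class: dict[str, list[SubjectParams]] = {c: [] for c in CLASS_ORDER}
    for s in subjects:
        by_class[s.diagnosis].append(s)
    for c, subs in by_class.items():
        if not subs:
            raise ValueError(f"no subject with diagnosis {c!r}")
    rm = default_region_map()
    ss = np.random.SeedSequence(seed)
    child_seeds = (ss.generate_state(4 * n_per_class * 2, dtype=np.uint64) % (2**31)).astype(int)
    recordings: list[PressureRecording] = []
    manifest: dict = {
        "seed": int(seed),
        "section": cfg.section,
        "n_per_class": int(n_per_class),
        "classes": {},
    }
    k = 0
    for c in CLASS_ORDER:
        subs = by_class[c]
        template = make_template(c, rm)
        per_sub = [n_per_class // len(subs)] * len(subs)
        for i in range(n_per_class % len(subs)):
            per_sub[i] += 1
        entries = []
        for sub, n_samples in zip(subs, per_sub):
            if n_samples == 0:
                continue
            if cfg.section == "dynamic":
                frames_needed = window_width + (n_samples - 1) * window_stride
            else:
                frames_needed = n_samples * segment_length
            duration = frames_needed / cfg.fs
            sub_cfg = replace(cfg, duration=duration, seed=int(child_seeds[k]))
            k += 1
            if cfg.section == "dynamic":
                rec = synth_dynamic(sub, template, sub_cfg, rm)
            else:
                rec = synth_static(sub, template, sub_cfg, rm)
            rec.meta["n_samples"] = n_samples
            recordings.append(rec)
            entries.append(
                {
                    "subject_id": sub.subject_id,
                    "n_frames": rec.n_frames,
                    "n_samples": n_samples,
                }
            )
        manifest["classes"][c] = entries
    return recordings, manifest
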