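"""Synthetic digital brain phantom for STAIR/PD acquisition simulation.

The phantom stands in for in-vivo data: an ellipsoidal brain with a
cortical grey-matter shell, a white-matter core, central CSF "ventricles",
optional multiple-sclerosis-like lesions inside white matter, and eight
procedurally placed white-matter sub-regions mirroring the regions used
for ROI quantification (centrum semiovale, subcortical WM, periventricular
WM, splenium, genu -- left/right).  Anatomical fidelity is a non-goal; the
geometry exists so that masking, ROI extraction and group statistics can
be exercised end to end.

Each voxel holds a two-compartment tissue: myelin water (T1 = 220 ms,
T2* = 10 ms, partial inversion) and a long-T1 water pool.  Two forward
modes are supported:

``model_matched``
    The acquisition equals the quantification model exactly -- the STAIR
    image contains only the myelin-water term and the PD image decays with
    the estimator's single T2*.  Noise-free simulation followed by
    quantification recovers the ground-truth aMWF to machine precision.

``two_pool``
    Both pools contribute to both images, so residual (incompletely
    suppressed) long-T1 signal leaks into the STAIR image and biases the
    apparent MWF upward -- the "apparent" in aMWF.

Noise is Rician: independent complex Gaussian deviates per excitation are
averaged in the complex domain (as a scanner's NEX averaging does) before
the magnitude is taken.  ``noise_sigma`` is expressed relative to the
noiseless PD signal of white matter, i.e. ``noise_sigma = 0.01`` means a
single-excitation PD-image SNR of 100 in white matter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stairmwi.errors import ConfigError, DomainError, PlacementError
from stairmwi.params import (
    PD_PROTOCOL,
    STAIR_PROTOCOL,
    QuantConstants,
    RelaxationPool,
    SequenceParams,
)
from stairmwi.signal_model import mw_signal_scale, pd_signal, stair_steady_state_signal

__all__ = [
    "TissueClassParams",
    "PhantomSpec",
    "ImageVolume",
    "default_tissue_classes",
    "build_label_map",
    "simulate_acquisition",
    "simulate_cohort",
    "simulate_study",
    "TISSUE_CODES",
    "ROI_NAMES",
]

#: Integer codes of the tissue label volume.
TISSUE_CODES = {"background": 0, "WM": 1, "GM": 2, "CSF": 3, "lesion": 4}

#: Names of the eight white-matter sub-regions (ROI codes 1..8).
ROI_NAMES = [
    "centrum_semiovale_L", "centrum_semiovale_R",
    "subcortical_wm_L", "subcortical_wm_R",
    "periventricular_L", "periventricular_R",
    "splenium", "genu",
]

# ROI sphere centres as offsets from the brain centre, in voxels
# (in-plane radius 3, through-plane half-extent 1.5).
_ROI_OFFSETS = [
    (-12, -10, 0), (12, -10, 0),
    (-17, 5, 1), (17, 5, 1),
    (-9, 0, 0), (9, 0, 0),
    (0, 15, -1), (0, -15, -1),
]
_ROI_RADIUS = (3.0, 3.0, 1.5)


@dataclass(frozen=True)
class TissueClassParams:
    """Ground-truth parameters of one tissue class.

    ``amwf_true`` is the myelin water fraction; the long pool carries the
    remaining ``(1 - amwf_true) * m0_total`` magnetization with relaxation
    times ``t1_long_ms`` / ``t2s_long_ms``.  ``amwf_subject_sd`` is the
    between-subject standard deviation applied by the cohort simulator.
    """

    name: str
    amwf_true: float
    t1_long_ms: float
    t2s_long_ms: float = 60.0
    t1_mw_ms: float = 220.0
    t2s_mw_ms: float = 10.0
    m0_total: float = 0.7
    amwf_subject_sd: float = 0.013

    def __post_init__(self) -> None:
        if not 0.0 <= self.amwf_true <= 0.5:
            raise DomainError(f"amwf_true must be in [0, 0.5], got {self.amwf_true}")
        if not 300.0 <= self.t1_long_ms <= 5000.0:
            raise DomainError(
                f"t1_long_ms must be in [300, 5000] ms, got {self.t1_long_ms}"
            )

    def replace(self, **kw) -> "TissueClassParams":
        return dataclasses.replace(self, **kw)


def default_tissue_classes(group: str = "healthy") -> dict[str, TissueClassParams]:
    """Default tissue table keyed by tissue-label name.

    ``group="healthy"`` uses normal white matter (aMWF 9.9%); ``"patient"``
    uses normal-appearing white matter (8.5%) and adds the lesion class
    (3.6%).  White-matter T1 sits in the reported 750-1000 ms band and
    grey matter in the 1300-1800 ms band; CSF and grey-matter values are
    editorial defaults.
    """
    wm_healthy = TissueClassParams("WM", amwf_true=0.099, t1_long_ms=850.0,
                                   m0_total=0.7, amwf_subject_sd=0.013)
    wm_patient = TissueClassParams("WM", amwf_true=0.085, t1_long_ms=900.0,
                                   m0_total=0.7, amwf_subject_sd=0.012)
    gm = TissueClassParams("GM", amwf_true=0.03, t1_long_ms=1500.0,
                           t2s_long_ms=65.0, m0_total=0.8,
                           amwf_subject_sd=0.005)
    csf = TissueClassParams("CSF", amwf_true=0.0, t1_long_ms=4000.0,
                            t2s_long_ms=500.0, m0_total=1.0,
                            amwf_subject_sd=0.0)
    lesion = TissueClassParams("lesion", amwf_true=0.036, t1_long_ms=1100.0,
                               t2s_long_ms=80.0, m0_total=0.7,
                               amwf_subject_sd=0.013)
    if group == "healthy":
        return {"WM": wm_healthy, "GM": gm, "CSF": csf}
    if group == "patient":
        return {"WM": wm_patient, "GM": gm, "CSF": csf, "lesion": lesion}
    raise ConfigError(f"unknown group {group!r}")


@dataclass(frozen=True)
class ImageVolume:
    """3-D scalar field with voxel size and orientation metadata."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.72, 1.72, 5.0)
    affine: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise DomainError("ImageVolume data must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise DomainError("ImageVolume data must be finite")
        if self.affine is None:
            aff = np.diag(list(self.voxel_mm) + [1.0])
            object.__setattr__(self, "affine", aff)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray, **meta) -> "ImageVolume":
        return ImageVolume(data=data, voxel_mm=self.voxel_mm,
                           affine=self.affine.copy(),
                           meta={**self.meta, **meta})


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and simulation settings of the digital brain."""

    shape: tuple[int, int, int] = (64, 64, 15)
    voxel_mm: tuple[float, float, float] = (1.72, 1.72, 5.0)
    n_lesions: int = 0
    lesion_radius_vox: tuple[float, float] = (2.0, 3.0)
    noise_sigma: float = 0.01
    mode: str = "model_matched"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise DomainError("n_lesions must be >= 0")
        if self.mode not in ("model_matched", "two_pool"):
            raise ConfigError(f"unknown simulation mode {self.mode!r}")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


def _ellipsoid_mask(shape, centre, semi_axes) -> np.ndarray:
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = ((ii - centre[0]) / semi_axes[0]) ** 2 \
        + ((jj - centre[1]) / semi_axes[1]) ** 2 \
        + ((kk - centre[2]) / semi_axes[2]) ** 2
    return r2 <= 1.0


def build_label_map(spec: PhantomSpec) -> ImageVolume:
    """Deterministic tissue label volume plus ROI / lesion maps.

    Returns an ImageVolume of integer tissue codes (see ``TISSUE_CODES``)
    whose ``meta`` carries ``roi_map`` (codes 1..8, the WM sub-regions,
    zero elsewhere), ``roi_names``, and ``lesion_map`` (one positive code
    per lesion).  Lesions are placed inside white matter by seeded
    rejection sampling, avoiding each other and the ROI spheres.
    """
    nx, ny, nz = spec.shape
    centre = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    brain_axes = (0.82 * nx / 2.0, 0.92 * ny / 2.0, 0.95 * nz / 2.0)

    brain = _ellipsoid_mask(spec.shape, centre, brain_axes)
    inner = _ellipsoid_mask(
        spec.shape, centre, tuple(0.78 * a for a in brain_axes))
    csf = _ellipsoid_mask(spec.shape, centre, (5.0, 9.0, 3.0))

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[brain] = TISSUE_CODES["GM"]
    labels[inner] = TISSUE_CODES["WM"]
    labels[csf & brain] = TISSUE_CODES["CSF"]

    roi_map = np.zeros(spec.shape, dtype=np.int16)
    for code, (dx, dy, dz) in enumerate(_ROI_OFFSETS, start=1):
        c = (centre[0] + dx, centre[1] + dy, centre[2] + dz)
        sphere = _ellipsoid_mask(spec.shape, c, _ROI_RADIUS)
        sphere &= labels == TISSUE_CODES["WM"]
        roi_map[sphere] = code

    lesion_map = np.zeros(spec.shape, dtype=np.int16)
    if spec.n_lesions > 0:
        rng = np.random.default_rng(spec.seed)
        placed = 0
        blocked = (labels != TISSUE_CODES["WM"]) | (roi_map > 0)
        for _ in range(1000):
            if placed == spec.n_lesions:
                break
            r = rng.uniform(*spec.lesion_radius_vox)
            c = (rng.uniform(2, nx - 3), rng.uniform(2, ny - 3),
                 rng.uniform(1, nz - 2))
            sphere = _ellipsoid_mask(spec.shape, c, (r, r, max(r / 2.0, 1.0)))
            if sphere.sum() < 4:
                continue
            if np.any(sphere & blocked) or np.any(sphere & (lesion_map > 0)):
                continue
            placed += 1
            lesion_map[sphere] = placed
            labels[sphere] = TISSUE_CODES["lesion"]
        if placed < spec.n_lesions:
            raise PlacementError(
                f"placed only {placed}/{spec.n_lesions} lesions after 1000 tries"
            )

    return ImageVolume(
        data=labels, voxel_mm=spec.voxel_mm,
        meta={
            "kind": "labels",
            "roi_map": roi_map,
            "roi_names": list(ROI_NAMES),
            "lesion_map": lesion_map,
            "seed": spec.seed,
        },
    )


def _noiseless_signals(
    labels: ImageVolume,
    classes: dict[str, TissueClassParams],
    seq: SequenceParams,
    constants: QuantConstants,
    mode: str,
) -> np.ndarray:
    """Per-voxel noiseless (signed) signal for one acquisition."""
    is_stair = seq.ti_ms is not None
    out = np.zeros(labels.shape, dtype=float)
    for name, cls in classes.items():
        code = TISSUE_CODES[name]
        sel = labels.data == code
        if not np.any(sel):
            continue
        m0_mw = cls.m0_total * cls.amwf_true
        m0_long = cls.m0_total * (1.0 - cls.amwf_true)
        if mode == "model_matched":
            if is_stair:
                s = m0_mw * mw_signal_scale(constants, seq)
            else:
                s = cls.m0_total * np.exp(-seq.te_ms / constants.t2s_total_ms)
        elif mode == "two_pool":
            mw = RelaxationPool(m0=m0_mw, t1_ms=cls.t1_mw_ms,
                                t2s_ms=cls.t2s_mw_ms, q=constants.q_mw)
            lw = RelaxationPool(m0=m0_long, t1_ms=cls.t1_long_ms,
                                t2s_ms=cls.t2s_long_ms, q=constants.q_long)
            if is_stair:
                s = stair_steady_state_signal(mw, seq) \
                    + stair_steady_state_signal(lw, seq)
            else:
                s = pd_signal(mw, seq) + pd_signal(lw, seq)
        else:
            raise ConfigError(f"unknown simulation mode {mode!r}")
        out[sel] = s
    return out


def _wm_pd_reference(
    classes: dict[str, TissueClassParams],
    seq_te_ms: float,
    constants: QuantConstants,
) -> float:
    """PD signal of white matter: the reference for relative noise levels."""
    wm = classes.get("WM")
    if wm is None:
        wm = max(classes.values(), key=lambda c: c.m0_total)
    return wm.m0_total * float(np.exp(-seq_te_ms / constants.t2s_total_ms))


def simulate_acquisition(
    labels: ImageVolume,
    classes: dict[str, TissueClassParams],
    seq: SequenceParams,
    constants: QuantConstants,
    mode: str = "model_matched",
    noise_sigma: float = 0.0,
    seed: int = 0,
    noise_average: str = "complex",
) -> ImageVolume:
    """Simulate one acquisition of the labelled phantom.

    ``noise_sigma`` is the per-excitation complex-channel noise SD relative
    to the white-matter PD signal.  The ``seq.nex`` excitations are
    averaged in the complex domain before taking the magnitude
    (``noise_average="magnitude"`` averages magnitudes instead, which
    raises the Rician floor).  With ``noise_sigma=0`` the signed noiseless
    signal is returned.
    """
    noiseless = _noiseless_signals(labels, classes, seq, constants, mode)
    if noise_sigma == 0.0:
        return labels.with_data(
            noiseless, kind="acquisition", sequence=seq.label, nex=seq.nex,
            mode=mode, noise_sigma=0.0, seed=seed,
        )

    sigma = noise_sigma * _wm_pd_reference(classes, seq.te_ms, constants)
    rng = np.random.default_rng(seed)
    nex = seq.nex
    shape = (nex,) + noiseless.shape
    real = noiseless[None, ...] + rng.normal(0.0, sigma, size=shape)
    imag = rng.normal(0.0, sigma, size=shape)
    if noise_average == "complex":
        data = np.abs(real.mean(axis=0) + 1j * imag.mean(axis=0))
    elif noise_average == "magnitude":
        data = np.hypot(real, imag).mean(axis=0)
    else:
        raise ConfigError(f"unknown noise_average {noise_average!r}")
    return labels.with_data(
        data, kind="acquisition", sequence=seq.label, nex=seq.nex,
        mode=mode, noise_sigma=noise_sigma, seed=seed,
    )


def _jittered_classes(
    classes: dict[str, TissueClassParams], rng: np.random.Generator
) -> dict[str, TissueClassParams]:
    out = {}
    for name, cls in classes.items():
        amwf = cls.amwf_true + rng.normal(0.0, cls.amwf_subject_sd) \
            if cls.amwf_subject_sd > 0 else cls.amwf_true
        out[name] = cls.replace(amwf_true=float(np.clip(amwf, 0.0, 0.5)))
    return out


def simulate_cohort(
    spec: PhantomSpec,
    n_subjects: int,
    seq_stair: SequenceParams = STAIR_PROTOCOL,
    seq_pd: SequenceParams = PD_PROTOCOL,
    constants: QuantConstants = QuantConstants(),
    classes: dict[str, TissueClassParams] | None = None,
    group: str = "healthy",
    master_seed: int = 0,
) -> list[dict]:
    """Simulate a cohort of subjects sharing one phantom geometry spec.

    Each subject's class aMWFs are jittered by the class's between-subject
    SD using a subject-indexed seed stream, then STAIR and PD volumes are
    simulated.  Returns one dict per subject with keys ``subject_id``,
    ``group``, ``stair``, ``pd``, ``labels``, ``classes`` (the jittered
    truth) and ``truth`` (a tidy DataFrame of class ground-truth aMWFs).
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    if classes is None:
        classes = default_tissue_classes(group)
    subjects = []
    seed_seq = np.random.SeedSequence(master_seed)
    child_seeds = seed_seq.spawn(n_subjects)
    for i, child in enumerate(child_seeds):
        sub_rng = np.random.default_rng(child)
        geom_seed = int(sub_rng.integers(0, 2**31 - 1))
        sub_spec = spec.replace(seed=geom_seed)
        labels = build_label_map(sub_spec)
        sub_classes = _jittered_classes(classes, sub_rng)
        stair_seed = int(sub_rng.integers(0, 2**31 - 1))
        pd_seed = int(sub_rng.integers(0, 2**31 - 1))
        stair = simulate_acquisition(
            labels, sub_classes, seq_stair, constants, mode=spec.mode,
            noise_sigma=spec.noise_sigma, seed=stair_seed)
        pdvol = simulate_acquisition(
            labels, sub_classes, seq_pd, constants, mode=spec.mode,
            noise_sigma=spec.noise_sigma, seed=pd_seed)
        truth = pd.DataFrame(
            [{"subject_id": f"{group}-{i + 1:02d}", "class": n,
              "amwf_true": c.amwf_true, "t1_long_ms": c.t1_long_ms,
              "m0_total": c.m0_total}
             for n, c in sub_classes.items()]
        )
        subjects.append({
            "subject_id": f"{group}-{i + 1:02d}", "group": group,
            "stair": stair, "pd": pdvol, "labels": labels,
            "classes": sub_classes, "truth": truth,
        })
    return subjects


def simulate_study(
    spec: PhantomSpec | None = None,
    n_healthy: int = 7,
    n_patients: int = 7,
    n_lesions_per_patient: int = 9,
    seq_stair: SequenceParams = STAIR_PROTOCOL,
    seq_pd: SequenceParams = PD_PROTOCOL,
    constants: QuantConstants = QuantConstants(),
    master_seed: int = 0,
) -> list[dict]:
    """Simulate the full two-group study: healthy volunteers plus patients.

    Healthy subjects carry normal white matter and no lesions; patients
    carry normal-appearing white matter and ``n_lesions_per_patient``
    lesions each (the study quantified 66 lesions across 7 patients).
    """
    spec = spec or PhantomSpec()
    healthy = simulate_cohort(
        spec.replace(n_lesions=0), n_healthy, seq_stair, seq_pd, constants,
        group="healthy", master_seed=master_seed,
    )
    patients = simulate_cohort(
        spec.replace(n_lesions=n_lesions_per_patient), n_patients,
        seq_stair, seq_pd, constants, group="patient",
        master_seed=master_seed + 10_007,
    )
    return healthy + patients
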