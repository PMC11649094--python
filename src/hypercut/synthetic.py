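"""Synthetic hyperspectral palm cubes with ground-truth identity.

The forward model is a Beer-Lambert-style multiplicative attenuation on a
smooth per-subject baseline spectrum:

    R(r, c, l) = B(l) * exp(-[ m * patch(r,c) * w_short(l)
                              + vein(r,c)  * w_long(l)
                              + crease(r,c) * w_broad(l) ]) * gain + noise

chosen as the simplest model reproducing the qualitative structure of real
palm hyperspectra: a reflectance baseline darker below ~600 nm and brighter
above ~650 nm with roll-off at the spectral edges; a patchy short-wavelength
absorber field (superficial capillaries / pigment); curvilinear vein-like
absorbers expressed above ~700 nm; and thin palm-line creases absorbing
broadband, which appear as shadow stripes perpendicular to the cut line in
the cross-section.  No radiative-transfer realism is claimed.

Every subject is a deterministic function of its seed; every capture applies
a small rigid perturbation (translation, rotation, illumination gain) plus
sensor noise, with the 21 hand landmarks transformed consistently so the
line ROI tracks the same anatomical cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ContractError
from .hypercube import REFERENCE_WAVELENGTHS_NM, Hypercube
from .roi import HandLandmarks

DEFAULT_SHAPE = (256, 256)

# Canonical 21-point hand layout in unit (row, col) coordinates: wrist at the
# bottom center, finger bases in the upper third, fingertips near the top.
# Only the relative geometry of #0, #9, #13 matters to the pipeline; the rest
# make the set a plausible MediaPipe-style hand.
_CANONICAL_LANDMARKS = np.array([
    [0.86, 0.50],                                   # 0 wrist
    [0.78, 0.33], [0.68, 0.24], [0.58, 0.18], [0.50, 0.14],   # 1-4 thumb
    [0.42, 0.32], [0.30, 0.30], [0.22, 0.29], [0.15, 0.28],   # 5-8 index
    [0.40, 0.44], [0.26, 0.43], [0.17, 0.43], [0.09, 0.42],   # 9-12 middle
    [0.40, 0.56], [0.28, 0.57], [0.19, 0.58], [0.12, 0.58],   # 13-16 ring
    [0.42, 0.68], [0.32, 0.71], [0.25, 0.73], [0.19, 0.75],   # 17-20 little
])


def spectral_weight_short(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Absorber weight supported below ~600 nm (superficial patchy field)."""
    w = np.asarray(wavelengths_nm, dtype=float)
    return 1.0 / (1.0 + np.exp((w - 590.0) / 20.0))


def spectral_weight_long(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Absorber weight supported above ~700 nm (deep vein-like structures)."""
    w = np.asarray(wavelengths_nm, dtype=float)
    return 1.0 / (1.0 + np.exp(-(w - 720.0) / 25.0))


def spectral_weight_broad(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Flat broadband weight (surface creases / palm lines)."""
    return np.ones_like(np.asarray(wavelengths_nm, dtype=float))


@dataclass
class SubjectModel:
    """Generative parameters of one synthetic identity."""

    subject_id: str
    seed: int
    shape: tuple[int, int]
    wavelengths_nm: np.ndarray
    baseline_spectrum: np.ndarray      # reflectance per band, in (0, 1]
    patch_field: np.ndarray            # optical density, short-wavelength absorber
    vein_field: np.ndarray             # optical density, long-wavelength absorber
    crease_field: np.ndarray           # optical density, broadband absorber
    vein_set: list = field(default_factory=list)     # polyline paths (k, 2) arrays
    crease_set: list = field(default_factory=list)   # ((r0,c0),(r1,c1)) segments
    melanin_scale: float = 1.0


@dataclass
class CaptureParams:
    """Per-capture placement jitter and sensor settings (small by default)."""

    translation: tuple[float, float] = (0.0, 0.0)   # (drow, dcol) px, |d| <= 5 typical
    rotation_deg: float = 0.0                       # |rot| <= 10 typical
    illumination_gain: float = 1.0                  # in [0.9, 1.1] typical
    noise_sd: float = 0.01                          # reflectance units
    seed: int = 0


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return f


def _rasterize_path(points: np.ndarray, shape, width: float, strength: float) -> np.ndarray:
    """Deposit a polyline onto a field and blur it into a tube of ~width px."""
    field = np.zeros(shape)
    # dense resampling so the deposited line has no gaps
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    n_dense = max(int(seg_len.sum() * 2), 2)
    t = np.linspace(0.0, 1.0, n_dense)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    if cum[-1] == 0:
        return field
    dense_r = np.interp(t * cum[-1], cum, points[:, 0])
    dense_c = np.interp(t * cum[-1], cum, points[:, 1])
    rr = np.clip(np.round(dense_r).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(dense_c).astype(int), 0, shape[1] - 1)
    field[rr, cc] = 1.0
    field = ndimage.gaussian_filter(field, width, mode="constant")
    if field.max() > 0:
        field *= strength / field.max()
    return field


def make_subject(
    subject_seed: int,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    wavelengths_nm=REFERENCE_WAVELENGTHS_NM,
    subject_id: str | None = None,
) -> SubjectModel:
    """Draw one identity: baseline spectrum, patch field, veins, creases.

    Deterministic per seed; distinct seeds give distinct geometry with
    overwhelming probability.
    """
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if len(wavelengths_nm) < 2 or wavelengths_nm[-1] - wavelengths_nm[0] < 200.0:
        raise ContractError("need >= 2 bands spanning >= 200 nm")
    if min(shape) < 32:
        raise ContractError(f"raster {shape} too small for a palm model")
    rng = np.random.default_rng(subject_seed)

    # baseline: low plateau below ~600 nm, high above ~650, edge roll-off
    low = rng.uniform(0.12, 0.28)
    high = rng.uniform(0.50, 0.78)
    center = rng.uniform(610.0, 640.0)
    widthnm = rng.uniform(18.0, 30.0)
    base = low + (high - low) / (1.0 + np.exp(-(wavelengths_nm - center) / widthnm))
    rolloff = 1.0 / (1.0 + np.exp(-(wavelengths_nm - 412.0) / 8.0))
    rolloff *= 1.0 / (1.0 + np.exp((wavelengths_nm - 985.0) / 10.0))
    wiggle = ndimage.gaussian_filter1d(rng.standard_normal(len(wavelengths_nm)), 6.0, mode="reflect")
    baseline = np.clip(base * (0.15 + 0.85 * rolloff) * (1.0 + 0.03 * wiggle), 1e-3, 1.0)

    patch = _smooth_field(rng, shape, sigma=rng.uniform(6.0, 10.0)) * rng.uniform(0.35, 0.6)

    vein_field = np.zeros(shape)
    vein_set = []
    for _ in range(int(rng.integers(3, 6))):
        start = np.array([rng.uniform(0.1, 0.9) * shape[0], rng.uniform(0.05, 0.3) * shape[1]])
        heading = rng.uniform(-0.5, 0.5)           # radians around the col axis
        n_pts = 40
        step = shape[1] * 0.8 / n_pts
        turns = ndimage.gaussian_filter1d(rng.standard_normal(n_pts), 4.0) * 0.25
        pts = [start]
        h = heading
        for k in range(n_pts - 1):
            h += turns[k] * 0.3
            pts.append(pts[-1] + step * np.array([np.sin(h), np.cos(h)]))
        path = np.array(pts)
        vein_set.append(path)
        vein_field += _rasterize_path(path, shape, width=rng.uniform(2.0, 4.0),
                                      strength=rng.uniform(0.5, 1.1))

    crease_field = np.zeros(shape)
    crease_set = []
    for _ in range(int(rng.integers(2, 5))):
        p0 = np.array([rng.uniform(0.15, 0.85) * shape[0], rng.uniform(0.05, 0.5) * shape[1]])
        ang = rng.uniform(-0.9, 0.9)
        length = rng.uniform(0.4, 0.9) * shape[1]
        p1 = p0 + length * np.array([np.sin(ang), np.cos(ang)])
        crease_set.append((tuple(p0), tuple(p1)))
        crease_field += _rasterize_path(np.array([p0, p1]), shape, width=1.5,
                                        strength=rng.uniform(0.10, 0.25))

    return SubjectModel(
        subject_id=subject_id or f"S{subject_seed}",
        seed=int(subject_seed),
        shape=tuple(shape),
        wavelengths_nm=wavelengths_nm,
        baseline_spectrum=baseline,
        patch_field=patch,
        vein_field=vein_field,
        crease_field=crease_field,
        vein_set=vein_set,
        crease_set=crease_set,
        melanin_scale=float(rng.uniform(0.8, 1.2)),
    )


def _rigid_transform_field(fieldarr: np.ndarray, rotation_deg: float, translation) -> np.ndarray:
    """Rotate about the raster center then translate; linear interp, zero fill."""
    if rotation_deg == 0.0 and tuple(translation) == (0.0, 0.0):
        return fieldarr
    theta = np.deg2rad(rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    center = (np.array(fieldarr.shape) - 1) / 2.0
    # output -> input mapping: x = R^-1 (y - t - center) + center
    rot_inv = np.array([[c, s], [-s, c]])
    offset = center - rot_inv @ (center + np.asarray(translation, dtype=float))
    return ndimage.affine_transform(fieldarr, rot_inv, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def transform_points(points: np.ndarray, rotation_deg: float, translation, shape) -> np.ndarray:
    """Forward rigid map applied to (row, col) points: rotate about center, translate."""
    theta = np.deg2rad(rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    center = (np.array(shape, dtype=float) - 1) / 2.0
    return (points - center) @ rot.T + center + np.asarray(translation, dtype=float)


def render_capture(model: SubjectModel, cap: CaptureParams | None = None) -> tuple[Hypercube, HandLandmarks]:
    """Render one capture of a subject: reflectance cube plus landmarks.

    The subject's absorber fields are rigidly transformed by the capture's
    (rotation, translation); the landmarks undergo the same forward map, so
    the anatomical cut line moves with the palm.
    """
    cap = cap or CaptureParams()
    w = model.wavelengths_nm
    patch = _rigid_transform_field(model.patch_field * model.melanin_scale,
                                   cap.rotation_deg, cap.translation).astype(np.float32)
    vein = _rigid_transform_field(model.vein_field, cap.rotation_deg, cap.translation).astype(np.float32)
    crease = _rigid_transform_field(model.crease_field, cap.rotation_deg, cap.translation).astype(np.float32)

    ws = spectral_weight_short(w).astype(np.float32)
    wl = spectral_weight_long(w).astype(np.float32)
    wb = spectral_weight_broad(w).astype(np.float32)

    od = (patch[:, :, None] * ws[None, None, :]
          + vein[:, :, None] * wl[None, None, :]
          + crease[:, :, None] * wb[None, None, :])
    refl = model.baseline_spectrum.astype(np.float32)[None, None, :] * np.exp(-od, dtype=np.float32)
    refl *= np.float32(cap.illumination_gain)
    if cap.noise_sd > 0:
        rng = np.random.default_rng(cap.seed)
        refl = refl + rng.normal(0.0, cap.noise_sd, refl.shape).astype(np.float32)
    refl = np.clip(refl, 1e-4, 1.0)

    lm_canon = _CANONICAL_LANDMARKS * (np.array(model.shape, dtype=float) - 1)
    lm_pts = transform_points(lm_canon, cap.rotation_deg, cap.translation, model.shape)
    landmarks = HandLandmarks(points=lm_pts, source=f"synthetic:{model.subject_id}")
    cube = Hypercube(data=refl, wavelengths_nm=w,
                     meta={"subject_id": model.subject_id, "synthetic": True})
    return cube, landmarks


@dataclass
class CaptureRecord:
    cube: Hypercube
    landmarks: HandLandmarks
    subject_id: str
    capture_id: str


class SyntheticDataset:
    """Lazily rendering sequence of capture records.

    Each record is rendered deterministically from (master_seed, subject index,
    capture index) on access, so iterating twice — or in a fresh process —
    yields byte-identical cubes without holding the whole cohort in memory.
    """

    def __init__(self, models, params, records):
        self._models = models          # subject index -> SubjectModel
        self._params = params          # flat capture index -> CaptureParams
        self._records = records        # flat index -> (subject_idx, subject_id, capture_id)

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, i: int) -> CaptureRecord:
        si, subject_id, capture_id = self._records[i]
        cube, lms = render_capture(self._models[si], self._params[i])
        return CaptureRecord(cube=cube, landmarks=lms, subject_id=subject_id, capture_id=capture_id)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def subject_ids(self):
        return [r[1] for r in self._records]

    @property
    def capture_ids(self):
        return [r[2] for r in self._records]


def make_dataset(
    n_subjects: int = 10,
    n_captures: int = 10,
    master_seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    wavelengths_nm=REFERENCE_WAVELENGTHS_NM,
    max_translation_px: float = 5.0,
    max_rotation_deg: float = 10.0,
    gain_range: tuple[float, float] = (0.9, 1.1),
    noise_sd: float = 0.01,
) -> SyntheticDataset:
    """A cohort of ``n_subjects`` x ``n_captures`` synthetic palm captures.

    Subject models and capture jitter are derived from ``master_seed`` through
    independent seed sequences, so the dataset is fully reproducible.
    """
    if n_subjects < 2 or n_captures < 2:
        raise ContractError("need at least 2 subjects and 2 captures each")
    models = []
    params = []
    records = []
    for si in range(n_subjects):
        sseed = int(np.random.SeedSequence([master_seed, si]).generate_state(1)[0] % (2**31))
        models.append(make_subject(sseed, shape=shape, wavelengths_nm=wavelengths_nm,
                                   subject_id=f"S{si:02d}"))
        for ci in range(n_captures):
            crng = np.random.default_rng(np.random.SeedSequence([master_seed, si, 1 + ci]))
            params.append(CaptureParams(
                translation=(crng.uniform(-max_translation_px, max_translation_px),
                             crng.uniform(-max_translation_px, max_translation_px)),
                rotation_deg=float(crng.uniform(-max_rotation_deg, max_rotation_deg)),
                illumination_gain=float(crng.uniform(*gain_range)),
                noise_sd=noise_sd,
                seed=int(crng.integers(0, 2**31)),
            ))
            records.append((si, f"S{si:02d}", f"S{si:02d}_C{ci:02d}"))
    return SyntheticDataset(models, params, records)
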