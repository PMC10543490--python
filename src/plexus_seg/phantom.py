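"""Synthetic head phantoms with ventricle- and plexus-like structures.

The generator emulates the statistical structure of an adult lifespan MRI
cohort: an ellipsoidal head, two mirrored lateral-ventricle ellipsoids that
enlarge with age, and a bilateral curved-tube "choroid plexus" hugging each
ventricle's posterior-medial wall whose total volume follows a linear age
model

    V(age, sex) = beta0 + beta_age * age + beta_male * 1[male] + eps,
    eps ~ Normal(0, sigma^2),

with defaults chosen so the cohort mean (~3.2 cm^3) and the lifespan slope
(0.047 cm^3/yr) match the adult ranges reported for the lateral-ventricle
choroid plexus.  Three contrasts are painted from an intensity table (CSF
dark on T1/FLAIR, bright on T2; plexus brighter than CSF on FLAIR), modulated
by a smooth polynomial bias field plus white Gaussian noise, and moved into a
per-subject "native" frame by a known rigid jitter.

Axis convention: axis 0 is left-right (the mid-sagittal mirror axis), axis 1
anterior-posterior, axis 2 inferior-superior.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .image_io import (
    BinaryMask3D,
    CohortManifest,
    Geometry,
    MANIFEST_COLUMNS,
    Volume3D,
    resample_with_affine,
    save_manifest,
    write_transform,
    write_volume,
)

__all__ = [
    "PhantomParams",
    "PhantomSubject",
    "generate_subject",
    "generate_cohort",
    "sample_cohort_metadata",
]

MODALITIES = ("t1", "t2", "flair")

# modality -> (parenchyma, csf, plexus, background)
DEFAULT_INTENSITIES = {
    "t1": {"parenchyma": 0.60, "csf": 0.15, "plexus": 0.45, "background": 0.0},
    "t2": {"parenchyma": 0.40, "csf": 0.90, "plexus": 0.60, "background": 0.0},
    "flair": {"parenchyma": 0.50, "csf": 0.10, "plexus": 0.70, "background": 0.0},
}


@dataclasses.dataclass
class PhantomParams:
    """Geometry, intensity and cohort-model parameters for the generator.

    Lengths are millimetres, volumes cm^3.  ``grid_shape``/``spacing`` define
    the common-space grid; the default 96 mm^3 field of view holds the head at
    1 mm isotropic, and a coarser spacing (e.g. 1.5 mm on a 64-cube) keeps the
    same physical anatomy on a smaller grid.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_semiaxes_mm: tuple[float, float, float] = (35.0, 42.0, 38.0)
    ventricle_semiaxes_mm: tuple[float, float, float] = (8.0, 16.0, 10.0)
    ventricle_center_mm: tuple[float, float, float] = (16.0, -6.0, 2.0)
    head_scale_sd: float = 0.03  # per-subject head-size factor ~ N(1, sd)
    atrophy_rate: float = 0.01  # per-axis ventricle growth per year
    beta0: float = 0.62  # cm^3
    beta_age: float = 0.047  # cm^3 / yr
    beta_male: float = 0.30  # cm^3
    sigma: float = 0.40  # cm^3
    min_volume: float = 0.5  # cm^3 truncation floor
    intensities: dict = dataclasses.field(
        default_factory=lambda: {m: dict(DEFAULT_INTENSITIES[m]) for m in MODALITIES}
    )
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.1
    jitter_rot_deg: float = 5.0
    jitter_trans_mm: float = 3.0
    age_range: tuple[float, float] = (21.0, 89.0)
    volume_tol: float = 0.05
    aniso_flair: bool = False
    flair_spacing: tuple[float, float, float] = (0.57, 0.57, 4.0)

    def __post_init__(self) -> None:
        for m, row in self.intensities.items():
            if abs(row["plexus"] - row["csf"]) < 0.1:
                raise ValueError(
                    f"{m}: |plexus - CSF| intensity gap must be >= 0.1 for separability"
                )
        lo, hi = self.age_range
        for age in (lo, hi):
            if self.beta0 + self.beta_age * age <= 0:
                raise ValueError("plexus volume model must be positive over the age range")

    @property
    def common_geometry(self) -> Geometry:
        # world origin at the grid centre so rigid jitters rotate about the head
        sp = np.asarray(self.spacing, dtype=float)
        shape = np.asarray(self.grid_shape)
        aff = np.eye(4)
        aff[:3, :3] = np.diag(sp)
        aff[:3, 3] = -sp * (shape - 1) / 2.0
        return Geometry(tuple(int(s) for s in shape), aff)

    def expected_volume(self, age: float, sex: str) -> float:
        return self.beta0 + self.beta_age * age + self.beta_male * (sex == "M")


@dataclasses.dataclass
class PhantomSubject:
    """One synthetic subject: native-space contrasts + common-space truth."""

    subject_id: str
    volumes: dict  # modality -> Volume3D, native space
    truth_mask: BinaryMask3D  # common space
    ventricle_mask: BinaryMask3D  # common space
    head_mask: BinaryMask3D  # common space
    age: float
    sex: str
    tiv_cm3: float
    lvv_cm3: float
    target_volume_cm3: float
    plexus_volume_cm3: float
    native_transform: np.ndarray  # common world -> native world
    diagnosis: str = "HC"


def _world_coords(geom: Geometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    aff = np.asarray(geom.affine)
    axes = [np.arange(n, dtype=np.float64) for n in geom.shape]
    I, J, K = np.meshgrid(*axes, indexing="ij", copy=False)
    x = aff[0, 0] * I + aff[0, 1] * J + aff[0, 2] * K + aff[0, 3]
    y = aff[1, 0] * I + aff[1, 1] * J + aff[1, 2] * K + aff[1, 3]
    z = aff[2, 0] * I + aff[2, 1] * J + aff[2, 2] * K + aff[2, 3]
    return x, y, z


def _ellipsoid(x, y, z, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _plexus_curve(center: np.ndarray, semiaxes: np.ndarray, side: float, n: int = 200) -> np.ndarray:
    """Polyline hugging a ventricle's posterior-medial wall (unit-ball frame).

    ``side`` is +1 for the right ventricle, -1 for the left; the curve sits
    medially (toward the midline), sweeps most of the long (A-P) axis and dips
    inferiorly mid-course, staying strictly inside the ellipsoid.
    """
    t = np.linspace(0.0, 1.0, n)
    u = np.stack(
        [
            -side * (0.40 + 0.10 * np.cos(np.pi * t)) * np.ones_like(t),
            0.75 * (2.0 * t - 1.0),
            -0.35 * np.sin(np.pi * t),
        ],
        axis=1,
    )
    return center[None, :] + u * semiaxes[None, :]


def _rigid_transform(rng: np.random.Generator, rot_deg: float, trans_mm: float) -> np.ndarray:
    angles = np.deg2rad(rng.uniform(-rot_deg, rot_deg, size=3))
    trans = rng.uniform(-trans_mm, trans_mm, size=3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rz @ Ry @ Rx
    T[:3, 3] = trans
    return T


def _bias_field(x, y, z, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Smooth multiplicative field: 1 + amplitude * low-order polynomial."""
    scale = max(float(np.max(np.abs(v))) for v in (x, y, z))
    xn, yn, zn = x / scale, y / scale, z / scale
    c = rng.uniform(-1.0, 1.0, size=7)
    poly = (
        c[0] * xn + c[1] * yn + c[2] * zn
        + c[3] * xn * yn + c[4] * yn * zn + c[5] * xn * zn
        + c[6] * (xn ** 2 - zn ** 2)
    )
    return 1.0 + amplitude * poly / max(1.0, float(np.max(np.abs(poly))))


def _native_geometry(params: PhantomParams, modality: str) -> Geometry:
    geom = params.common_geometry
    if modality == "flair" and params.aniso_flair:
        fov = np.asarray(geom.shape) * np.asarray(params.spacing)
        sp = np.asarray(params.flair_spacing, dtype=float)
        shape = np.maximum(1, np.round(fov / sp)).astype(int)
        aff = np.eye(4)
        aff[:3, :3] = np.diag(sp)
        aff[:3, 3] = -sp * (shape - 1) / 2.0
        return Geometry(tuple(int(s) for s in shape), aff)
    return geom


def generate_subject(
    params: PhantomParams,
    age: float,
    sex: str,
    seed: int,
    subject_id: str = "sub-000",
    render_intensities: bool = True,
) -> PhantomSubject:
    """Generate one phantom subject; deterministic in (params, age, sex, seed)."""
    lo, hi = params.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside the configured range [{lo}, {hi}]")
    if sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    rng = np.random.default_rng(seed)
    geom = params.common_geometry
    x, y, z = _world_coords(geom)
    voxvol = float(np.prod(params.spacing))

    # (1) head, with a per-subject size factor so TIV varies across the cohort
    head_factor = max(0.8, 1.0 + rng.normal(0.0, params.head_scale_sd)) \
        if params.head_scale_sd > 0 else 1.0
    head = _ellipsoid(x, y, z, (0.0, 0.0, 0.0),
                      np.asarray(params.head_semiaxes_mm) * head_factor)
    tiv = head.sum() * voxvol / 1000.0

    # (2) mirrored ventricles, enlarged with age and scaled with head size
    scale = (1.0 + params.atrophy_rate * (age - lo)) * head_factor
    semi = np.asarray(params.ventricle_semiaxes_mm) * scale
    vx, vy, vz = np.asarray(params.ventricle_center_mm) * head_factor
    vent_r = _ellipsoid(x, y, z, (vx, vy, vz), semi)
    vent_l = _ellipsoid(x, y, z, (-vx, vy, vz), semi)
    vent = (vent_r | vent_l) & head
    lvv = vent.sum() * voxvol / 1000.0

    # (3) target plexus volume from the linear age model
    eps = rng.normal(0.0, params.sigma) if params.sigma > 0 else 0.0
    target = max(params.expected_volume(age, sex) + eps, params.min_volume)

    # (4) carve one tube per side to half the target volume
    plexus = np.zeros(geom.shape, dtype=bool)
    need_half = target * 1000.0 / voxvol / 2.0
    for side, vmask, center in ((+1.0, vent_r & head, np.array([vx, vy, vz])),
                                (-1.0, vent_l & head, np.array([-vx, vy, vz]))):
        idx = np.argwhere(vmask)
        if len(idx) < need_half:
            raise ValueError(
                "target plexus volume unreachable inside the ventricle; "
                "increase ventricle_semiaxes_mm or lower the volume model"
            )
        coords = np.stack(
            [x[vmask.nonzero()], y[vmask.nonzero()], z[vmask.nonzero()]], axis=1
        )
        curve = _plexus_curve(center, semi, side)
        dist, _ = cKDTree(curve).query(coords, workers=1)
        # volume targeting: bisect the tube radius on the precomputed distances
        k = int(round(need_half))
        r_lo, r_hi = 0.0, float(dist.max())
        for _ in range(40):
            r_mid = 0.5 * (r_lo + r_hi)
            if int((dist <= r_mid).sum()) < k:
                r_lo = r_mid
            else:
                r_hi = r_mid
        sel = dist <= r_hi
        plexus[tuple(idx[sel].T)] = True
    achieved = plexus.sum() * voxvol / 1000.0
    if abs(achieved - target) > params.volume_tol * target:
        raise ValueError(
            f"rasterized plexus volume {achieved:.3f} cm^3 misses target "
            f"{target:.3f} cm^3 by more than {params.volume_tol:.0%}"
        )

    aff = np.asarray(geom.affine)
    truth = BinaryMask3D(plexus, aff, space_tag="common")
    vent_mask = BinaryMask3D(vent, aff, space_tag="common")
    head_mask = BinaryMask3D(head, aff, space_tag="common")

    # (6, transform drawn before painting so masks-only runs stay cheap)
    native_T = _rigid_transform(rng, params.jitter_rot_deg, params.jitter_trans_mm)

    volumes: dict[str, Volume3D] = {}
    if render_intensities:
        # (5) paint contrasts, multiply bias, add noise
        bias = _bias_field(x, y, z, rng, params.bias_amplitude)
        for m in MODALITIES:
            tab = params.intensities[m]
            img = np.full(geom.shape, tab["background"], dtype=np.float32)
            img[head] = tab["parenchyma"]
            img[vent] = tab["csf"]
            img[plexus] = tab["plexus"]
            img = img * bias + rng.normal(0.0, params.noise_sigma, size=geom.shape)
            common_vol = Volume3D(img.astype(np.float32), aff, space_tag="common")
            volumes[m] = resample_with_affine(
                common_vol, native_T, _native_geometry(params, m),
                interp="trilinear", space_tag="native",
            )

    return PhantomSubject(
        subject_id=subject_id,
        volumes=volumes,
        truth_mask=truth,
        ventricle_mask=vent_mask,
        head_mask=head_mask,
        age=float(age),
        sex=sex,
        tiv_cm3=tiv,
        lvv_cm3=lvv,
        target_volume_cm3=float(target),
        plexus_volume_cm3=float(achieved),
        native_transform=native_T,
    )


def sample_cohort_metadata(params: PhantomParams, n: int, seed: int) -> pd.DataFrame:
    """Draw cohort metadata (age, sex, model plexus volume) without rasterizing.

    Uses the same age/sex sampling scheme as :func:`generate_cohort`; intended
    for cohort-level statistical checks where mask rendering is unnecessary.
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.age_range
    ages = rng.uniform(lo, hi, size=n)
    sexes = np.where(rng.random(n) < 0.5, "M", "F")
    eps = rng.normal(0.0, params.sigma, size=n) if params.sigma > 0 else np.zeros(n)
    vols = np.maximum(
        params.beta0 + params.beta_age * ages + params.beta_male * (sexes == "M") + eps,
        params.min_volume,
    )
    factor = np.maximum(0.8, 1.0 + rng.normal(0.0, params.head_scale_sd, size=n)) \
        if params.head_scale_sd > 0 else np.ones(n)
    tiv = 4.0 / 3.0 * np.pi * np.prod(params.head_semiaxes_mm) * factor**3 / 1000.0
    vent_scale = (1.0 + params.atrophy_rate * (ages - lo)) * factor
    lvv = 2.0 * 4.0 / 3.0 * np.pi * np.prod(params.ventricle_semiaxes_mm) \
        * vent_scale**3 / 1000.0
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "plexus_volume_cm3": vols,
            "tiv_cm3": tiv,
            "lvv_cm3": lvv,
        }
    )


def generate_cohort(
    params: PhantomParams,
    n: int,
    seed: int,
    out_dir: str | Path | None = None,
    render_intensities: bool = True,
) -> tuple[list[PhantomSubject], CohortManifest]:
    """Generate ``n`` subjects (ages uniform, sexes Bernoulli(0.5)).

    With ``out_dir`` set, writes NIfTI volumes/masks, transform text files and
    a ``manifest.csv`` that round-trips through :func:`load_manifest`.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    lo, hi = params.age_range
    ages = rng.uniform(lo, hi, size=n)
    sexes = np.where(rng.random(n) < 0.5, "M", "F")
    subject_seeds = rng.integers(0, 2**31 - 1, size=n)

    subjects = []
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i in range(n):
        sid = f"sub-{i:03d}"
        subj = generate_subject(
            params, float(ages[i]), str(sexes[i]), int(subject_seeds[i]),
            subject_id=sid, render_intensities=render_intensities,
        )
        subjects.append(subj)
        row = {
            "subject_id": sid,
            "age": subj.age,
            "sex": subj.sex,
            "diagnosis": subj.diagnosis,
            "tiv_cm3": subj.tiv_cm3,
            "lvv_cm3": subj.lvv_cm3,
            "t1_path": "",
            "t2_path": "",
            "flair_path": "",
            "mask_path": "",
            "transform_path": "",
        }
        if out is not None:
            for m in MODALITIES:
                if subj.volumes:
                    p = f"{sid}_{m}.nii.gz"
                    write_volume(subj.volumes[m], out / p)
                    row[f"{m}_path"] = p
            write_volume(subj.truth_mask, out / f"{sid}_mask.nii.gz")
            row["mask_path"] = f"{sid}_mask.nii.gz"
            write_transform(subj.native_transform, out / f"{sid}_xfm.txt")
            row["transform_path"] = f"{sid}_xfm.txt"
        rows.append(row)

    manifest = CohortManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS),
                              root=out if out is not None else Path("."))
    if out is not None:
        save_manifest(manifest, out / "manifest.csv")
    return subjects, manifest
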