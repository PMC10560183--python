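"""Synthetic 4D face-motion generator with known ground truth.

Real 4D recordings of patients are not redistributable, so every stage
of the pipeline is exercised on synthetic corresponded mesh sequences
whose true magnitude, symmetry and timing are known by construction:

* :func:`build_face_template` — a deterministic, bilaterally symmetric
  face-like surface on a structured vertex grid, with the five required
  landmarks and a ground-truth head-orientation normal. At the default
  resolution the subnasale-plane cut selects exactly 559 lower-face
  vertices, matching the region size used in the study the calibration
  emulates.
* :class:`ExpressionRig` — per-vertex unit deformation fields (smile: a
  lateral-superior pull around each mouth corner; lip purse: anterior
  protrusion around each midline lip point) with compact support, so a
  commanded amplitude *is* the true landmark displacement, exactly.
* :func:`generate_cohort` — a full pre/post-surgery cohort whose
  subject-level parameter distributions default to a calibration
  fixture encoding the published cohort statistics (means and
  CI-derived between-subject SDs) of a 26-patient orthognathic-surgery
  study; sequences carry i.i.d. isotropic Gaussian tracking noise.

The rigs are deliberately simple radial-decay fields rather than
biomechanical muscle models: ground-truth fidelity, not visual realism,
is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import truncnorm

from .errors import Face4DError
from .mesh_io import (
    LandmarkMap,
    MeshFrame,
    MeshSequence,
    write_landmark_map,
    write_manifest,
    write_mesh_sequence,
)
from .roi import EXPRESSION_LANDMARKS

SQRT_2_OVER_PI = float(np.sqrt(2.0 / np.pi))

#: Calibration fixture: cohort-level distribution parameters per
#: expression and timepoint. Means are the published estimated marginal
#: means; between-subject SDs are back-solved from the printed 95% CIs
#: (SD = sqrt(26) * half-width / 1.96); the symmetry entries are mean
#: |left-right| differences, realized as half-normal magnitudes with
#: random sign. Within-subject (T0 -> T1 residual) SDs are assumptions
#: documented in docs/methods.md.
DEFAULT_CALIBRATION: dict[str, dict[str, float]] = {
    "smile": dict(
        magnitude_mean_t0=15.24,
        magnitude_between_sd=5.63,
        magnitude_shift=2.03,
        magnitude_within_sd=1.4,
        symmetry_mean_t0=0.99,
        symmetry_mean_t1=1.78,
        time_mean_t0=0.41,
        time_between_sd=0.117,
        time_shift=0.02,
        time_within_sd=0.04,
    ),
    "lip_purse": dict(
        magnitude_mean_t0=9.34,
        magnitude_between_sd=2.37,
        magnitude_shift=-1.03,
        magnitude_within_sd=0.6,
        symmetry_mean_t0=1.27,
        symmetry_mean_t1=1.06,
        time_mean_t0=0.36,
        time_between_sd=0.078,
        time_shift=-0.04,
        time_within_sd=0.04,
    ),
}

#: Surgical-movement covariates: (mean, SD, truncated at zero). The
#: translation magnitudes cannot be negative; the rotations can.
SURGICAL_COVARIATES: dict[str, tuple[float, float, bool]] = {
    "sagittal_translation_maxilla": (2.82, 2.2, True),
    "vertical_translation_maxilla": (1.76, 1.3, True),
    "transversal_translation_maxilla": (0.95, 0.9, True),
    "sagittal_translation_mandibula": (4.13, 2.83, True),
    "vertical_translation_mandibula": (2.42, 1.58, True),
    "transversal_translation_mandibula": (1.48, 1.27, True),
    "roll_maxillomandibular": (0.62, 0.85, False),
    "pitch_maxillomandibular": (1.58, 2.48, False),
    "yaw_maxillomandibular": (0.73, 1.04, False),
}

COVARIATE_COLUMNS = tuple(SURGICAL_COVARIATES)


class TemplateConstructionError(Face4DError):
    """Template parameters violate a construction constraint."""


@dataclass(frozen=True)
class FaceTemplate:
    """Neutral face surface + landmarks + ground-truth head orientation."""

    frame: MeshFrame
    landmarks: LandmarkMap
    fh_normal: np.ndarray
    grid_shape: tuple[int, int]  # (columns, rows)
    dimensions: tuple[float, float, float]  # width, height, depth (mm)

    @property
    def n_vertices(self) -> int:
        return self.frame.n_vertices


# Grid layout constants of the default template. The subnasale row is
# chosen so that the rows below it hold 558 vertices; together with
# subnasale itself (which lies exactly on the cut plane and is included
# by the boundary convention) the lower-face selection has 559 vertices.
_LOWER_FACE_STRICT = 558
_DEFAULT_NX = 31
_DEFAULT_NY = 38


def build_face_template(
    nx: int = _DEFAULT_NX,
    ny: int = _DEFAULT_NY,
    width: float = 95.0,
    height: float = 125.0,
    depth: float = 32.0,
    lateral_lift: float = 1.2,
) -> FaceTemplate:
    """Deterministic face-like template on an ``nx`` x ``ny`` vertex grid.

    The surface is a smooth anterior bulge over a rectangular grid
    (x: left-right, y: inferior-superior, z: posterior-anterior, mm).
    Rows rise laterally by up to ``lateral_lift`` mm (a gentle jaw-line
    curve), which guarantees that within the subnasale row only the
    midline vertex lies on the cut plane. ``nx`` must be odd (a midline
    column) and divide 558 so the lower-face constraint is satisfiable.
    """
    if nx % 2 == 0:
        raise TemplateConstructionError("nx must be odd (bilateral symmetry needs a midline)")
    if _LOWER_FACE_STRICT % nx != 0:
        raise TemplateConstructionError(
            f"nx={nx} cannot honour the 559-vertex lower-face constraint "
            f"({_LOWER_FACE_STRICT} is not a multiple of nx)"
        )
    sn_row = _LOWER_FACE_STRICT // nx
    if ny < sn_row + 2:
        raise TemplateConstructionError(f"ny must be at least {sn_row + 2}, got {ny}")
    if nx * ny < 600:
        raise TemplateConstructionError("grid must contain at least 600 vertices")
    dy = height / (ny - 1)
    if not 0 <= lateral_lift < dy:
        raise TemplateConstructionError(
            f"lateral_lift must be in [0, {dy:.3f}) to keep the row order at the cut"
        )

    xs = np.linspace(-width / 2.0, width / 2.0, nx)
    col, row = np.meshgrid(np.arange(nx), np.arange(ny))  # row-major: idx = row*nx + col
    X = xs[col]
    Y = row * dy + lateral_lift * (np.abs(X) / (width / 2.0)) ** 2
    Z = depth * np.exp(-((X / (0.45 * width)) ** 2) - (((Y - 0.55 * height) / (0.5 * height)) ** 2))
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    # Two triangles per grid quad.
    r, c = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    v00 = (r * nx + c).ravel()
    v01, v10, v11 = v00 + 1, v00 + nx, v00 + nx + 1
    faces = np.concatenate(
        [np.column_stack([v00, v01, v11]), np.column_stack([v00, v11, v10])]
    )

    mid = nx // 2

    def vid(r_, c_):
        return int(r_ * nx + c_)

    cheilion_off = max(2, round(0.25 * (nx - 1)))  # about a quarter width out
    landmarks = LandmarkMap(
        indices={
            "subnasale": vid(sn_row, mid),
            "labrale_superius": vid(sn_row - 4, mid),
            "cheilion_right": vid(sn_row - 5, mid - cheilion_off),
            "cheilion_left": vid(sn_row - 5, mid + cheilion_off),
            "labrale_inferius": vid(sn_row - 7, mid),
        }
    )
    template = FaceTemplate(
        frame=MeshFrame(vertices=vertices, faces=faces, index=0),
        landmarks=landmarks,
        fh_normal=np.array([0.0, 1.0, 0.0]),
        grid_shape=(nx, ny),
        dimensions=(width, height, depth),
    )
    n_lower = _lower_face_count(template)
    if n_lower != 559:
        raise TemplateConstructionError(
            f"lower-face constraint violated: cut selects {n_lower} vertices, expected 559"
        )
    return template


def _lower_face_count(template: FaceTemplate) -> int:
    from .roi import make_subnasale_plane, select_lower_face

    plane = make_subnasale_plane(template.frame, template.landmarks, template.fh_normal)
    return len(select_lower_face(template.frame, plane))


def _wendland(d: np.ndarray, radius: float) -> np.ndarray:
    """Compactly supported C2 bump: 1 at d=0, exactly 0 for d >= radius."""
    q = np.clip(d / radius, 0.0, 1.0)
    return (1.0 - q) ** 4 * (4.0 * q + 1.0)


@dataclass(frozen=True)
class ExpressionRig:
    """Two unit deformation fields, one per most-moving landmark.

    ``field_a`` peaks (unit magnitude) at the first landmark of the
    expression pair (cheilion right / labrale superius), ``field_b`` at
    the second; supports do not overlap the opposite landmark, so the
    peak displacement of landmark a under amplitude A and asymmetry s is
    exactly A + s/2 and of landmark b exactly A - s/2.
    """

    expression: str
    field_a: np.ndarray
    field_b: np.ndarray
    landmark_names: tuple[str, str]

    def peak_displacement(self, amplitude: float, asymmetry: float) -> np.ndarray:
        return (amplitude + asymmetry / 2.0) * self.field_a + (
            amplitude - asymmetry / 2.0
        ) * self.field_b


def build_expression_rig(
    template: FaceTemplate,
    expression: str,
    smile_radius: float = 20.0,
    purse_radius: float = 8.0,
) -> ExpressionRig:
    """Construct the deformation basis of an expression on a template.

    Smile: each mouth corner is pulled laterally and superiorly (with a
    slight posterior component), with influence decaying over
    ``smile_radius`` mm. Lip purse: each midline lip point protrudes
    anteriorly with slight vertical convergence over ``purse_radius``
    mm. Radii are small enough that the two fields never reach the
    opposite landmark.
    """
    try:
        names = EXPRESSION_LANDMARKS[expression]
    except KeyError:
        raise ValueError(f"unknown expression '{expression}'") from None
    V = template.frame.vertices
    ia, ib = (template.landmarks[n] for n in names)
    da = np.linalg.norm(V - V[ia], axis=1)
    db = np.linalg.norm(V - V[ib], axis=1)
    gap = np.linalg.norm(V[ia] - V[ib])

    if expression == "smile":
        radius = smile_radius
        # outward = away from midline; cheilion_right sits at x < 0
        dir_a = np.array([-0.55, 0.80, -0.23])
        dir_b = np.array([0.55, 0.80, -0.23])
    else:
        radius = purse_radius
        dir_a = np.array([0.0, -0.15, 0.98])  # upper lip: forward, slightly down
        dir_b = np.array([0.0, 0.15, 0.98])  # lower lip: forward, slightly up
    if radius >= gap:
        raise ValueError(
            f"support radius {radius} mm reaches the opposite landmark ({gap:.1f} mm apart)"
        )
    dir_a = dir_a / np.linalg.norm(dir_a)
    dir_b = dir_b / np.linalg.norm(dir_b)
    field_a = _wendland(da, radius)[:, None] * dir_a
    field_b = _wendland(db, radius)[:, None] * dir_b
    return ExpressionRig(
        expression=expression, field_a=field_a, field_b=field_b, landmark_names=names
    )


def smoothstep(t: np.ndarray) -> np.ndarray:
    """Cubic ease (0 -> 1 with zero end slopes): 3t^2 - 2t^3."""
    t = np.clip(t, 0.0, 1.0)
    return 3.0 * t**2 - 2.0 * t**3


def animate_expression(
    template: FaceTemplate,
    rig: ExpressionRig,
    amplitude: float,
    asymmetry: float = 0.0,
    time_to_peak: float = 0.4,
    rest_frames: int = 12,
    fps: float = 60.0,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    hold_frames: int = 6,
    subject_id: str | None = None,
    timepoint: str | None = None,
) -> tuple[MeshSequence, dict]:
    """Animate one expression; returns the sequence and its ground truth.

    The sequence holds ``rest_frames`` static frames, ramps to peak with
    a smoothstep profile over ``round(time_to_peak * fps)`` frames, then
    holds the peak for ``hold_frames`` frames. Ground truth: magnitude =
    ``amplitude``, symmetry = ``|asymmetry|`` (one landmark moves
    amplitude + asymmetry/2, the other amplitude - asymmetry/2), time =
    the frame-quantized time to peak. Tracking noise is i.i.d. isotropic
    Gaussian per vertex per frame.
    """
    if not amplitude > 0:
        raise ValueError("amplitude must be positive")
    if abs(asymmetry) > 2.0 * amplitude:
        raise ValueError("asymmetry beyond twice the amplitude would reverse landmark motion")
    if not fps > 0:
        raise ValueError("fps must be positive")
    if rest_frames < 1:
        raise ValueError("need at least one rest frame")
    n_ramp = max(1, int(round(time_to_peak * fps)))
    peak = rig.peak_displacement(amplitude, asymmetry)
    base = template.frame.vertices
    profile = np.concatenate(
        [
            np.zeros(rest_frames),
            smoothstep(np.arange(1, n_ramp + 1) / n_ramp),
            np.ones(max(0, hold_frames)),
        ]
    )
    V = base[None, :, :] + profile[:, None, None] * peak[None, :, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        V = V + rng.normal(0.0, noise_sd, size=V.shape)
    frames = [
        MeshFrame(vertices=V[t], faces=template.frame.faces, index=t)
        for t in range(V.shape[0])
    ]
    seq = MeshSequence(
        frames=frames,
        fps=fps,
        subject_id=subject_id,
        timepoint=timepoint,
        expression=rig.expression,
    )
    truth = dict(
        magnitude=float(amplitude),
        symmetry=float(abs(asymmetry)),
        asymmetry=float(asymmetry),
        time=n_ramp / fps,
        start_index=rest_frames - 1,
        end_index=rest_frames + n_ramp - 1,
    )
    return seq, truth


@dataclass
class CohortConfig:
    """Everything needed to draw one reproducible synthetic cohort.

    ``sampling`` selects how subject-level parameters are drawn:
    ``"stratified"`` (default) uses permuted normal quantiles so every
    cohort reproduces the calibration's cohort-level statistics —
    recovery error then measures pipeline bias, not sampling luck;
    ``"iid"`` draws ordinary i.i.d. normals, as required when studying
    sampling-based inference (e.g. type-I-error calibration).
    """

    n_subjects: int = 26
    n_class_ii: int | None = None  # default: balanced split
    n_bimax: int | None = None  # default: round(21/26 * n)
    calibration: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CALIBRATION.items()}
    )
    noise_sd: float = 0.15
    fps: float = 60.0
    rest_frames: int = 12
    hold_frames: int = 6
    sampling: str = "stratified"
    covariate_effects: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.sampling not in ("stratified", "iid"):
            raise ValueError("sampling must be 'stratified' or 'iid'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for expr, cal in self.calibration.items():
            for key, value in cal.items():
                if key.endswith("_sd") and value < 0:
                    raise ValueError(f"{expr}.{key} must be non-negative")
        if self.n_class_ii is None:
            self.n_class_ii = self.n_subjects // 2
        if self.n_bimax is None:
            self.n_bimax = int(round(21.0 / 26.0 * self.n_subjects))


def _scores(n: int, rng: np.random.Generator, mode: str) -> np.ndarray:
    """Standard-normal subject scores, stratified or i.i.d."""
    if mode == "stratified":
        z = ndtri((np.arange(n) + 0.5) / n)
        rng.shuffle(z)
        return z
    return rng.standard_normal(n)


def _halfnormal_scores(n: int, rng: np.random.Generator, mode: str) -> np.ndarray:
    """|N(0,1)| scores with mean ~ sqrt(2/pi), stratified or i.i.d."""
    if mode == "stratified":
        h = ndtri(0.5 + (np.arange(n) + 0.5) / (2.0 * n))
        rng.shuffle(h)
        return h
    return np.abs(rng.standard_normal(n))


@dataclass
class ClipRecord:
    """One realized sequence plus its ground truth row."""

    sequence: MeshSequence
    truth: dict
    subject_id: str
    timepoint: str
    expression: str


@dataclass
class SyntheticCohort:
    """A drawn cohort: ground truth now, mesh sequences on demand."""

    config: CohortConfig
    template: FaceTemplate
    rigs: dict[str, ExpressionRig]
    ground_truth: pd.DataFrame  # one row per subject x expression x timepoint
    subjects: pd.DataFrame  # one row per subject (class, covariates, ...)

    def clip_seed(self, subject_idx: int, expression: str, timepoint: str) -> np.random.SeedSequence:
        """Documented seed split: (cohort seed, 1, subject, expression, timepoint)."""
        e = list(EXPRESSION_LANDMARKS).index(expression)
        t = ("T0", "T1").index(timepoint)
        return np.random.SeedSequence(entropy=self.config.seed, spawn_key=(1, subject_idx, e, t))

    def realize_clip(self, row: pd.Series) -> ClipRecord:
        """Materialize the mesh sequence for one ground-truth row."""
        cfg = self.config
        seq, truth = animate_expression(
            self.template,
            self.rigs[row["expression"]],
            amplitude=row["magnitude"],
            asymmetry=row["asymmetry"],
            time_to_peak=row["time"],
            rest_frames=cfg.rest_frames,
            fps=cfg.fps,
            noise_sd=cfg.noise_sd,
            seed=self.clip_seed(int(row["subject_idx"]), row["expression"], row["timepoint"]),
            hold_frames=cfg.hold_frames,
            subject_id=row["subject_id"],
            timepoint=row["timepoint"],
        )
        return ClipRecord(
            sequence=seq,
            truth=truth,
            subject_id=row["subject_id"],
            timepoint=row["timepoint"],
            expression=row["expression"],
        )

    def iter_clips(self, expressions: tuple[str, ...] | None = None) -> Iterator[ClipRecord]:
        for _, row in self.ground_truth.iterrows():
            if expressions is None or row["expression"] in expressions:
                yield self.realize_clip(row)

    def write(self, directory: str | Path, fmt: str = "ply") -> Path:
        """Write PLY sequences, landmark map, manifests and ground truth."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        lm_path = write_landmark_map(self.template.landmarks, directory / "landmarks.txt")
        for record in self.iter_clips():
            name = f"{record.subject_id}_{record.timepoint}_{record.expression}"
            clip_dir = directory / name
            paths = write_mesh_sequence(record.sequence, clip_dir, fmt=fmt)
            write_manifest(
                clip_dir / "manifest.yaml",
                frame_paths=[p.name for p in paths],
                fps=self.config.fps,
                landmark_path="../landmarks.txt",
                fh_normal=self.template.fh_normal,
                subject_id=record.subject_id,
                timepoint=record.timepoint,
                expression=record.expression,
            )
        self.ground_truth.to_csv(directory / "ground_truth.csv", index=False)
        self.subjects.to_csv(directory / "subjects.csv", index=False)
        return directory


def generate_cohort(config: CohortConfig | None = None, template: FaceTemplate | None = None) -> SyntheticCohort:
    """Draw a cohort's ground truth (meshes are realized lazily).

    Subject-level structure: the T0 value of each metric is
    mean + between_sd * z_subject; the T1 value adds the configured mean
    shift plus a within-subject residual — a paired design with the
    within-subject correlation the mixed model and the signed-rank test
    assume. Asymmetry is drawn per timepoint as a signed half-normal
    whose mean magnitude matches the calibration. All randomness flows
    from ``config.seed`` through a documented splitting scheme.
    """
    config = config or CohortConfig()
    template = template or build_face_template()
    rigs = {expr: build_expression_rig(template, expr) for expr in EXPRESSION_LANDMARKS}
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    n = config.n_subjects
    mode = config.sampling
    fps = config.fps

    classes = np.array(["II"] * config.n_class_ii + ["III"] * (n - config.n_class_ii))
    intervention = np.array(
        ["bimax"] * config.n_bimax + ["bsso_only"] * (n - config.n_bimax)
    )
    rng.shuffle(intervention)
    subjects = pd.DataFrame(
        {
            "subject_idx": np.arange(n),
            "subject_id": [f"S{i + 1:02d}" for i in range(n)],
            "skeletal_class": classes,
            "intervention_type": intervention,
        }
    )
    for name, (mean, sd, nonneg) in SURGICAL_COVARIATES.items():
        if nonneg:
            a = (0.0 - mean) / sd
            subjects[name] = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
        else:
            subjects[name] = rng.normal(mean, sd, size=n)

    rows = []
    for expr, cal in config.calibration.items():
        mag0 = cal["magnitude_mean_t0"] + cal["magnitude_between_sd"] * _scores(n, rng, mode)
        mag0 = np.clip(mag0, 1.0, None)
        mag1 = mag0 + cal["magnitude_shift"] + cal["magnitude_within_sd"] * _scores(n, rng, mode)
        mag1 = np.clip(mag1, 1.0, None)
        if config.covariate_effects and expr in config.covariate_effects:
            for cov, beta in config.covariate_effects[expr].items():
                mag1 = mag1 + beta * subjects[cov].to_numpy()
        t0 = cal["time_mean_t0"] + cal["time_between_sd"] * _scores(n, rng, mode)
        t1 = t0 + cal["time_shift"] + cal["time_within_sd"] * _scores(n, rng, mode)
        t0 = np.clip(t0, 6.0 / fps, None)
        t1 = np.clip(t1, 6.0 / fps, None)
        for tp, mag, tt, sym_mean in (
            ("T0", mag0, t0, cal["symmetry_mean_t0"]),
            ("T1", mag1, t1, cal["symmetry_mean_t1"]),
        ):
            sigma_signed = sym_mean / SQRT_2_OVER_PI
            asym = sigma_signed * _halfnormal_scores(n, rng, mode) * rng.choice([-1.0, 1.0], size=n)
            asym = np.clip(asym, -1.9 * mag, 1.9 * mag)
            time_q = np.round(tt * fps) / fps  # frame-quantized ground truth
            for i in range(n):
                rows.append(
                    dict(
                        subject_idx=i,
                        subject_id=subjects.loc[i, "subject_id"],
                        skeletal_class=classes[i],
                        timepoint=tp,
                        expression=expr,
                        magnitude=float(mag[i]),
                        symmetry=float(abs(asym[i])),
                        asymmetry=float(asym[i]),
                        time=float(time_q[i]),
                    )
                )
    truth = pd.DataFrame(rows).merge(
        subjects.drop(columns=["skeletal_class"]), on=["subject_idx", "subject_id"]
    )
    return SyntheticCohort(
        config=config, template=template, rigs=rigs, ground_truth=truth, subjects=subjects
    )
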