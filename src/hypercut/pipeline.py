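"""End-to-end orchestration: captures -> features -> embedding -> verification report.

The stage chain mirrors the acquisition-to-decision flow:

    [calibrate if references given] -> Gaussian denoise -> landmark line ROI
    -> cross-section reslice -> 100x100 8-bit standardization -> 225-dim LBP
    vector -> 2-D embedding -> genuine/impostor enumeration -> distance
    normalization -> FAR/FRR sweep -> EER / ROC / AUC / Welch's t-test.

The deterministic path (PCA) is a pure function of inputs + config; t-SNE and
UMAP are seed-stable per backend version.  ``run_pipeline`` consumes any
iterable of capture records (e.g. a lazily rendering synthetic cohort) and
optionally writes every intermediate artifact to a directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, lbp, roi
from .embedding import Embedding, EmbeddingConfig, reduce, save_embedding
from .errors import ContractError
from .evaluation import EvalReport, enumerate_matches, evaluate_matchset, save_scores
from .hypercube import CalibrationSet, calibrate_reflectance, gaussian_denoise, read_cube
from .lbp import LBPConfig, extract_feature_vector
from .roi import HandLandmarks, line_from_landmarks, sample_cross_section, standardize_section

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything that, together with the inputs, determines a run."""

    calibration_eps: float = 1e-6
    denoise_sigma: float = 2.0
    extension: float = 1.0
    step_px: float = 1.0
    out_shape: tuple[int, int] = (100, 100)
    orientation: str = "spatial-rows"
    lbp: LBPConfig = field(default_factory=LBPConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    eval_steps: int = 1000
    ordered_pairs: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    report: EvalReport
    embedding: Embedding
    features: np.ndarray
    subject_ids: list
    capture_ids: list
    curves: evaluation.ErrorCurves
    roc: np.ndarray
    match_set: evaluation.MatchSet


def extract_capture_features(cube, landmarks: HandLandmarks, cfg: PipelineConfig | None = None):
    """Single-capture feature path: denoise -> ROI -> reslice -> standardize -> LBP.

    Returns ``(feature_vector, standardized_image)``.
    """
    cfg = cfg or PipelineConfig()
    smooth = gaussian_denoise(cube, sigma=cfg.denoise_sigma)
    line = line_from_landmarks(landmarks, extension=cfg.extension)
    section = sample_cross_section(smooth, line, step_px=cfg.step_px)
    img8 = standardize_section(section, out_shape=cfg.out_shape, orientation=cfg.orientation)
    fv = extract_feature_vector(img8, cfg.lbp)
    return fv, img8


def run_pipeline(captures, cfg: PipelineConfig | None = None, out_dir=None,
                 calibration: CalibrationSet | None = None) -> PipelineResult:
    """Run the full method over an iterable of capture records.

    ``captures`` yields objects with ``cube``, ``landmarks``, ``subject_id``
    and ``capture_id`` attributes (e.g. :class:`~hypercut.synthetic.CaptureRecord`).
    Needs at least two subjects, otherwise there are no impostor pairs to
    threshold.
    """
    cfg = cfg or PipelineConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    vectors, subject_ids, capture_ids = [], [], []
    for rec in captures:
        cube = rec.cube
        if calibration is not None:
            cube = calibrate_reflectance(cube, calibration, eps=cfg.calibration_eps)
        try:
            fv, _ = extract_capture_features(cube, rec.landmarks, cfg)
        except Exception as exc:
            raise ContractError(f"capture {rec.capture_id}: feature extraction failed: {exc}") from exc
        vectors.append(fv.values)
        subject_ids.append(rec.subject_id)
        capture_ids.append(rec.capture_id)
        logger.info("features extracted for capture %s", rec.capture_id)

    if len(set(subject_ids)) < 2:
        raise ContractError("evaluation needs captures from at least 2 subjects (no impostor pairs)")
    X = np.asarray(vectors, dtype=float)

    emb = reduce(X, cfg.embedding, labels=np.asarray(subject_ids))
    ms = enumerate_matches(emb.coords, subject_ids, capture_ids=capture_ids,
                           ordered=cfg.ordered_pairs)
    report, curves, roc_pts = evaluate_matchset(ms, n_steps=cfg.eval_steps,
                                                method=cfg.embedding.method)

    result = PipelineResult(report=report, embedding=emb, features=X,
                            subject_ids=subject_ids, capture_ids=capture_ids,
                            curves=curves, roc=roc_pts, match_set=ms)
    if out_dir is not None:
        _write_artifacts(result, cfg, out_dir)
    return result


def _write_artifacts(res: PipelineResult, cfg: PipelineConfig, out_dir: Path) -> None:
    lbp.save_features(out_dir / "features.csv", res.features, res.subject_ids, res.capture_ids)
    save_embedding(out_dir / "embedding.csv", res.embedding, capture_ids=res.capture_ids)
    save_scores(out_dir / "scores.csv", res.match_set)
    pd.DataFrame({
        "threshold": res.curves.thresholds,
        "far": res.curves.far,
        "frr": res.curves.frr,
    }).to_csv(out_dir / "curves.csv", index=False)
    pd.DataFrame(res.roc, columns=["far", "tar"]).to_csv(out_dir / "roc.csv", index=False)
    res.report.to_json(out_dir / "report.json")
    (out_dir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, default=str))


def run_from_manifest(manifest_csv, cfg: PipelineConfig | None = None, out_dir=None) -> PipelineResult:
    """Run the pipeline from a manifest CSV on disk.

    Required columns: ``subject_id``, ``capture_id``, ``cube_path``,
    ``landmarks_path``.  Optional ``white_path``/``dark_path`` columns switch
    on reflectance calibration per capture.
    """
    cfg = cfg or PipelineConfig()
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    need = {"subject_id", "capture_id", "cube_path", "landmarks_path"}
    if not need <= set(df.columns):
        raise ContractError(f"manifest needs columns {sorted(need)}")
    base = manifest_csv.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    @dataclass
    class _Rec:
        cube: object
        landmarks: HandLandmarks
        subject_id: str
        capture_id: str

    def _iter():
        for row in df.itertuples(index=False):
            cube = read_cube(_resolve(row.cube_path))
            if {"white_path", "dark_path"} <= set(df.columns) and isinstance(row.white_path, str):
                cal = CalibrationSet(white=read_cube(_resolve(row.white_path)),
                                     dark=read_cube(_resolve(row.dark_path)))
                cube = calibrate_reflectance(cube, cal, eps=cfg.calibration_eps)
            lms = HandLandmarks.from_json(_resolve(row.landmarks_path))
            yield _Rec(cube=cube, landmarks=lms,
                       subject_id=str(row.subject_id), capture_id=str(row.capture_id))

    return run_pipeline(_iter(), cfg=cfg, out_dir=out_dir)
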