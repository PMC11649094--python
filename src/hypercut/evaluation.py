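"""Verification metrics: match enumeration, FAR/FRR sweep, EER, ROC/AUC, Welch test.

Captures are compared pairwise in the embedded space with the Euclidean
distance: genuine (intra-subject) pairs should score low, impostor
(inter-subject) pairs high.  Distances are normalized by their global maximum
so thresholds live on [0, 1]; the accept rule is ``distance <= threshold``
(closed).  Pairs are ordered (directed) by default, which for a 10-subject x
10-capture cohort gives 900 genuine and 9000 impostor matches; an unordered
mode halves both counts.

FAR(t) is the fraction of impostor pairs accepted at threshold t, FRR(t) the
fraction of genuine pairs rejected.  The EER is read off at the FAR = FRR
crossing with linear interpolation between grid thresholds; the ROC plots
TAR = 1 - FRR against FAR and its AUC (trapezoidal over all distinct scores)
equals the rank statistic P(genuine < impostor) + 0.5 P(tie).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import ContractError, DegenerateDataError


@dataclass
class MatchSet:
    """Labeled genuine/impostor distance populations."""

    intra: np.ndarray                 # genuine distances
    inter: np.ndarray                 # impostor distances
    intra_pairs: list = field(default_factory=list)
    inter_pairs: list = field(default_factory=list)
    normalized: bool = False
    normalizer: float = 1.0

    def __post_init__(self) -> None:
        self.intra = np.asarray(self.intra, dtype=float)
        self.inter = np.asarray(self.inter, dtype=float)
        if (self.intra < 0).any() or (self.inter < 0).any():
            raise ContractError("distances must be non-negative")


@dataclass
class ErrorCurves:
    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.far = np.asarray(self.far, dtype=float)
        self.frr = np.asarray(self.frr, dtype=float)
        if not (len(self.thresholds) == len(self.far) == len(self.frr)):
            raise ContractError("curves must share the threshold grid")


@dataclass
class EvalReport:
    eer: float
    eer_threshold: float
    auc: float
    welch_t: float
    welch_df: float
    welch_p: float
    n_intra: int
    n_inter: int
    mean_intra: float
    mean_inter: float
    method: str = ""

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "eer": self.eer,
            "eer_percent": 100.0 * self.eer,
            "eer_threshold": self.eer_threshold,
            "auc": self.auc,
            "auc_percent": 100.0 * self.auc,
            "welch": {"t": self.welch_t, "df": self.welch_df, "p": self.welch_p},
            "counts": {"intra": self.n_intra, "inter": self.n_inter},
            "mean_distance": {"intra": self.mean_intra, "inter": self.mean_inter},
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def enumerate_matches(coords: np.ndarray, labels, capture_ids=None, ordered: bool = True) -> MatchSet:
    """All pairs of distinct captures with Euclidean distances in embedding space.

    ``ordered=True`` counts each pair in both directions (the convention under
    which 10 x 10 captures yield 900/9000 matches).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if coords.ndim != 2 or len(coords) < 2:
        raise ContractError("need at least 2 captures to enumerate matches")
    if len(labels) != len(coords):
        raise ContractError("one subject label per capture required")
    n = len(coords)
    ids = list(capture_ids) if capture_ids is not None else list(range(n))

    dist = cdist(coords, coords)
    same = labels[:, None] == labels[None, :]
    if ordered:
        mask = ~np.eye(n, dtype=bool)
    else:
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)
    ii, jj = np.nonzero(mask & same)
    ik, jk = np.nonzero(mask & ~same)
    return MatchSet(
        intra=dist[ii, jj],
        inter=dist[ik, jk],
        intra_pairs=[(ids[a], ids[b]) for a, b in zip(ii, jj)],
        inter_pairs=[(ids[a], ids[b]) for a, b in zip(ik, jk)],
    )


def normalize_distances(ms: MatchSet) -> MatchSet:
    """Divide every distance by the global maximum so the top score is exactly 1."""
    all_d = np.concatenate([ms.intra, ms.inter])
    if all_d.size == 0:
        raise ContractError("empty match set")
    m = float(all_d.max())
    if m == 0.0:
        raise DegenerateDataError("all pairwise distances are zero; nothing to threshold")
    return MatchSet(
        intra=ms.intra / m,
        inter=ms.inter / m,
        intra_pairs=ms.intra_pairs,
        inter_pairs=ms.inter_pairs,
        normalized=True,
        normalizer=m * ms.normalizer,
    )


def far_frr_curves(ms: MatchSet, n_steps: int = 1000) -> ErrorCurves:
    """FAR and FRR over a uniform [0, 1] grid augmented with the exact scores.

    Accept iff distance <= threshold; FAR(t) = #{inter <= t} / |inter| and
    FRR(t) = #{intra > t} / |intra|.
    """
    if not ms.normalized:
        raise ContractError("normalize the match set before sweeping thresholds")
    if ms.intra.size == 0 or ms.inter.size == 0:
        raise ContractError("both genuine and impostor populations must be nonempty")
    grid = np.unique(np.concatenate([np.linspace(0.0, 1.0, n_steps + 1), ms.intra, ms.inter]))
    intra_sorted = np.sort(ms.intra)
    inter_sorted = np.sort(ms.inter)
    far = np.searchsorted(inter_sorted, grid, side="right") / inter_sorted.size
    frr = 1.0 - np.searchsorted(intra_sorted, grid, side="right") / intra_sorted.size
    return ErrorCurves(thresholds=grid, far=far, frr=frr)


def compute_eer(curves: ErrorCurves) -> tuple[float, float]:
    """Locate the FAR = FRR crossing; linear interpolation between grid points.

    If the curves touch (FAR == FRR) over an interval, the midpoint threshold
    is returned with the common error value there.
    """
    d = curves.far - curves.frr
    zero = np.abs(d) < 1e-15
    if zero.any():
        idx = np.flatnonzero(zero)
        # contiguous run containing the first zero
        first = idx[0]
        last = first
        while last + 1 < len(d) and zero[last + 1]:
            last += 1
        t = 0.5 * (curves.thresholds[first] + curves.thresholds[last])
        eer = 0.5 * (
            np.interp(t, curves.thresholds, curves.far)
            + np.interp(t, curves.thresholds, curves.frr)
        )
        return float(eer), float(t)
    i = int(np.argmax(d >= 0))
    if i == 0:  # FAR already above FRR at the lowest threshold
        return float(0.5 * (curves.far[0] + curves.frr[0])), float(curves.thresholds[0])
    t0, t1 = curves.thresholds[i - 1], curves.thresholds[i]
    d0, d1 = d[i - 1], d[i]
    frac = -d0 / (d1 - d0)
    t = t0 + frac * (t1 - t0)
    far_t = curves.far[i - 1] + frac * (curves.far[i] - curves.far[i - 1])
    frr_t = curves.frr[i - 1] + frac * (curves.frr[i] - curves.frr[i - 1])
    return float(0.5 * (far_t + frr_t)), float(t)


def roc_auc(ms: MatchSet) -> tuple[np.ndarray, float]:
    """ROC points (FAR, TAR) over all distinct scores plus endpoints, and its AUC.

    Trapezoidal integration over the score-threshold ROC equals the
    Mann-Whitney statistic P(genuine < impostor) + 0.5 P(tie).
    """
    if ms.intra.size == 0 or ms.inter.size == 0:
        raise ContractError("both populations must be nonempty")
    scores = np.unique(np.concatenate([ms.intra, ms.inter]))
    intra_sorted = np.sort(ms.intra)
    inter_sorted = np.sort(ms.inter)
    far = np.searchsorted(inter_sorted, scores, side="right") / inter_sorted.size
    tar = np.searchsorted(intra_sorted, scores, side="right") / intra_sorted.size
    far = np.concatenate([[0.0], far])
    tar = np.concatenate([[0.0], tar])
    if far[-1] < 1.0 or tar[-1] < 1.0:  # guaranteed 1 at the max score; keep endpoint explicit
        far = np.concatenate([far, [1.0]])
        tar = np.concatenate([tar, [1.0]])
    auc = float(np.trapezoid(tar, far))
    return np.column_stack([far, tar]), auc


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Unpaired Welch's t-test: statistic, Welch-Satterthwaite df, two-sided P."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ContractError("both samples have zero variance")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def evaluate_matchset(ms: MatchSet, n_steps: int = 1000, method: str = "") -> tuple[EvalReport, ErrorCurves, np.ndarray]:
    """Normalize, sweep thresholds and summarize one embedding's match set."""
    raw_intra, raw_inter = ms.intra, ms.inter
    msn = ms if ms.normalized else normalize_distances(ms)
    curves = far_frr_curves(msn, n_steps=n_steps)
    eer, thr = compute_eer(curves)
    roc, auc = roc_auc(msn)
    t, df, p = welch_t_test(raw_intra, raw_inter)
    report = EvalReport(
        eer=eer, eer_threshold=thr, auc=auc,
        welch_t=t, welch_df=df, welch_p=p,
        n_intra=int(raw_intra.size), n_inter=int(raw_inter.size),
        mean_intra=float(raw_intra.mean()), mean_inter=float(raw_inter.mean()),
        method=method,
    )
    return report, curves, roc


def save_scores(path: str | Path, ms: MatchSet) -> Path:
    """Scores CSV: pair_type, id_a, id_b, distance."""
    rows = [("intra", a, b, d) for (a, b), d in zip(ms.intra_pairs, ms.intra)]
    rows += [("inter", a, b, d) for (a, b), d in zip(ms.inter_pairs, ms.inter)]
    df = pd.DataFrame(rows, columns=["pair_type", "id_a", "id_b", "distance"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_scores(path: str | Path) -> MatchSet:
    df = pd.read_csv(path)
    need = {"pair_type", "id_a", "id_b", "distance"}
    if not need <= set(df.columns):
        raise ContractError(f"scores CSV needs columns {sorted(need)}")
    intra = df[df.pair_type == "intra"]
    inter = df[df.pair_type == "inter"]
    return MatchSet(
        intra=intra.distance.to_numpy(float),
        inter=inter.distance.to_numpy(float),
        intra_pairs=list(zip(intra.id_a, intra.id_b)),
        inter_pairs=list(zip(inter.id_a, inter.id_b)),
    )
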