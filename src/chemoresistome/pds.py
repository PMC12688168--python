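"""Principal-curve pathway deregulation score (PDS).

For each pathway, all samples are embedded in a low-dimensional space of the
pathway's genes (standardized against the normal samples, then PCA), a
one-dimensional principal curve is threaded through the cloud, and each
sample is summarized by its arc-length position along the curve. The PDS of
a sample is how far beyond the normal samples' typical position it sits:
the arc-length distance from the normal median, minus the normals' median
such distance, floored at zero, and normalized per pathway to [0, 1]. By
construction the median PDS of the normal samples is exactly 0 and the most
deviant sample scores 1.

This is a deliberately simplified relative of published
principal-curve deregulation scoring: the curve is a Hastie–Stuetzle fit
(alternate projection and per-coordinate scatterplot smoothing, initialized
at the first principal component) without additional gene-filtering or
curve-stability heuristics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import GeneSetCollection
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class PrincipalCurve:
    """Fitted one-dimensional curve: ordered nodes plus per-sample arc lengths."""

    nodes: np.ndarray        # (m, d) polyline vertices in fit order
    arc_lengths: np.ndarray  # (n,) arc-length coordinate of each sample's projection
    residuals: np.ndarray    # (n,) Euclidean distance sample -> projection
    n_iter: int
    converged: bool


def _project_polyline(points: np.ndarray, nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline; returns (arc_lengths, distances)."""
    seg = np.diff(nodes, axis=0)                      # (m-1, d)
    seg_len2 = (seg ** 2).sum(axis=1)
    seg_len = np.sqrt(seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # t of the projection of every point on every segment, clamped to [0,1]
    diffs = points[:, None, :] - nodes[None, :-1, :]  # (n, m-1, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("nmd,md->nm", diffs, seg) / np.where(seg_len2 > 0, seg_len2, 1.0)
    t = np.clip(t, 0.0, 1.0)
    proj = nodes[None, :-1, :] + t[:, :, None] * seg[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    idx = np.arange(len(points))
    lam = cum[best] + t[idx, best] * seg_len[best]
    return lam, np.sqrt(d2[idx, best])


def fit_principal_curve(
    points: np.ndarray,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
    span: float = 0.6,
) -> PrincipalCurve:
    """Hastie–Stuetzle principal curve through an (n, d) point cloud.

    Initialization at the first principal component; each iteration orders
    the samples by their current arc-length coordinate, smooths every
    coordinate against it (lowess with fraction ``span``), rebuilds the
    polyline, and reprojects. Stops when the mean squared projection
    distance changes by less than ``tol``, or after ``max_iter`` iterations.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or len(pts) < 3:
        raise ValidationError("fit_principal_curve needs >= 3 samples")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("non-finite coordinates")
    center = pts.mean(axis=0)
    x = pts - center
    if np.allclose(x, 0):
        raise ValidationError("all points identical; principal curve undefined")

    # PC1 initialization
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    lam = x @ vt[0]
    nodes = np.outer(np.sort(lam), vt[0])
    lam, dist = _project_polyline(x, nodes)
    mse = float(np.mean(dist ** 2))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        order = np.argsort(lam, kind="stable")
        lam_s = lam[order]
        smoothed = np.empty_like(x[order])
        delta = 0.01 * max(lam_s[-1] - lam_s[0], 1e-12)
        for j in range(x.shape[1]):
            sm = lowess(x[order, j], lam_s, frac=span, it=0, delta=delta,
                        return_sorted=False)
            smoothed[:, j] = sm
        # collapse consecutive duplicate vertices so segments are nondegenerate
        keep = np.concatenate([[True], np.any(np.diff(smoothed, axis=0) != 0, axis=1)])
        nodes = smoothed[keep]
        if len(nodes) < 2:
            break  # curve collapsed to a point; keep previous projection
        lam, dist = _project_polyline(x, nodes)
        new_mse = float(np.mean(dist ** 2))
        if abs(mse - new_mse) < tol:
            mse = new_mse
            converged = True
            break
        mse = new_mse
    return PrincipalCurve(nodes + center, lam, dist, it, converged)


# ---------------------------------------------------------------- PDS

@dataclass
class PDSRecord:
    sample: str
    pathway: str
    pds: float
    curve_position: float


def compute_pds(
    expression: pd.DataFrame,
    pathway_genes: Iterable[str],
    normal_sample_ids: Sequence[str],
    *,
    pathway: str = "",
    var_explained: float = 0.9,
    max_components: int = 5,
    **curve_kw,
) -> list[PDSRecord] | None:
    """PDS of every sample for one pathway, or None when the pathway is
    unusable (< 3 genes present in the expression matrix).

    ``expression`` is genes x samples on a normalized (log-like) scale.
    Genes are standardized by the normal samples' mean and SD (falling back
    to the overall SD for genes constant in normals), samples reduced by PCA
    to the leading components explaining ``var_explained`` of variance
    (capped at ``max_components``), and a principal curve is fitted over all
    samples.
    """
    genes = [g for g in pathway_genes if g in expression.index]
    if len(genes) < 3:
        log.info("compute_pds: pathway %s skipped (%d usable genes < 3)", pathway, len(genes))
        return None
    normals = [s for s in normal_sample_ids if s in expression.columns]
    if len(normals) < 2:
        raise ValidationError("compute_pds needs >= 2 normal samples")
    sub = expression.loc[genes]
    mean = sub[normals].mean(axis=1)
    sd = sub[normals].std(axis=1, ddof=0)
    overall_sd = sub.std(axis=1, ddof=0)
    sd = sd.where(sd > 1e-8, overall_sd)
    usable = sd > 1e-8
    if usable.sum() < 3:
        log.info("compute_pds: pathway %s skipped (constant expression)", pathway)
        return None
    z = ((sub[usable.to_numpy()].T - mean[usable]) / sd[usable]).to_numpy()  # samples x genes

    # PCA on the standardized pathway space
    zc = z - z.mean(axis=0)
    u, s, _ = np.linalg.svd(zc, full_matrices=False)
    var = s ** 2
    if var.sum() == 0:
        log.info("compute_pds: pathway %s skipped (no variance)", pathway)
        return None
    frac = np.cumsum(var) / var.sum()
    ncomp = int(np.searchsorted(frac, var_explained) + 1)
    ncomp = min(max(ncomp, 1), max_components, len(s))
    coords = u[:, :ncomp] * s[:ncomp]

    curve = fit_principal_curve(coords, **curve_kw)
    lam = curve.arc_lengths
    sample_ids = list(expression.columns)
    normal_idx = [sample_ids.index(s) for s in normals]
    med = np.median(lam[normal_idx])
    d = np.abs(lam - med)
    d0 = np.median(d[normal_idx])
    pds_raw = np.clip(d - d0, 0.0, None)
    top = pds_raw.max()
    pds = pds_raw / top if top > 0 else pds_raw
    return [PDSRecord(sid, pathway, float(v), float(l))
            for sid, v, l in zip(sample_ids, pds, lam)]


def compute_pds_collection(
    expression: pd.DataFrame,
    collection: GeneSetCollection,
    normal_sample_ids: Sequence[str],
    **kw,
) -> pd.DataFrame:
    """PDS matrix (pathways x samples) over a whole gene-set collection.

    Unusable pathways are skipped with a logged reason.
    """
    rows = {}
    for gs in collection:
        recs = compute_pds(expression, gs.genes, normal_sample_ids, pathway=gs.name, **kw)
        if recs is None:
            continue
        rows[gs.name] = {r.sample: r.pds for r in recs}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(expression.columns))
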