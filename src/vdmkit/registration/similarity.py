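"""Similarity measures: normalized cross-correlation, mutual information, SSD.

Each measure has two layers: a fast sample-array kernel returning the score
and its gradient with respect to the moving sample values (used inside the
optimizer), and a public image-level function matching the pipeline contracts
(fixed image, moving image, optional transform, domain mask).

MI uses Parzen windowing: a linear (hat) window on the fixed-intensity axis
and a cubic B-spline window on the moving axis, so the score is differentiable
in the moving intensities.  The public function reports MI in bits.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from ..core import ImageVolume
from .bspline import bspline3, bspline3_deriv

__all__ = ["ncc", "mutual_information", "ncc_and_grad", "mi_and_grad", "ssd_and_grad"]


# ---------------------------------------------------------------------------
# sample-array kernels


def ncc_and_grad(fv: np.ndarray, mv: np.ndarray) -> tuple[float, np.ndarray]:
    """NCC of two sample vectors and d(NCC)/d(mv)."""
    n = fv.size
    fc = fv - fv.mean()
    mc = mv - mv.mean()
    sf = np.sqrt(np.dot(fc, fc))
    sm = np.sqrt(np.dot(mc, mc))
    if sf == 0 or sm == 0:
        raise ValueError("NCC undefined: an image is constant over the domain")
    num = np.dot(fc, mc)
    score = num / (sf * sm)
    # d/dmv: centering projects out the mean component
    g = fc / (sf * sm) - (num / (sf * sm**3)) * mc
    return float(score), g


def ssd_and_grad(fv: np.ndarray, mv: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared difference and gradient w.r.t. moving samples."""
    d = mv - fv
    return float(np.mean(d * d)), (2.0 / d.size) * d


def _parzen_weights(vals: np.ndarray, lo: float, hi: float, nbins: int):
    """Cubic-B-spline bin weights: indices (N,4), weights, d(weights)/d(val)."""
    width = (hi - lo) / (nbins - 3)  # 3 bins of padding absorb the support
    pos = (vals - lo) / width + 1.0  # continuous bin coordinate
    base = np.floor(pos).astype(int)
    idx = base[:, None] + np.arange(-1, 3)[None, :]
    t = pos[:, None] - idx
    w = bspline3(t)
    dw = bspline3_deriv(t) / width
    np.clip(idx, 0, nbins - 1, out=idx)
    return idx, w, dw


def _hat_weights(vals: np.ndarray, lo: float, hi: float, nbins: int):
    width = (hi - lo) / (nbins - 1)
    pos = (vals - lo) / width
    base = np.clip(np.floor(pos).astype(int), 0, nbins - 2)
    frac = pos - base
    idx = np.stack([base, base + 1], axis=1)
    w = np.stack([1.0 - frac, frac], axis=1)
    return idx, w


def mi_and_grad(
    fv: np.ndarray,
    mv: np.ndarray,
    nbins: int = 32,
    f_range: Optional[tuple[float, float]] = None,
    m_range: Optional[tuple[float, float]] = None,
) -> tuple[float, np.ndarray]:
    """Mutual information (nats) of paired samples and d(MI)/d(mv).

    The fixed marginal is invariant to moving-intensity changes (B-spline
    partition of unity), so the gradient only involves log(p / p_m).
    """
    n = fv.size
    flo, fhi = f_range if f_range else (float(fv.min()), float(fv.max()))
    mlo, mhi = m_range if m_range else (float(mv.min()), float(mv.max()))
    if fhi <= flo or mhi <= mlo:
        raise ValueError("MI undefined: an image is constant over the domain")
    fi, fw = _hat_weights(np.clip(fv, flo, fhi), flo, fhi, nbins)
    mi_idx, mw, mdw = _parzen_weights(np.clip(mv, mlo, mhi), mlo, mhi, nbins)

    joint = np.zeros(nbins * nbins)
    for a in range(2):
        for b in range(4):
            np.add.at(joint, fi[:, a] * nbins + mi_idx[:, b], fw[:, a] * mw[:, b])
    joint = joint.reshape(nbins, nbins) / n
    pf = joint.sum(axis=1)
    pm = joint.sum(axis=0)
    nz = joint > 1e-12
    outer_pm = np.broadcast_to(pf[:, None] * pm[None, :], joint.shape)
    mi_val = float(np.sum(joint[nz] * (np.log(joint[nz]) - np.log(outer_pm[nz]))))

    # gradient: dMI/dmv_i = (1/n) Σ_{a,b} fw_a * mdw_b * log(p_ab / pm_b)
    log_ratio = np.zeros_like(joint)
    pm_b = np.broadcast_to(np.maximum(pm, 1e-300), joint.shape)
    log_ratio[nz] = np.log(joint[nz] / pm_b[nz])
    g = np.zeros(n)
    for a in range(2):
        for b in range(4):
            g += fw[:, a] * mdw[:, b] * log_ratio[fi[:, a], mi_idx[:, b]]
    return mi_val, g / n


# ---------------------------------------------------------------------------
# public image-level measures


def _domain_samples(
    fixed: ImageVolume,
    moving: ImageVolume,
    transform: Optional[Callable[[np.ndarray], np.ndarray]],
    domain: Optional[ImageVolume],
) -> tuple[np.ndarray, np.ndarray]:
    if domain is not None:
        sel = domain.data.astype(bool)
        if not sel.any():
            raise ValueError("similarity domain is empty")
        idx = np.argwhere(sel)
    else:
        idx = np.argwhere(np.ones(fixed.grid.shape, dtype=bool))
    pts = fixed.grid.index_to_world(idx)
    fv = fixed.data[tuple(idx.T)].astype(float)
    warped = transform(pts) if transform is not None else pts
    mv = moving.sample(warped, order=1)
    return fv, mv


def ncc(
    fixed: ImageVolume,
    moving: ImageVolume,
    transform: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    domain: Optional[ImageVolume] = None,
) -> float:
    """Mean-subtracted normalized cross-correlation over the domain, in [-1, 1]."""
    fv, mv = _domain_samples(fixed, moving, transform, domain)
    return ncc_and_grad(fv, mv)[0]


def mutual_information(
    fixed: ImageVolume,
    moving: ImageVolume,
    transform: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    domain: Optional[ImageVolume] = None,
    nbins: int = 32,
) -> float:
    """Parzen-window mutual information over the domain, in bits."""
    fv, mv = _domain_samples(fixed, moving, transform, domain)
    if fv.size == 0:
        raise ValueError("empty overlap between images")
    val, _ = mi_and_grad(fv, mv, nbins=nbins)
    return val / np.log(2.0)
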