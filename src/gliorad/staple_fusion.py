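"""Multi-rater, multi-label STAPLE fusion by expectation-maximization.

STAPLE (Simultaneous Truth And Performance Level Estimation) treats the
unknown true label of each voxel as a latent variable and each rater
(here: each automatic segmentation scheme) as a noisy channel described
by a K×K confusion matrix theta_j, where ``theta_j[s, s']`` is the
probability that rater j emits label s' when the truth is s.  EM
alternates:

* E-step: per-voxel posterior ``W_i(s) ∝ prior(s) · Π_j theta_j[s, d_ij]``,
* M-step: ``theta_j[s, s'] = Σ_i W_i(s)·1[d_ij = s'] / Σ_i W_i(s)``,

until the mean absolute change of theta drops below tolerance.  The
fused map is the per-voxel argmax of W, ties broken by higher prior
frequency then lower numeric label.

This is the full multi-category model over the BraTS alphabet
(0, 1, 2, 4) — one EM for the complete label map rather than one binary
STAPLE per structure — with a static (not re-estimated) label prior for
stability on small alphabets.  Computation is restricted to the union
bounding box of all nonzero voxels dilated by 3 voxels; outside it all
raters agree on background, and such unanimous voxels are fused as
background directly.  The restriction is an explicit, logged
approximation (it leaves the M-step counts of the background row
dominated by the box's background voxels rather than the whole grid's).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volumes_core import DataError, GeometryError, LabelVolume

logger = logging.getLogger("gliorad")

DEFAULT_ALPHABET = (0, 1, 2, 4)
EPS = 1e-12


@dataclass
class RaterSet:
    """Two or more label maps on one grid plus their label alphabet."""

    maps: list[LabelVolume]
    alphabet: tuple[int, ...] = DEFAULT_ALPHABET

    def __post_init__(self):
        if len(self.maps) < 2:
            raise DataError("STAPLE needs at least 2 raters")
        ref = self.maps[0]
        for m in self.maps[1:]:
            if m.shape != ref.shape or not np.allclose(m.spacing, ref.spacing):
                raise GeometryError("rater maps on different grids")
        allowed = set(self.alphabet)
        for j, m in enumerate(self.maps):
            extra = m.labels() - allowed
            if extra:
                raise DataError(f"rater {j} uses labels {sorted(extra)} outside alphabet")


@dataclass
class ConfusionParams:
    """Per-rater confusion matrices over the alphabet (rows = true label)."""

    theta: np.ndarray  # (n_raters, K, K)
    alphabet: tuple[int, ...]

    def __post_init__(self):
        rows = self.theta.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise DataError("confusion-matrix rows must sum to 1")


@dataclass
class FusionResult:
    fused: LabelVolume
    theta: ConfusionParams
    prior: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0


def initialize_params(raters: RaterSet) -> tuple[ConfusionParams, np.ndarray]:
    """Symmetric initialization: diagonal 0.95; prior from majority vote.

    The prior is the label-frequency histogram of the voxel-wise
    majority vote (ties to the lower alphabet index), smoothed by 1e-6
    so every label keeps positive mass.
    """
    K = len(raters.alphabet)
    n = len(raters.maps)
    theta = np.full((n, K, K), 0.05 / (K - 1))
    for j in range(n):
        np.fill_diagonal(theta[j], 0.95)

    lut = _label_lut(raters.alphabet)
    counts = np.zeros((K,) + raters.maps[0].shape, dtype=np.int32)
    for m in raters.maps:
        idx = lut[m.data]
        for k in range(K):
            counts[k] += idx == k
    majority = counts.argmax(axis=0)  # ties -> lower index
    freq = np.bincount(majority.ravel(), minlength=K).astype(float)
    prior = freq + 1e-6 * freq.sum()
    prior /= prior.sum()
    return ConfusionParams(theta=theta, alphabet=raters.alphabet), prior


def _label_lut(alphabet) -> np.ndarray:
    lut = np.full(max(alphabet) + 1, -1, dtype=np.int64)
    for k, lbl in enumerate(alphabet):
        lut[lbl] = k
    return lut


def _union_bbox(maps: list[LabelVolume], margin: int = 3):
    union = np.zeros(maps[0].shape, dtype=bool)
    for m in maps:
        union |= m.data > 0
    if not union.any():
        return None
    coords = np.argwhere(union)
    lo = np.maximum(coords.min(axis=0) - margin, 0)
    hi = np.minimum(coords.max(axis=0) + margin + 1, maps[0].shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def staple_fuse(
    raters: RaterSet,
    max_iter: int = 100,
    tol: float = 1e-6,
    prior: np.ndarray | None = None,
) -> FusionResult:
    """Fuse rater label maps into a consensus map by STAPLE EM.

    ``prior`` optionally overrides the majority-vote label prior; labels
    present in the data but given zero prior are repaired by epsilon
    smoothing (logged).  The log-likelihood trace is non-decreasing up
    to numerical tolerance; convergence is mean absolute theta change
    below ``tol``.
    """
    alphabet = raters.alphabet
    K = len(alphabet)
    n_raters = len(raters.maps)
    params, default_prior = initialize_params(raters)
    theta = params.theta
    if prior is None:
        prior = default_prior
    else:
        prior = np.asarray(prior, dtype=float).copy()
        if prior.shape != (K,):
            raise DataError(f"prior must have length {K}")
        present = np.zeros(K, dtype=bool)
        lut = _label_lut(alphabet)
        for m in raters.maps:
            present[np.unique(lut[m.data])] = True
        degenerate = present & (prior <= 0)
        if degenerate.any():
            logger.warning(
                "prior gives zero mass to observed labels %s; epsilon-smoothing",
                [alphabet[k] for k in np.where(degenerate)[0]],
            )
            prior = prior + 1e-6
        prior = prior / prior.sum()

    sl = _union_bbox(raters.maps)
    shape = raters.maps[0].shape
    fused_full = np.zeros(shape, dtype=np.int16)
    if sl is None:  # all raters all-background
        trace = [0.0]
        return FusionResult(
            fused=LabelVolume(fused_full, raters.maps[0].spacing),
            theta=ConfusionParams(theta=theta, alphabet=alphabet),
            prior=prior, loglik_trace=trace, n_iter=0,
        )
    logger.debug("STAPLE restricted to bbox %s of grid %s", sl, shape)

    lut = _label_lut(alphabet)
    D = np.stack([lut[m.data[sl]].ravel() for m in raters.maps], axis=1)  # (V, J)
    V = D.shape[0]

    log_prior = np.log(prior + EPS)
    trace: list[float] = []
    W = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step in log space
        logW = np.broadcast_to(log_prior, (V, K)).copy()
        for j in range(n_raters):
            logW += np.log(theta[j, :, D[:, j]] + EPS)  # (V, K)
        m = logW.max(axis=1, keepdims=True)
        lik = np.exp(logW - m)
        norm = lik.sum(axis=1, keepdims=True)
        W = lik / norm
        trace.append(float((m[:, 0] + np.log(norm[:, 0])).sum()))

        # M-step
        new_theta = np.empty_like(theta)
        Wsum = W.sum(axis=0) + EPS  # (K,)
        for j in range(n_raters):
            counts = np.zeros((K, K))
            for k_obs in range(K):
                sel = D[:, j] == k_obs
                if sel.any():
                    counts[:, k_obs] = W[sel].sum(axis=0)
            new_theta[j] = counts / Wsum[:, None]
            # guard: rows of a label never observed anywhere stay stochastic
            zero_rows = new_theta[j].sum(axis=1) < EPS
            new_theta[j][zero_rows] = 1.0 / K
        delta = float(np.abs(new_theta - theta).mean())
        theta = new_theta
        if delta < tol:
            break

    # fused labels: argmax of W; ties by higher prior, then lower label value
    order = np.lexsort((alphabet, -prior))  # preferred label order for ties
    Wo = W[:, order]
    fused_idx = order[Wo.argmax(axis=1)]  # argmax picks first max in ordered view
    fused_box = np.asarray(alphabet, dtype=np.int16)[fused_idx].reshape(
        tuple(s.stop - s.start for s in sl)
    )
    fused_full[sl] = fused_box
    return FusionResult(
        fused=LabelVolume(fused_full, raters.maps[0].spacing),
        theta=ConfusionParams(theta=theta, alphabet=alphabet),
        prior=prior,
        loglik_trace=trace,
        n_iter=n_iter,
    )
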