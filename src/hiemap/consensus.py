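"""Multi-rater annotation fusion (binary STAPLE EM) and agreement stats.

STAPLE (Simultaneous Truth And Performance Level Estimation) treats the
unknown true segmentation as a latent binary field and each rater j as a
noisy channel with sensitivity p_j and specificity q_j.  The EM
iteration alternates a per-voxel posterior of the true label (E-step)
with closed-form re-estimates of every rater's (p_j, q_j) (M-step); the
posterior at convergence is the probabilistic consensus, thresholded at
0.5 for a binary reference.  Loosely, it is majority voting with raters
reweighted by their estimated reliability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hiemap.core_io import ValidationError, Volume3D, require_same_grid
from hiemap.detect import score_detection

__all__ = ["ConsensusResult", "staple_fuse", "inter_rater_dice", "staple_log_likelihood"]


@dataclass(frozen=True)
class ConsensusResult:
    prob: Volume3D
    consensus: Volume3D
    sensitivities: np.ndarray  # p_j, NaN when undefined (all raters blank)
    specificities: np.ndarray  # q_j
    iterations: int
    converged: bool
    all_blank: bool = False


def _rater_matrix(raters: list[Volume3D]) -> np.ndarray:
    if len(raters) < 2:
        raise ValidationError("fusion needs at least 2 raters")
    ref = raters[0]
    for r in raters[1:]:
        require_same_grid(ref, r, "rater masks")
    return np.stack([(r.data > 0).ravel() for r in raters]).astype(np.float64)


def staple_log_likelihood(D: np.ndarray, p: np.ndarray, q: np.ndarray,
                          prior: float) -> float:
    """Observed-data log-likelihood of rater decisions D (raters x voxels)."""
    a, b = _posterior_terms(D, p, q, prior)
    return float(np.log(a + b).sum())


def _posterior_terms(D: np.ndarray, p: np.ndarray, q: np.ndarray,
                     prior: float) -> tuple[np.ndarray, np.ndarray]:
    eps = 1e-12
    logp = D.T @ np.log(p + eps) + (1 - D.T) @ np.log(1 - p + eps)
    logq = D.T @ np.log(1 - q + eps) + (1 - D.T) @ np.log(q + eps)
    a = prior * np.exp(logp)
    b = (1 - prior) * np.exp(logq)
    return a, b


def staple_fuse(raters: list[Volume3D], prior: float | str = "from-data",
                tol: float = 1e-6, max_iter: int = 100) -> ConsensusResult:
    """Fuse rater masks into a probabilistic consensus by binary STAPLE EM.

    ``prior`` is the prior probability that a voxel is truly lesioned;
    the default "from-data" uses the mean positive fraction across
    raters.  Rater performance is initialized at p_j = q_j = 0.99 and
    iterated until the summed change in (p, q) drops below ``tol``.
    If every rater is blank the consensus is blank and per-rater
    performance is reported missing (NaN) with a flag.
    """
    D = _rater_matrix(raters)
    ref = raters[0]
    shape = ref.shape
    n_raters = D.shape[0]

    if not D.any():
        nan = np.full(n_raters, np.nan)
        zero = ref.with_data(np.zeros(shape))
        return ConsensusResult(prob=zero, consensus=zero, sensitivities=nan,
                               specificities=nan, iterations=0, converged=True,
                               all_blank=True)

    if prior == "from-data":
        prior_val = float(D.mean())
    else:
        prior_val = float(prior)
        if not (0.0 < prior_val < 1.0):
            raise ValidationError("prior must lie in (0, 1)")
    prior_val = min(max(prior_val, 1e-6), 1 - 1e-6)

    p = np.full(n_raters, 0.99)
    q = np.full(n_raters, 0.99)
    W = np.zeros(D.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        a, b = _posterior_terms(D, p, q, prior_val)
        W = a / (a + b)
        wsum = W.sum()
        nsum = (1 - W).sum()
        new_p = (D @ W) / wsum if wsum > 0 else p
        new_q = ((1 - D) @ (1 - W)) / nsum if nsum > 0 else q
        new_p = np.clip(new_p, 1e-6, 1 - 1e-6)
        new_q = np.clip(new_q, 1e-6, 1 - 1e-6)
        delta = np.abs(new_p - p).sum() + np.abs(new_q - q).sum()
        p, q = new_p, new_q
        if delta < tol:
            converged = True
            break

    prob = ref.with_data(W.reshape(shape))
    consensus = ref.with_data((W >= 0.5).reshape(shape).astype(np.float64))
    return ConsensusResult(prob=prob, consensus=consensus, sensitivities=p,
                           specificities=q, iterations=it, converged=converged)


def inter_rater_dice(raters: list[Volume3D]) -> tuple[dict[tuple[int, int], float], float]:
    """Pairwise Dice over all unordered rater pairs, plus the mean."""
    if len(raters) < 2:
        raise ValidationError("need at least 2 raters")
    table = {}
    for i in range(len(raters)):
        for j in range(i + 1, len(raters)):
            table[(i, j)] = score_detection(raters[i], raters[j]).dice
    return table, float(np.mean(list(table.values())))
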