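"""Information-maximization ICA (Infomax) for spatial decomposition.

Natural-gradient Infomax with the logistic nonlinearity and a bias term
(optionally the extended variant with a kurtosis-switched nonlinearity),
after PCA pre-whitening to the requested model order.  Updates run over
seeded random mini-batches with an annealed learning rate; weight blow-up
triggers a restart at a smaller rate.  Written for the maps x voxels
spatial-ICA setting: observations are voxels, mixed channels are maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class InfomaxResult:
    sources: np.ndarray      # (n_components, n_samples), unit variance
    mixing: np.ndarray       # (n_rows, n_components): X_centered ~ mixing @ sources
    unmixing: np.ndarray     # weights in whitened space
    n_iter: int
    converged: bool


def _pca_whiten(x: np.ndarray, n_components: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-centered PCA whitening; returns (z, whitener, dewhitener)."""
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    s = s[:n_components]
    u = u[:, :n_components]
    scale = np.sqrt(x.shape[1])
    z = vt[:n_components] * scale  # whitened: z z^T / n = I
    whitener = (u / s).T * scale
    dewhitener = u * s / scale
    return z, whitener, dewhitener


def infomax(x: np.ndarray, n_components: int, seed: int = 0,
            extended: bool = False, lr: float | None = None,
            max_iter: int = 512, tol: float = 1e-7,
            anneal_step: float = 0.9, anneal_deg: float = 60.0,
            max_restarts: int = 5) -> InfomaxResult:
    """Run Infomax ICA on ``x`` (rows = mixed signals, columns = samples).

    One iteration is a full pass over the samples in seeded random
    mini-batches, applying the natural-gradient update
    ``dW = lr (I + phi(u) u^T) W`` per batch (phi = 1 - 2 logistic(u), plus a
    bias update).  The learning rate is annealed whenever the direction of
    the per-pass weight change turns by more than ``anneal_deg`` degrees;
    convergence is declared when the relative per-pass weight change falls
    below ``tol``.  Diverging weights restart the pass with a halved rate
    (bounded by ``max_restarts``); if no run converges the best-scoring run
    is returned with ``converged=False``.
    """
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    z, _, dewhiten = _pca_whiten(x, n_components)
    k, n = z.shape
    block = int(np.ceil(min(5.0 * np.log(n), 0.3 * n)))
    base_lr = lr if lr is not None else 0.01 / np.log(max(k, 3))

    best: tuple[float, np.ndarray, np.ndarray, int, bool] | None = None
    eye = np.eye(k)
    for restart in range(max_restarts):
        rng = np.random.default_rng(seed + 1000 * restart)
        w = eye.copy() if restart == 0 else np.linalg.qr(
            rng.normal(size=(k, k)))[0]
        bias = np.zeros((k, 1))
        step = base_lr * (0.5 ** restart)
        prev_delta: np.ndarray | None = None
        converged = False
        blown_up = False
        it = 0
        for it in range(1, max_iter + 1):
            order = rng.permutation(n)
            w_start = w.copy()
            for lo in range(0, n - block + 1, block):
                u = w @ z[:, order[lo:lo + block]] + bias
                if extended:
                    kurt = np.mean(u ** 4, axis=1) - 3.0 * np.mean(u ** 2, axis=1) ** 2
                    sign = np.where(kurt >= 0, 1.0, -1.0)[:, None]
                    phi = -(sign * np.tanh(u) + u)
                else:
                    phi = 1.0 - 2.0 / (1.0 + np.exp(-u))
                w = w + step * ((eye + (phi @ u.T) / block) @ w)
                bias = bias + step * phi.mean(axis=1, keepdims=True)
                if not np.all(np.isfinite(w)) or np.max(np.abs(w)) > 1e8:
                    blown_up = True
                    break
            if blown_up:
                break
            delta = (w - w_start).ravel()
            ndelta = np.linalg.norm(delta)
            if prev_delta is not None and ndelta > 0 and np.linalg.norm(prev_delta) > 0:
                cosang = float(delta @ prev_delta /
                               (ndelta * np.linalg.norm(prev_delta)))
                if cosang < np.cos(np.deg2rad(anneal_deg)):
                    step *= anneal_step
            prev_delta = delta
            if ndelta / max(np.linalg.norm(w_start), 1e-12) < tol:
                converged = True
                break
        if blown_up:
            continue
        u = w @ z
        score = -float(np.mean(np.log(np.cosh(u))))  # sparsity of the sources
        if best is None or (converged and not best[4]) or (
                converged == best[4] and score > best[0]):
            best = (score, w, bias, it, converged)
        if converged:
            break

    if best is None:
        raise RuntimeError("Infomax diverged on every restart")
    _, w, bias, n_iter, converged = best
    sources = w @ z
    sd = sources.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    sources = (sources - sources.mean(axis=1, keepdims=True)) / sd
    mixing = dewhiten @ np.linalg.inv(w) * sd.T
    return InfomaxResult(sources, mixing, w, n_iter, converged)
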