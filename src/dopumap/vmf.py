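"""von Mises-Fisher sampling on the Poincare sphere.

The mean resultant length of a 3-D vMF distribution with concentration
kappa is the Langevin function L(kappa) = coth(kappa) - 1/kappa.  Because
DOPU is exactly the resultant length of window-averaged normalized Stokes
vectors, drawing per-voxel polarization directions from vMF(mu, kappa)
with L(kappa) equal to a target value makes the expected large-window DOPU
equal that target.
"""

from __future__ import annotations

import numpy as np

__all__ = ["langevin", "kappa_from_resultant", "sample_vmf"]


def langevin(kappa):
    """Mean resultant length L(kappa) = coth(kappa) - 1/kappa of a 3-D vMF.

    Uses the small-argument series below 1e-4 to avoid cancellation.
    """
    kappa = np.asarray(kappa, dtype=float)
    out = np.empty_like(kappa)
    small = kappa < 1e-4
    k = kappa[~small]
    out[~small] = 1.0 / np.tanh(k) - 1.0 / k
    ks = kappa[small]
    out[small] = ks / 3.0 - ks**3 / 45.0
    return out if out.ndim else float(out)


def kappa_from_resultant(rho):
    """Invert the Langevin function: concentration giving resultant length rho.

    Vectorized: a Banerjee-style starting guess ``rho (3 - rho^2)/(1 - rho^2)``
    refined by Newton iterations on L(kappa) - rho; accurate to ~1e-12 over
    rho in (0, 1).  rho = 0 maps to 0 (uniform), rho = 1 to +inf.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("target resultant length must lie in [0, 1]")
    kappa = np.where(rho < 1.0, rho * (3.0 - rho**2) / np.maximum(1.0 - rho**2, 1e-300), np.inf)
    finite = np.isfinite(kappa) & (rho > 0)
    k = kappa[finite]
    r = rho[finite]
    for _ in range(50):
        # L'(kappa) = 1/kappa^2 - 1/sinh(kappa)^2
        f = (1.0 / np.tanh(k) - 1.0 / k) - r
        sinh2 = np.sinh(np.minimum(k, 350.0)) ** 2
        deriv = 1.0 / k**2 - 1.0 / sinh2
        step = f / np.maximum(deriv, 1e-300)
        k = np.maximum(k - step, 1e-12)
        if np.all(np.abs(f) < 1e-13):
            break
    kappa[finite] = k
    return kappa if kappa.ndim else float(kappa)


def _rotate_from_pole(xyz: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Rotate samples whose mean is +z so their mean becomes mu."""
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if np.allclose(mu, [0.0, 0.0, 1.0]):
        return xyz
    if np.allclose(mu, [0.0, 0.0, -1.0]):
        out = xyz.copy()
        out[..., 2] *= -1
        out[..., 0] *= -1
        return out
    # Rodrigues rotation taking +z to mu
    axis = np.cross([0.0, 0.0, 1.0], mu)
    s = np.linalg.norm(axis)
    axis = axis / s
    c = mu[2]
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    return xyz @ R.T


def sample_vmf(mu, kappa, size=None, rng=None) -> np.ndarray:
    """Draw unit vectors from vMF(mu, kappa) on the 2-sphere.

    ``kappa`` may be a scalar or an array broadcastable to ``size``;
    kappa = 0 gives the uniform distribution, kappa = inf the point mass
    at ``mu``.  Returns an array of shape ``size + (3,)``.
    """
    rng = np.random.default_rng(rng)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    if size is None:
        size = kappa.shape
    size = tuple(np.atleast_1d(size)) if not isinstance(size, tuple) else size
    kappa = np.broadcast_to(kappa, size)

    u = rng.random(size)
    w = np.empty(size, dtype=float)
    tiny = kappa < 1e-8
    inf = np.isinf(kappa)
    mid = ~tiny & ~inf
    w[tiny] = 2.0 * u[tiny] - 1.0
    w[inf] = 1.0
    k = kappa[mid]
    # inverse-CDF of the marginal along mu (Ulrich/Wood construction)
    w[mid] = 1.0 + np.log(u[mid] + (1.0 - u[mid]) * np.exp(-2.0 * k)) / k

    phi = rng.random(size) * (2.0 * np.pi)
    s = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    xyz = np.stack([s * np.cos(phi), s * np.sin(phi), w], axis=-1)
    return _rotate_from_pole(xyz, mu)
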