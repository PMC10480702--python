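"""Real spherical-harmonics analysis and synthesis on equiangular grids.

Low-level numerical core used by :mod:`spheroidkit.spharm`.  Functions on the
unit sphere are sampled on a midpoint equiangular grid (colatitude
``theta_j = pi*(j+0.5)/n_lat``, longitude ``phi_k = 2*pi*k/n_lon``) and
expanded in the real orthonormal basis

    Y_l0        =           Lambda_l0(cos theta)
    Y_lm^cos    = sqrt(2) * Lambda_lm(cos theta) * cos(m phi)
    Y_lm^sin    = sqrt(2) * Lambda_lm(cos theta) * sin(m phi)

where ``Lambda_lm = sqrt((2l+1)/(4 pi) * (l-m)!/(l+m)!) * P_lm`` is the fully
normalised associated Legendre function (Condon-Shortley phase included; the
phase cancels in all energy quantities).  The longitude sums are evaluated
with a real FFT, the colatitude sums with sin(theta)-weighted midpoint
quadrature, so one analysis costs O(n_lat * n_lon * log(n_lon) + n_lat * lmax^2).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "legendre_normalized",
    "grid_angles",
    "quadrature_weights",
    "analyze_grid",
    "synthesize_grid",
    "band_energies",
]


def legendre_normalized(lmax: int, x: np.ndarray) -> np.ndarray:
    """Fully normalised associated Legendre functions Lambda_lm(x).

    Parameters
    ----------
    lmax : int
        Maximum degree.
    x : ndarray, shape (n,)
        Arguments in [-1, 1] (cos of colatitude).

    Returns
    -------
    ndarray, shape (lmax+1, lmax+1, n)
        ``out[l, m]`` holds Lambda_lm(x); entries with m > l are zero.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("Legendre argument outside [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    s = np.sqrt(1.0 - x * x)  # sin(theta) >= 0
    n = x.shape[0]
    lam = np.zeros((lmax + 1, lmax + 1, n))
    lam[0, 0] = np.sqrt(1.0 / (4.0 * np.pi))
    # diagonal: Lambda_mm = -sqrt((2m+1)/(2m)) * s * Lambda_{m-1,m-1}
    for m in range(1, lmax + 1):
        lam[m, m] = -np.sqrt((2.0 * m + 1.0) / (2.0 * m)) * s * lam[m - 1, m - 1]
    # first off-diagonal: Lambda_{m+1,m} = sqrt(2m+3) * x * Lambda_mm
    for m in range(0, lmax):
        lam[m + 1, m] = np.sqrt(2.0 * m + 3.0) * x * lam[m, m]
    # upward recurrence in l
    for m in range(0, lmax + 1):
        for l in range(m + 2, lmax + 1):
            a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
            b = np.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
            lam[l, m] = a * (x * lam[l - 1, m] - b * lam[l - 2, m])
    return lam


def grid_angles(n_lat: int, n_lon: int) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint-equiangular colatitudes (n_lat,) and longitudes (n_lon,)."""
    theta = np.pi * (np.arange(n_lat) + 0.5) / n_lat
    phi = 2.0 * np.pi * np.arange(n_lon) / n_lon
    return theta, phi


def quadrature_weights(n_lat: int, n_lon: int) -> np.ndarray:
    """Solid-angle weights per colatitude row (row weight x dphi).

    The midpoint colatitudes are Fejer-1 nodes in cos(theta), so Fejer's first
    quadrature rule integrates polynomials in cos(theta) up to degree
    n_lat - 1 exactly; combined with the exact FFT in longitude this yields an
    exact analysis for functions band-limited below degree ~n_lat/2.
    """
    theta, _ = grid_angles(n_lat, n_lon)
    n = n_lat
    k = np.arange(1, n // 2 + 1)
    # Fejer-1 weights for integration d(cos theta) over [-1, 1]
    w = (2.0 / n) * (1.0 - 2.0 * np.sum(
        np.cos(2.0 * np.outer(theta, k)) / (4.0 * k**2 - 1.0), axis=1))
    return w * (2.0 * np.pi / n_lon)


def analyze_grid(f: np.ndarray, lmax: int) -> np.ndarray:
    """Expand grid samples ``f[theta, phi]`` in the real orthonormal basis.

    Returns coefficients as ndarray of shape (2, lmax+1, lmax+1): ``c[0, l, m]``
    is the cosine (and m=0) coefficient, ``c[1, l, m]`` the sine coefficient.
    """
    f = np.asarray(f, dtype=float)
    n_lat, n_lon = f.shape
    if n_lon < 2 * lmax + 1 or n_lat < lmax + 1:
        raise ValueError(
            f"grid {n_lat}x{n_lon} cannot resolve degree {lmax}; "
            f"need n_lat >= lmax+1 and n_lon >= 2*lmax+1"
        )
    theta, _ = grid_angles(n_lat, n_lon)
    w = quadrature_weights(n_lat, n_lon)  # includes d(phi) factor
    lam = legendre_normalized(lmax, np.cos(theta))  # (L, M, n_lat)

    F = np.fft.rfft(f, axis=1)  # Sum_k f e^{-i m phi_k}
    m_idx = np.arange(lmax + 1)
    Fc = F[:, : lmax + 1].real  # Sum f cos(m phi)
    Fs = -F[:, : lmax + 1].imag  # Sum f sin(m phi)

    # c^cos_lm = sqrt(2) * Sum_j w_j Lambda_lm(x_j) Fc_m(j)   (m > 0)
    c = np.zeros((2, lmax + 1, lmax + 1))
    wc = w[:, None] * Fc  # (n_lat, M), weight already carries dphi via /n_lon norm
    ws = w[:, None] * Fs
    c[0] = np.einsum("lmt,tm->lm", lam, wc)
    c[1] = np.einsum("lmt,tm->lm", lam, ws)
    scale = np.where(m_idx == 0, 1.0, np.sqrt(2.0))
    c[0] *= scale
    c[1] *= scale
    c[1][:, 0] = 0.0
    # zero out m > l
    tri = m_idx[None, :] > np.arange(lmax + 1)[:, None]
    c[:, tri] = 0.0
    return c


def synthesize_grid(c: np.ndarray, n_lat: int, n_lon: int, lmax: int | None = None) -> np.ndarray:
    """Evaluate a coefficient set on an equiangular grid, optionally truncated."""
    L = c.shape[1] - 1
    if lmax is None:
        lmax = L
    if lmax > L:
        raise ValueError(f"truncation degree {lmax} exceeds expansion degree {L}")
    theta, phi = grid_angles(n_lat, n_lon)
    lam = legendre_normalized(lmax, np.cos(theta))  # (L+1, M+1, n_lat)
    cc = c[0, : lmax + 1, : lmax + 1]
    cs = c[1, : lmax + 1, : lmax + 1]
    # theta profiles per m
    gc = np.einsum("lm,lmt->tm", cc, lam)
    gs = np.einsum("lm,lmt->tm", cs, lam)
    m = np.arange(lmax + 1)
    scale = np.where(m == 0, 1.0, np.sqrt(2.0))
    cosm = np.cos(np.outer(phi, m))  # (n_lon, M+1)
    sinm = np.sin(np.outer(phi, m))
    return (gc * scale) @ cosm.T + (gs * scale) @ sinm.T


def band_energies(c: np.ndarray) -> np.ndarray:
    """Per-degree energy E_l = sum_m (c^cos_lm^2 + c^sin_lm^2), shape (lmax+1,)."""
    return (c**2).sum(axis=(0, 2))
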