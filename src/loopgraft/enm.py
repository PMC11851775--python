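"""Elastic network models on the CA trace: Gaussian (GNM) and anisotropic
(ANM) normal modes, mean-square fluctuations, predicted B factors and
residue-residue motion cross-correlations.

Units: the spring constant and kT are set to 1, so fluctuations are in
arbitrary model units.  Only relative flexibility matters downstream —
profiles are min-max normalized before any comparison — so the absolute
scale (including the Debye-Waller constant in the B-factor map) cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .structures import Region

#: Default contact cutoffs in Å (conventional GNM/ANM values).
GNM_CUTOFF = 10.0
ANM_CUTOFF = 15.0

DEBYE_WALLER = 8.0 * np.pi ** 2 / 3.0


@dataclass(frozen=True)
class ENMParams:
    model: str = "GNM"            # "GNM" or "ANM"
    cutoff: float | None = None   # Å; model default if None
    gamma: float = 1.0            # uniform spring constant
    n_modes: int | None = None    # default: N - 1 lowest nonzero modes

    def __post_init__(self) -> None:
        if self.model not in ("GNM", "ANM"):
            raise ValueError("model must be 'GNM' or 'ANM'")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def effective_cutoff(self) -> float:
        if self.cutoff is not None:
            return self.cutoff
        return GNM_CUTOFF if self.model == "GNM" else ANM_CUTOFF


@dataclass
class ModeSpectrum:
    """Nonzero normal modes, ascending by eigenvalue."""

    eigenvalues: np.ndarray   # (k,)
    eigenvectors: np.ndarray  # (dim, k) columns; dim = N (GNM) or 3N (ANM)
    n_zero: int               # rigid-body modes discarded
    model: str

    @property
    def n_residues(self) -> int:
        dim = self.eigenvectors.shape[0]
        return dim if self.model == "GNM" else dim // 3


@dataclass
class FlexibilityProfile:
    msf: np.ndarray         # per-residue mean-square fluctuation, model units
    bfactor: np.ndarray     # Debye-Waller scaled
    normalized: np.ndarray  # min-max normalized to [0, 1]


def build_kirchhoff(coords: np.ndarray, cutoff: float = GNM_CUTOFF,
                    gamma: float = 1.0) -> np.ndarray:
    """GNM connectivity (Kirchhoff/Laplacian) matrix: -gamma for contacts
    within the cutoff, diagonal = minus the off-diagonal row sum."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("at least 2 residues required")
    dist = squareform(pdist(coords))
    contact = (dist <= cutoff) & ~np.eye(len(coords), dtype=bool)
    K = np.where(contact, -gamma, 0.0)
    np.fill_diagonal(K, -K.sum(axis=1))
    return K


def build_hessian(coords: np.ndarray, cutoff: float = ANM_CUTOFF,
                  gamma: float = 1.0) -> np.ndarray:
    """ANM Hessian: 3x3 super-element -gamma * d d^T / |d|^2 for each
    contact pair, diagonal blocks minus the sum of the row's off-diagonal
    blocks."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 3:
        raise ValueError("at least 3 residues required")
    H = np.zeros((3 * n, 3 * n))
    dist = squareform(pdist(coords))
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] > cutoff or dist[i, j] == 0:
                continue
            d = coords[j] - coords[i]
            block = -gamma * np.outer(d, d) / (d @ d)
            H[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            H[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return H


def compute_modes(matrix: np.ndarray, n_modes: int | None = None,
                  zero_tolerance: float = 1e-8, model: str = "GNM",
                  expected_zero: int | None = None) -> ModeSpectrum:
    """Eigendecomposition with rigid-body modes removed.

    Eigenvalues below ``zero_tolerance`` times the largest eigenvalue are
    discarded as zero modes (1 expected for a connected GNM graph, 6 for a
    non-degenerate ANM structure); the ``n_modes`` lowest nonzero modes
    are retained.  If fewer nonzero modes exist than requested, all are
    retained with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    evals, evecs = eigh(matrix)
    scale = max(evals[-1], 1.0e-300)
    nonzero = evals > zero_tolerance * scale
    n_zero = int(np.sum(~nonzero))
    if expected_zero is not None and n_zero != expected_zero:
        warnings.warn(
            f"{model}: found {n_zero} zero modes, expected {expected_zero} "
            "(disconnected contact graph or degenerate geometry)",
            stacklevel=2,
        )
    evals, evecs = evals[nonzero], evecs[:, nonzero]
    if n_modes is not None:
        if n_modes > len(evals):
            warnings.warn(
                f"only {len(evals)} nonzero modes available "
                f"({n_modes} requested); retaining all", stacklevel=2,
            )
        else:
            evals, evecs = evals[:n_modes], evecs[:, :n_modes]
    return ModeSpectrum(evals, evecs, n_zero, model)


def gnm_modes(coords: np.ndarray, params: ENMParams | None = None) -> ModeSpectrum:
    params = params or ENMParams(model="GNM")
    K = build_kirchhoff(coords, params.effective_cutoff, params.gamma)
    n_modes = params.n_modes if params.n_modes is not None else len(coords) - 1
    return compute_modes(K, n_modes, model="GNM", expected_zero=1)


def anm_modes(coords: np.ndarray, params: ENMParams | None = None) -> ModeSpectrum:
    params = params or ENMParams(model="ANM")
    H = build_hessian(coords, params.effective_cutoff, params.gamma)
    n_modes = params.n_modes if params.n_modes is not None else len(coords) - 1
    return compute_modes(H, n_modes, model="ANM", expected_zero=6)


def square_fluctuations(spectrum: ModeSpectrum) -> np.ndarray:
    """Per-residue mean-square fluctuation <(dR_i)^2> from the mode sum
    (kT/gamma = 1)."""
    inv = 1.0 / spectrum.eigenvalues
    if spectrum.model == "GNM":
        return (spectrum.eigenvectors ** 2) @ inv
    per_coord = (spectrum.eigenvectors ** 2) @ inv
    return per_coord.reshape(-1, 3).sum(axis=1)


def bfactors(msf: np.ndarray) -> np.ndarray:
    """Predicted B factors B_i = (8 pi^2 / 3) * msf_i (Debye-Waller)."""
    msf = np.asarray(msf, dtype=float)
    if np.any(msf < 0):
        raise ValueError("mean-square fluctuations must be non-negative")
    return DEBYE_WALLER * msf


def cross_correlations(spectrum: ModeSpectrum) -> np.ndarray:
    """Normalized fluctuation cross-correlation matrix C in [-1, 1].

    GNM: c_ij = sum_k u_ki u_kj / lambda_k; ANM: c_ij = trace of the 3x3
    covariance superblock.  C_ij = c_ij / sqrt(c_ii c_jj).
    """
    inv = 1.0 / spectrum.eigenvalues
    V = spectrum.eigenvectors
    if spectrum.model == "GNM":
        raw = (V * inv) @ V.T
    else:
        full = (V * inv) @ V.T  # 3N x 3N covariance
        n = full.shape[0] // 3
        raw = full.reshape(n, 3, n, 3)
        raw = np.einsum("iaja->ij", raw)
    diag = np.diag(raw)
    if np.any(diag <= 0):
        raise ValueError("immobile node: zero self-covariance")
    C = raw / np.sqrt(np.outer(diag, diag))
    return C


def normalize_profile(values: np.ndarray) -> np.ndarray:
    """Min-max normalization (v - min) / (max - min); a constant profile
    maps to all zeros with a warning."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty profile")
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("constant profile; normalization returns zeros",
                      stacklevel=2)
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def flexibility_profile(coords: np.ndarray,
                        params: ENMParams | None = None) -> FlexibilityProfile:
    """One-call profile: modes -> msf -> B factors -> normalized values."""
    params = params or ENMParams()
    spectrum = gnm_modes(coords, params) if params.model == "GNM" \
        else anm_modes(coords, params)
    msf = square_fluctuations(spectrum)
    b = bfactors(msf)
    return FlexibilityProfile(msf, b, normalize_profile(b))


def region_mean_flexibility(values: np.ndarray, region: Region) -> float:
    """Arithmetic mean of a per-residue profile over a region."""
    values = np.asarray(values, dtype=float)
    if region.end >= len(values):
        raise IndexError(f"region {region} outside profile")
    return float(values[region.start:region.end + 1].mean())


def region_cross_correlation(C: np.ndarray, region_a: Region,
                             region_b: Region) -> float:
    """Mean of C_ij over all (i in a, j in b); overlapping self-pairs are
    included as-is."""
    C = np.asarray(C, dtype=float)
    if region_a.end >= C.shape[0] or region_b.end >= C.shape[1]:
        raise IndexError("region outside correlation matrix")
    block = C[region_a.start:region_a.end + 1, region_b.start:region_b.end + 1]
    return float(block.mean())
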