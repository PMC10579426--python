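"""Gaussian Network Model (GNM) residue flexibility from Cα coordinates.

The GNM treats a folded protein as an elastic network: Cα atoms within a
distance cutoff are joined by identical springs of stiffness ``gamma``.
The network topology is encoded in the Kirchhoff (connectivity) matrix Γ,
and the equilibrium mean-square fluctuation (MSF) of each residue is
proportional to the corresponding diagonal element of the Moore-Penrose
pseudo-inverse of Γ,

    MSF_i ∝ [Γ⁺]_ii = Σ_{k: λ_k > 0} v_ki² / λ_k ,

where (λ_k, v_k) are the non-zero eigenpairs of Γ.  A connected contact
graph has exactly one zero mode (the rigid-body translation along the mode
coordinate); more than one zero mode means the structure fell apart into
disconnected components at the chosen cutoff, which is reported as an
error rather than silently producing meaningless fluctuations.

Units: coordinates in Å, MSF in units of 1/γ (proportional to Å² for a
physical spring constant); only relative fluctuation profiles are used
downstream as features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components

__all__ = [
    "CalphaModel",
    "GNMResult",
    "DisconnectedContactGraphError",
    "build_kirchhoff",
    "compute_msf",
    "gnm_msf",
    "DEFAULT_CUTOFF",
    "DEFAULT_GAMMA",
]

#: Standard GNM contact cutoff for Cα-only networks, Å.
DEFAULT_CUTOFF = 7.3
#: Uniform spring constant (arbitrary units); MSF scales as 1/γ.
DEFAULT_GAMMA = 1.0

#: Relative eigenvalue tolerance below which a mode counts as a zero mode.
ZERO_MODE_RTOL = 1e-8


class DisconnectedContactGraphError(ValueError):
    """Raised when the contact graph has more than one connected component."""

    def __init__(self, labels: np.ndarray, residue_ids: list):
        self.n_components = int(labels.max()) + 1
        self.components = [
            [residue_ids[i] for i in np.flatnonzero(labels == c)]
            for c in range(self.n_components)
        ]
        sizes = ", ".join(str(len(c)) for c in self.components)
        super().__init__(
            f"contact graph is disconnected: {self.n_components} components "
            f"(sizes {sizes}); increase the cutoff or analyse components "
            f"separately. Components: {self.components}"
        )


@dataclass(frozen=True)
class CalphaModel:
    """Ordered Cα trace: residue identifiers and an n×3 coordinate matrix (Å)."""

    residue_ids: tuple
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be n×3, got shape {coords.shape}")
        if len(self.residue_ids) != coords.shape[0]:
            raise ValueError("residue_ids and coords length mismatch")
        if len(set(self.residue_ids)) != len(self.residue_ids):
            raise ValueError("residue_ids must be unique")
        if coords.shape[0] < 2:
            raise ValueError("a Cα model needs at least 2 residues")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def subset(self, residue_ids) -> "CalphaModel":
        """Model restricted to the given residues (caller-specified chain sets)."""
        wanted = list(residue_ids)
        index = {rid: i for i, rid in enumerate(self.residue_ids)}
        missing = [r for r in wanted if r not in index]
        if missing:
            raise KeyError(f"residues not in model: {missing}")
        rows = [index[r] for r in wanted]
        return CalphaModel(tuple(wanted), self.coords[rows])


@dataclass(frozen=True)
class GNMResult:
    """Spectral decomposition of a GNM and the derived fluctuation profile."""

    kirchhoff: np.ndarray
    eigenvalues: np.ndarray  # ascending, first is the zero mode
    eigenvectors: np.ndarray  # columns match eigenvalues
    msf: np.ndarray
    cutoff: float
    spring_constant: float
    residue_ids: tuple = field(default=())

    @property
    def n_modes(self) -> int:
        return int(np.sum(self.eigenvalues > 0))


def build_kirchhoff(
    model: CalphaModel,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
) -> np.ndarray:
    """Contact Kirchhoff matrix Γ of the Cα network.

    Γ_ij = −γ when 0 < d(i,j) ≤ cutoff, 0 otherwise (i ≠ j);
    Γ_ii = −Σ_{j≠i} Γ_ij, so every row sums to zero exactly.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    xyz = model.coords
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    contact = (dist <= cutoff) & (dist > 0)
    kirchhoff = np.where(contact, -gamma, 0.0)
    np.fill_diagonal(kirchhoff, 0.0)
    np.fill_diagonal(kirchhoff, -kirchhoff.sum(axis=1))
    return kirchhoff


def compute_msf(
    kirchhoff: np.ndarray,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
    residue_ids: tuple = (),
) -> GNMResult:
    """Eigendecompose Γ and return per-residue mean-square fluctuations.

    Zero modes are identified by λ < ZERO_MODE_RTOL · λ_max.  Exactly one
    zero mode is required; otherwise the contact graph is disconnected and
    a :class:`DisconnectedContactGraphError` names the components.
    """
    g = np.asarray(kirchhoff, dtype=float)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("kirchhoff must be square")
    if not np.allclose(g, g.T, atol=1e-10):
        raise ValueError("kirchhoff must be symmetric")
    if not np.allclose(g.sum(axis=1), 0.0, atol=1e-8):
        raise ValueError("kirchhoff rows must sum to zero")

    eigvals, eigvecs = eigh(g)
    tol = ZERO_MODE_RTOL * max(eigvals[-1], 1.0)
    zero = eigvals < tol
    n_zero = int(zero.sum())
    if n_zero != 1:
        rids = list(residue_ids) if residue_ids else list(range(g.shape[0]))
        adjacency = (g != 0) & ~np.eye(g.shape[0], dtype=bool)
        _, labels = connected_components(adjacency, directed=False)
        raise DisconnectedContactGraphError(labels, rids)

    nonzero = ~zero
    inv_lambda = 1.0 / eigvals[nonzero]
    msf = np.einsum("ik,k,ik->i", eigvecs[:, nonzero], inv_lambda, eigvecs[:, nonzero])
    eigvals = eigvals.copy()
    eigvals[0] = 0.0  # exact zero for the single rigid mode
    return GNMResult(
        kirchhoff=g,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        msf=msf,
        cutoff=cutoff,
        spring_constant=gamma,
        residue_ids=tuple(residue_ids),
    )


def gnm_msf(
    model: CalphaModel,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
) -> GNMResult:
    """Convenience wrapper: Kirchhoff construction followed by MSF."""
    kirchhoff = build_kirchhoff(model, cutoff=cutoff, gamma=gamma)
    return compute_msf(
        kirchhoff, cutoff=cutoff, gamma=gamma, residue_ids=model.residue_ids
    )
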