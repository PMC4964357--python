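"""Analytic spherical head model: montage, source space and leadfield.

The forward model is a concentric three-shell conductor sphere (brain, skull,
scalp; conductivity ratio 1 : 1/80 : 1). For each spherical-harmonic order the
radial two-point boundary problem is solved exactly, so the scalp potential of
an arbitrary dipole inside the innermost shell is obtained as a rapidly
converging Legendre series — the classical alternative to a BEM on a template
anatomy, and sufficient for a linear minimum-norm inverse.

Coordinate frame: head-centered, +x right, +y anterior, +z superior; meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Montage

__all__ = [
    "SphereModel",
    "SourceSpace",
    "Leadfield",
    "default_montage",
    "default_sphere",
    "build_source_space",
    "build_spherical_leadfield",
    "dipole_potential",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class SphereModel:
    """Concentric-shell conductor. Radii strictly increasing (innermost first)."""

    radii: tuple[float, ...] = (0.080, 0.085, 0.092)  # brain, outer skull, scalp
    conductivities: tuple[float, ...] = (0.33, 0.33 / 80.0, 0.33)  # S/m
    n_terms: int = 100

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.conductivities):
            raise GeometryError("one conductivity per shell required")
        if not all(np.diff(self.radii) > 0):
            raise GeometryError("shell radii must be strictly increasing")
        if min(self.conductivities) <= 0:
            raise GeometryError("conductivities must be positive")

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]

    @property
    def brain_radius(self) -> float:
        return self.radii[0]


def _fibonacci_cap(n: int, z_min: float) -> np.ndarray:
    """n roughly equidistant unit vectors with z >= z_min (Fibonacci lattice)."""
    i = np.arange(n)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_montage(sphere: SphereModel | None = None, n_scalp: int = 128) -> Montage:
    """128 scalp sensors on the upper sphere plus left/right mastoids.

    Sensors are laid out quasi-equidistantly down to slightly below the
    equator; the lattice point nearest the canonical frontal-midline site is
    snapped there and named ``Fz``. Mastoids sit low behind the ears.
    """
    sphere = sphere or default_sphere()
    R = sphere.scalp_radius
    pts = _fibonacci_cap(n_scalp, z_min=-0.25)
    # canonical frontal-midline direction: 46 deg from vertex toward nasion
    ang = np.deg2rad(46.0)
    fz_dir = np.array([0.0, np.sin(ang), np.cos(ang)])
    k = int(np.argmax(pts @ fz_dir))
    pts[k] = fz_dir
    names = [f"E{i + 1:03d}" for i in range(n_scalp)]
    names[k] = "Fz"
    m1 = np.array([-0.93, -0.31, -0.19])
    m2 = np.array([0.93, -0.31, -0.19])
    pts = np.vstack([pts, m1 / np.linalg.norm(m1), m2 / np.linalg.norm(m2)])
    names += ["M1", "M2"]
    return Montage(names=tuple(names), positions=pts * R)


def default_sphere() -> SphereModel:
    return SphereModel()


@dataclass(frozen=True)
class SourceSpace:
    """Cortical-proxy source sheet: positions, unit normals, ROI labels."""

    positions: np.ndarray  # (n_sources, 3) m
    orientations: np.ndarray  # (n_sources, 3) unit
    rois: dict[str, np.ndarray] = field(default_factory=dict)  # label -> index array

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        ori = np.asarray(self.orientations, float)
        if pos.shape != ori.shape or pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError("positions/orientations must be matching (n, 3) arrays")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise GeometryError("orientations must be unit vectors")
        for label, idx in self.rois.items():
            if len(idx) == 0:
                raise GeometryError(f"ROI {label!r} is empty")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def roi_indices(self, label: str) -> np.ndarray:
        if label not in self.rois:
            raise KeyError(f"ROI {label!r} not defined (have {sorted(self.rois)})")
        return self.rois[label]


def build_source_space(
    sphere: SphereModel | None = None,
    depth_fractions: tuple[float, ...] = (0.55, 0.675, 0.80),
    n_per_shell: int = 260,
    acc_half_width: float = 0.40,
) -> SourceSpace:
    """Cortical-proxy sheet: concentric upper-hemisphere caps at several depths.

    Orientations are the (inward) surface normals, implementing the
    orthogonal-to-cortex constraint. The "ACC" ROI is the deep frontal-midline
    sector of the deepest cap (anterior cingulate proxy): anterior (y > 0),
    within ``acc_half_width`` (as a fraction of the cap radius) of the midline.
    """
    sphere = sphere or default_sphere()
    rb = sphere.brain_radius
    pos_parts, shell_idx = [], []
    for s, f in enumerate(depth_fractions):
        if not 0 < f < 1:
            raise GeometryError("depth fractions must lie strictly inside the brain shell")
        dirs = _fibonacci_cap(n_per_shell, z_min=0.02)
        pos_parts.append(dirs * (f * rb))
        shell_idx.append(np.full(n_per_shell, s))
    pos = np.vstack(pos_parts)
    shell_idx = np.concatenate(shell_idx)
    # inward normals: the sign convention is chosen so that the generator of a
    # frontocentral scalp *negativity* carries positive source activation
    ori = -pos / np.linalg.norm(pos, axis=1, keepdims=True)
    deep = shell_idx == 0
    r_deep = depth_fractions[0] * rb
    acc = np.flatnonzero(
        deep
        & (pos[:, 1] > 0.35 * r_deep)
        & (np.abs(pos[:, 0]) < acc_half_width * r_deep)
    )
    if len(acc) == 0:
        raise GeometryError("ACC sector parameters selected no sources")
    return SourceSpace(positions=pos, orientations=ori, rois={"ACC": acc})


# ---------------------------------------------------------------------------
# analytic multi-shell dipole potential


def _legendre_pair(u: np.ndarray, n_terms: int):
    """Yield (n, P_n(u), P'_n(u)) for n = 1..n_terms via stable recurrences."""
    u = np.clip(u, -1.0 + 1e-12, 1.0 - 1e-12)
    p_nm1 = np.ones_like(u)  # P_0
    p_n = u.copy()  # P_1
    one_minus_u2 = 1.0 - u * u
    for n in range(1, n_terms + 1):
        dp = n * (p_nm1 - u * p_n) / one_minus_u2
        yield n, p_n, dp
        p_np1 = ((2 * n + 1) * u * p_n - n * p_nm1) / (n + 1)
        p_nm1, p_n = p_n, p_np1


def _shell_factors(sphere: SphereModel, n_terms: int) -> np.ndarray:
    """Per-order surface factor F_n for a unit r^-(n+1) source harmonic.

    Solves, for each order n, the radial continuity/flux system across all
    shell interfaces with an insulating outer boundary. In the homogeneous
    (single-shell) case F_n reduces to the classical (2n+1)/n * R^-(n+1).
    """
    radii = np.asarray(sphere.radii)
    sig = np.asarray(sphere.conductivities)
    S = len(radii)
    R = radii[-1]
    F = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        # unknowns: A_1, (A_j, B_j) for j = 2..S  -> 2S-1 of them
        m = 2 * S - 1
        A = np.zeros((m, m))
        rhs = np.zeros(m)

        def a_col(j):  # column of A_j
            return 0 if j == 1 else 2 * j - 3

        def b_col(j):  # column of B_j (j >= 2)
            return 2 * j - 2

        row = 0
        for j in range(1, S):  # interface between shell j and j+1 at radii[j-1]
            r = radii[j - 1]
            rn, rmn = r**n, r ** -(n + 1)
            drn, drmn = n * r ** (n - 1), -(n + 1) * r ** -(n + 2)
            # potential continuity
            A[row, a_col(j)] += rn
            if j >= 2:
                A[row, b_col(j)] += rmn
            else:
                rhs[row] -= rmn  # B_1 = 1 (source term)
            A[row, a_col(j + 1)] -= rn
            A[row, b_col(j + 1)] -= rmn
            row += 1
            # radial current continuity
            A[row, a_col(j)] += sig[j - 1] * drn
            if j >= 2:
                A[row, b_col(j)] += sig[j - 1] * drmn
            else:
                rhs[row] -= sig[j - 1] * drmn
            A[row, a_col(j + 1)] -= sig[j] * drn
            A[row, b_col(j + 1)] -= sig[j] * drmn
            row += 1
        # insulating outer boundary at R
        A[row, a_col(S)] += sig[-1] * n * R ** (n - 1)
        if S >= 2:
            A[row, b_col(S)] += sig[-1] * -(n + 1) * R ** -(n + 2)
        else:
            rhs[row] -= sig[-1] * -(n + 1) * R ** -(n + 2)
        sol = np.linalg.solve(A, rhs)
        if S >= 2:
            F[n] = sol[a_col(S)] * R**n + sol[b_col(S)] * R ** -(n + 1)
        else:
            F[n] = sol[0] * R**n + R ** -(n + 1)
    return F


def dipole_potential(
    sphere: SphereModel,
    dip_pos: np.ndarray,
    dip_moment: np.ndarray,
    elec_pos: np.ndarray,
) -> np.ndarray:
    """Scalp potential (V) of dipoles inside the innermost shell.

    dip_pos, dip_moment : (n_dip, 3); moments in A*m.
    elec_pos : (n_elec, 3) on the outer surface.
    Returns (n_elec, n_dip).
    """
    dip_pos = np.atleast_2d(np.asarray(dip_pos, float))
    dip_moment = np.atleast_2d(np.asarray(dip_moment, float))
    elec_pos = np.atleast_2d(np.asarray(elec_pos, float))
    b = np.linalg.norm(dip_pos, axis=1)
    if np.any(b >= sphere.brain_radius):
        raise GeometryError("dipole outside the innermost shell")
    b = np.maximum(b, 1e-9)
    p_hat = dip_pos / b[:, None]
    e_hat = elec_pos / np.linalg.norm(elec_pos, axis=1, keepdims=True)

    u = e_hat @ p_hat.T  # (n_elec, n_dip)
    q_dot_p = np.sum(dip_moment * p_hat, axis=1)  # (n_dip,)
    q_dot_e = e_hat @ dip_moment.T  # (n_elec, n_dip)

    F = _shell_factors(sphere, sphere.n_terms)
    sigma1 = sphere.conductivities[0]
    V = np.zeros_like(u)
    bn = np.ones_like(b)  # b^(n-1)
    for n, p_n, dp_n in _legendre_pair(u, sphere.n_terms):
        term = n * p_n * q_dot_p[None, :] + dp_n * (q_dot_e - u * q_dot_p[None, :])
        V += (F[n] * bn)[None, :] * term
        bn = bn * b
    return V / (4.0 * np.pi * sigma1)


@dataclass(frozen=True)
class Leadfield:
    """Gain matrix: referenced scalp microvolts per unit dipole moment (nA*m)."""

    gain: np.ndarray  # (n_channels, n_sources)
    montage: Montage
    space: SourceSpace
    reference: str = "mastoids"

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, float)
        if not np.all(np.isfinite(g)):
            raise GeometryError("leadfield contains non-finite entries")
        if g.shape != (self.montage.n_channels, self.space.n_sources):
            raise GeometryError("gain shape does not match montage/source space")
        object.__setattr__(self, "gain", g)


def build_spherical_leadfield(
    montage: Montage,
    space: SourceSpace,
    sphere: SphereModel | None = None,
    reference: str = "mastoids",
) -> Leadfield:
    """Leadfield for orientation-constrained unit dipoles (1 nA*m) at each source.

    Column i is the referenced scalp potential pattern (microvolts) of a
    dipole at source i along its constrained orientation. ``reference`` is
    ``"mastoids"`` (averaged-mastoid, matching preprocessing), ``"average"``
    or ``"none"``.
    """
    sphere = sphere or default_sphere()
    R = sphere.scalp_radius
    r_elec = np.linalg.norm(montage.positions, axis=1)
    if np.any(r_elec < R - 1e-9):
        raise GeometryError("electrodes must lie on or outside the scalp sphere")
    moments = space.orientations * 1e-9  # 1 nA*m unit dipoles
    V = dipole_potential(sphere, space.positions, moments, montage.positions)
    gain = V * 1e6  # volts -> microvolts
    if reference == "mastoids":
        i1, i2 = montage.mastoid_indices
        gain = gain - 0.5 * (gain[i1] + gain[i2])[None, :]
    elif reference == "average":
        gain = gain - gain.mean(axis=0, keepdims=True)
    elif reference != "none":
        raise ValueError(f"unknown reference {reference!r}")
    return Leadfield(gain=gain, montage=montage, space=space, reference=reference)
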