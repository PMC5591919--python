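"""Magnetostatics of the electromagnetic bioreactor.

The exposure system is a pair of coaxial air-cored solenoids connected in
series, driven by a trapezoidal current pulse repeated at 75 Hz, with the
culture dish in the midplane where the axial field B_Z is quasi-homogeneous.

The elemental computation is the field of a circular current loop, for which
the exact closed form in terms of complete elliptic integrals is used::

    B_z = mu0 I / (2 pi sqrt((a+rho)^2 + z^2))
          * [K(m) + (a^2 - rho^2 - z^2) / ((a-rho)^2 + z^2) E(m)]
    B_rho = mu0 I z / (2 pi rho sqrt((a+rho)^2 + z^2))
          * [-K(m) + (a^2 + rho^2 + z^2) / ((a-rho)^2 + z^2) E(m)]

with ``m = 4 a rho / ((a+rho)^2 + z^2)``. A straight-segment Biot-Savart
quadrature of the same loop is provided as an independent numerical route
for validation. A solenoid is the superposition of its turns.

The coil geometry shipped as default is a *calibrated surrogate*: the paper
of record for the rig's geometry is its dosimetry reference, which is not
reproduced here; radius, length, spacing and turn count were fixed once so
that the printed peak current (0.319 A) yields a center field of ~2.83 mT,
the value consistent with the printed energy density of ~3.18 J/m^3 and the
stated "circa 3 mT".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ellipe, ellipk

MU0 = 4e-7 * np.pi  # vacuum permeability [H/m]

__all__ = [
    "MU0",
    "SolenoidSpec",
    "CurrentWaveform",
    "FieldMap",
    "loop_b",
    "loop_b_quadrature",
    "solenoid_b",
    "pair_field_map",
    "homogeneity",
    "energy_density",
    "induced_e_field",
    "default_bioreactor",
]


@dataclass(frozen=True)
class SolenoidSpec:
    """Air-cored solenoid: ``n_turns`` loops spread uniformly over ``length``,
    centered at ``z_center`` on the common axis."""

    radius: float            # [m]
    length: float            # [m]
    n_turns: int
    z_center: float = 0.0    # [m]
    sense: int = +1          # winding sense: +1 or -1

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be positive")
        if self.n_turns < 1:
            raise ValueError("need at least 1 turn")
        if self.sense not in (+1, -1):
            raise ValueError("sense must be +1 or -1")


@dataclass(frozen=True)
class CurrentWaveform:
    """Trapezoidal current pulse repeated at ``frequency``.

    Defaults: 0 -> 319 mA in 1.36 ms, symmetric fall, plateau sized so the
    active part of the pulse fills half of the 75 Hz period.
    """

    i_peak: float = 0.319          # [A]
    rise: float = 1.36e-3          # [s]
    fall: float = 1.36e-3          # [s]
    frequency: float = 75.0        # [Hz]
    plateau: float | None = None   # [s]; default: half period minus ramps

    def __post_init__(self) -> None:
        if self.plateau is None:
            object.__setattr__(
                self, "plateau",
                0.5 / self.frequency - self.rise - self.fall)
        if min(self.i_peak, self.rise, self.fall, self.plateau) < 0:
            raise ValueError("waveform parameters must be non-negative")
        if self.rise + self.plateau + self.fall > 1.0 / self.frequency:
            raise ValueError("pulse does not fit in one repetition period")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def current(self, t: np.ndarray) -> np.ndarray:
        """I(t), periodic, piecewise linear in [0, i_peak]."""
        u = np.asarray(t, dtype=float) % self.period
        i = np.zeros_like(u)
        r, p, f = self.rise, self.plateau, self.fall
        m = u < r
        i[m] = self.i_peak * u[m] / r
        m = (u >= r) & (u < r + p)
        i[m] = self.i_peak
        m = (u >= r + p) & (u < r + p + f)
        i[m] = self.i_peak * (1 - (u[m] - r - p) / f)
        return i

    @property
    def max_didt(self) -> float:
        return self.i_peak / min(self.rise, self.fall)


@dataclass
class FieldMap:
    """B_Z profiles [mT] along the X and Y axes of the culture plane."""

    x: np.ndarray            # [m]
    bz_x: np.ndarray         # [mT]
    y: np.ndarray            # [m]
    bz_y: np.ndarray         # [mT]
    bt_x: np.ndarray         # transverse |B| along the X line [mT]
    bt_y: np.ndarray         # transverse |B| along the Y line [mT]
    z_plane: float
    current: float

    @property
    def center_bz(self) -> float:
        return float(self.bz_x[np.argmin(np.abs(self.x))])

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [
                pd.DataFrame({"axis": "X", "coord_m": self.x, "Bz_mT": self.bz_x}),
                pd.DataFrame({"axis": "Y", "coord_m": self.y, "Bz_mT": self.bz_y}),
            ],
            ignore_index=True,
        )


def _loop_b_cyl(a: float, current: float, rho, z):
    """(B_rho, B_z) of a loop of radius ``a`` at the origin, exact."""
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    d2 = (a + rho) ** 2 + z ** 2
    m = 4 * a * rho / d2
    K = ellipk(m)
    E = ellipe(m)
    denom = (a - rho) ** 2 + z ** 2
    pref = MU0 * current / (2 * np.pi * np.sqrt(d2))
    bz = pref * (K + (a * a - rho * rho - z * z) / denom * E)
    with np.errstate(divide="ignore", invalid="ignore"):
        brho = np.where(
            rho > 0,
            pref * z / np.where(rho == 0, 1.0, rho)
            * (-K + (a * a + rho * rho + z * z) / denom * E),
            0.0,
        )
    return brho, bz


def loop_b(radius: float, current: float, z_center: float,
           point) -> np.ndarray:
    """Magnetic field vector [T] of a circular loop at an arbitrary point.

    The loop lies in the plane ``z = z_center`` centered on the Z axis.
    Raises on points within 1 um of the wire, where the field diverges.
    """
    x, y, z = (float(c) for c in point)
    zr = z - z_center
    rho = np.hypot(x, y)
    if np.hypot(rho - radius, zr) < 1e-6:
        raise ValueError("singular point: field requested on the loop wire")
    brho, bz = _loop_b_cyl(radius, current, rho, zr)
    if rho > 0:
        bx, by = brho * x / rho, brho * y / rho
    else:
        bx = by = 0.0
    return np.array([float(bx), float(by), float(bz)])


def loop_b_quadrature(radius: float, current: float, z_center: float,
                      point, n_segments: int = 720) -> np.ndarray:
    """Same loop field by Biot-Savart summation over straight segments.

    Kept as an independent numerical route for validating the closed form;
    doubling ``n_segments`` changes the result at the 1e-6 relative level.
    """
    x, y, z = (float(c) for c in point)
    if np.hypot(np.hypot(x, y) - radius, z - z_center) < 1e-6:
        raise ValueError("singular point: field requested on the loop wire")
    phi = np.linspace(0, 2 * np.pi, n_segments + 1)
    nodes = np.column_stack([
        radius * np.cos(phi), radius * np.sin(phi), np.full_like(phi, z_center)
    ])
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    dl = np.diff(nodes, axis=0)
    r = np.array([x, y, z]) - mid
    rn = np.linalg.norm(r, axis=1, keepdims=True)
    db = np.cross(dl, r) / rn ** 3
    return MU0 * current / (4 * np.pi) * db.sum(axis=0)


def solenoid_b(spec: SolenoidSpec, current: float, point) -> np.ndarray:
    """Field of a finite solenoid: superposition of its turns' loops.

    Turns sit at the midpoints of ``n_turns`` equal segments of the winding
    length, so the discrete sum converges quadratically to the continuous
    uniform-winding closed form.
    """
    h = spec.length / spec.n_turns
    zs = spec.z_center - spec.length / 2 + h * (np.arange(spec.n_turns) + 0.5)
    x, y, z = (float(c) for c in point)
    rho = np.hypot(x, y)
    brho, bz = _loop_b_cyl(spec.radius, current, np.full_like(zs, rho), z - zs)
    brho_t, bz_t = brho.sum(), bz.sum()
    if rho > 0:
        bx, by = brho_t * x / rho, brho_t * y / rho
    else:
        bx = by = 0.0
    return spec.sense * np.array([bx, by, bz_t])


def pair_field_map(pair: tuple[SolenoidSpec, SolenoidSpec], current: float,
                   z_plane: float = 0.0,
                   extent: float = 0.05, n_samples: int = 81) -> FieldMap:
    """B_Z(X) and B_Z(Y) profiles at the culture plane for the coil pair
    in series, plus the transverse-field magnitude along each line."""
    coords = np.linspace(-extent, extent, n_samples)

    def profile(points):
        b = np.array([
            solenoid_b(pair[0], current, p) + solenoid_b(pair[1], current, p)
            for p in points
        ])
        bz = b[:, 2]
        bt = np.hypot(b[:, 0], b[:, 1])
        return bz * 1e3, bt * 1e3

    bz_x, bt_x = profile([(c, 0.0, z_plane) for c in coords])
    bz_y, bt_y = profile([(0.0, c, z_plane) for c in coords])
    return FieldMap(coords, bz_x, coords.copy(), bz_y, bt_x, bt_y,
                    z_plane, current)


def homogeneity(fmap: FieldMap, half_width: float | None = None) -> float:
    """Max relative deviation of B_Z from the center value over the central
    region (default: central 30% of the sampled span), across both axes."""
    if half_width is None:
        half_width = 0.30 * (fmap.x.max() - fmap.x.min()) / 2
    b0 = fmap.center_bz
    devs = []
    for coords, bz in ((fmap.x, fmap.bz_x), (fmap.y, fmap.bz_y)):
        m = np.abs(coords) <= half_width
        if not m.any():
            raise ValueError("empty homogeneity region")
        devs.append(np.max(np.abs(bz[m] - b0) / abs(b0)))
    return float(max(devs))


def energy_density(b_tesla: float) -> float:
    """Magnetic energy density u = B^2 / (2 mu0) [J/m^3]."""
    return float(b_tesla ** 2 / (2 * MU0))


def induced_e_field(r: float, dbdt: float) -> float:
    """Azimuthal induced electric field E = (r/2) |dB/dt| [V/m] at radius
    ``r`` under a spatially uniform axial field ramp (Faraday's law for an
    axisymmetric dish)."""
    if r < 0:
        raise ValueError("radius must be >= 0")
    return 0.5 * r * abs(dbdt)


# Turn count calibrated once (long-solenoid estimate refined against the
# elliptic-integral model) so that 0.319 A gives ~2.83 mT at the center.
_DEFAULT_RADIUS = 0.05
_DEFAULT_LENGTH = 0.10
_DEFAULT_GAP = 0.04          # face-to-face spacing of the pair [m]
_DEFAULT_TURNS = 1279


def default_bioreactor() -> tuple[tuple[SolenoidSpec, SolenoidSpec],
                                  CurrentWaveform]:
    """The shipped surrogate geometry and the printed current waveform."""
    dz = _DEFAULT_GAP / 2 + _DEFAULT_LENGTH / 2
    pair = (
        SolenoidSpec(_DEFAULT_RADIUS, _DEFAULT_LENGTH, _DEFAULT_TURNS, -dz),
        SolenoidSpec(_DEFAULT_RADIUS, _DEFAULT_LENGTH, _DEFAULT_TURNS, +dz),
    )
    return pair, CurrentWaveform()
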