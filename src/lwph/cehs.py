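"""CEHS helical geometry: frames, parameters, and their analysis.

The Cambridge University Engineering Department Helix computation Scheme
(CEHS) describes the relative placement of two stacked base pairs by six
step parameters (shift, slide, rise in Angstrom; tilt, roll, twist in
degrees) and the relative placement of the two bases within one pair by
six base-pair parameters (shear, stretch, stagger; buckle, propeller,
opening).  Both sets share the same mathematics: a mid-frame ("mid-step
triad") from which the two objects are reached by symmetric half
rotations.

Construction uses the closed-form matrices

    R_2   = Rz(omega/2 - phi) * Ry(Gamma)   * Rz(omega/2 + phi)
    R_mid = Rz(omega/2 - phi) * Ry(Gamma/2) * Rz(phi)

with Gamma = sqrt(tilt^2 + roll^2) the bending angle and
phi = atan2(tilt, roll) its phase (roll bends about the mid-frame y axis,
tilt about x).  The translation (shift, slide, rise) is expressed in
mid-frame coordinates.  For base-pair parameters, (buckle, propeller,
opening) play the roles of (tilt, roll, twist) and (shear, stretch,
stagger) the roles of (shift, slide, rise).

Analysis (`step_parameters`) deliberately does *not* invert those
matrices symbolically.  It uses the geometric hinge algorithm instead:
bend both frames onto the common mid-plane about the hinge axis
z1 x z2, read the twist between the in-plane x axes, and decompose the
bending angle along the mid-frame axes.  Having two independent routes
to the same six numbers is what makes the builder testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

PAIR_PARAMETER_NAMES = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
STEP_PARAMETER_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
PARAMETER_NAMES = PAIR_PARAMETER_NAMES + STEP_PARAMETER_NAMES


@dataclass(frozen=True)
class HelicalParams:
    """The twelve CEHS parameters; translations in Angstrom, angles in degrees."""

    shear: float = 0.0
    stretch: float = 0.0
    stagger: float = 0.0
    buckle: float = 0.0
    propeller: float = 0.0
    opening: float = 0.0
    shift: float = 0.0
    slide: float = 0.0
    rise: float = 0.0
    tilt: float = 0.0
    roll: float = 0.0
    twist: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"helical parameter {f.name!r} must be finite, got {v!r}")

    @property
    def pair_part(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PAIR_PARAMETER_NAMES], dtype=float)

    @property
    def step_part(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STEP_PARAMETER_NAMES], dtype=float)

    def with_(self, **kwargs: float) -> "HelicalParams":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "HelicalParams":
        unknown = set(d) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown helical parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class HelicalParamTable:
    """Per-parameter mean and standard deviation (e.g. from a crystal survey)."""

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"standard deviation of {name!r} must be >= 0, got {sd}")

    @classmethod
    def from_yaml(cls, path) -> "HelicalParamTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        means = {k: float(v["mean"]) for k, v in raw.items() if k in PARAMETER_NAMES}
        sds = {k: float(v["sd"]) for k, v in raw.items() if k in PARAMETER_NAMES}
        return cls(means=means, sds=sds)

    @classmethod
    def default(cls) -> "HelicalParamTable":
        from importlib.resources import files

        return cls.from_yaml(files("lwph.data") / "helical_defaults.yaml")

    def mean_params(self) -> HelicalParams:
        return HelicalParams.from_dict(self.means)


# ---------------------------------------------------------------------------
# rotation helpers (right-handed, column-vector convention)
# ---------------------------------------------------------------------------


def rot_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation about an arbitrary unit axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    x, y, z = axis / n
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def step_transform(translation, rotation) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form CEHS transform for one step (or one pair).

    Parameters
    ----------
    translation : (shift, slide, rise) in mid-frame coordinates, Angstrom.
    rotation : (tilt, roll, twist) in degrees.

    Returns
    -------
    R2 : orientation of frame 2 expressed in frame 1.
    origin2 : origin of frame 2 in frame-1 coordinates.
    Rmid : orientation of the mid-step triad in frame 1.
    """
    shift, slide, rise = translation
    tilt, roll, twist = rotation
    gamma = float(np.hypot(tilt, roll))
    phi = float(np.rad2deg(np.arctan2(tilt, roll)))
    R2 = rot_z(twist / 2.0 - phi) @ rot_y(gamma) @ rot_z(twist / 2.0 + phi)
    Rmid = rot_z(twist / 2.0 - phi) @ rot_y(gamma / 2.0) @ rot_z(phi)
    origin2 = Rmid @ np.array([shift, slide, rise], dtype=float)
    return R2, origin2, Rmid


def _signed_angle(u: np.ndarray, v: np.ndarray, about: np.ndarray) -> float:
    return float(np.rad2deg(np.arctan2(np.dot(np.cross(u, v), about), np.dot(u, v))))


def mid_frame(R1: np.ndarray, o1: np.ndarray, R2: np.ndarray, o2: np.ndarray):
    """Mid-step triad of two frames via the hinge construction.

    Returns (Rmid, omid, params) where params = (d1, d2, d3, tilt, roll,
    twist): the translation of frame 2 relative to frame 1 expressed in
    mid-frame coordinates and the CEHS rotation parameters in degrees.
    """
    z1, z2 = R1[:, 2], R2[:, 2]
    cross = np.cross(z1, z2)
    norm = np.linalg.norm(cross)
    gamma = float(np.rad2deg(np.arctan2(norm, float(np.dot(z1, z2)))))
    if norm > 1e-12:
        hinge = cross / norm
        R1p = rot_axis(hinge, gamma / 2.0) @ R1
        R2p = rot_axis(hinge, -gamma / 2.0) @ R2
    else:  # coplanar frames: no bending, hinge undefined
        hinge = None
        R1p, R2p = R1, R2
    zm = R1p[:, 2]
    twist = _signed_angle(R1p[:, 0], R2p[:, 0], zm)
    xm = R1p[:, 0] + R2p[:, 0]
    nxm = np.linalg.norm(xm)
    if nxm < 1e-12:
        raise ValueError("twist of 180 degrees: mid-frame x axis undefined")
    xm = xm / nxm
    ym = np.cross(zm, xm)
    Rmid = np.column_stack([xm, ym, zm])
    omid = (np.asarray(o1, float) + np.asarray(o2, float)) / 2.0
    d = Rmid.T @ (np.asarray(o2, float) - np.asarray(o1, float))
    if hinge is None:
        tilt = roll = 0.0
    else:
        # phase of the hinge axis in the mid-frame xy-plane, measured from
        # +y toward -x so that it matches the builder's atan2(tilt, roll)
        phi = -_signed_angle(ym, hinge, zm)
        roll = gamma * float(np.cos(np.deg2rad(phi)))
        tilt = gamma * float(np.sin(np.deg2rad(phi)))
    return Rmid, omid, (float(d[0]), float(d[1]), float(d[2]), tilt, roll, twist)


def fit_frame(template: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) minimizing ||R @ template_i + t - observed_i|| (Kabsch)."""
    template = np.asarray(template, float)
    observed = np.asarray(observed, float)
    tc = template.mean(axis=0)
    oc = observed.mean(axis=0)
    H = (template - tc).T @ (observed - oc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, float(np.sign(np.linalg.det(Vt.T @ U.T)))])
    R = Vt.T @ D @ U.T
    t = oc - R @ tc
    return R, t
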