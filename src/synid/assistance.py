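"""Simplified 4-DOF exoskeleton arm: kinematics, statics, and assistance.

The active chain is a generic serial shoulder-elbow arm with three
intersecting shoulder axes — abduction/adduction (sAA, about x), flexion/
extension (sFE, about y), internal/external rotation (sIE, about z) — and
one elbow flexion/extension axis (eFE).  In the reference pose (all joints
zero) the arm hangs straight down: the hand sits at [0, 0, -(l1 + l2)] in
the shoulder frame.  Positive elbow flexion brings the forearm toward +x.

Assistance is a virtual-stiffness force field: an elastic force pulls the
hand toward the estimated target, is expressed in the sAA frame, and is
mapped to joint torques through the transposed Jacobian (statics).  A
feed-forward pose-dependent gravity term for two point-mass segments
completes the reference torque.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import ConfigurationError, DataError

G = 9.81  # m/s^2

JOINT_NAMES = ("sAA", "sFE", "sIE", "eFE")


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class ArmModel:
    """Geometry, inertia and mounting of the simplified arm.

    ``base_rotation`` expresses the sAA (shoulder) frame axes in the global
    frame; ``base_position`` locates the shoulder center.  ``centers_m`` are
    the distances of the two point masses from their proximal joints, along
    each segment.
    """

    l_upper_m: float = 0.30
    l_forearm_m: float = 0.33          # forearm + hand
    base_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    base_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    masses_kg: tuple = (2.0, 1.5)
    centers_m: tuple = (0.15, 0.17)
    joint_limits: tuple = (
        (-1.57, 3.14),   # sAA
        (-1.57, 3.14),   # sFE
        (-1.57, 1.57),   # sIE
        (0.0, 2.62),     # eFE
    )
    manipulability_measure: str = "inv_cond"

    def __post_init__(self) -> None:
        if self.l_upper_m <= 0 or self.l_forearm_m <= 0:
            raise ConfigurationError("segment lengths must be positive")
        self.base_rotation = np.asarray(self.base_rotation, float)
        self.base_position = np.asarray(self.base_position, float)
        RtR = self.base_rotation.T @ self.base_rotation
        if not np.allclose(RtR, np.eye(3), atol=1e-9):
            raise ConfigurationError("base_rotation must be orthonormal")


def _chain(q: np.ndarray, arm: ArmModel):
    """Rotations and joint positions along the chain (global frame)."""
    q = np.asarray(q, float)
    if q.shape != (4,) or not np.all(np.isfinite(q)):
        raise DataError("q must be a finite 4-vector of joint angles")
    Rb = arm.base_rotation
    R1 = Rb @ _rx(q[0])
    R2 = R1 @ _ry(-q[1])       # positive shoulder flexion -> arm toward +x
    R3 = R2 @ _rz(q[2])
    R4 = R3 @ _ry(-q[3])       # positive elbow flexion -> forearm toward +x
    p_sh = arm.base_position
    p_el = p_sh + R3 @ np.array([0.0, 0.0, -arm.l_upper_m])
    p_hand = p_el + R4 @ np.array([0.0, 0.0, -arm.l_forearm_m])
    axes = (
        Rb @ np.array([1.0, 0.0, 0.0]),      # sAA
        R1 @ np.array([0.0, -1.0, 0.0]),     # sFE (rotation about -y of R1)
        R2 @ np.array([0.0, 0.0, 1.0]),      # sIE
        R3 @ np.array([0.0, -1.0, 0.0]),     # eFE (rotation about -y of R3)
    )
    origins = (p_sh, p_sh, p_sh, p_el)
    return axes, origins, p_el, p_hand


def forward_kinematics(q: np.ndarray, arm: ArmModel) -> np.ndarray:
    """Hand position in the global frame."""
    return _chain(q, arm)[3]


def jacobian(q: np.ndarray, arm: ArmModel) -> np.ndarray:
    """Geometric 3x4 positional Jacobian of the hand (global frame)."""
    axes, origins, _, p_hand = _chain(q, arm)
    J = np.empty((3, 4))
    for i in range(4):
        J[:, i] = np.cross(axes[i], p_hand - origins[i])
    return J


def virtual_force(
    x_hand: np.ndarray,
    x_target: np.ndarray,
    gains: np.ndarray,
    arm: ArmModel,
) -> np.ndarray:
    """Virtual-stiffness force pulling the hand toward the target (sAA frame).

    The hand-to-target displacement (global frame) is rotated into the sAA
    frame and multiplied element-wise by the per-axis stiffness gains.
    """
    gains = np.asarray(gains, float)
    if np.any(gains < 0):
        raise DataError("stiffness gains must be non-negative")
    d = np.asarray(x_target, float) - np.asarray(x_hand, float)
    return gains * (arm.base_rotation.T @ d)


def assistive_torques(F: np.ndarray, q: np.ndarray, arm: ArmModel) -> np.ndarray:
    """Map an sAA-frame hand force to joint torques by the statics equation
    tau = J^T F, with the Jacobian expressed in the same frame as F."""
    J_saa = arm.base_rotation.T @ jacobian(q, arm)
    return J_saa.T @ np.asarray(F, float)


def gravity_torques(q: np.ndarray, arm: ArmModel, g: float = G) -> np.ndarray:
    """Torques opposing gravity for the two point-mass segments."""
    axes, origins, p_el, p_hand = _chain(q, arm)
    # mass 1 at centers_m[0] along the upper arm from the shoulder
    u_dir = (p_el - arm.base_position) / arm.l_upper_m
    p_m1 = arm.base_position + arm.centers_m[0] * u_dir
    f_dir = (p_hand - p_el) / arm.l_forearm_m
    p_m2 = p_el + arm.centers_m[1] * f_dir
    tau = np.zeros(4)
    for mass, point, n_joints in ((arm.masses_kg[0], p_m1, 3), (arm.masses_kg[1], p_m2, 4)):
        if mass == 0:
            continue
        Jm = np.zeros((3, 4))
        for i in range(n_joints):
            Jm[:, i] = np.cross(axes[i], point - origins[i])
        # supporting torque opposes the gravity force -m g z
        tau += Jm.T @ np.array([0.0, 0.0, mass * g])
    return tau


@dataclass
class TorqueCommand:
    tau_assist: np.ndarray
    tau_gravity: np.ndarray

    @property
    def tau_ref(self) -> np.ndarray:
        return self.tau_gravity + self.tau_assist


def reference_torques(
    F: np.ndarray, q: np.ndarray, arm: ArmModel
) -> TorqueCommand:
    """Reference torques = gravity compensation + assistive statics."""
    return TorqueCommand(
        tau_assist=assistive_torques(F, q, arm),
        tau_gravity=gravity_torques(q, arm),
    )


def default_exo_arm() -> ArmModel:
    """Arm model mounted so the whole center-out workspace (25 cm circle on
    a table at the home position) is reachable: the shoulder sits 40 cm
    above and 15 cm behind the home point."""
    return ArmModel(base_position=np.array([-0.15, 0.0, 0.40]))


def manipulability_from_jacobian(J: np.ndarray, measure: str = "inv_cond") -> float:
    """Manipulability index of an explicit Jacobian (see ``manipulability``)."""
    s = np.linalg.svd(np.asarray(J, float), compute_uv=False)
    if s[0] == 0:
        raise DataError("Jacobian is identically zero; manipulability undefined")
    if measure == "inv_cond":
        return float(s[-1] / s[0])
    raise ConfigurationError(f"unknown measure {measure!r} for explicit Jacobian")


def manipulability(q: np.ndarray, arm: ArmModel, measure: Optional[str] = None) -> float:
    """Configuration-dependent manipulability index in [0, 1].

    Default measure is the inverse condition number of the positional
    Jacobian, sqrt(lambda_min / lambda_max) of J J^T: exactly 0 at singular
    configurations and 1 when the velocity ellipsoid is isotropic.  A
    Yoshikawa-style option (sqrt(det(J J^T)), normalized by its maximum
    over a sampled workspace) is selectable per arm model.
    """
    measure = measure or arm.manipulability_measure
    J = jacobian(q, arm)
    s = np.linalg.svd(J, compute_uv=False)
    if s[0] == 0:
        raise DataError("Jacobian is identically zero; manipulability undefined")
    if measure == "inv_cond":
        return float(s[-1] / s[0])
    if measure == "yoshikawa_norm":
        w = float(np.sqrt(np.prod(s * s)))
        return w / _yoshikawa_max(arm)
    raise ConfigurationError(f"unknown manipulability measure {measure!r}")


_yoshikawa_cache: dict = {}


def _yoshikawa_max(arm: ArmModel, n: int = 2000) -> float:
    key = (arm.l_upper_m, arm.l_forearm_m)
    if key not in _yoshikawa_cache:
        rng = np.random.default_rng(0)
        lo = np.array([b[0] for b in arm.joint_limits])
        hi = np.array([b[1] for b in arm.joint_limits])
        best = 0.0
        for _ in range(n):
            q = rng.uniform(lo, hi)
            s = np.linalg.svd(jacobian(q, arm), compute_uv=False)
            best = max(best, float(np.sqrt(np.prod(s * s))))
        _yoshikawa_cache[key] = best
    return _yoshikawa_cache[key]


def inverse_kinematics(
    x_target: np.ndarray,
    arm: ArmModel,
    q0: Optional[np.ndarray] = None,
    damping: float = 1e-3,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> np.ndarray:
    """Damped-least-squares inverse kinematics with joint-limit clamping."""
    q = np.array([0.3, 0.5, 0.0, 0.8]) if q0 is None else np.array(q0, float)
    lo = np.array([b[0] for b in arm.joint_limits])
    hi = np.array([b[1] for b in arm.joint_limits])
    x_target = np.asarray(x_target, float)
    for _ in range(max_iter):
        err = x_target - forward_kinematics(q, arm)
        if np.linalg.norm(err) < tol:
            break
        J = jacobian(q, arm)
        A = J @ J.T + damping * np.eye(3)
        dq = J.T @ np.linalg.solve(A, err)
        q = np.clip(q + dq, lo, hi)
    return q


def trajectory_manipulability(
    trajectory: np.ndarray, arm: ArmModel, measure: Optional[str] = None
) -> float:
    """Mean manipulability along a hand trajectory (time-normalized samples).

    Joint configurations are recovered by damped-least-squares inverse
    kinematics warm-started sample to sample.
    """
    traj = np.asarray(trajectory, float)
    q = None
    vals = []
    for x in traj:
        q = inverse_kinematics(x, arm, q0=q)
        vals.append(manipulability(q, arm, measure=measure))
    return float(np.mean(vals))


def simulate_assisted_reach(
    v_intent: np.ndarray,
    x_target: np.ndarray | Callable[[int], np.ndarray],
    gains: np.ndarray,
    admittance: float,
    arm: ArmModel,
    dt: float,
    x0: np.ndarray,
    gain_multiplier: float = 1000.0,
) -> np.ndarray:
    """First-order admittance simulation of an assisted reach.

    ``x_{k+1} = x_k + (v_intent_k + admittance * F_k) * dt`` where ``F_k``
    is the virtual-stiffness force toward the (possibly time-varying)
    estimated target, expressed back in the global frame.  The printed
    reference stiffness gains are tiny; ``gain_multiplier`` scales them so
    the simulated assistance is mechanically meaningful (see methods note).
    With zero admittance the trajectory is the pure integrated intent.
    """
    if admittance < 0:
        raise ConfigurationError("admittance must be non-negative")
    v_intent = np.asarray(v_intent, float)
    n = v_intent.shape[0]
    gains = np.asarray(gains, float) * gain_multiplier
    xs = np.empty((n + 1, 3))
    xs[0] = np.asarray(x0, float)
    for k in range(n):
        tgt = x_target(k) if callable(x_target) else x_target
        F_saa = virtual_force(xs[k], tgt, gains, arm)
        F_glob = arm.base_rotation @ F_saa
        xs[k + 1] = xs[k] + (v_intent[k] + admittance * F_glob) * dt
    return xs
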