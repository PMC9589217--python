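"""Passive restraint structures of the tibiofemoral joint.

Three element families act in parallel with the articular contact:

* **Ligament bundles** — the cruciates (ACL, PCL), collaterals (MCL,
  LCL), posteromedial capsule (PMC), anterolateral structure (ALS) and
  oblique popliteal ligament (OPL), each discretised into 1–3 parallel
  tension-only nonlinear springs.  A bundle with current length ``l``,
  slack length ``l0`` and strain ``eps = (l - l0)/l0`` carries

  .. math::

      f = \\begin{cases}
            0                         & \\epsilon \\le 0 \\\\
            k_1 (l - l_0)^2           & 0 < \\epsilon \\le 2\\epsilon_l \\\\
            k_2 [l - (1+\\epsilon_l) l_0] & \\epsilon > 2\\epsilon_l
          \\end{cases}

  with the reference strain constant ``eps_l = 0.03``.  The two branches
  with tabulated (k1, k2) need not meet continuously at
  ``eps = 2 eps_l``; the law is applied literally and the jump can be
  inspected with :func:`branch_jump`.

* **Meniscal horn attachments** — each of the four horns is anchored to
  the tibia by ``n_h`` parallel linear springs whose individual
  stiffness derives from the attachment's Young's modulus ``E`` and
  horn-face area ``a_h``: ``k_hp = E * a_h / (n_h * l_hp)``, i.e. the
  assembly reproduces the axial stiffness ``E a / l`` of a uniform rod
  of the same length.  Horn springs act in both tension and compression.

* **Transverse ligament** — linear springs joining the anterior margins
  of the two menisci, with a total stiffness of 12.5 N/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

DEFAULT_EPS_L = 0.03
TRANSVERSE_LIGAMENT_STIFFNESS = 12.5  # N/mm, total
LIGAMENT_NAMES = ("ACL", "PCL", "MCL", "PMC", "LCL", "ALS", "OPL")


@dataclass
class LigamentBundle:
    """One tension-only nonlinear spring of a ligament."""

    name: str                 # ligament, e.g. "ACL"
    bundle: str               # bundle label, e.g. "anterior"
    index: int                # bundle replica index (0-based)
    k1: float                 # N/mm^2, quadratic toe region
    k2: float                 # N/mm, linear region
    l0: float = 1.0           # mm, slack length
    eps_l: float = DEFAULT_EPS_L
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))     # femur-local, mm
    insertion: np.ndarray = field(default_factory=lambda: np.zeros(3))  # tibia-local, mm

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError(f"{self.name} {self.bundle}: stiffness must be positive")
        if self.l0 <= 0:
            raise ValueError(f"{self.name} {self.bundle}: slack length must be positive")

    @property
    def label(self) -> str:
        return f"{self.name}_{self.bundle}_{self.index}"


def ligament_force(bundle: LigamentBundle, l: float) -> float:
    """Tension (N) carried by a bundle at current length ``l`` (mm)."""
    if l <= 0:
        raise ValueError("ligament length must be positive")
    l0 = bundle.l0
    eps = (l - l0) / l0
    if eps <= 0.0:
        return 0.0
    if eps <= 2.0 * bundle.eps_l:
        return bundle.k1 * (l - l0) ** 2
    return bundle.k2 * (l - (1.0 + bundle.eps_l) * l0)


def ligament_stiffness(bundle: LigamentBundle, l: float) -> float:
    """d(force)/d(length) of the piecewise law (N/mm); 0 when slack."""
    l0 = bundle.l0
    eps = (l - l0) / l0
    if eps <= 0.0:
        return 0.0
    if eps <= 2.0 * bundle.eps_l:
        return 2.0 * bundle.k1 * (l - l0)
    return bundle.k2


def branch_jump(bundle: LigamentBundle) -> float:
    """Force discontinuity (N) at the branch transition ``eps = 2 eps_l``.

    Positive means the linear branch starts above the quadratic one.
    The tabulated constants do not in general make the two branches
    meet; the jump is reported rather than smoothed away.
    """
    l_t = bundle.l0 * (1.0 + 2.0 * bundle.eps_l)
    quad = bundle.k1 * (l_t - bundle.l0) ** 2
    lin = bundle.k2 * (l_t - (1.0 + bundle.eps_l) * bundle.l0)
    return lin - quad


def load_ligament_table(path=None) -> list[LigamentBundle]:
    """Load the ligament stiffness table (packaged default or a YAML file).

    Returns one :class:`LigamentBundle` per replica; 20 bundles for the
    default table.  The loader validates names, replica counts and the
    positivity invariants.
    """
    if path is None:
        text = resources.files("femsgait.data").joinpath("ligaments.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    eps_l = float(doc.get("eps_l", DEFAULT_EPS_L))
    bundles: list[LigamentBundle] = []
    for name, rows in doc["ligaments"].items():
        if name not in LIGAMENT_NAMES:
            raise ValueError(f"unknown ligament name {name!r}")
        for row in rows:
            n = int(row["n"])
            if n < 1:
                raise ValueError(f"{name}: replica count must be >= 1")
            for i in range(n):
                bundles.append(
                    LigamentBundle(
                        name=name,
                        bundle=str(row["bundle"]),
                        index=i,
                        k1=float(row["k1"]),
                        k2=float(row["k2"]),
                        eps_l=eps_l,
                    )
                )
    return bundles


@dataclass
class HornAttachment:
    """Spring anchorage of one meniscal horn to the tibial plateau."""

    horn: str                 # e.g. "medial_anterior"
    youngs_modulus: float     # MPa
    face_area: float          # mm^2
    horn_nodes: np.ndarray    # (n, 3) tibia-frame positions of horn-face nodes
    tibia_nodes: np.ndarray   # (n, 3) tibia-frame anchor positions
    node_ids: np.ndarray | None = None   # indices into the host meniscus mesh

    def __post_init__(self) -> None:
        self.horn_nodes = np.atleast_2d(np.asarray(self.horn_nodes, dtype=float))
        self.tibia_nodes = np.atleast_2d(np.asarray(self.tibia_nodes, dtype=float))
        if self.youngs_modulus <= 0 or self.face_area <= 0:
            raise ValueError(f"horn {self.horn}: E and area must be positive")
        if self.horn_nodes.shape != self.tibia_nodes.shape or self.horn_nodes.shape[0] < 1:
            raise ValueError(f"horn {self.horn}: node pairings malformed")


@dataclass
class HornSpring:
    horn: str
    horn_node: np.ndarray
    tibia_node: np.ndarray
    rest_length: float   # mm
    stiffness: float     # N/mm


def build_horn_springs(attachment: HornAttachment) -> list[HornSpring]:
    """Distribute the rod stiffness ``E a / l`` over the horn's springs.

    Each of the ``n_h`` springs gets ``k_hp = E a_h / (n_h l_hp)`` with
    ``l_hp`` its own anchor-to-face length, so equal-length springs in
    parallel reproduce the uniform-rod stiffness exactly, independent of
    ``n_h``.  Springs are linear and carry both tension and compression.
    """
    n_h = attachment.horn_nodes.shape[0]
    springs = []
    for hn, tn in zip(attachment.horn_nodes, attachment.tibia_nodes):
        l_hp = float(np.linalg.norm(tn - hn))
        if l_hp <= 1e-12:
            raise ValueError(f"horn {attachment.horn}: zero-length spring")
        k_hp = attachment.youngs_modulus * attachment.face_area / (n_h * l_hp)
        springs.append(
            HornSpring(attachment.horn, hn.copy(), tn.copy(), l_hp, k_hp)
        )
    return springs


def horn_spring_force(spring: HornSpring, horn_pos: np.ndarray) -> np.ndarray:
    """Force (N) on the horn node for a displaced horn-node position."""
    d = horn_pos - spring.tibia_node
    l = float(np.linalg.norm(d))
    if l <= 1e-12:
        return np.zeros(3)
    return -spring.stiffness * (l - spring.rest_length) * d / l


def ligament_wrench(
    bundles: list[LigamentBundle],
    origins_global: np.ndarray,
    insertions_global: np.ndarray,
    about: np.ndarray,
):
    """Resultant ligament force/moment on the tibia (and minus on femur).

    ``origins_global`` / ``insertions_global`` are the current femoral
    and tibial attachment points, (n, 3) in any common frame; ``about``
    is the moment reference point.  Returns ``(force, moment)`` acting
    on the tibia; the femur sees the exact opposite wrench about the
    same point (internal forces cancel pairwise).
    """
    origins_global = np.atleast_2d(origins_global)
    insertions_global = np.atleast_2d(insertions_global)
    force = np.zeros(3)
    moment = np.zeros(3)
    for b, o, ins in zip(bundles, origins_global, insertions_global):
        d = o - ins
        l = float(np.linalg.norm(d))
        f = ligament_force(b, l)
        if f == 0.0:
            continue
        fv = f * d / l          # pulls tibia insertion toward femur origin
        force += fv
        moment += np.cross(ins - about, fv)
    return force, moment
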