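"""Compartmental pyramidal-cell morphologies.

A :class:`Morphology` is a tree of cylindrical compartments rooted at the
soma, each carrying a section type (soma, basal, apical trunk, apical
branch), a length and diameter in micrometres, and the somatodendritic path
distance ``z`` measured along the tree from the soma centre to the distal
end of the compartment. Passive membrane properties follow the CA1
conventions used by the cell model: axial resistivity 100 Ohm*cm, somatic
capacitance 5 uF/cm^2 with a 1.8x spine-corrected value elsewhere, and a
sigmoidal leak-conductance profile rising with distance from the soma.

Synthetic morphologies are binary branching trees sized for desk-scale
simulation (tens of compartments by default, configurable to the 200-300
range of full reconstructions); real reconstructions can be loaded from
standard SWC files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Compartment",
    "Morphology",
    "MorphSpec",
    "PassiveRules",
    "generate_morphology",
    "leak_conductance",
    "read_swc",
    "spine_correction",
    "write_swc",
]

SECTION_TYPES = ("soma", "basal", "apical_trunk", "apical_branch")

# SWC structure identifiers
_SWC_SOMA = 1
_SWC_BASAL = 3
_SWC_APICAL = 4


@dataclass
class Compartment:
    id: int
    parent: int  # -1 for the root (soma)
    section_type: str
    length: float  # um
    diameter: float  # um
    z: float  # path distance from soma centre to distal end, um


@dataclass
class PassiveRules:
    """Passive membrane parameterization.

    Ra_base : axial resistivity, Ohm*cm.
    Cm_soma : somatic specific capacitance, uF/cm^2.
    Cm_dend_multiplier : dendritic Cm = multiplier * Cm_soma * SS.
    """

    Ra_base: float = 100.0
    Cm_soma: float = 5.0
    Cm_dend_multiplier: float = 1.8


def spine_correction(section_type: str, z: float, thickness: float) -> float:
    """Spine surface-area correction factor SS for one compartment.

    The factor accounts for the extra membrane contributed by dendritic
    spines: 1 at the soma, 2.51 on basal dendrites, and a diameter- and
    distance-dependent table on apical dendrites. Diameter thresholds are
    half-open, closed on the lower bound; the 350 um near/far boundary is
    assigned to the near rule.
    """
    if thickness <= 0:
        raise ValueError("spine_correction: thickness must be > 0")
    if z < 0:
        raise ValueError("spine_correction: z must be >= 0")
    if section_type == "soma":
        return 1.0
    if section_type == "basal":
        return 2.51
    if section_type in ("apical_trunk", "apical_branch", "apical"):
        if z <= 350.0:
            if thickness >= 1.6:
                return 1.69
            if thickness >= 0.55:
                return 1.60
            return 1.86
        if thickness >= 0.35:
            return 2.10
        return 1.71
    raise ValueError(f"spine_correction: unknown section type {section_type!r}")


def leak_conductance(z: float, SS: float = 1.0):
    """Leak (passive membrane) conductance in S/cm^2 at path distance z.

    The somatic profile is a rising sigmoid of distance,
    g = 0.001 / (80 + (0.4 - 80) / (1 + exp((225 - z)/30))),
    bounded between 0.001/80 near the soma and 0.001/0.4 distally;
    non-somatic compartments scale it by their spine factor SS.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("leak_conductance: z must be >= 0")
    if np.any(np.asarray(SS) < 1.0):
        raise ValueError("leak_conductance: SS must be >= 1")
    g = 0.001 / (80.0 + (0.4 - 80.0) / (1.0 + np.exp((225.0 - z) / 30.0)))
    out = np.asarray(SS, dtype=float) * g
    return float(out) if out.ndim == 0 else out


class Morphology:
    """Tree of cylindrical compartments rooted at the soma."""

    def __init__(self, compartments: list[Compartment], name: str = "morph"):
        self.name = name
        self.compartments = list(compartments)
        self._validate()

    # -- construction / validation -------------------------------------
    def _validate(self) -> None:
        comps = self.compartments
        if not comps:
            raise ValueError("Morphology: empty compartment list")
        ids = [c.id for c in comps]
        if len(set(ids)) != len(ids):
            raise ValueError("Morphology: duplicate compartment ids")
        by_id = {c.id: c for c in comps}
        roots = [c for c in comps if c.parent == -1]
        if len(roots) != 1:
            raise ValueError(f"Morphology: expected exactly one root, got {len(roots)}")
        root = roots[0]
        if root.section_type != "soma":
            raise ValueError("Morphology: root must be the soma")
        if root.z != 0.0:
            raise ValueError("Morphology: soma z must be 0")
        for c in comps:
            if c.section_type not in SECTION_TYPES:
                raise ValueError(f"Morphology: bad section type {c.section_type!r}")
            if c.length <= 0 or c.diameter <= 0:
                raise ValueError(f"Morphology: non-positive geometry at id {c.id}")
            if c.parent != -1:
                if c.parent not in by_id:
                    raise ValueError(f"Morphology: compartment {c.id} has missing parent {c.parent}")
                if c.z <= by_id[c.parent].z:
                    raise ValueError(f"Morphology: z not increasing at compartment {c.id}")
        # acyclicity: walk each compartment to the root
        for c in comps:
            seen = set()
            cur = c
            while cur.parent != -1:
                if cur.id in seen:
                    raise ValueError("Morphology: cycle detected")
                seen.add(cur.id)
                cur = by_id[cur.parent]

    # -- derived quantities ---------------------------------------------
    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def _children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {c.id: [] for c in self.compartments}
        for c in self.compartments:
            if c.parent != -1:
                ch[c.parent].append(c.id)
        return ch

    def _terminal_count(self, types: tuple[str, ...]) -> int:
        ch = self._children()
        return sum(
            1
            for c in self.compartments
            if c.section_type in types and not ch[c.id]
        )

    @property
    def n_basal_branches(self) -> int:
        return self._terminal_count(("basal",))

    @property
    def n_apical_branches(self) -> int:
        return self._terminal_count(("apical_trunk", "apical_branch"))

    @property
    def n_total_branches(self) -> int:
        return self.n_basal_branches + self.n_apical_branches

    def areas_cm2(self) -> np.ndarray:
        """Lateral membrane area of each compartment in cm^2."""
        return np.array(
            [math.pi * c.diameter * c.length * 1e-8 for c in self.compartments]
        )

    def signed_z(self) -> np.ndarray:
        """Somatodendritic coordinate: apical/soma positive, basal negative."""
        return np.array(
            [-c.z if c.section_type == "basal" else c.z for c in self.compartments]
        )

    def spine_factors(self) -> np.ndarray:
        return np.array(
            [spine_correction(c.section_type, c.z, c.diameter) for c in self.compartments]
        )

    def ordered_indices(self) -> np.ndarray:
        """Topological order (parents before children) as positions."""
        pos = {c.id: i for i, c in enumerate(self.compartments)}
        order: list[int] = []
        ch = self._children()
        root = next(c.id for c in self.compartments if c.parent == -1)
        stack = [root]
        while stack:
            cid = stack.pop()
            order.append(pos[cid])
            stack.extend(reversed(ch[cid]))
        return np.array(order)

    def summary(self) -> dict:
        return {
            "name": self.name,
            "n_compartments": self.n_compartments,
            "n_basal_branches": self.n_basal_branches,
            "n_apical_branches": self.n_apical_branches,
            "n_total_branches": self.n_total_branches,
            "total_length_um": float(sum(c.length for c in self.compartments)),
        }

    def summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


@dataclass
class MorphSpec:
    """Recipe for a synthetic binary-tree morphology.

    n_basal / n_apical : terminal branch counts.
    depth : compartments per unbranched section.
    mean_seg_length : mean compartment length, um.
    taper : diameter multiplier applied per branch order.
    trunk_sections : chained trunk sections before the apical tuft.
    """

    n_basal: int = 5
    n_apical: int = 8
    depth: int = 2
    mean_seg_length: float = 30.0
    taper: float = 0.8
    trunk_sections: int = 3
    soma_length: float = 20.0
    soma_diameter: float = 20.0
    trunk_diameter: float = 3.0
    basal_diameter: float = 1.2


def _chain(comps, rng, parent_id, next_id, z0, n_seg, seg_len, diam, sec_type):
    """Append a chain of n_seg compartments; return (last_id, next_id, z)."""
    z = z0
    pid = parent_id
    for _ in range(n_seg):
        length = max(1.0, seg_len * (1.0 + 0.2 * rng.standard_normal()))
        z = z + length
        comps.append(Compartment(next_id, pid, sec_type, length, diam, z))
        pid = next_id
        next_id += 1
    return pid, next_id, z


def _subtree(comps, rng, parent_id, next_id, z0, n_tips, order, spec, sec_type, diam):
    """Binary tree with exactly n_tips terminal branches."""
    pid, next_id, z = _chain(
        comps, rng, parent_id, next_id, z0, spec.depth, spec.mean_seg_length, diam, sec_type
    )
    if n_tips <= 1:
        return next_id
    left = (n_tips + 1) // 2
    right = n_tips - left
    child_diam = max(0.15, diam * spec.taper)
    next_id = _subtree(comps, rng, pid, next_id, z, left, order + 1, spec, sec_type, child_diam)
    next_id = _subtree(comps, rng, pid, next_id, z, right, order + 1, spec, sec_type, child_diam)
    return next_id


def generate_morphology(spec: MorphSpec | None = None, seed: int = 0, name: str | None = None) -> Morphology:
    """Generate a synthetic pyramidal-cell morphology.

    Builds a soma, an apical trunk continued by a binary tuft with exactly
    ``spec.n_apical`` terminal branches, and a basal binary tree with
    exactly ``spec.n_basal`` terminal branches. Deterministic in ``seed``.
    """
    spec = spec or MorphSpec()
    if spec.n_basal < 1 or spec.n_apical < 1:
        raise ValueError("generate_morphology: branch counts must be >= 1")
    if spec.depth < 1 or spec.mean_seg_length <= 0:
        raise ValueError("generate_morphology: infeasible spec")
    rng = np.random.default_rng(seed)
    comps: list[Compartment] = [
        Compartment(0, -1, "soma", spec.soma_length, spec.soma_diameter, 0.0)
    ]
    next_id = 1
    # apical trunk: chained sections tapering mildly
    pid, z, diam = 0, 0.0, spec.trunk_diameter
    for _ in range(spec.trunk_sections):
        pid, next_id, z = _chain(
            comps, rng, pid, next_id, z, spec.depth, spec.mean_seg_length, diam, "apical_trunk"
        )
        diam *= 0.9
    next_id = _subtree(
        comps, rng, pid, next_id, z, spec.n_apical, 0, spec, "apical_branch", max(0.3, diam * spec.taper)
    )
    # basal tree straight off the soma
    _subtree(comps, rng, 0, next_id, 0.0, spec.n_basal, 0, spec, "basal", spec.basal_diameter)
    return Morphology(comps, name=name or f"synth-{seed}")


# ---------------------------------------------------------------------------
# SWC input/output
# ---------------------------------------------------------------------------

def write_swc(morph: Morphology, path: str | Path) -> None:
    """Write a morphology as a standard 7-column SWC file.

    The package stores topology and cable geometry, not 3-D shape, so node
    coordinates are synthesized: each node is placed along +y (apical) or
    -y (basal) at its path distance, with a deterministic x offset per
    branch to keep nodes distinct. Radii are half the compartment diameter.
    """
    by_id = {c.id: c for c in morph.compartments}
    lines = ["# generated by thetalock; columns: id type x y z radius parent"]
    xoff: dict[int, float] = {}
    for c in sorted(morph.compartments, key=lambda c: c.id):
        if c.section_type == "soma":
            stype = _SWC_SOMA
            x, y = 0.0, 0.0
        else:
            stype = _SWC_BASAL if c.section_type == "basal" else _SWC_APICAL
            sign = -1.0 if c.section_type == "basal" else 1.0
            # siblings fan out in x
            parent_x = xoff.get(c.parent, 0.0)
            nsib = sum(1 for o in morph.compartments if o.parent == c.parent and o.id < c.id)
            x = parent_x + 0.01 * nsib  # tiny fan-out; keeps node-to-parent distance == length
            y = sign * c.z
        xoff[c.id] = x
        r = c.diameter / 2.0
        parent = c.parent if c.parent != -1 else -1
        lines.append(f"{c.id + 1} {stype} {x:.4f} {y:.4f} 0.0 {r:.4f} {parent + 1 if parent != -1 else -1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path) -> Morphology:
    """Read a 7-column SWC file into a Morphology.

    Compartment length is the Euclidean distance to the parent node; the
    soma node becomes the root compartment with its own radius as length
    scale. Apical nodes are typed trunk/branch by whether their subtree
    carries more than one terminal tip.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) != 7:
            raise ValueError(f"read_swc: line {lineno}: expected 7 columns, got {len(parts)}")
        rows.append((lineno, int(parts[0]), int(parts[1]), float(parts[2]),
                     float(parts[3]), float(parts[4]), float(parts[5]), int(parts[6])))
    if not rows:
        raise ValueError("read_swc: no records")
    nodes = {r[1]: r for r in rows}
    roots = [r for r in rows if r[7] == -1]
    if len(roots) != 1:
        lns = [r[0] for r in roots]
        raise ValueError(f"read_swc: expected one root, found {len(roots)} (lines {lns})")
    for r in rows:
        if r[7] != -1 and r[7] not in nodes:
            raise ValueError(f"read_swc: line {r[0]}: node {r[1]} references missing parent {r[7]}")
    children: dict[int, list[int]] = {r[1]: [] for r in rows}
    for r in rows:
        if r[7] != -1:
            children[r[7]].append(r[1])

    def tips(nid: int) -> int:
        if not children[nid]:
            return 1
        return sum(tips(c) for c in children[nid])

    sorted_ids = sorted(nodes)
    id_map = {nid: i for i, nid in enumerate(sorted_ids)}
    comps: list[Compartment] = [None] * len(sorted_ids)  # type: ignore[list-item]
    zmap: dict[int, float] = {}
    # breadth-first from the root so parents are processed first even if
    # the file orders ids arbitrarily
    root_id = roots[0][1]
    queue = [root_id]
    while queue:
        nid = queue.pop(0)
        lineno, _, stype, x, y, zc, rad, parent = nodes[nid]
        new_id = id_map[nid]
        if parent == -1:
            comps[new_id] = Compartment(new_id, -1, "soma", max(rad * 2.0, 1.0), rad * 2.0, 0.0)
            zmap[nid] = 0.0
        else:
            pr = nodes[parent]
            length = math.dist((x, y, zc), (pr[3], pr[4], pr[5]))
            if length <= 0:
                length = 1e-3
            z = zmap[parent] + length
            zmap[nid] = z
            if stype == _SWC_APICAL:
                sec = "apical_trunk" if tips(nid) > 1 else "apical_branch"
            elif stype == _SWC_SOMA:
                sec = "apical_trunk"  # extra soma points treated as proximal stem
            else:
                sec = "basal"
            comps[new_id] = Compartment(new_id, id_map[parent], sec, length, rad * 2.0, z)
        queue.extend(children[nid])
    return Morphology(comps, name=Path(path).stem)
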