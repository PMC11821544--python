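"""Atomic building blocks and cage assembly.

Synthetic trimers are coarse Calpha/Cbeta pseudo-atom models: each chain is a
straight "arm" radiating from the C3 axis, so a trimer is a three-armed star
with exact three-fold symmetry about +z.  That shape makes the wireframe
contact topology of the cages literal: each arm points at exactly one
neighbouring trimer and touches it tip-to-tip, while the three arms meet near
the hub to form the intra-trimer interface.

Structure I/O goes through gemmi (PDB and mmCIF).  Assembled cages carry one
multi-character chain label per subunit (written to mmCIF label_asym_id /
auth_asym_id); PDB output is refused when more than 62 single-character
labels would be needed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.optimize import brentq

import gemmi

from . import symcore
from .symcore import Axis
from .lattice import CageLayout

CA_SPACING = 3.8  # consecutive Calpha spacing along an arm, Angstrom
CLASH_DISTANCE = 2.4  # default heavy-atom clash threshold (~0.8 x vdW sum)
_PDB_CHAIN_CHARS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass
class AtomRecord:
    element: str
    atom_name: str
    coords: np.ndarray
    residue_index: int  # 1-based
    residue_name: str
    chain_label: str

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Chain:
    label: str
    atoms: list[AtomRecord]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy])

    def ca_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.atom_name == "CA"])

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Chain":
        r = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [
            AtomRecord(a.element, a.atom_name, r @ a.coords + t, a.residue_index,
                       a.residue_name, a.chain_label)
            for a in self.atoms
        ]
        return Chain(self.label, atoms)

    def relabeled(self, label: str) -> "Chain":
        atoms = [
            AtomRecord(a.element, a.atom_name, a.coords.copy(), a.residue_index,
                       a.residue_name, label)
            for a in self.atoms
        ]
        return Chain(label, atoms)


@dataclass
class StructureModel:
    chains: list[Chain]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.chains]
        if len(set(labels)) != len(labels):
            raise ValueError("chain labels must be unique")

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def get_chain(self, label: str) -> Chain:
        for c in self.chains:
            if c.label == label:
                return c
        raise KeyError(label)

    def all_coords(self) -> np.ndarray:
        return np.vstack([c.coords() for c in self.chains])

    def heavy_coords(self) -> np.ndarray:
        return np.vstack([c.heavy_coords() for c in self.chains])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        return StructureModel(
            [c.transformed(rotation, translation) for c in self.chains],
            dict(self.metadata),
        )


@dataclass
class TrimerModel(StructureModel):
    """A C3 trimer: exactly three chains about ``symmetry_axis``."""

    symmetry_axis: Axis = field(default_factory=lambda: Axis(np.array([0.0, 0.0, 1.0]), 3))
    pattern: str = "AAA"

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.chains) != 3:
            raise ValueError("a trimer has exactly 3 chains")

    def c3_backbone_rmsd(self) -> float:
        """Max r.m.s.d. between each chain and the 120-degree rotation of the
        next chain; zero for an exactly symmetric backbone."""
        r = symcore.rotation_matrix_about(self.symmetry_axis.direction, 120.0)
        worst = 0.0
        for k in range(3):
            a = self.chains[(k + 1) % 3].coords()
            b = self.chains[k].coords() @ r.T
            worst = max(worst, float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))))
        return worst


@dataclass
class Pentasymmetron:
    """Five AAB heterotrimers ringing a five-fold vertex (15 chains)."""

    trimers: list[TrimerModel]
    five_fold_axis: Axis

    def __post_init__(self) -> None:
        if len(self.trimers) != 5:
            raise ValueError("a pentasymmetron has exactly 5 trimers")

    @property
    def chains(self) -> list[Chain]:
        return [c for t in self.trimers for c in t.chains]


@dataclass
class Disymmetron:
    """Two ABB heterotrimers joined by one A:A contact across a two-fold."""

    trimers: list[TrimerModel]
    two_fold_axis: Axis

    def __post_init__(self) -> None:
        if len(self.trimers) != 2:
            raise ValueError("a disymmetron has exactly 2 trimers")

    @property
    def chains(self) -> list[Chain]:
        return [c for t in self.trimers for c in t.chains]


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def read_structure(path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (atoms grouped by
    chain; insertion codes kept on the residue index as written)."""
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(
                str(path),
                format=gemmi.CoorFormat.Pdb if fmt.upper() == "PDB" else gemmi.CoorFormat.Mmcif,
            )
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0 or sum(1 for _ in st[0]) == 0:
        raise ValueError(f"{path}: no model/chains found")
    chains = []
    for ch in st[0]:
        atoms = []
        for res in ch:
            for at in res:
                atoms.append(
                    AtomRecord(
                        element=at.element.name,
                        atom_name=at.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        residue_index=res.seqid.num,
                        residue_name=res.name,
                        chain_label=ch.name,
                    )
                )
        chains.append(Chain(ch.name, atoms))
    return StructureModel(chains, {"source": str(path)})


def write_structure(model: StructureModel, path, fmt: str | None = None) -> None:
    """Write PDB or mmCIF (format from ``fmt`` or the file suffix).

    mmCIF handles any number of multi-character chain labels; PDB is only
    written when at most 62 chains allow single-character labels.
    """
    path = str(path)
    if fmt is None:
        fmt = "PDB" if path.lower().endswith(".pdb") else "MMCIF"
    fmt = fmt.upper().replace("CIF", "MMCIF").replace("MMMMCIF", "MMCIF")

    st = gemmi.Structure()
    st.name = model.metadata.get("title", "pseudocage model")
    gm = gemmi.Model("1")

    if fmt == "PDB":
        if model.n_chains > 62:
            raise ValueError(
                f"{model.n_chains} chains cannot be written as PDB "
                "(62 single-character chain labels available); write mmCIF instead"
            )
        labels = [c.label for c in model.chains]
        if any(len(l) > 1 for l in labels) or len(set(labels)) != len(labels):
            labels = [_PDB_CHAIN_CHARS[i] for i in range(model.n_chains)]
    else:
        labels = [c.label for c in model.chains]

    for chain, label in zip(model.chains, labels):
        gc = gemmi.Chain(label)
        res = None
        for a in chain.atoms:
            if res is None or res.seqid.num != a.residue_index:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_index, " ")
                gc.add_residue(res)
                res = gc[-1]
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coords)
            at.occ = 1.0
            at.b_iso = 0.0
            res.add_atom(at)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    if fmt == "PDB":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


# ---------------------------------------------------------------------------
# synthetic trimer
# ---------------------------------------------------------------------------

def synthetic_trimer(
    radius: float = 15.0,
    n_residues_per_chain: int = 20,
    seed: int = 0,
    jitter: float = 0.05,
    cb_length: float = 1.6,
    bar_residues: int = 5,
) -> TrimerModel:
    """Idealized poly-alanine-like C3 trimer of Calpha/Cbeta pseudo-atoms.

    Each chain is an arm radiating from the +z axis: a straight stem whose
    residue i has its Calpha at ``radius + i * 3.8`` Angstrom from the axis
    (with a small alternating z zigzag), capped by a contact "bar" of
    ``bar_residues`` residues running perpendicular to the stem and centred
    on it.  The bar stands in for an interface patch: two facing arms meet
    bar-on-bar (parallel lines), so inter-trimer contacts are extended
    surfaces rather than single points and docking scores vary smoothly
    with slide and twist.  One template arm receives deterministic Gaussian
    coordinate jitter (sigma ``jitter``, from ``seed``) and is replicated
    by exact 120-degree rotations, so the backbone C3 symmetry is exact by
    construction.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_residues_per_chain < 5:
        raise ValueError("need at least 5 residues per chain")
    if not 0 <= bar_residues < n_residues_per_chain:
        raise ValueError("bar_residues must be smaller than the chain length")
    rng = np.random.default_rng(seed)
    n_stem = n_residues_per_chain - bar_residues
    tip_r = radius + (n_stem - 1) * CA_SPACING
    template = []
    for i in range(n_residues_per_chain):
        z = 0.4 * (-1.0) ** i
        if i < n_stem:
            ca = np.array([radius + i * CA_SPACING, 0.0, z])
        else:
            k = i - n_stem
            lateral = (k - (bar_residues - 1) / 2.0) * CA_SPACING
            ca = np.array([tip_r, lateral, z])
        cb = ca + np.array([0.0, 0.0, cb_length])
        template.append((ca, cb))
    noise = rng.normal(0.0, jitter, size=(n_residues_per_chain, 2, 3))
    chains = []
    for k, label in enumerate(("A1", "A2", "A3")):
        rot = symcore.rotation_matrix_about([0, 0, 1], 120.0 * k)
        atoms = []
        for i, (ca, cb) in enumerate(template):
            for name, pos, noi in (("CA", ca, noise[i, 0]), ("CB", cb, noise[i, 1])):
                atoms.append(
                    AtomRecord(
                        element="C",
                        atom_name=name,
                        coords=rot @ (pos + noi),
                        residue_index=i + 1,
                        residue_name="ALA",
                        chain_label=label,
                    )
                )
        chains.append(Chain(label, atoms))
    return TrimerModel(
        chains=chains,
        metadata={"radius": radius, "n_residues": n_residues_per_chain, "seed": seed},
        symmetry_axis=Axis(np.array([0.0, 0.0, 1.0]), 3),
        pattern="AAA",
    )


def arm_tip_radius(trimer: TrimerModel) -> float:
    """Largest distance of any atom from the trimer's C3 axis."""
    coords = trimer.all_coords()
    d = trimer.symmetry_axis.direction
    radial = coords - np.outer(coords @ d, d)
    return float(np.max(np.linalg.norm(radial, axis=1)))


def arm_reach(trimer: TrimerModel) -> float:
    """Extent of an arm along its own radial direction.

    The maximum projection of a chain's atoms onto the chain's mean radial
    direction (perpendicular to the C3 axis); for bar-tipped arms this is
    the stem length, not the bar-end corner distance.
    """
    d = trimer.symmetry_axis.direction
    best = 0.0
    for c in trimer.chains:
        coords = c.coords()
        radial = coords - np.outer(coords @ d, d)
        mean = radial.mean(axis=0)
        u = mean / np.linalg.norm(mean)
        best = max(best, float(np.max(radial @ u)))
    return best


def recommended_lattice_constant(trimer: TrimerModel, gap: float = 4.0) -> float:
    """Site spacing that leaves facing arm tips of adjacent trimers ``gap``
    apart (head-on, bar-to-bar for bar-tipped arms)."""
    return 2.0 * arm_reach(trimer) + gap


_PATTERN_LABELS = {
    "AAA": ("A1", "A2", "A3"),
    "AAB": ("A1", "A2", "B1"),
    "ABB": ("A1", "B1", "B2"),
    "BBB": ("B1", "B2", "B3"),
    "CCC": ("C1", "C2", "C3"),
}


def relabel(trimer: TrimerModel, pattern: str) -> TrimerModel:
    """Reassign subunit-type labels (coordinates untouched).

    For AAB/ABB the mapping of physical chain to letter is positional here;
    geometric context fixes it at placement time (assemble_cage,
    extract_pentasymmetron).
    """
    if pattern == "ABC":
        raise ValueError(
            "ABC heterotrimers are not supported: co-expression of three "
            "variants yields AAB/ABB off-target trimers instead of the "
            "intended ABC species, so the design path uses AAB and ABB "
            "heterotrimers plus BBB/CCC homotrimers"
        )
    if pattern not in _PATTERN_LABELS:
        raise ValueError(f"unknown trimer pattern {pattern!r}")
    labels = _PATTERN_LABELS[pattern]
    chains = [c.relabeled(l) for c, l in zip(trimer.chains, labels)]
    return TrimerModel(
        chains=chains,
        metadata=dict(trimer.metadata),
        symmetry_axis=trimer.symmetry_axis,
        pattern=pattern,
    )


# ---------------------------------------------------------------------------
# T = 1 parent and sub-assemblies
# ---------------------------------------------------------------------------

def build_t1_parent(
    trimer: TrimerModel,
    radius: float | None = None,
    azimuth: float = 0.0,
    gap: float = 4.0,
    group: symcore.SymmetryGroup | None = None,
) -> StructureModel:
    """Place 20 copies of a C3 trimer on the icosahedral three-fold axes.

    The seed trimer is oriented with its C3 axis on the first three-fold
    pole, arm 0 rotated toward an adjacent three-fold pole (plus
    ``azimuth`` degrees), translated to ``radius``, and replicated by the
    icosahedral group.  When ``radius`` is omitted it is solved so the
    nearest inter-trimer heavy-atom distance equals ``gap``.
    """
    if trimer.c3_backbone_rmsd() > 0.5:
        raise ValueError("trimer backbone is not C3-symmetric within 0.5 A")
    group = group or symcore.icosahedral_rotations()
    poles = symcore.directed_poles(group, 3)
    a0 = poles[np.argmax(poles[:, 2])]  # a deterministic seed pole
    # adjacent three-fold pole: smallest positive angular distance
    dots = poles @ a0
    dots[np.argmax(dots)] = -2
    a1 = poles[np.argmax(dots)]
    frame = symcore.frame_from_z_x(a0, a1 - a0)
    frame = frame @ symcore.rotation_matrix_about([0, 0, 1], azimuth)

    local = trimer.all_coords()

    def min_intertrimer(r: float) -> float:
        c0 = local @ frame.T + r * a0
        # nearest neighbouring placement: map a0 -> a1 by the canonical op
        op = _op_mapping(group, a0, a1)
        c1 = c0 @ op.matrix.T
        return float(cKDTree(c0).query(c1)[0].min())

    if radius is None:
        lo = arm_tip_radius(trimer) * 0.8
        hi = arm_tip_radius(trimer) * 8.0
        radius = float(brentq(lambda r: min_intertrimer(r) - gap, lo, hi, xtol=1e-6))

    seed_chains = [
        c.transformed(frame, radius * a0).relabeled(c.label) for c in trimer.chains
    ]

    chains: list[Chain] = []
    used = set()
    for op in group.operators:
        pole = op.matrix @ a0
        key = tuple(np.round(pole, 6))
        if key in used:
            continue
        used.add(key)
        ti = len(used) - 1
        for c in seed_chains:
            chains.append(
                c.transformed(op.matrix, np.zeros(3)).relabeled(f"t{ti:02d}{c.label}")
            )
    model = StructureModel(
        chains,
        {
            "kind": "t1_parent",
            "radius": radius,
            "azimuth": azimuth,
            "n_trimers": len(used),
        },
    )
    if clash_count(model, 2.0) > 0:
        model.metadata["clash_warning"] = True
    return model


def _op_mapping(group: symcore.SymmetryGroup, src: np.ndarray, dst: np.ndarray):
    for op in group.operators:
        if np.max(np.abs(op.matrix @ src - dst)) < 1e-6:
            return op
    raise ValueError("no group operator maps the requested poles")


def _t1_trimers(t1: StructureModel) -> dict[str, list[Chain]]:
    groups: dict[str, list[Chain]] = {}
    for c in t1.chains:
        groups.setdefault(c.label[:3], []).append(c)
    return groups


def nearest_intertrimer_distance(t1: StructureModel) -> float:
    """Minimum heavy-atom distance between chains of different trimers."""
    groups = _t1_trimers(t1)
    keys = sorted(groups)
    coords = {k: np.vstack([c.heavy_coords() for c in groups[k]]) for k in keys}
    trees = {k: cKDTree(coords[k]) for k in keys}
    best = np.inf
    for i, ki in enumerate(keys):
        for kj in keys[i + 1:]:
            best = min(best, float(trees[ki].query(coords[kj])[0].min()))
    return best


def extract_pentasymmetron(t1: StructureModel, vertex: Axis) -> Pentasymmetron:
    """The 5 trimers around a five-fold vertex of the T = 1 parent,
    relabelled AAB: the two chains holding the vertex-adjacent inter-trimer
    (A:A) contacts become A, the outward-facing chain becomes B."""
    if vertex.order != 5:
        raise ValueError("vertex must be a five-fold axis")
    groups = _t1_trimers(t1)
    centers = {k: np.mean([c.centroid() for c in v], axis=0) for k, v in groups.items()}
    v = vertex.direction
    ang = sorted(
        (float(np.arccos(np.clip(np.dot(c / np.linalg.norm(c), v), -1, 1))), k)
        for k, c in centers.items()
    )
    if abs(ang[4][0] - ang[5][0]) < 1e-6:
        raise ValueError("ambiguous nearest-trimer selection at the vertex")
    chosen = [k for _, k in ang[:5]]
    sel_coords = {
        k: [c.heavy_coords() for c in groups[k]] for k in chosen
    }
    trimers = []
    for ti, k in enumerate(sorted(chosen)):
        # per chain: min heavy distance to any chain of the other 4 trimers
        dmins = []
        others = np.vstack(
            [np.vstack(sel_coords[o]) for o in chosen if o != k]
        )
        tree = cKDTree(others)
        for c, hc in zip(groups[k], sel_coords[k]):
            dmins.append((float(tree.query(hc)[0].min()), c.label, c))
        dmins.sort()
        a_chains = [d[2] for d in dmins[:2]]
        b_chain = dmins[2][2]
        chains = [
            a_chains[0].relabeled(f"p{ti}A1"),
            a_chains[1].relabeled(f"p{ti}A2"),
            b_chain.relabeled(f"p{ti}B1"),
        ]
        trimers.append(
            TrimerModel(
                chains=chains,
                metadata={"parent_trimer": k},
                symmetry_axis=Axis(
                    centers[k] / np.linalg.norm(centers[k]), 3
                ),
                pattern="AAB",
            )
        )
    return Pentasymmetron(trimers=trimers, five_fold_axis=vertex)


def build_disymmetron(t1: StructureModel, edge: Axis) -> Disymmetron:
    """The two trimers straddling a two-fold edge of the T = 1 parent,
    relabelled ABB with the A chains at the shared contact."""
    if edge.order != 2:
        raise ValueError("edge must be a two-fold axis")
    groups = _t1_trimers(t1)
    centers = {k: np.mean([c.centroid() for c in v], axis=0) for k, v in groups.items()}
    # the two-fold axis pierces two antipodal edges; use the canonical (+)
    # pole so exactly the two faces flanking that edge are selected
    e = edge.direction
    ang = sorted(
        (float(np.arccos(np.clip(np.dot(c / np.linalg.norm(c), e), -1, 1))), k)
        for k, c in centers.items()
    )
    if abs(ang[1][0] - ang[2][0]) < 1e-6:
        raise ValueError("ambiguous nearest-trimer selection at the edge")
    chosen = [k for _, k in ang[:2]]
    coords = {k: [c.heavy_coords() for c in groups[k]] for k in chosen}
    trimers = []
    for ti, k in enumerate(sorted(chosen)):
        other = chosen[1] if k == chosen[0] else chosen[0]
        tree = cKDTree(np.vstack(coords[other]))
        dmins = sorted(
            (float(tree.query(hc)[0].min()), c.label, c)
            for c, hc in zip(groups[k], coords[k])
        )
        a_chain = dmins[0][2]
        b_chains = [d[2] for d in dmins[1:]]
        chains = [
            a_chain.relabeled(f"d{ti}A1"),
            b_chains[0].relabeled(f"d{ti}B1"),
            b_chains[1].relabeled(f"d{ti}B2"),
        ]
        trimers.append(
            TrimerModel(
                chains=chains,
                metadata={"parent_trimer": k},
                symmetry_axis=Axis(centers[k] / np.linalg.norm(centers[k]), 3),
                pattern="ABB",
            )
        )
    return Disymmetron(trimers=trimers, two_fold_axis=edge)


# ---------------------------------------------------------------------------
# full-cage assembly
# ---------------------------------------------------------------------------

def assemble_cage(
    layout: CageLayout,
    components: TrimerModel | dict[str, TrimerModel],
) -> StructureModel:
    """One trimer copy per layout site, oriented by the site frame.

    ``components`` maps trimer type (AAB/ABB/BBB/CCC/AAA) to an atomic C3
    trimer; a single trimer may be passed to use the same backbone
    everywhere (the pseudosymmetric case).  Chain k of the component is
    placed facing neighbour slot k and takes the layout's chain label.
    """
    chains: list[Chain] = []
    for s in layout.sites:
        if isinstance(components, dict):
            if s.trimer_type not in components:
                raise KeyError(
                    f"no component provided for trimer type {s.trimer_type} "
                    f"(site {s.site_id})"
                )
            comp = components[s.trimer_type]
        else:
            comp = components
        for k in range(3):
            chains.append(
                comp.chains[k]
                .transformed(s.orientation, s.center)
                .relabeled(s.chain_labels[k])
            )
    return StructureModel(
        chains,
        {
            "kind": "cage",
            "h": layout.h,
            "lattice_constant": layout.lattice_constant,
        },
    )


def asymmetric_unit(
    model: StructureModel, group: symcore.SymmetryGroup | None = None
) -> StructureModel:
    """Canonical asymmetric unit: one chain per orbit of the 60 rotations.

    The representative of each orbit is the chain whose (rounded) centroid
    is lexicographically smallest among its 60 symmetry images.
    """
    group = group or symcore.icosahedral_rotations()
    mats = group.matrices()
    centroids = np.stack([c.centroid() for c in model.chains])
    tree = cKDTree(centroids)
    scale = max(1.0, float(np.max(np.abs(centroids))))
    tol = 1e-5 * scale
    assigned = np.full(len(model.chains), -1)
    reps = []
    for ci in range(len(model.chains)):
        if assigned[ci] >= 0:
            continue
        images = mats @ centroids[ci]
        members = set()
        for img in images:
            d, j = tree.query(img)
            if d > tol:
                raise ValueError(
                    "model is not invariant under the icosahedral group; "
                    "cannot extract an asymmetric unit"
                )
            members.add(int(j))
        orbit = len(reps)
        for j in members:
            assigned[j] = orbit
        rep = min(members, key=lambda j: tuple(np.round(centroids[j], 6)))
        reps.append(rep)
    reps.sort()
    return StructureModel(
        [model.chains[i] for i in reps],
        {**model.metadata, "kind": "asu", "n_orbits": len(reps)},
    )


def clash_count(model: StructureModel, threshold: float = CLASH_DISTANCE) -> int:
    """Number of heavy-atom pairs closer than ``threshold`` between
    different chains."""
    coords = []
    owner = []
    for i, c in enumerate(model.chains):
        hc = c.heavy_coords()
        coords.append(hc)
        owner.extend([i] * len(hc))
    xyz = np.vstack(coords)
    owner = np.array(owner)
    pairs = cKDTree(xyz).query_pairs(threshold, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    return int(np.sum(owner[pairs[:, 0]] != owner[pairs[:, 1]]))
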