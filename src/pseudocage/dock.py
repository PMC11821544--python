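"""Rigid-body symmetric docking of a pentasymmetron against a C3 trimer.

The T = 4 cage has two independent components: the pentasymmetron rides a
five-fold axis and the CCC homotrimer a three-fold axis, so the dock has
four degrees of freedom — a translation along and a rotation about each
component's own symmetry axis.  Configurations are scored with a coarse
contact/clash count (this package's stand-in for a molecular-mechanics
docking score): number of cross-component residue pairs with Cbeta atoms
within ``d_contact``, minus ``w_clash`` times the number of heavy-atom
pairs closer than ``d_clash``.

The scan is an exhaustive deterministic grid search; ties are broken by
lexicographic DOF order so repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial import cKDTree

from . import symcore
from .blocks import Chain, Pentasymmetron, StructureModel, TrimerModel

D_CONTACT = 8.0  # Cbeta-Cbeta contact distance, Angstrom
D_CLASH = 2.4  # heavy-atom clash distance, Angstrom
W_CLASH = 10.0  # clash weight in the composite score


@dataclass(frozen=True)
class DockDOF:
    """(r_penta, phi_penta, r_tri, phi_tri): Angstrom / degrees.

    Angles are reduced modulo each component's internal symmetry (C5 for
    the pentasymmetron, C3 for the trimer).
    """

    r_penta: float
    phi_penta: float
    r_tri: float
    phi_tri: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi_penta", float(self.phi_penta) % 72.0)
        object.__setattr__(self, "phi_tri", float(self.phi_tri) % 120.0)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.r_penta, self.phi_penta, self.r_tri, self.phi_tri)


@dataclass(frozen=True)
class DockScore:
    n_contacts: int
    n_clashes: int
    w_clash: float = W_CLASH

    @property
    def composite(self) -> float:
        return self.n_contacts - self.w_clash * self.n_clashes


@dataclass
class DockedConfig:
    dof: DockDOF
    score: DockScore
    # chains of each component touching the other, with contact counts
    interface_partition: dict = field(default_factory=dict)


@dataclass
class PreparedComponent:
    """A component centred at the origin with its symmetry axis along +z.

    Stores flat arrays so grid configurations are cheap rigid transforms;
    ``chains`` holds the full atomic chains in the same prepared frame.
    """

    heavy: np.ndarray  # (H, 3)
    cb: np.ndarray  # (R, 3) one point per residue (Cbeta, Calpha fallback)
    cb_chain: np.ndarray  # (R,) chain label per residue point
    order: int  # internal cyclic symmetry (5 or 3)
    chains: list[Chain] = field(default_factory=list)
    b_chains: frozenset[str] = frozenset()

    def placed(self, axis: np.ndarray, r: float, phi: float) -> tuple[np.ndarray, np.ndarray]:
        """(heavy, cb) coords at translation r along and rotation phi about
        ``axis`` (the component's +z is mapped onto ``axis``)."""
        rot = _axis_frame(axis) @ symcore.rotation_matrix_about([0, 0, 1], phi)
        t = r * np.asarray(axis, float)
        return self.heavy @ rot.T + t, self.cb @ rot.T + t


def _axis_frame(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    if abs(axis[2]) > 0.999999:
        hint = np.array([1.0, 0.0, 0.0])
    else:
        hint = np.array([0.0, 0.0, 1.0])
    return symcore.frame_from_z_x(axis, hint)


def _residue_points(chains: list[Chain]) -> tuple[np.ndarray, np.ndarray]:
    pts, owner = [], []
    for c in chains:
        by_res: dict[int, dict[str, np.ndarray]] = {}
        for a in c.atoms:
            by_res.setdefault(a.residue_index, {})[a.atom_name] = a.coords
        for ri in sorted(by_res):
            d = by_res[ri]
            pts.append(d.get("CB", d.get("CA", next(iter(d.values())))))
            owner.append(c.label)
    return np.array(pts), np.array(owner)


def prepare_component(
    chains: list[Chain],
    axis: np.ndarray,
    order: int,
    b_chains: frozenset[str] | None = None,
) -> PreparedComponent:
    """Centre a component and align its symmetry axis to +z.

    The centroid is translated to the origin; its projection along the axis
    defines the component's own r = 0 reference.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    rot = _axis_frame(axis).T  # world axis -> +z
    heavy = np.vstack([c.heavy_coords() for c in chains])
    centroid = heavy.mean(axis=0)
    prep_chains = [c.transformed(rot, -rot @ centroid) for c in chains]
    heavy = np.vstack([c.heavy_coords() for c in prep_chains])
    cb, owner = _residue_points(prep_chains)
    if b_chains is None:
        b_chains = frozenset(c.label for c in chains if "B" in c.label[-2:])
    return PreparedComponent(heavy=heavy, cb=cb, cb_chain=owner, order=order,
                             chains=prep_chains, b_chains=frozenset(b_chains))


def prepare_pentasymmetron(penta: Pentasymmetron) -> PreparedComponent:
    return prepare_component(penta.chains, penta.five_fold_axis.direction, 5)


def prepare_trimer(trimer: TrimerModel) -> PreparedComponent:
    return prepare_component(trimer.chains, trimer.symmetry_axis.direction, 3)


def default_axis_pair() -> tuple[np.ndarray, np.ndarray]:
    """A five-fold axis and an adjacent three-fold axis of the icosahedral
    frame (the T = 4 dock geometry)."""
    g = symcore.icosahedral_rotations()
    p5 = symcore.directed_poles(g, 5)
    v = p5[np.argmax(p5[:, 2])]
    p3 = symcore.directed_poles(g, 3)
    f = p3[np.argmax(p3 @ v)]
    return v, f


def count_contacts_clashes(
    cb_a: np.ndarray,
    cb_b: np.ndarray,
    heavy_a: np.ndarray,
    heavy_b: np.ndarray,
    d_contact: float = D_CONTACT,
    d_clash: float = D_CLASH,
) -> tuple[int, int, list[list[int]]]:
    """Exact cross-component pair counts: residue-centre pairs within
    ``d_contact`` and heavy-atom pairs within ``d_clash``.  Returns
    (n_contacts, n_clashes, per-residue contact match lists)."""
    contact_pairs = cKDTree(cb_a).query_ball_tree(cKDTree(cb_b), d_contact)
    n_contacts = sum(len(m) for m in contact_pairs)
    clash_pairs = cKDTree(heavy_a).query_ball_tree(cKDTree(heavy_b), d_clash)
    n_clashes = sum(len(m) for m in clash_pairs)
    return n_contacts, n_clashes, contact_pairs


def score_dock(
    penta: PreparedComponent,
    trimer: PreparedComponent,
    dof: DockDOF,
    axes: tuple[np.ndarray, np.ndarray] | None = None,
    d_contact: float = D_CONTACT,
    d_clash: float = D_CLASH,
    w_clash: float = W_CLASH,
) -> DockedConfig:
    """Score one configuration; pair search is exact (KD-tree, verified
    against brute force in the test suite)."""
    v, f = axes if axes is not None else default_axis_pair()
    ph, pcb = penta.placed(v, dof.r_penta, dof.phi_penta)
    th, tcb = trimer.placed(f, dof.r_tri, dof.phi_tri)

    n_contacts, n_clashes, contact_pairs = count_contacts_clashes(
        pcb, tcb, ph, th, d_contact, d_clash
    )

    penta_counts: dict[str, int] = {}
    trimer_counts: dict[str, int] = {}
    n_b = 0
    for i, matches in enumerate(contact_pairs):
        if not matches:
            continue
        pc = penta.cb_chain[i]
        penta_counts[pc] = penta_counts.get(pc, 0) + len(matches)
        if pc in penta.b_chains:
            n_b += len(matches)
        for j in matches:
            tc = trimer.cb_chain[j]
            trimer_counts[tc] = trimer_counts.get(tc, 0) + 1
    partition = {
        "penta_chains": penta_counts,
        "trimer_chains": trimer_counts,
        "b_fraction": (n_b / n_contacts) if n_contacts else 0.0,
    }
    return DockedConfig(
        dof=dof,
        score=DockScore(n_contacts, n_clashes, w_clash),
        interface_partition=partition,
    )


def dock_grid(
    penta: PreparedComponent,
    trimer: PreparedComponent,
    grid: dict[str, np.ndarray],
    axes: tuple[np.ndarray, np.ndarray] | None = None,
    **score_kwargs,
) -> list[DockedConfig]:
    """Exhaustive scan over the 4-D DOF grid.

    ``grid`` maps the DOF names (r_penta, phi_penta, r_tri, phi_tri) to
    1-D arrays of values.  Output is sorted by (composite desc, then
    lexicographic DOF) — fully reproducible.
    """
    names = ("r_penta", "phi_penta", "r_tri", "phi_tri")
    missing = [n for n in names if n not in grid or len(np.atleast_1d(grid[n])) == 0]
    if missing:
        raise ValueError(f"empty grid for DOFs: {missing}")
    axes = axes if axes is not None else default_axis_pair()
    configs = []
    for vals in product(*(np.atleast_1d(grid[n]) for n in names)):
        dof = DockDOF(*map(float, vals))
        configs.append(score_dock(penta, trimer, dof, axes=axes, **score_kwargs))
    configs.sort(key=lambda c: (-c.score.composite, c.dof.as_tuple()))
    return configs


def filter_docks(
    configs: list[DockedConfig],
    min_b_fraction: float = 1.0,
    min_composite: float = 1.0,
    max_clashes: int = 0,
) -> list[DockedConfig]:
    """Keep configurations whose cross-component contacts run through the
    unpaired (B) pentasymmetron chains — the screening rule for productive
    docks — and that meet the score/clash thresholds."""
    out = []
    for c in configs:
        if c.score.n_contacts == 0:
            continue
        if c.interface_partition.get("b_fraction", 0.0) < min_b_fraction:
            continue
        if c.score.composite < min_composite or c.score.n_clashes > max_clashes:
            continue
        out.append(c)
    return out


def expand_dock(
    config: DockedConfig,
    penta: PreparedComponent,
    trimer: PreparedComponent,
    axes: tuple[np.ndarray, np.ndarray] | None = None,
    group: symcore.SymmetryGroup | None = None,
    merge_tol: float = 1e-3,
) -> StructureModel:
    """Apply the icosahedral group to the docked two-component configuration.

    Components sit on their symmetry axes, so symmetry-duplicate copies are
    merged (12 pentasymmetron and 20 trimer placements for T = 4; 240
    chains).  A residual mismatch between merged duplicates above
    ``merge_tol`` signals an off-axis placement and raises.
    """
    group = group or symcore.icosahedral_rotations()
    v, f = axes if axes is not None else default_axis_pair()

    chains: list[Chain] = []
    for tag, prep, axis, r, phi in (
        ("v", penta, v, config.dof.r_penta, config.dof.phi_penta),
        ("f", trimer, f, config.dof.r_tri, config.dof.phi_tri),
    ):
        rot = _axis_frame(axis) @ symcore.rotation_matrix_about([0, 0, 1], phi)
        t = r * np.asarray(axis, float)
        placed_heavy = prep.heavy @ rot.T + t
        centroid = placed_heavy.mean(axis=0)
        seen: list[tuple[np.ndarray, np.ndarray]] = []
        copy_idx = 0
        for op in group.operators:
            c_img = op.matrix @ centroid
            dup = None
            for heavy_img, cc in seen:
                if np.linalg.norm(cc - c_img) < max(1.0, 10 * merge_tol):
                    dup = heavy_img
                    break
            img = placed_heavy @ op.matrix.T
            if dup is not None:
                # verify the duplicate is a true symmetry copy (atom sets match)
                resid = float(cKDTree(dup).query(img)[0].max())
                if resid > merge_tol:
                    raise ValueError(
                        f"duplicate-merge residual {resid:.3g} A exceeds "
                        f"{merge_tol}; component is off its symmetry axis"
                    )
                continue
            seen.append((img, c_img))
            for ch in prep.chains:
                chains.append(
                    ch.transformed(op.matrix @ rot, op.matrix @ t).relabeled(
                        f"{tag}{copy_idx:02d}{ch.label}"
                    )
                )
            copy_idx += 1
    return StructureModel(chains, {"kind": "expanded_dock", "dof": config.dof.as_tuple()})
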