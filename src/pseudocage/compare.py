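"""Design-vs-observed comparison: superposition, fixed-frame r.m.s.d. and
rigid-body deviation decomposition.

Two r.m.s.d. conventions are used, mirroring how large cage structures are
analysed: ``rmsd_fixed`` compares models after both have been centred and
axis-aligned but *not* re-superposed per component (the global, fixed
correspondence number), while ``kabsch`` performs a least-squares
superposition first.  Per-component deviations are decomposed into a
rotation angle (trace formula), a translation magnitude and the signed
radial component of the translation (positive = away from the cage
origin); the rotation sign convention, where reported, is clockwise when
viewed from outside the cage looking down the component axis toward the
origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import StructureModel


@dataclass(frozen=True)
class Transform:
    """Proper rotation + translation: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("transform rotation must be proper (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class DeviationReport:
    rotation_angle: float  # degrees, in [0, 180]
    translation: float  # Angstrom
    radial_translation: float  # signed, along the origin direction
    rmsd_fixed: float
    rmsd_superposed: float


def rmsd_fixed(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean square of paired distances; no fitting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"point counts differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[Transform, float]:
    """Least-squares proper superposition of ``moving`` onto ``fixed``.

    Returns the optimal Transform and the post-fit r.m.s.d.  SVD-based with
    the determinant correction, so reflection-related point sets still get
    a proper rotation (at the cost of residual r.m.s.d.).
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("need equal-shaped (N, 3) point sets")
    if len(moving) < 3:
        raise ValueError("need at least 3 points")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) point sets")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = fc - r @ mc
    tr = Transform(r, t)
    return tr, rmsd_fixed(tr.apply(moving), fixed)


def rigid_body_deviation(
    design: np.ndarray,
    observed: np.ndarray,
    radial_direction: np.ndarray | None = None,
) -> DeviationReport:
    """Rigid-body deviation of an observed component from its design.

    Superposes observed onto design (fixed atom correspondence) and reports
    the rotation angle, translation magnitude, and the translation's signed
    projection on ``radial_direction`` (default: the unit vector from the
    origin to the design centroid — positive means away from the origin).
    """
    design = np.asarray(design, float)
    observed = np.asarray(observed, float)
    transform, rmsd_sup = kabsch(design, observed)
    delta = observed.mean(axis=0) - design.mean(axis=0)
    if radial_direction is None:
        c = design.mean(axis=0)
        n = np.linalg.norm(c)
        radial_direction = c / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
    else:
        radial_direction = np.asarray(radial_direction, float)
        radial_direction = radial_direction / np.linalg.norm(radial_direction)
    return DeviationReport(
        rotation_angle=transform.angle_deg,
        translation=float(np.linalg.norm(delta)),
        radial_translation=float(np.dot(delta, radial_direction)),
        rmsd_fixed=rmsd_fixed(design, observed),
        rmsd_superposed=rmsd_sup,
    )


def _ca_map(model: StructureModel, chains: list[str]) -> dict[tuple[str, int], np.ndarray]:
    out = {}
    for label in chains:
        for a in model.get_chain(label).atoms:
            if a.atom_name == "CA":
                out[(label, a.residue_index)] = a.coords
    return out


def harmonized_ca(
    design: StructureModel,
    observed: StructureModel,
    chains: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Calpha coordinate pair with the correspondence harmonized: only
    residues present in both models (per chain label and residue index) are
    kept, in a deterministic order."""
    dmap = _ca_map(design, chains)
    omap = _ca_map(observed, chains)
    common = sorted(set(dmap) & set(omap))
    if not common:
        raise ValueError("no common Calpha atoms between the models")
    return (
        np.array([dmap[k] for k in common]),
        np.array([omap[k] for k in common]),
    )


def compare_cage(
    design: StructureModel,
    observed: StructureModel,
    components: dict[str, list[str]] | None = None,
    chain_map: dict[str, str] | None = None,
) -> tuple[dict[str, DeviationReport], float]:
    """Global axis-aligned Calpha r.m.s.d. plus per-component deviations.

    ``components`` maps a component name to the chain labels (in the design
    model) that form it; by default every chain is its own component.
    ``chain_map`` renames observed chains onto design labels first.  Both
    models are assumed already centred with their symmetry axes aligned
    (the fixed-frame convention); no global re-superposition is applied.
    """
    if chain_map:
        observed = StructureModel(
            [c.relabeled(chain_map.get(c.label, c.label)) for c in observed.chains],
            dict(observed.metadata),
        )
    d_labels = {c.label for c in design.chains}
    o_labels = {c.label for c in observed.chains}
    unmapped = sorted(d_labels ^ o_labels)
    if unmapped:
        raise ValueError(f"chains not present in both models: {unmapped}")
    if components is None:
        components = {label: [label] for label in sorted(d_labels)}

    all_d, all_o = harmonized_ca(design, observed, sorted(d_labels))
    global_rmsd = rmsd_fixed(all_d, all_o)

    reports = {}
    for name, chains in components.items():
        d, o = harmonized_ca(design, observed, chains)
        reports[name] = rigid_body_deviation(d, o)
    return reports, global_rmsd
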