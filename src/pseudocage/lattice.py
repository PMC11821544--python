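"""Generative geometry for class-I Goldberg icosahedral cages (T = h^2).

The cages are wireframe assemblies of C3 trimers.  Trimer sites are the
vertices of the Goldberg polyhedron GP(h, 0): each icosahedral face is
subdivided into h^2 small triangles and one trimer sits at the centroid of
each, so a cage has 20*h^2 trimers and 60*h^2 chains.  Each chain (subunit)
pairs with exactly one chain of a neighbouring trimer across a Goldberg edge,
giving 30*h^2 two-chain inter-trimer interfaces.  The polyhedron's faces are
the pores: always 12 pentagonal (around the icosahedral vertices) plus
10*(T - 1) hexagonal.

Site classes follow from the subdivision combinatorics:

* the 3 corner triangles of every face ring the icosahedral vertices ->
  pentasymmetron sites (AAB heterotrimers; 5 per vertex, 60 total);
* edge-interior triangles with a full side on an icosahedral edge pair up
  across that edge -> disymmetron sites (ABB; 60*(h - 2) total);
* remaining "upward" facet triangles -> BBB homotrimers (10*(h-2)*(h-3));
* "downward" (inverted) facet triangles -> CCC homotrimers (10*h*(h-1)).

Inter-trimer edges that cross an icosahedral edge carry the inherited
two-fold A:A interface (60 + 30*(h - 2) of them); all intra-face edges join
the two orientation sublattices of the honeycomb and carry the designed B:C
interface (30*h*(h - 1)).  The two-colouring by triangle orientation is the
facet colouring rule: pentasymmetron and disymmetron sites always lie on the
"upward" (B-carrying) sublattice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import symcore

_VKEY_DECIMALS = 6


@dataclass(frozen=True)
class Stoichiometry:
    """Component counts for the T = h^2 cage."""

    h: int
    T: int
    n_AAB: int
    n_ABB: int
    n_CCC: int
    n_BBB: int
    n_pentasymmetron: int
    n_disymmetron: int
    n_chains_A: int
    n_chains_B: int
    n_chains_C: int

    @property
    def total_trimers(self) -> int:
        return self.n_AAB + self.n_ABB + self.n_CCC + self.n_BBB

    @property
    def total_chains(self) -> int:
        return self.n_chains_A + self.n_chains_B + self.n_chains_C


@dataclass
class TrimerSite:
    """One trimer position on the Goldberg lattice.

    ``chain_letters[k]`` is the subunit type presented toward neighbour slot
    k; ``chain_labels[k]`` the unique chain label used in assembled models.
    Slots are ordered counterclockwise (seen from outside) starting from the
    site's reference azimuth.
    """

    index: int
    site_id: str
    face_index: int
    tri: tuple[int, int, int]
    up: bool  # True for "upward" triangles (B sublattice)
    center: np.ndarray
    orientation: np.ndarray  # columns (x', y', z'); z' = face normal
    site_class: str  # pentasymmetron | disymmetron | facet_B | facet_C
    trimer_type: str  # AAB | ABB | BBB | CCC | AAA (h = 1 stub)
    chain_letters: tuple[str, str, str]
    chain_labels: tuple[str, str, str]
    vertex_keys: tuple[tuple, tuple, tuple]
    parent_feature: str


@dataclass
class CageLayout:
    """Trimer sites + chain-pairing edge graph for one h."""

    h: int
    lattice_constant: float
    sites: list[TrimerSite]
    # ((site_index, slot), (site_index, slot), edge_type) with edge_type in
    # {"AA", "BC"}; every chain appears in exactly one edge
    interface_edges: list[tuple[tuple[int, int], tuple[int, int], str]]

    @property
    def n_chains(self) -> int:
        return 3 * len(self.sites)

    def centers(self) -> np.ndarray:
        return np.stack([s.center for s in self.sites])


def t_number(h: int) -> int:
    """Triangulation number of the class-I (k = 0) Goldberg lattice: T = h^2."""
    if h < 1:
        raise ValueError("h must be a positive integer")
    return h * h


def stoichiometry(h: int) -> Stoichiometry:
    """Closed-form component counts for the T = h^2 cage (h >= 2)."""
    if h < 2:
        raise ValueError(
            "h must be >= 2; the T = 1 cage is a single-component assembly "
            "(no pseudosymmetric components) and is not generated here"
        )
    T = t_number(h)
    n_dis = 30 * (h - 2)
    s = Stoichiometry(
        h=h,
        T=T,
        n_AAB=60,
        n_ABB=2 * n_dis,
        n_CCC=10 * h * (h - 1),
        n_BBB=10 * (h - 2) * (h - 3),
        n_pentasymmetron=12,
        n_disymmetron=n_dis,
        n_chains_A=60 * T - 2 * (30 * h * (h - 1)),
        n_chains_B=30 * h * (h - 1),
        n_chains_C=30 * h * (h - 1),
    )
    assert s.total_trimers == 20 * T and s.total_chains == 60 * T
    return s


def mixture_ratio(h: int) -> tuple[int, int, int, int]:
    """Per-trimer molar ratio AAB : ABB : CCC : BBB, in smallest integers."""
    s = stoichiometry(h)
    counts = [s.n_AAB, s.n_ABB, s.n_CCC, s.n_BBB]
    g = 0
    for c in counts:
        g = math.gcd(g, c)
    return tuple(c // g for c in counts)


def predict_diameter(h: int, calibration: tuple[int, float] = (2, 49.0)) -> float:
    """Predicted outer diameter (nm), linear in h at fixed lattice constant."""
    if h < 2:
        raise ValueError("h must be >= 2")
    h0, d0 = calibration
    if d0 <= 0:
        raise ValueError("calibration diameter must be positive")
    return d0 * h / h0


@lru_cache(maxsize=1)
def _icosahedron_faces() -> tuple[np.ndarray, tuple[tuple[int, int, int], ...]]:
    """Unit-circumradius vertices and outward-oriented faces, canonical order."""
    v = symcore.icosahedron_vertices()
    edge = np.min(
        [np.linalg.norm(v[i] - v[j]) for i in range(12) for j in range(i + 1, 12)]
    )
    faces = []
    for i in range(12):
        for j in range(i + 1, 12):
            if abs(np.linalg.norm(v[i] - v[j]) - edge) > 1e-6:
                continue
            for k in range(j + 1, 12):
                if (
                    abs(np.linalg.norm(v[i] - v[k]) - edge) < 1e-6
                    and abs(np.linalg.norm(v[j] - v[k]) - edge) < 1e-6
                ):
                    f = [i, j, k]
                    # orient counterclockwise seen from outside
                    if np.dot(np.cross(v[j] - v[i], v[k] - v[i]), v[i]) < 0:
                        f = [i, k, j]
                    faces.append(tuple(f))
    faces.sort()
    assert len(faces) == 20
    return v, tuple(faces)


def _vkey(p: np.ndarray) -> tuple:
    return tuple(np.round(p, _VKEY_DECIMALS) + 0.0)


def layout(h: int, lattice_constant: float = 50.0, spherical: bool = False) -> CageLayout:
    """Enumerate, classify and wire the trimer sites of the T = h^2 cage.

    Sites are placed on flat icosahedral facets (matching the picture of 20
    folded triangular hexagonal lattices); ``spherical=True`` instead projects
    site centers to the circumsphere.  ``lattice_constant`` is the
    center-to-center spacing of adjacent trimers within a facet, in Angstrom.
    """
    if h < 1:
        raise ValueError("h must be a positive integer")
    if lattice_constant <= 0:
        raise ValueError("lattice_constant must be positive")

    verts, faces = _icosahedron_faces()
    edge_unit = np.linalg.norm(verts[faces[0][0]] - verts[faces[0][1]])
    # intra-face centroid spacing of adjacent small triangles = s / sqrt(3)
    # with small-triangle side s = edge / h
    scale = lattice_constant * math.sqrt(3.0) * h / edge_unit

    sites: list[TrimerSite] = []
    site_of_vkeys: dict[frozenset, list[int]] = {}

    for fi, (a, b, c) in enumerate(faces):
        va, vb, vc = verts[a], verts[b], verts[c]
        normal = np.cross(vb - va, vc - va)
        normal = normal / np.linalg.norm(normal)

        def point(i: int, j: int, k: int) -> np.ndarray:
            return (i * va + j * vb + k * vc) / h

        tris: list[tuple[tuple[int, int, int], bool, list[np.ndarray]]] = []
        for i in range(h):
            for j in range(h - i):
                k = h - 1 - i - j
                tris.append(
                    ((i, j, k), True, [point(i + 1, j, k), point(i, j + 1, k), point(i, j, k + 1)])
                )
        for i in range(1, h + 1):
            for j in range(1, h + 1 - i):
                k = h + 1 - i - j
                if k < 1:
                    continue
                tris.append(
                    ((i, j, k), False, [point(i - 1, j, k), point(i, j - 1, k), point(i, j, k - 1)])
                )

        for tri, up, pts in tris:
            zeros = sum(1 for x in tri if x == 0)
            if not up:
                site_class, ttype = "facet_C", "CCC"
            elif h == 1:
                site_class, ttype = "pentasymmetron", "AAA"
            elif zeros == 2:
                site_class, ttype = "pentasymmetron", "AAB"
            elif zeros == 1:
                site_class, ttype = "disymmetron", "ABB"
            else:
                site_class, ttype = "facet_B", "BBB"
            center = np.mean(pts, axis=0)
            vkeys = tuple(_vkey(p) for p in pts)
            idx = len(sites)
            sites.append(
                TrimerSite(
                    index=idx,
                    site_id=f"f{fi:02d}_{tri[0]}_{tri[1]}_{tri[2]}{'u' if up else 'd'}",
                    face_index=fi,
                    tri=tri,
                    up=up,
                    center=center,  # unit-scale for now; rescaled below
                    orientation=np.eye(3),  # filled in after wiring
                    site_class=site_class,
                    trimer_type=ttype,
                    chain_letters=("?", "?", "?"),
                    chain_labels=("", "", ""),
                    vertex_keys=vkeys,
                    parent_feature=_parent_feature(fi, tri, up, zeros, h),
                )
            )
            for m in range(3):
                ek = frozenset((vkeys[m], vkeys[(m + 1) % 3]))
                site_of_vkeys.setdefault(ek, []).append(idx)

    # --- edge graph -------------------------------------------------------
    raw_edges: list[tuple[int, int, str]] = []
    for ek, owners in site_of_vkeys.items():
        if len(owners) != 2:
            raise RuntimeError("malformed subdivision: edge not shared by 2 sites")
        i, j = sorted(owners)
        etype = "AA" if sites[i].face_index != sites[j].face_index else "BC"
        raw_edges.append((i, j, etype))
    assert len(raw_edges) == 30 * h * h

    # per-site neighbour list (slot order fixed below by azimuth)
    neighbor_info: list[list[tuple[int, str, frozenset]]] = [[] for _ in sites]
    for i, j, etype in raw_edges:
        ek = frozenset(set(sites[i].vertex_keys) & set(sites[j].vertex_keys))
        neighbor_info[i].append((j, etype, ek))
        neighbor_info[j].append((i, etype, ek))

    slot_of: dict[tuple[int, frozenset], int] = {}
    verts_u, faces_u = verts, faces
    for s_idx, s in enumerate(sites):
        normal = np.cross(
            verts_u[faces_u[s.face_index][1]] - verts_u[faces_u[s.face_index][0]],
            verts_u[faces_u[s.face_index][2]] - verts_u[faces_u[s.face_index][0]],
        )
        normal = normal / np.linalg.norm(normal)
        ref = verts_u[faces_u[s.face_index][0]] - s.center
        ref = ref - np.dot(ref, normal) * normal
        ref = ref / np.linalg.norm(ref)
        entries = []
        for o_idx, etype, ek in neighbor_info[s_idx]:
            shared = sorted(ek)
            mid = (np.array(shared[0]) + np.array(shared[1])) / 2.0
            d = mid - s.center
            d = d - np.dot(d, normal) * normal
            theta = math.atan2(
                float(np.dot(np.cross(ref, d), normal)), float(np.dot(ref, d))
            ) % (2 * math.pi)
            entries.append((theta, o_idx, etype, ek))
        entries.sort(key=lambda e: e[0])
        if len(entries) != 3:
            raise RuntimeError("site does not have exactly 3 neighbours")
        # align local arm k (at 120k deg) with slot k: mean angular offset
        offs = [e[0] - 2 * math.pi * k / 3 for k, e in enumerate(entries)]
        alpha = math.atan2(
            sum(math.sin(o) for o in offs) / 3, sum(math.cos(o) for o in offs) / 3
        )
        xprime = symcore.rotation_matrix_about(normal, math.degrees(alpha)) @ ref
        s.orientation = symcore.frame_from_z_x(normal, xprime)
        letters = []
        for k, (theta, o_idx, etype, ek) in enumerate(entries):
            slot_of[(s_idx, ek)] = k
            if etype == "AA":
                letters.append("A")
            else:
                letters.append("B" if s.up else "C")
        s.chain_letters = tuple(letters)
        s.chain_labels = tuple(
            f"s{s_idx:04d}{letters[k]}{k}" for k in range(3)
        )
        expected = {"AAA": "AAA", "AAB": "AAB", "ABB": "ABB", "BBB": "BBB", "CCC": "CCC"}[
            s.trimer_type
        ]
        if "".join(sorted(letters)) != "".join(sorted(expected)):
            raise RuntimeError(
                f"site {s.site_id}: slot letters {letters} conflict with "
                f"trimer type {s.trimer_type}"
            )

    interface_edges = []
    for i, j, etype in raw_edges:
        ek = frozenset(set(sites[i].vertex_keys) & set(sites[j].vertex_keys))
        interface_edges.append(((i, slot_of[(i, ek)]), (j, slot_of[(j, ek)]), etype))
    interface_edges.sort()

    # --- final coordinates ------------------------------------------------
    for s in sites:
        if spherical:
            c = s.center / np.linalg.norm(s.center)
            s.center = c * scale  # project to the circumsphere
            s.orientation = symcore.frame_from_z_x(c, s.orientation[:, 0])
        else:
            s.center = s.center * scale

    return CageLayout(
        h=h, lattice_constant=lattice_constant, sites=sites, interface_edges=interface_edges
    )


def _parent_feature(fi: int, tri: tuple[int, int, int], up: bool, zeros: int, h: int) -> str:
    if not up:
        return f"face:{fi}"
    if h == 1 or zeros == 2:
        corner = int(np.argmax(tri)) if h > 1 else 0
        return f"vertex:f{fi}c{corner}"
    if zeros == 1:
        edge = int(np.argmin(tri))
        return f"edge:f{fi}e{edge}"
    return f"face:{fi}"


def pore_census(layout_: CageLayout) -> tuple[int, int]:
    """Count (pentagonal, hexagonal) pores by trimer incidence at each
    honeycomb vertex of the Goldberg polyhedron."""
    degree: dict[tuple, int] = {}
    for s in layout_.sites:
        for k in s.vertex_keys:
            degree[k] = degree.get(k, 0) + 1
    n5 = sum(1 for d in degree.values() if d == 5)
    n6 = sum(1 for d in degree.values() if d == 6)
    if n5 + n6 != len(degree):
        bad = {d for d in degree.values() if d not in (5, 6)}
        raise ValueError(f"malformed pore graph: vertex degrees {bad}")
    return n5, n6


def infer_h(obj) -> int:
    """Recover h from a layout (or an assembled model) by two independent
    routes and cross-check them.

    For a layout: the number of pore-to-pore steps between the two nearest
    pentagonal pores (graph distance on the pore lattice) vs. the trimer
    count (20*h^2 sites).  For an assembled model: chain count (60*h^2) vs.
    the number of distinct trimer sites encoded in the chain labels.
    """
    if isinstance(obj, CageLayout):
        h_steps = _pentagon_graph_distance(obj)
        h_count = round(math.sqrt(len(obj.sites) / 20.0))
        if h_steps != h_count:
            raise ValueError(
                f"inconsistent h estimates: pore steps give {h_steps}, "
                f"site count gives {h_count}"
            )
        return h_steps
    # assembled StructureModel (avoid importing blocks at module load)
    chains = getattr(obj, "chains", None)
    if chains is None:
        raise TypeError("expected a CageLayout or an assembled StructureModel")
    n = len(chains)
    h_chains = round(math.sqrt(n / 60.0))
    # chain labels from assemble_cage are "s<4-digit site index><letter><slot>"
    prefixes = {ch.label[:5] for ch in chains}
    h_sites = round(math.sqrt(len(prefixes) / 20.0))
    if h_chains != h_sites:
        raise ValueError(
            f"inconsistent h estimates: chain count gives {h_chains}, "
            f"trimer-site count gives {h_sites}"
        )
    return h_chains


def _pentagon_graph_distance(layout_: CageLayout) -> int:
    from collections import deque

    adj: dict[tuple, set] = {}
    degree: dict[tuple, int] = {}
    for s in layout_.sites:
        ks = s.vertex_keys
        for a in range(3):
            degree[ks[a]] = degree.get(ks[a], 0) + 1
            adj.setdefault(ks[a], set()).add(ks[(a + 1) % 3])
            adj.setdefault(ks[(a + 1) % 3], set()).add(ks[a])
    pentagons = {k for k, d in degree.items() if d == 5}
    start = min(pentagons)
    dist = {start: 0}
    q = deque([start])
    while q:
        u = q.popleft()
        if u in pentagons and u != start:
            return dist[u]
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    raise ValueError("no second pentagonal pore found")


def layout_to_dict(layout_: CageLayout) -> dict:
    """JSON-serializable summary of a layout (sites, classes, labels, edges)."""
    return {
        "h": layout_.h,
        "T": t_number(layout_.h),
        "lattice_constant": layout_.lattice_constant,
        "sites": [
            {
                "index": s.index,
                "site_id": s.site_id,
                "site_class": s.site_class,
                "trimer_type": s.trimer_type,
                "center": [round(float(x), 4) for x in s.center],
                "chain_letters": list(s.chain_letters),
                "chain_labels": list(s.chain_labels),
                "parent_feature": s.parent_feature,
            }
            for s in layout_.sites
        ],
        "interface_edges": [
            {"a": list(a), "b": list(b), "type": t}
            for a, b, t in layout_.interface_edges
        ],
    }


def layout_to_json(layout_: CageLayout, path) -> None:
    with open(path, "w") as fh:
        json.dump(layout_to_dict(layout_), fh, indent=1, sort_keys=True)
        fh.write("\n")


def layout_to_tsv(layout_: CageLayout, path) -> None:
    """Flat one-site-per-row TSV for eyeballing a layout."""
    with open(path, "w") as fh:
        fh.write(
            "site_id\tsite_class\ttrimer_type\tx\ty\tz\tchain_letters\tparent_feature\n"
        )
        for s in layout_.sites:
            fh.write(
                f"{s.site_id}\t{s.site_class}\t{s.trimer_type}\t"
                f"{s.center[0]:.3f}\t{s.center[1]:.3f}\t{s.center[2]:.3f}\t"
                f"{''.join(s.chain_letters)}\t{s.parent_feature}\n"
            )


def layout_diameter(layout_: CageLayout) -> float:
    """Outer diameter: twice the maximum site-center radius (Angstrom)."""
    return 2.0 * float(np.max(np.linalg.norm(layout_.centers(), axis=1)))
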