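"""Pseudosymmetrization scan: disrupt/rescue mutant pairs at a trimer interface.

The route to a pseudosymmetric heterotrimer is to find single mutations that
disrupt the homotrimer interface together with compensatory mutations that
rescue it.  This module enumerates interface contacts (heavy-atom distance
rule), scores all single and pairwise mutations with a pluggable pairwise
energy model, applies the disrupt/rescue selection rule

    selected  iff  (Δscore_1 > τ_disrupt or ΔddG_1 > τ_disrupt, or the same
                    for mutation 2)
              and  (Δscore_12 <= τ_rescue and ΔddG_12 <= τ_rescue)

with Δ = mutant - wild type throughout, and offers an independent
coevolution channel that proposes compensatory pairs from residue-coupling
frequency tables.

The reference energy model is a softened steric repulsion between residue
centres (Cbeta, Calpha fallback) with volume-derived effective radii;
mutations change only a residue's type parameters, never coordinates, so
the scan is exact, deterministic and additive over residue pairs.  It
reproduces the clash-and-relief logic of disrupt/rescue pairs without any
side-chain packing; it makes no attempt to reproduce molecular-mechanics
energies numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CONTACT_CUTOFF = 4.0  # heavy-atom interface contact rule, Angstrom

# mean residue volumes (A^3), Zamyatnin-style; effective radius ~ (3V/4pi)^(1/3)
RESIDUE_VOLUMES = {
    "GLY": 60.1, "ALA": 88.6, "SER": 89.0, "CYS": 108.5, "ASP": 111.1,
    "PRO": 112.7, "ASN": 114.1, "THR": 116.1, "GLU": 138.4, "VAL": 140.0,
    "GLN": 143.8, "HIS": 153.2, "MET": 162.9, "ILE": 166.7, "LEU": 166.7,
    "LYS": 168.6, "ARG": 173.4, "PHE": 189.9, "TYR": 193.6, "TRP": 227.8,
}


def residue_radius(restype: str) -> float:
    """Effective steric radius (A) from the mean residue volume."""
    try:
        v = RESIDUE_VOLUMES[restype.upper()]
    except KeyError:
        raise KeyError(f"unknown residue type {restype!r}") from None
    return (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ContactPair:
    """One interface residue pair, canonical order (chain_i, residue_i) <
    (chain_j, residue_j)."""

    chain_i: str
    residue_i: int
    chain_j: str
    residue_j: int
    min_heavy_distance: float

    def __post_init__(self) -> None:
        if self.chain_i == self.chain_j:
            raise ValueError("a contact pair spans two different chains")
        if (self.chain_i, self.residue_i) > (self.chain_j, self.residue_j):
            raise ValueError("contact pair is not in canonical order")


@dataclass(frozen=True)
class MutationSpec:
    chain: str
    residue_index: int
    from_type: str
    to_type: str

    @property
    def is_null(self) -> bool:
        return self.from_type == self.to_type

    def __str__(self) -> str:
        return f"{self.chain}/{self.from_type}{self.residue_index}{self.to_type}"


@dataclass
class PairScanRecord:
    mutation_1: MutationSpec
    mutation_2: MutationSpec
    d_score_1: float
    d_ddg_1: float
    d_score_2: float
    d_ddg_2: float
    d_score_12: float
    d_ddg_12: float
    selected: bool = False


# ---------------------------------------------------------------------------
# residue-centre geometry
# ---------------------------------------------------------------------------

@dataclass
class _Residues:
    """Flattened residue-centre view of a structure."""

    keys: list[tuple[str, int]]  # (chain label, residue index)
    types: list[str]
    centers: np.ndarray  # (N, 3) Cbeta (Calpha fallback)
    chain_of: np.ndarray  # integer chain id per residue
    res_id: np.ndarray  # residue index per residue
    index: dict[tuple[str, int], int]


def _residue_view(structure) -> _Residues:
    keys, types, centers, chain_ids, res_ids = [], [], [], [], []
    chain_id = {}
    for c in structure.chains:
        chain_id.setdefault(c.label, len(chain_id))
        by_res: dict[int, dict] = {}
        names: dict[int, str] = {}
        for a in c.atoms:
            by_res.setdefault(a.residue_index, {})[a.atom_name] = a.coords
            names[a.residue_index] = a.residue_name
        for ri in sorted(by_res):
            d = by_res[ri]
            keys.append((c.label, ri))
            types.append(names[ri])
            centers.append(d.get("CB", d.get("CA", next(iter(d.values())))))
            chain_ids.append(chain_id[c.label])
            res_ids.append(ri)
    return _Residues(
        keys=keys,
        types=types,
        centers=np.array(centers),
        chain_of=np.array(chain_ids),
        res_id=np.array(res_ids),
        index={k: i for i, k in enumerate(keys)},
    )


# ---------------------------------------------------------------------------
# interface contacts
# ---------------------------------------------------------------------------

def interface_contacts(
    structure,
    partition: tuple[set[str], set[str]] | None = None,
    cutoff: float = CONTACT_CUTOFF,
) -> list[ContactPair]:
    """Residue pairs with any heavy-atom pair within ``cutoff`` across the
    interface (exact enumeration, canonical order, each unordered pair once).

    ``partition`` restricts the search to pairs with one chain in each set;
    by default every pair of distinct chains counts.
    """
    if structure.n_chains < 2:
        raise ValueError("interface contacts need at least 2 chains")
    coords, owner = [], []
    for c in structure.chains:
        for a in c.atoms:
            if a.is_heavy:
                coords.append(a.coords)
                owner.append((c.label, a.residue_index))
    coords = np.asarray(coords)
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    best: dict[tuple, float] = {}
    for i, j in pairs:
        (ci, ri), (cj, rj) = owner[i], owner[j]
        if ci == cj:
            continue
        if partition is not None:
            a_set, b_set = partition
            if not (
                (ci in a_set and cj in b_set) or (ci in b_set and cj in a_set)
            ):
                continue
        key = ((ci, ri), (cj, rj)) if (ci, ri) < (cj, rj) else ((cj, rj), (ci, ri))
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < best.get(key, np.inf):
            best[key] = d
    return [
        ContactPair(k[0][0], k[0][1], k[1][0], k[1][1], best[k])
        for k in sorted(best)
    ]


def contact_positions(contacts: list[ContactPair]) -> set[tuple[str, int]]:
    """Unique (chain, residue) positions touched by a contact list."""
    out = set()
    for c in contacts:
        out.add((c.chain_i, c.residue_i))
        out.add((c.chain_j, c.residue_j))
    return out


def merged_position_pairs(contacts: list[ContactPair]) -> set[tuple[int, int]]:
    """Chain-agnostic (residue_i, residue_j) pairs: the counting convention
    that merges the symmetry-related copies of a homo-oligomer interface."""
    return {tuple(sorted((c.residue_i, c.residue_j))) for c in contacts}


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

class StericEnergyModel:
    """Pairwise softened steric repulsion between residue centres.

    pair energy = k_rep * max(0, r_a + r_b - d)^2 for residue centres at
    distance d with effective radii r from the residue volume.  Same-chain
    pairs closer than ``min_seq_sep`` in sequence are excluded (bonded
    neighbours are not sterically free).  total() sums over all remaining
    residue pairs; ddG() = total(oligomer) - sum of total(chain) = the
    cross-chain pair sum (intra-chain terms cancel exactly).  Additive over
    pairs by construction.
    """

    def __init__(self, k_rep: float = 1.0, min_seq_sep: int = 2):
        self.k_rep = k_rep
        self.min_seq_sep = min_seq_sep
        self.max_reach = 2.0 * residue_radius("TRP")

    def pair_energy(self, type_a: str, type_b: str, distance: float) -> float:
        overlap = residue_radius(type_a) + residue_radius(type_b) - distance
        return self.k_rep * overlap * overlap if overlap > 0 else 0.0

    # -- internal vectorized sums ------------------------------------------
    def _pairsum(self, res: _Residues, types: list[str], cross_only: bool) -> float:
        radii = np.array([residue_radius(t) for t in types])
        pairs = cKDTree(res.centers).query_pairs(self.max_reach, output_type="ndarray")
        if len(pairs) == 0:
            return 0.0
        i, j = pairs[:, 0], pairs[:, 1]
        cross = res.chain_of[i] != res.chain_of[j]
        if cross_only:
            keep = cross
        else:
            keep = cross | (np.abs(res.res_id[i] - res.res_id[j]) >= self.min_seq_sep)
        i, j = i[keep], j[keep]
        d = np.linalg.norm(res.centers[i] - res.centers[j], axis=1)
        overlap = radii[i] + radii[j] - d
        overlap[overlap < 0] = 0.0
        return float(self.k_rep * np.sum(overlap * overlap))

    def total(self, structure, mutations: dict[tuple[str, int], str] | None = None) -> float:
        res = _residue_view(structure)
        types = _mutated_types(res, mutations)
        return self._pairsum(res, types, cross_only=False)

    def ddg(self, structure, mutations: dict[tuple[str, int], str] | None = None) -> float:
        res = _residue_view(structure)
        types = _mutated_types(res, mutations)
        return self._pairsum(res, types, cross_only=True)


def _mutated_types(res: _Residues, mutations: dict | None) -> list[str]:
    types = list(res.types)
    for (chain, ri), to_type in (mutations or {}).items():
        if (chain, ri) not in res.index:
            raise KeyError(f"no residue {ri} in chain {chain}")
        types[res.index[(chain, ri)]] = to_type
    return types


def delta_scores(structure, mutations: list[MutationSpec], model) -> tuple[float, float]:
    """(Δscore, ΔddG) of a set of mutations: mutant minus wild type.

    The mutation is a residue-type substitution interpreted by the energy
    model; coordinates are never repacked.
    """
    res = _residue_view(structure)
    mut = {}
    for m in mutations:
        key = (m.chain, m.residue_index)
        if key not in res.index:
            raise KeyError(f"no residue {m.residue_index} in chain {m.chain}")
        found = res.types[res.index[key]]
        if found.upper() != m.from_type.upper():
            raise ValueError(
                f"mutation {m}: structure has {found} at {m.chain}/{m.residue_index}"
            )
        mut[key] = m.to_type
    d_score = model.total(structure, mut) - model.total(structure)
    d_ddg = model.ddg(structure, mut) - model.ddg(structure)
    return d_score, d_ddg


# ---------------------------------------------------------------------------
# pair scan + selection
# ---------------------------------------------------------------------------

def scan_pairs(
    structure,
    contacts: list[ContactPair],
    alphabet: list[str],
    model,
) -> list[PairScanRecord]:
    """Score all mutation combinations from ``alphabet`` at every contact
    pair (single deltas on each side plus the double), deterministic order."""
    if not contacts:
        raise ValueError("no contacts to scan")
    res = _residue_view(structure)
    records = []
    for c in contacts:
        wt_i = res.types[res.index[(c.chain_i, c.residue_i)]]
        wt_j = res.types[res.index[(c.chain_j, c.residue_j)]]
        for a in alphabet:
            m1 = MutationSpec(c.chain_i, c.residue_i, wt_i, a)
            d1 = (0.0, 0.0) if m1.is_null else delta_scores(structure, [m1], model)
            for b in alphabet:
                m2 = MutationSpec(c.chain_j, c.residue_j, wt_j, b)
                d2 = (0.0, 0.0) if m2.is_null else delta_scores(structure, [m2], model)
                if m1.is_null and m2.is_null:
                    d12 = (0.0, 0.0)
                else:
                    muts = [m for m in (m1, m2) if not m.is_null]
                    d12 = delta_scores(structure, muts, model)
                records.append(
                    PairScanRecord(
                        mutation_1=m1, mutation_2=m2,
                        d_score_1=d1[0], d_ddg_1=d1[1],
                        d_score_2=d2[0], d_ddg_2=d2[1],
                        d_score_12=d12[0], d_ddg_12=d12[1],
                    )
                )
    return records


def select_pairs(
    records: list[PairScanRecord],
    tau_disrupt: float = 0.0,
    tau_rescue: float = 0.0,
) -> list[PairScanRecord]:
    """Disrupt/rescue rule: at least one single mutation raises the trimer
    energy above ``tau_disrupt`` while the double leaves it at or below
    ``tau_rescue``.  Null double mutations are never selected.  Marks
    ``selected`` in place and returns the selected records."""
    out = []
    for r in records:
        disrupts = (
            r.d_score_1 > tau_disrupt or r.d_ddg_1 > tau_disrupt
            or r.d_score_2 > tau_disrupt or r.d_ddg_2 > tau_disrupt
        )
        rescued = r.d_score_12 <= tau_rescue and r.d_ddg_12 <= tau_rescue
        r.selected = bool(
            disrupts and rescued and not (r.mutation_1.is_null and r.mutation_2.is_null)
        )
        if r.selected:
            out.append(r)
    return out


def records_to_frame(records: list[PairScanRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "mutation_1": str(r.mutation_1),
                "mutation_2": str(r.mutation_2),
                "d_score_1": r.d_score_1, "d_ddg_1": r.d_ddg_1,
                "d_score_2": r.d_score_2, "d_ddg_2": r.d_ddg_2,
                "d_score_12": r.d_score_12, "d_ddg_12": r.d_ddg_12,
                "selected": r.selected,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coevolution channel
# ---------------------------------------------------------------------------

@dataclass
class CouplingStats:
    """Observed/expected amino-acid pair frequencies for one position pair.

    f_obs maps (a, b) -> frequency (sums to 1 over the table); f_i and f_j
    are the single-position marginals.  Enrichment e(a, b) =
    f_obs / (f_i(a) * f_j(b)).
    """

    i: int
    j: int
    f_obs: dict[tuple[str, str], float]
    f_i: dict[str, float]
    f_j: dict[str, float]

    def enrichment(self, a: str, b: str, pseudocount: float | None = None) -> float | None:
        obs = self.f_obs.get((a, b), 0.0)
        exp = self.f_i.get(a, 0.0) * self.f_j.get(b, 0.0)
        if pseudocount:
            obs = obs + pseudocount
            exp = exp + pseudocount
        if exp == 0.0:
            return None
        return obs / exp


@dataclass(frozen=True)
class CoevolutionCandidate:
    mutation_position: int
    mutation_aa: str
    compensatory_position: int
    compensatory_aa: str
    e_with_wt: float
    e_with_compensatory: float

    @property
    def rank_score(self) -> float:
        return self.e_with_compensatory / self.e_with_wt


def coevolution_select(
    stats: list[CouplingStats],
    wt_types: dict[int, str],
    theta_low: float = 1.0,
    theta_high: float = 1.0,
    pseudocount: float | None = None,
) -> list[CoevolutionCandidate]:
    """Compensatory-pair proposals from coupling tables.

    For a coupled position pair (i, j), propose (i -> m, j -> c) when the
    mutant/wild-type combination is depleted, e(m, wt_j) < theta_low, and
    some mutant/compensatory combination is enriched, e(m, c) > theta_high
    with c != wt_j.  Ranked by e(m, c) / e(m, wt_j), descending.  Pairs
    with zero expected frequency are skipped with a warning unless a
    pseudocount is supplied.
    """
    out = []
    for st in stats:
        for (pos_m, pos_c, wt_c, flip) in (
            (st.i, st.j, wt_types.get(st.j), False),
            (st.j, st.i, wt_types.get(st.i), True),
        ):
            if wt_c is None or wt_types.get(pos_m) is None:
                continue
            aas_m = sorted({(b if flip else a) for a, b in st.f_obs})
            aas_c = sorted({(a if flip else b) for a, b in st.f_obs})
            for m in aas_m:
                if m == wt_types[pos_m]:
                    continue
                e_wt = st.enrichment(*((wt_c, m) if flip else (m, wt_c)), pseudocount=pseudocount)
                if e_wt is None:
                    warnings.warn(
                        f"zero expected frequency for ({pos_m}{m}, {pos_c}{wt_c}); skipped"
                    )
                    continue
                if not (e_wt < theta_low and e_wt > 0):
                    continue
                for cand in aas_c:
                    if cand == wt_c:
                        continue
                    e_c = st.enrichment(
                        *((cand, m) if flip else (m, cand)), pseudocount=pseudocount
                    )
                    if e_c is None or e_c <= theta_high:
                        continue
                    out.append(
                        CoevolutionCandidate(pos_m, m, pos_c, cand, e_wt, e_c)
                    )
    out.sort(key=lambda c: (-c.rank_score, c.mutation_position, c.mutation_aa,
                            c.compensatory_position, c.compensatory_aa))
    return out


def read_coupling_table(path) -> list[CouplingStats]:
    """Read a residue-coupling table: TSV with columns
    i, j, a, b, f_obs, f_i, f_j (one row per amino-acid pair)."""
    df = pd.read_csv(path, sep="\t")
    need = {"i", "j", "a", "b", "f_obs", "f_i", "f_j"}
    if not need.issubset(df.columns):
        raise ValueError(f"coupling table needs columns {sorted(need)}")
    out = []
    for (i, j), grp in df.groupby(["i", "j"], sort=True):
        f_obs = {(r.a, r.b): float(r.f_obs) for r in grp.itertuples()}
        f_i = {r.a: float(r.f_i) for r in grp.itertuples()}
        f_j = {r.b: float(r.f_j) for r in grp.itertuples()}
        out.append(CouplingStats(int(i), int(j), f_obs, f_i, f_j))
    return out
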