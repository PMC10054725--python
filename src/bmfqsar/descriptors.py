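"""2D molecular descriptors for the biomagnification QSARs.

Implements, from the hydrogen-suppressed molecular graph, every descriptor
entering the frozen MLR equations and the cross-validation frequency
analyses:

====================  =====================================================
AATS5i                average Broto-Moreau autocorrelation, lag 5,
                      weighted by first ionization potential
MATS1i                Moran autocorrelation, lag 1, ionization potential
GATS5m / GATS2i       Geary autocorrelation, lag 5 (mass) / lag 2 (IP)
BCUTw-1l              lowest eigenvalue of the mass-weighted Burden matrix
C3SP2                 doubly-bonded carbons with 3 carbon neighbours
GGI5                  Galvez topological charge index, order 5
PubchemFP38/257/      PubChem-style substructure keys (>=2 Cl, >=2 aromatic
  503/738             rings, Cl-C:C-H aromatic fragment, meta C/Cl benzene)
SubFPC295             count of C-(O, N or S) bonds
R_TpiPCTPC            total conventional bond order over total path count,
                      simple paths up to length 10
MLFER_S               Abraham dipolarity/polarizability via a shipped
                      fragment-contribution table
maxHother             maximum hydrogen E-state over aaCH/dCH2/dsCH hydrogens
VE3_Dt                log coefficient sum of the principal eigenvector of
                      the detour (longest-path) matrix
nBondsS3              single non-aromatic bonds between heavy atoms
====================  =====================================================

Degenerate cases (no atom pair at the requested lag, zero property
variance) return 0 by convention with a logged warning, so matrix assembly
never stalls; the convention is recorded in :data:`PROVENANCE`.
"""

from __future__ import annotations

import itertools
import json
import logging
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem

from .graph import MolecularGraph, from_smiles

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# atom property tables

with resources.files("bmfqsar.data").joinpath("atom_properties.json").open() as _fh:
    _PROPS = json.load(_fh)

with resources.files("bmfqsar.data").joinpath("mlfer_s_fragments_synthetic.json").open() as _fh:
    _MLFER = json.load(_fh)

ATOM_PROPERTY_VERSION = _PROPS["version"]
MLFER_TABLE_VERSION = _MLFER["version"]

#: conventions recorded alongside every descriptor matrix
PROVENANCE = {
    "atom_property_table": ATOM_PROPERTY_VERSION,
    "mlfer_s_table": MLFER_TABLE_VERSION,
    "hydrogen_handling": "hydrogen-suppressed graph, attached-H counts used for atom typing",
    "autocorrelation_weights": "raw property values (not carbon-referenced)",
    "burden_offdiagonal": "0.1*order, aromatic 0.15, +0.01 terminal, 0.001 non-bonded",
    "degenerate_convention": "no pair at lag or zero property variance -> 0 (logged)",
    "path_length_cap": 10,
    "pubchem_fp738_smarts": "[#6]c1cc(Cl)ccc1",
}


class DescriptorError(ValueError):
    """A descriptor could not be computed for a molecule."""


def _property_values(g: MolecularGraph, prop: str) -> np.ndarray:
    table = {"mass": _PROPS["mass"], "ionization": _PROPS["ionization_eV"]}.get(prop)
    if table is None:
        raise ValueError(f"unknown atomic property {prop!r}; use 'mass' or 'ionization'")
    try:
        return np.array([table[a.element] for a in g.atoms], dtype=float)
    except KeyError as exc:
        raise DescriptorError(f"no {prop} value for element {exc}") from exc


# ---------------------------------------------------------------------------
# autocorrelations

def autocorrelation_weighted(g: MolecularGraph, lag: int, w, flavor: str) -> float:
    """Autocorrelation over explicit per-atom weights (see :func:`autocorrelation`)."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if flavor not in {"ATS", "AATS", "MATS", "GATS"}:
        raise ValueError(f"unknown autocorrelation flavor {flavor!r}")
    if g.n_atoms < 2:
        raise DescriptorError("autocorrelation needs at least 2 heavy atoms")
    w = np.asarray(w, dtype=float)
    d = g.distance_matrix()
    iu = np.triu_indices(g.n_atoms, k=1)
    at_lag = d[iu] == lag
    delta = int(at_lag.sum())
    if delta == 0:
        logger.warning("no atom pair at lag %d; returning 0 by convention", lag)
        return 0.0
    wi, wj = w[iu[0][at_lag]], w[iu[1][at_lag]]
    if flavor == "ATS":
        return float(np.sum(wi * wj))
    if flavor == "AATS":
        return float(np.sum(wi * wj) / delta)
    wc = w - w.mean()
    var = float(np.sum(wc**2))
    # relative threshold: identical weights can leave rounding dust in var
    if var <= 1e-20 * float(np.sum(w**2)):
        logger.warning("zero property variance; %s returns 0 by convention", flavor)
        return 0.0
    n = g.n_atoms
    if flavor == "MATS":
        num = float(np.sum((wi - w.mean()) * (wj - w.mean()))) / delta
        return num / (var / n)
    num = float(np.sum((wi - wj) ** 2)) / (2 * delta)
    return num / (var / (n - 1))


def autocorrelation(g: MolecularGraph, lag: int, prop: str, flavor: str) -> float:
    """Broto-Moreau (ATS/AATS), Moran (MATS) or Geary (GATS) autocorrelation.

    With d_ij topological distances on the heavy-atom graph, w the atomic
    property values (atomic mass or first ionization potential), w_bar
    their mean and Delta the number of unordered atom pairs at distance
    ``lag``:

    * ATS  = sum_{d_ij=lag} w_i w_j
    * AATS = ATS / Delta
    * MATS = [sum (w_i-w_bar)(w_j-w_bar)/Delta] / [sum_i (w_i-w_bar)^2 / n]
    * GATS = [sum (w_i-w_j)^2 / (2 Delta)] / [sum_i (w_i-w_bar)^2 / (n-1)]

    MATS and GATS are invariant under affine rescaling of the property;
    ATS/AATS are not.
    """
    return autocorrelation_weighted(g, lag, _property_values(g, prop), flavor)


def aats5i(g: MolecularGraph) -> float:
    return autocorrelation(g, 5, "ionization", "AATS")


def mats1i(g: MolecularGraph) -> float:
    return autocorrelation(g, 1, "ionization", "MATS")


def gats5m(g: MolecularGraph) -> float:
    return autocorrelation(g, 5, "mass", "GATS")


def gats2i(g: MolecularGraph) -> float:
    return autocorrelation(g, 2, "ionization", "GATS")


# ---------------------------------------------------------------------------
# Burden matrix / BCUT

def burden_matrix(g: MolecularGraph, prop: str = "mass") -> np.ndarray:
    """Burden connectivity matrix: property values on the diagonal,
    0.1*(conventional bond order) for bonded pairs (aromatic 0.15), +0.01
    for terminal bonds, 0.001 everywhere else."""
    n = g.n_atoms
    w = _property_values(g, prop)
    b = np.full((n, n), 0.001)
    deg = g.degrees()
    for bond in g.bonds:
        val = 0.15 if bond.aromatic else 0.1 * bond.order
        if deg[bond.i] == 1 or deg[bond.j] == 1:
            val += 0.01
        b[bond.i, bond.j] = b[bond.j, bond.i] = val
    np.fill_diagonal(b, w)
    return b


def bcut_lowest(g: MolecularGraph, prop: str = "mass") -> float:
    """BCUTw-1l: smallest eigenvalue of the mass-weighted Burden matrix."""
    if g.n_atoms < 1:
        raise DescriptorError("empty graph")
    return float(np.linalg.eigvalsh(burden_matrix(g, prop))[0])


# ---------------------------------------------------------------------------
# carbon types, fingerprints, bond counts

def carbon_type_c3sp2(g: MolecularGraph) -> int:
    """C3SP2: carbons in a double or aromatic bond with exactly 3 carbon
    neighbours (ring-fusion carbons of PAHs, branched sp2 centres)."""
    count = 0
    for i, atom in enumerate(g.atoms):
        if atom.element != "C":
            continue
        doubly = any(
            (b.order == 2 or b.aromatic)
            for b in g.bonds
            if i in (b.i, b.j)
        )
        if not doubly:
            continue
        c_neighbors = sum(1 for j in g.neighbors(i) if g.atoms[j].element == "C")
        if c_neighbors == 3:
            count += 1
    return count


def topological_charge_index(g: MolecularGraph, order: int) -> float:
    """Galvez charge index GGI_k = sum_{i<j, d_ij=k} |M_ij - M_ji| with
    M = A.Q, Q_ij = 1/d_ij^2 off-diagonal, 0 on the diagonal."""
    if order < 1:
        raise ValueError("order must be >= 1")
    n = g.n_atoms
    if n < 2:
        return 0.0
    a = g.adjacency()
    d = g.distance_matrix()
    with np.errstate(divide="ignore"):
        q = 1.0 / d**2
    q[~np.isfinite(q)] = 0.0
    np.fill_diagonal(q, 0.0)
    m = a @ q
    iu = np.triu_indices(n, k=1)
    sel = d[iu] == order
    if not sel.any():
        return 0.0
    return float(np.sum(np.abs(m[iu][sel] - m.T[iu][sel])))


def ggi5(g: MolecularGraph) -> float:
    return topological_charge_index(g, 5)


_FP503 = Chem.MolFromSmarts("Cl-[c]:[c;!H0]")
_FP738 = Chem.MolFromSmarts("[#6]c1cc(Cl)ccc1")


def pubchem_bit(g: MolecularGraph, bit: int) -> int:
    """PubChem-style substructure keys used by the models.

    * bit 38: two or more chlorine atoms
    * bit 257: SSSR ring set contains >= 2 aromatic rings
    * bit 503: Cl on an aromatic carbon whose aromatic neighbour bears an H
    * bit 738: meta carbon/chlorine disubstituted benzene (published
      PubChem complex-SMARTS key ``Cc1cc(Cl)ccc1``)
    """
    mol = g.to_rdkit()
    if bit == 38:
        return int(sum(1 for a in g.atoms if a.element == "Cl") >= 2)
    if bit == 257:
        ri = mol.GetRingInfo()
        n_arom = sum(
            1
            for ring in ri.BondRings()
            if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
        )
        return int(n_arom >= 2)
    if bit == 503:
        return int(mol.HasSubstructMatch(_FP503))
    if bit == 738:
        return int(mol.HasSubstructMatch(_FP738))
    raise ValueError(f"unsupported PubChem bit {bit}; supported: 38, 257, 503, 738")


def subfpc_295(g: MolecularGraph) -> int:
    """SubFPC295: number of bonds (any order) joining C to O, N or S."""
    hetero = {"O", "N", "S"}
    count = 0
    for b in g.bonds:
        e1, e2 = g.atoms[b.i].element, g.atoms[b.j].element
        if (e1 == "C" and e2 in hetero) or (e2 == "C" and e1 in hetero):
            count += 1
    return count


def nbonds_s3(g: MolecularGraph) -> int:
    """nBondsS3: single non-aromatic bonds between heavy atoms."""
    return sum(1 for b in g.bonds if b.order == 1 and not b.aromatic)


# ---------------------------------------------------------------------------
# path-based descriptors

#: DFS expansion budget for simple-path enumeration; molecules exceeding it
#: fail the affected cell explicitly rather than stalling the matrix.
PATH_BUDGET = 2_000_000


def _simple_paths(g: MolecularGraph, cutoff: int, budget: int = PATH_BUDGET):
    """Yield bond-index tuples of all simple paths with 1..cutoff bonds,
    each undirected path once (smaller endpoint first)."""
    adj: list[list[tuple[int, int]]] = [[] for _ in range(g.n_atoms)]
    for bi, b in enumerate(g.bonds):
        adj[b.i].append((b.j, bi))
        adj[b.j].append((b.i, bi))
    steps = 0
    for start in range(g.n_atoms):
        stack = [(start, [start], [])]
        while stack:
            node, visited, bonds = stack.pop()
            for nxt, bi in adj[node]:
                if nxt in visited:
                    continue
                steps += 1
                if steps > budget:
                    raise DescriptorError("simple-path enumeration budget exceeded")
                path_bonds = bonds + [bi]
                if nxt > start:
                    yield tuple(path_bonds)
                if len(path_bonds) < cutoff:
                    stack.append((nxt, visited + [nxt], path_bonds))


def path_count_ratio(g: MolecularGraph, cutoff: int = 10) -> float:
    """R_TpiPCTPC: ratio of the total conventional bond order to the total
    path count, over simple paths of length 0..cutoff.

    A length-0 path is a single atom with empty product 1; bond orders are
    1/2/3 with aromatic bonds 1.5.
    """
    orders = np.array([b.conventional_order for b in g.bonds])
    tpipc = float(g.n_atoms)  # length-0 paths
    tpc = g.n_atoms
    for path_bonds in _simple_paths(g, cutoff):
        tpipc += float(np.prod(orders[list(path_bonds)]))
        tpc += 1
    return tpipc / tpc


def detour_matrix(g: MolecularGraph, budget: int = PATH_BUDGET) -> np.ndarray:
    """Matrix of longest simple-path lengths between heavy atoms.

    On acyclic graphs this equals the topological distance matrix (paths
    are unique), which is used as a shortcut; cyclic graphs fall back to
    exhaustive DFS with a step budget.
    """
    n = g.n_atoms
    if not g.is_connected():
        raise DescriptorError("detour matrix requires a connected graph")
    if len(g.bonds) == n - 1:  # tree
        return g.distance_matrix()
    adj: list[list[int]] = [[] for _ in range(n)]
    for b in g.bonds:
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
    dt = np.zeros((n, n))
    steps = 0
    for start in range(n):
        # DFS over all simple paths from `start`, recording max depth per node
        stack = [(start, 1 << start, 0)]
        while stack:
            node, visited, depth = stack.pop()
            if depth > dt[start, node]:
                dt[start, node] = depth
            for nxt in adj[node]:
                if visited & (1 << nxt):
                    continue
                steps += 1
                if steps > budget:
                    raise DescriptorError("detour-matrix path budget exceeded")
                stack.append((nxt, visited | (1 << nxt), depth + 1))
    return np.maximum(dt, dt.T)


def ve3_detour(g: MolecularGraph) -> float:
    """VE3_Dt = ln(0.1 * n * VE1) where VE1 is the absolute coefficient sum
    of the unit-norm eigenvector of the detour matrix' largest eigenvalue."""
    n = g.n_atoms
    if n < 2:
        raise DescriptorError("VE3_Dt undefined for a single atom")
    dt = detour_matrix(g)
    vals, vecs = np.linalg.eigh(dt)
    v = vecs[:, -1]
    ve1 = float(np.sum(np.abs(v)))
    return float(np.log(0.1 * n * ve1))


# ---------------------------------------------------------------------------
# MLFER_S fragment scheme

_MLFER_PATTERNS = [
    (f["label"], Chem.MolFromSmarts(f["smarts"]), f["coefficient"]) for f in _MLFER["fragments"]
]


def mlfer_s(g: MolecularGraph) -> float:
    """Abraham dipolarity/polarizability S by fragment contributions.

    Evaluates the shipped (synthetic, package-calibrated) fragment table:
    intercept + sum over fragments of unique-match count x coefficient.
    A molecule matching no fragment returns the intercept alone.
    """
    mol = g.to_rdkit()
    total = float(_MLFER["intercept"])
    matched = False
    for _label, patt, coef in _MLFER_PATTERNS:
        k = len(mol.GetSubstructMatches(patt, uniquify=True))
        if k:
            matched = True
            total += k * coef
    if not matched:
        logger.warning("no MLFER_S fragment matched; returning intercept alone")
    return total


# ---------------------------------------------------------------------------
# hydrogen E-state (maxHother)

def _h_estate_types(g: MolecularGraph) -> list[int]:
    """Indices of heavy atoms bearing aaCH, dCH2 or dsCH hydrogens."""
    out = []
    for i, atom in enumerate(g.atoms):
        if atom.element != "C" or atom.n_h == 0:
            continue
        if atom.aromatic and atom.n_h == 1:
            out.append(i)  # aaCH
            continue
        double = sum(1 for b in g.bonds if i in (b.i, b.j) and b.order == 2 and not b.aromatic)
        single = sum(1 for b in g.bonds if i in (b.i, b.j) and b.order == 1 and not b.aromatic)
        if double == 1 and atom.n_h == 2 and single == 0:
            out.append(i)  # dCH2 (=CH2)
        elif double == 1 and single == 1 and atom.n_h == 1:
            out.append(i)  # dsCH (=CH-)
    return out


def _hydrogen_intrinsic_states(g: MolecularGraph) -> np.ndarray:
    """Kier-Hall-style hydrogen intrinsic state of each heavy atom:
    I_H = (dv - d + 1)/d with dv = valence electrons - attached H and
    d = heavy-atom degree."""
    zv = _PROPS["valence_electrons"]
    deg = g.degrees()
    out = np.zeros(g.n_atoms)
    for i, atom in enumerate(g.atoms):
        if atom.element not in zv:
            raise DescriptorError(f"no valence-electron count for {atom.element}")
        d = max(int(deg[i]), 1)
        dv = zv[atom.element] - atom.n_h
        out[i] = (dv - d + 1) / d
    return out


def hydrogen_estates(g: MolecularGraph) -> dict[int, float]:
    """Hydrogen E-state per qualifying heavy atom (aaCH/dCH2/dsCH).

    HS_i = I_H(i) + sum_j (I_H(i) - I_H(j)) / (d_ij + 1)^2 over all other
    heavy atoms j, the usual inverse-square topological perturbation.
    """
    targets = _h_estate_types(g)
    if not targets:
        return {}
    ih = _hydrogen_intrinsic_states(g)
    d = g.distance_matrix()
    out = {}
    for i in targets:
        pert = 0.0
        for j in range(g.n_atoms):
            if j == i:
                continue
            pert += (ih[i] - ih[j]) / (d[i, j] + 1.0) ** 2
        out[i] = float(ih[i] + pert)
    return out


def max_h_estate_other(g: MolecularGraph) -> float:
    """maxHother: maximum hydrogen E-state over aaCH, dCH2, dsCH hydrogens;
    0 when no qualifying hydrogen exists."""
    hs = hydrogen_estates(g)
    return max(hs.values()) if hs else 0.0


# ---------------------------------------------------------------------------
# descriptor registry / matrix assembly

DESCRIPTORS: dict[str, callable] = {
    "AATS5i": aats5i,
    "MATS1i": mats1i,
    "GATS5m": gats5m,
    "GATS2i": gats2i,
    "BCUTw-1l": bcut_lowest,
    "C3SP2": carbon_type_c3sp2,
    "GGI5": ggi5,
    "PubchemFP38": lambda g: pubchem_bit(g, 38),
    "PubchemFP257": lambda g: pubchem_bit(g, 257),
    "PubchemFP503": lambda g: pubchem_bit(g, 503),
    "PubchemFP738": lambda g: pubchem_bit(g, 738),
    "SubFPC295": subfpc_295,
    "R_TpiPCTPC": path_count_ratio,
    "MLFER_S": mlfer_s,
    "maxHother": max_h_estate_other,
    "VE3_Dt": ve3_detour,
    "nBondsS3": nbonds_s3,
}

ALL_DESCRIPTOR_NAMES = list(DESCRIPTORS)


def compute_vector(g: MolecularGraph, names: list[str] | None = None) -> dict[str, float]:
    """Descriptor values for one molecule (raises on any failure)."""
    names = names or ALL_DESCRIPTOR_NAMES
    unknown = [n for n in names if n not in DESCRIPTORS]
    if unknown:
        raise ValueError(f"unknown descriptor(s) {unknown}; supported: {ALL_DESCRIPTOR_NAMES}")
    return {name: float(DESCRIPTORS[name](g)) for name in names}


def compute_matrix(dataset, names: list[str] | None = None) -> tuple[pd.DataFrame, list[dict]]:
    """Descriptor matrix for a curated dataset.

    One row per record, indexed by canonical SMILES. A row is dropped (and
    reported in the failure log) if any requested descriptor fails for it.

    Returns
    -------
    (DataFrame, failures)
        failures: list of dicts with canonical SMILES, descriptor, reason.
    """
    names = names or ALL_DESCRIPTOR_NAMES
    rows, index, failures = [], [], []
    for rec in dataset:
        g = rec.graph if rec.graph is not None else from_smiles(rec.smiles)
        row, ok = {}, True
        for name in names:
            if name not in DESCRIPTORS:
                raise ValueError(
                    f"unknown descriptor {name!r}; supported: {ALL_DESCRIPTOR_NAMES}"
                )
            try:
                row[name] = float(DESCRIPTORS[name](g))
            except DescriptorError as exc:
                failures.append(
                    {"canonical_smiles": rec.canonical_smiles, "descriptor": name, "reason": str(exc)}
                )
                ok = False
        if ok:
            rows.append(row)
            index.append(rec.canonical_smiles)
    df = pd.DataFrame(rows, index=index, columns=names)
    df.attrs["provenance"] = dict(PROVENANCE)
    return df, failures


class DescriptorCalculator:
    """scikit-learn style transformer: SMILES in, descriptor matrix out.

    ``transform`` accepts an iterable of SMILES strings (or a Dataset) and
    returns a DataFrame of the requested descriptors, indexed by canonical
    SMILES.  Stateless; ``fit`` only records the column names, so the
    transformer composes with sklearn pipelines and ``clone``.
    """

    def __init__(self, descriptor_names: list[str] | None = None):
        self.descriptor_names = descriptor_names

    def get_params(self, deep=True):
        return {"descriptor_names": self.descriptor_names}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        names = self.descriptor_names or ALL_DESCRIPTOR_NAMES
        unknown = [n for n in names if n not in DESCRIPTORS]
        if unknown:
            raise ValueError(f"unknown descriptor(s) {unknown}")
        self.feature_names_out_ = list(names)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        names = self.feature_names_out_
        rows, index = [], []
        for item in X:
            g = item.graph if hasattr(item, "graph") and item.graph is not None else (
                from_smiles(item if isinstance(item, str) else item.smiles)
            )
            rows.append({n: float(DESCRIPTORS[n](g)) for n in names})
            from rdkit import Chem

            index.append(Chem.MolToSmiles(g.to_rdkit()))
        df = pd.DataFrame(rows, index=index, columns=names)
        df.attrs["provenance"] = dict(PROVENANCE)
        return df

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)


def prereduce(
    m: pd.DataFrame, const_fraction: float = 0.95, corr_cut: float = 0.98
) -> tuple[pd.DataFrame, list[dict]]:
    """Pre-reduction of a descriptor matrix.

    Drops near-constant columns (a single value occupying >= const_fraction
    of the rows), then scans column pairs in fixed (sorted) name order and
    drops the later-named column of any pair with |Pearson r| > corr_cut.
    """
    if len(m) < 2:
        raise ValueError("pre-reduction needs at least 2 rows")
    dropped: list[dict] = []
    keep = list(m.columns)
    for col in list(keep):
        top = m[col].value_counts(normalize=True).iloc[0]
        if top >= const_fraction:
            keep.remove(col)
            dropped.append({"column": col, "reason": f"near-constant ({top:.0%} identical)"})
    alive = sorted(keep)
    removed = set()
    for a, b in itertools.combinations(alive, 2):
        if a in removed or b in removed:
            continue
        sa, sb = m[a], m[b]
        if sa.std() == 0 or sb.std() == 0:
            continue
        r = abs(sa.corr(sb))
        if r > corr_cut:
            removed.add(b)
            dropped.append({"column": b, "reason": f"|r|={r:.3f} with {a}"})
    out = m[[c for c in m.columns if c in keep and c not in removed]].copy()
    out.attrs["provenance"] = dict(m.attrs.get("provenance", PROVENANCE))
    return out, dropped
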