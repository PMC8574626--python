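"""Atomic models, per-residue secondary structure, and synthetic fixtures.

A :class:`Structure` is a minimal container for atoms grouped into residues
and chains, with one secondary-structure label per residue (Helix, Sheet,
Others, or Unlabeled before assignment).  Labels come either from an
external per-residue code file (STRIDE/DSSP-style letters, see
:func:`ingest_ss_codes`) or from the built-in dihedral-window assigner
(:func:`assign_secondary_structure`).

The module also generates synthetic structures: ideal poly-alanine helices,
antiparallel beta-sheets, and random "toy domains" mixing helices, sheets
and coils.  Backbones are grown from ideal internal coordinates (bond
lengths/angles plus per-residue phi/psi), so canonical helix geometry
(~1.5 A rise, ~2.3 A Calpha radius) and strand geometry (~3.3 A rise)
emerge from the dihedrals rather than being painted on.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from enum import IntEnum

import gemmi
import numpy as np

BACKBONE_NAMES = ("N", "CA", "C")

# ideal backbone internal coordinates (A, degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.530
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_A_N_CA_CB = 110.5
_OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)

# dihedral windows of the built-in assigner (degrees)
HELIX_PHI_WINDOW = (-100.0, -30.0)
HELIX_PSI_WINDOW = (-80.0, -5.0)
SHEET_PHI_WINDOW = (-180.0, -90.0)
SHEET_PSI_WINDOW = (90.0, 180.0)

_HELIX_CODES = frozenset("HGI")
_SHEET_CODES = frozenset(("B", "b", "E"))


class SSLabel(IntEnum):
    """Three-state secondary structure, plus a pre-assignment sentinel."""

    HELIX = 0
    SHEET = 1
    OTHERS = 2
    UNLABELED = -1


class EmptyStructureError(ValueError):
    """Raised when a model file contains no usable ATOM records."""


class GenerationError(RuntimeError):
    """Raised when random structure placement fails after bounded retries."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    chain_id: str
    residue_index: int

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES


@dataclass
class Residue:
    chain_id: str
    residue_index: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    ss_label: SSLabel = SSLabel.UNLABELED

    @property
    def ca(self) -> Atom | None:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def residues(self) -> list[Residue]:
        return [r for ch in self.chains.values() for r in ch]

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues() for a in r.atoms]

    def coords(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        """(n, 3) coordinates, optionally restricted to given atom names."""
        pts = [
            a.coord
            for a in self.atoms()
            if names is None or a.name in names
        ]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def add_residue(self, res: Residue) -> None:
        chain = self.chains.setdefault(res.chain_id, [])
        if chain and res.residue_index <= chain[-1].residue_index:
            raise ValueError(
                f"residue index {res.residue_index} not increasing in chain "
                f"{res.chain_id!r}"
            )
        chain.append(res)

    def merged_with(self, other: "Structure") -> "Structure":
        """Union of two structures (chain ids must not collide)."""
        out = Structure()
        for s in (self, other):
            for cid, residues in s.chains.items():
                if cid in out.chains:
                    raise ValueError(f"duplicate chain id {cid!r} in merge")
                out.chains[cid] = residues
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid transform x -> R x + t applied to every atom."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = Structure()
        for cid, residues in self.chains.items():
            out.chains[cid] = [
                Residue(
                    chain_id=r.chain_id,
                    residue_index=r.residue_index,
                    res_name=r.res_name,
                    atoms=[
                        Atom(a.name, a.element, rotation @ a.coord + translation,
                             a.chain_id, a.residue_index)
                        for a in r.atoms
                    ],
                    ss_label=r.ss_label,
                )
                for r in residues
            ]
        return out


# ---------------------------------------------------------------------------
# PDB I/O


def parse_pdb(path: str | os.PathLike) -> Structure:
    """Load the first model's ATOM records of a PDB file.

    Alternate locations collapse to the highest-occupancy conformer (first
    wins on ties); HETATM records are ignored; every residue starts with
    ``ss_label = UNLABELED``.
    """
    st = gemmi.read_structure(os.fspath(path))
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path!r}")
    model = st[0]
    out = Structure()
    for chain in model:
        for res in chain:
            if res.het_flag != "A":  # ATOM records only
                continue
            atoms: dict[str, Atom] = {}
            occ: dict[str, float] = {}
            for a in res:
                prev = occ.get(a.name)
                if prev is None or a.occ > prev:
                    occ[a.name] = a.occ
                    atoms[a.name] = Atom(
                        name=a.name,
                        element=a.element.name,
                        coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        chain_id=chain.name,
                        residue_index=res.seqid.num,
                    )
            if atoms:
                out.add_residue(
                    Residue(
                        chain_id=chain.name,
                        residue_index=res.seqid.num,
                        res_name=res.name,
                        atoms=list(atoms.values()),
                    )
                )
    if not out.chains:
        raise EmptyStructureError(f"no ATOM records in {path!r}")
    return out


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write a structure as a single-model PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = "cryoss"
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.res_name
            gr.seqid = gemmi.SeqId(r.residue_index, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = 1.0
                gr.add_atom(ga)
            chain.add_residue(gr)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(os.fspath(path))


def read_ss_codes(path: str | os.PathLike) -> dict[tuple[str, int], str]:
    """Read a two-column SS code file: ``chain:resindex<TAB>code`` per line."""
    codes: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                key, code = line.split("\t")
                chain, idx = key.rsplit(":", 1)
                codes[(chain, int(idx))] = code
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: malformed line {line!r}") from exc
    return codes


def ingest_ss_codes(
    structure: Structure, codes: dict[tuple[str, int], str]
) -> Structure:
    """Apply external per-residue codes to the three-class scheme.

    H/G/I count as Helix, B/b/E as Sheet, and everything else (turns,
    bends, coil, or residues absent from ``codes``) as Others.
    """
    for res in structure.residues():
        code = codes.get((res.chain_id, res.residue_index))
        if code in _HELIX_CODES:
            res.ss_label = SSLabel.HELIX
        elif code in _SHEET_CODES:
            res.ss_label = SSLabel.SHEET
        else:
            res.ss_label = SSLabel.OTHERS
    return structure


# ---------------------------------------------------------------------------
# Dihedral-window secondary-structure assignment


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(chain: list[Residue]) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue; ``None`` where undefined (termini, gaps)."""
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(chain):
        n, ca, c = (res.atom(x) for x in BACKBONE_NAMES)
        phi = psi = None
        if n is not None and ca is not None and c is not None:
            if i > 0:
                c_prev = chain[i - 1].atom("C")
                if c_prev is not None:
                    phi = dihedral(c_prev.coord, n.coord, ca.coord, c.coord)
            if i < len(chain) - 1:
                n_next = chain[i + 1].atom("N")
                if n_next is not None:
                    psi = dihedral(n.coord, ca.coord, c.coord, n_next.coord)
        out.append((phi, psi))
    return out


def _in_window(value: float | None, window: tuple[float, float]) -> bool:
    return value is not None and window[0] <= value <= window[1]


def assign_secondary_structure(structure: Structure) -> Structure:
    """Label every residue Helix/Sheet/Others from backbone dihedrals.

    A residue is Helix when its own (phi, psi) and those of both sequence
    neighbours fall in the helical window (an implied run of >= 3); Sheet
    when its (phi, psi) and at least one neighbour's fall in the extended
    window (run of >= 2); otherwise Others.  Chain termini, where phi or
    psi is undefined, and residues missing backbone atoms are Others.
    """
    import warnings

    for chain in structure.chains.values():
        phipsi = backbone_dihedrals(chain)
        in_h = [
            _in_window(phi, HELIX_PHI_WINDOW) and _in_window(psi, HELIX_PSI_WINDOW)
            for phi, psi in phipsi
        ]
        in_s = [
            _in_window(phi, SHEET_PHI_WINDOW) and _in_window(psi, SHEET_PSI_WINDOW)
            for phi, psi in phipsi
        ]
        n = len(chain)
        for i, res in enumerate(chain):
            if any(res.atom(x) is None for x in BACKBONE_NAMES):
                warnings.warn(
                    f"residue {res.chain_id}:{res.residue_index} lacks backbone "
                    "atoms; labeled Others"
                )
                res.ss_label = SSLabel.OTHERS
                continue
            helix = (
                0 < i < n - 1 and in_h[i - 1] and in_h[i] and in_h[i + 1]
            )
            sheet = in_s[i] and (
                (i > 0 and in_s[i - 1]) or (i < n - 1 and in_s[i + 1])
            )
            if helix:
                res.ss_label = SSLabel.HELIX
            elif sheet:
                res.ss_label = SSLabel.SHEET
            else:
                res.ss_label = SSLabel.OTHERS
    return structure


# ---------------------------------------------------------------------------
# Backbone construction from internal coordinates


def _nerf(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, chi: float
) -> np.ndarray:
    """Place atom d with |cd| = r, angle(b,c,d) = theta, dihedral(a,b,c,d) = chi."""
    th = math.radians(theta)
    ch = math.radians(chi)
    d_local = np.array(
        [
            -r * math.cos(th),
            r * math.sin(th) * math.cos(ch),
            r * math.sin(th) * math.sin(ch),
        ]
    )
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_u)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc_u)
    frame = np.column_stack([bc_u, m, n])
    return c + frame @ d_local


def _build_chain(
    chain_id: str,
    phi: np.ndarray,
    psi: np.ndarray,
    label: SSLabel | list[SSLabel],
    first_index: int = 1,
) -> Structure:
    """Grow an ALA chain with the given per-residue dihedrals (omega trans)."""
    n_res = len(phi)
    labels = [label] * n_res if isinstance(label, SSLabel) else list(label)
    st = Structure()
    coords: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        if i == 0:
            n_at = np.zeros(3)
            ca = np.array([_B_N_CA, 0.0, 0.0])
            ang = math.radians(_A_N_CA_C)
            c = ca + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            prev = coords[i - 1]
            n_at = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi[i - 1])
            ca = _nerf(prev["CA"], prev["C"], n_at, _B_N_CA, _A_C_N_CA, _OMEGA)
            c = _nerf(prev["C"], n_at, ca, _B_CA_C, _A_N_CA_C, phi[i])
        coords.append({"N": n_at, "CA": ca, "C": c})
    for i in range(n_res):
        n_at, ca, c = coords[i]["N"], coords[i]["CA"], coords[i]["C"]
        o = _nerf(n_at, ca, c, _B_C_O, _A_CA_C_O, psi[i] + 180.0)
        cb = _nerf(c, n_at, ca, _B_CA_CB, _A_N_CA_CB, 122.6)
        idx = first_index + i
        atoms = [
            Atom("N", "N", n_at, chain_id, idx),
            Atom("CA", "C", ca, chain_id, idx),
            Atom("C", "C", c, chain_id, idx),
            Atom("O", "O", o, chain_id, idx),
            Atom("CB", "C", cb, chain_id, idx),
        ]
        st.add_residue(
            Residue(chain_id, idx, "ALA", atoms, labels[i])
        )
    return st


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180-degree flip about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Dominant direction of a point cloud, oriented first-to-last."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(points[-1] - points[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _align(structure: Structure, origin, axis, anchor: str = "first") -> Structure:
    """Rotate the structure's CA principal axis onto ``axis``.

    ``anchor`` places either the first CA (``"first"``) or the CA centroid
    (``"centroid"``) at ``origin``.
    """
    ca = structure.coords(("CA",))
    rot = (
        np.eye(3)
        if len(ca) < 2
        else _rotation_between(_principal_axis(ca), np.asarray(axis, float))
    )
    ref = ca[0] if anchor == "first" else ca.mean(axis=0)
    shift = np.asarray(origin, float) - rot @ ref
    return structure.transformed(rot, shift)


def build_ideal_helix(
    n_residues: int,
    origin=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
    chain_id: str = "A",
) -> Structure:
    """Poly-alanine alpha-helix (phi, psi = -57, -47) along ``axis``.

    The canonical helix parameters -- 1.5 A rise per residue, ~100 degree
    twist, ~2.3 A Calpha radius, so 10 residues span about 15 A -- follow
    from the dihedrals.  All residues are labeled Helix.
    """
    if n_residues < 1:
        raise ValueError(f"n_residues must be >= 1, got {n_residues}")
    phi = np.full(n_residues, HELIX_PHI_PSI[0])
    psi = np.full(n_residues, HELIX_PHI_PSI[1])
    st = _build_chain(chain_id, phi, psi, SSLabel.HELIX)
    return _align(st, origin, axis)


def build_ideal_sheet(
    n_strands: int,
    strand_len: int,
    origin=(0.0, 0.0, 0.0),
    orientation: np.ndarray | None = None,
) -> Structure:
    """Antiparallel beta-sheet: ``n_strands`` chains of ``strand_len`` residues.

    Strands run along x with ~3.3 A rise per residue and 4.8 A inter-strand
    spacing along y; successive strands alternate direction.  ``orientation``
    is an optional 3x3 rotation applied to the whole sheet about ``origin``.
    All residues are labeled Sheet.
    """
    if n_strands < 1:
        raise ValueError(f"n_strands must be >= 1, got {n_strands}")
    if strand_len < 2:
        raise ValueError(f"strand_len must be >= 2, got {strand_len}")
    phi = np.full(strand_len, STRAND_PHI_PSI[0])
    psi = np.full(strand_len, STRAND_PHI_PSI[1])
    sheet = Structure()
    for k in range(n_strands):
        cid = chr(ord("A") + k)
        strand = _build_chain(cid, phi, psi, SSLabel.SHEET)
        direction = (1.0, 0.0, 0.0) if k % 2 == 0 else (-1.0, 0.0, 0.0)
        strand = _align(strand, (0.0, 4.8 * k, 0.0), direction, anchor="centroid")
        sheet = sheet.merged_with(strand)
    if orientation is not None:
        sheet = sheet.transformed(np.asarray(orientation, float), np.zeros(3))
    return sheet.transformed(np.eye(3), np.asarray(origin, float))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _build_coil(chain_id: str, n_residues: int, rng: np.random.Generator) -> Structure:
    """Irregular extended segment (polyproline-II-like dihedrals, jittered)."""
    phi = rng.uniform(-85.0, -65.0, n_residues)
    psi = rng.uniform(135.0, 160.0, n_residues)
    return _build_chain(chain_id, phi, psi, SSLabel.OTHERS)


def build_toy_domain(
    seed: int,
    n_elements: int,
    extent: float | None = None,
    min_separation: float = 3.0,
    max_tries: int = 1000,
) -> Structure:
    """Random arrangement of helices, sheets and coils in a bounded cube.

    A deterministic function of ``(seed, n_elements, extent)``.  The first
    three elements are one helix, one sheet and one coil, so every class is
    present whenever ``n_elements >= 3``; further elements are drawn at
    random.  Helices have 5-18 residues, sheets 2-4 strands of 4-8 residues,
    coils 4-10 residues.  Elements are rigidly placed with a minimum
    inter-element atom distance of ``min_separation`` (default 3.0 A) inside
    a cube of side ``extent`` (default grows with n_elements).

    Raises :class:`GenerationError` if an element cannot be placed within
    ``max_tries`` random poses.
    """
    if n_elements < 1:
        raise ValueError(f"n_elements must be >= 1, got {n_elements}")
    import string

    chain_chars = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if n_elements > len(chain_chars):
        raise ValueError(f"n_elements must be <= {len(chain_chars)}")
    rng = np.random.default_rng(seed)
    if extent is None:
        extent = 24.0 + 12.0 * n_elements ** (1.0 / 3.0)
    half = extent / 2.0

    kinds = ["helix", "sheet", "coil"][:n_elements]
    kinds += [rng.choice(["helix", "sheet", "coil"]) for _ in range(n_elements - len(kinds))]

    domain = Structure()
    placed_coords: np.ndarray | None = None
    from scipy.spatial import cKDTree

    for e, kind in enumerate(kinds):
        cid = chain_chars[e]  # chain ids stay PDB-compatible (<= 2 chars)
        if kind == "helix":
            element = build_ideal_helix(int(rng.integers(5, 19)), chain_id=cid)
        elif kind == "sheet":
            n_strands = int(rng.integers(2, 5))
            strand_len = int(rng.integers(4, 9))
            element = build_ideal_sheet(n_strands, strand_len)
            # rename strand chains so ids stay unique across elements
            renamed = Structure()
            for k, (_, residues) in enumerate(element.chains.items()):
                new_id = f"{cid}{k}"
                for r in residues:
                    r.chain_id = new_id
                    for a in r.atoms:
                        a.chain_id = new_id
                renamed.chains[new_id] = residues
            element = renamed
        else:
            element = _build_coil(cid, int(rng.integers(4, 11)), rng)

        base = element.coords()
        base = base - base.mean(axis=0)
        placed = None
        grow = half
        for _round in range(5):  # relax the cube slightly if packing is tight
            for attempt in range(max_tries):
                rot = _random_rotation(rng)
                center = rng.uniform(-(grow - 2.0), grow - 2.0, 3)
                cand = base @ rot.T + center
                if np.any(cand < -grow) or np.any(cand > grow):
                    continue
                if placed_coords is not None:
                    dist, _ = cKDTree(placed_coords).query(cand, k=1)
                    if float(np.min(dist)) < min_separation:
                        continue
                shift = center - rot @ element.coords().mean(axis=0)
                placed = element.transformed(rot, shift)
                break
            if placed is not None:
                break
            grow *= 1.06
        if placed is None:
            raise GenerationError(
                f"could not place element {e} ({kind}) after {5 * max_tries} "
                f"tries in a {extent:.0f} A cube"
            )
        domain = domain.merged_with(placed)
        placed_coords = (
            cand if placed_coords is None else np.vstack([placed_coords, cand])
        )
    return domain
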