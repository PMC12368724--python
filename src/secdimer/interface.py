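"""Structure-based characterisation of a homodimer interface.

Solvent-accessible surface area (SASA) is computed with the
Shrake-Rupley method: each atom's van der Waals sphere is inflated by
the probe radius (1.4 A, a water molecule), sampled with a deterministic
golden-spiral point set, and the fraction of points not occluded by any
neighbouring inflated sphere gives the accessible fraction of the
sphere's area.  The point set contains no randomness, so results are
bit-for-bit reproducible.

An interface residue is one whose SASA in the isolated chain exceeds its
SASA in the complex: buried = SASA_monomer - SASA_complex, and the
relative burial is buried/SASA_monomer.  Polarity follows the classical
sidechain classification (Gly/Ala/Val/Leu/Ile/Pro/Met/Phe/Trp/Tyr
apolar, everything else polar).  Hydrogen bonds across the interface are
detected geometrically from heavy atoms only: donor-capable N/O
(residue-template based, crystal structures carry no hydrogens) within a
donor-acceptor distance cutoff of acceptor-capable N/O on the other
chain.  No angular criterion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "VDW_RADII",
    "APOLAR_RESIDUES",
    "Structure",
    "InterfaceResidue",
    "InterfaceReport",
    "HydrogenBond",
    "read_pdb",
    "write_pdb",
    "shrake_rupley_sasa",
    "classify_polarity",
    "interface_residues",
    "detect_hbonds",
]

#: element -> van der Waals radius (A)
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "H": 1.10, "P": 1.80, "SE": 1.90, "F": 1.47,
    "CL": 1.75, "BR": 1.85, "I": 1.98,
}

#: residues whose sidechains are classified apolar (Gly grouped here by
#: absence of a polar sidechain)
APOLAR_RESIDUES = frozenset(
    {"GLY", "ALA", "VAL", "LEU", "ILE", "PRO", "MET", "PHE", "TRP", "TYR"})

_STANDARD_RESIDUES = APOLAR_RESIDUES | frozenset(
    {"SER", "THR", "CYS", "ASN", "GLN", "ASP", "GLU", "LYS", "ARG", "HIS"})

# Heavy atoms able to donate a hydrogen bond (carry at least one H) and
# to accept one, per residue template.  Backbone N donates (except in
# proline) and backbone O accepts, for every residue.
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"},
}
_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Structure:
    """Flat atom table of a (multi-chain) structure.

    Parallel arrays over atoms; ``radius`` holds the van der Waals
    radius assigned per element at load time.
    """

    chain: np.ndarray       # str
    res_id: np.ndarray      # int
    icode: np.ndarray       # str, insertion code ('' if none)
    res_name: np.ndarray    # str
    atom_name: np.ndarray   # str
    element: np.ndarray     # str, upper-case
    coords: np.ndarray      # (n, 3) float, A
    radius: np.ndarray      # float, A

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        if n == 0:
            raise ValueError("structure has no atoms")
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(np.asarray(self.radius) <= 0):
            raise ValueError("every atom needs a positive van der Waals radius")

    def __len__(self) -> int:
        return len(self.atom_name)

    @property
    def chains(self) -> set[str]:
        return set(self.chain.tolist())

    def select_chain(self, chain_id: str) -> "Structure":
        mask = self.chain == chain_id
        if not mask.any():
            raise KeyError(f"chain {chain_id!r} not present (have {sorted(self.chains)})")
        return Structure(*(a[mask] for a in (
            self.chain, self.res_id, self.icode, self.res_name,
            self.atom_name, self.element)), self.coords[mask], self.radius[mask])

    @classmethod
    def from_atoms(cls, atoms, fallback_radius: float | None = None) -> "Structure":
        """Build from ``(chain, res_id, res_name, atom_name, element, x, y, z)`` rows."""
        rows = list(atoms)
        elem = np.array([str(a[4]).upper() for a in rows])
        return cls(
            chain=np.array([str(a[0]) for a in rows]),
            res_id=np.array([int(a[1]) for a in rows]),
            icode=np.array([""] * len(rows)),
            res_name=np.array([str(a[2]).upper() for a in rows]),
            atom_name=np.array([str(a[3]) for a in rows]),
            element=elem,
            coords=np.array([[a[5], a[6], a[7]] for a in rows], dtype=float),
            radius=_radii_for(elem, fallback_radius),
        )

    def residue_keys(self) -> np.ndarray:
        """Stable per-atom residue identifier ``chain:res_id:icode``."""
        return np.array([f"{c}:{r}:{i}" for c, r, i in
                         zip(self.chain, self.res_id, self.icode)])


def _radii_for(elements: np.ndarray, fallback_radius: float | None) -> np.ndarray:
    radii = np.empty(len(elements), dtype=float)
    for i, el in enumerate(elements):
        r = VDW_RADII.get(el)
        if r is None:
            if fallback_radius is None:
                raise ValueError(
                    f"no van der Waals radius for element {el!r}; "
                    "pass fallback_radius to accept a default")
            r = fallback_radius
        radii[i] = r
    return radii


def read_pdb(path, keep_hetero: bool = False,
             fallback_radius: float | None = None) -> Structure:
    """Parse a PDB file into a `Structure`.

    Waters are always dropped; other HETATM records only if
    ``keep_hetero``.  For alternate locations, only blank or 'A' altlocs
    are kept.  Unknown elements raise unless ``fallback_radius`` is given.
    """
    st = gemmi.read_structure(str(Path(path)), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    rows = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES or res.is_water():
                continue
            if res.het_flag == "H" and not keep_hetero:
                continue
            for atom in res:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                rows.append((chain.name, res.seqid.num, res.seqid.icode.strip(),
                             res.name, atom.name, atom.element.name.upper(),
                             atom.pos.x, atom.pos.y, atom.pos.z))
    if not rows:
        raise ValueError(f"{path}: no usable ATOM records")
    elem = np.array([r[5] for r in rows])
    return Structure(
        chain=np.array([r[0] for r in rows]),
        res_id=np.array([r[1] for r in rows]),
        icode=np.array([r[2] for r in rows]),
        res_name=np.array([r[3] for r in rows]),
        atom_name=np.array([r[4] for r in rows]),
        element=elem,
        coords=np.array([r[6:9] for r in rows], dtype=float),
        radius=_radii_for(elem, fallback_radius),
    )


def write_pdb(structure: Structure, path) -> Path:
    """Write the atom table as minimal PDB ATOM records."""
    path = Path(path)
    lines = []
    for i in range(len(structure)):
        x, y, z = structure.coords[i]
        name = structure.atom_name[i]
        # PDB convention: 1-2 char element names start in column 13
        name_f = f" {name:<3s}" if len(name) < 4 and len(structure.element[i]) == 1 \
            else f"{name:<4s}"
        lines.append(
            f"ATOM  {i + 1:5d} {name_f}{'':1s}{structure.res_name[i]:>3s} "
            f"{structure.chain[i]:1s}{structure.res_id[i]:4d}{structure.icode[i]:1s}"
            f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{structure.element[i]:>2s}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i       # golden angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley_sasa(structure: Structure, probe: float = 1.4,
                       n_points: int = 960) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-atom and per-residue solvent-accessible surface area (A^2).

    Returns ``(atom_sasa, residue_table)``; the table has one row per
    residue (chain, res_id, icode, res_name, sasa) in order of first
    appearance.  SASA converges as ``n_points`` grows; 960 points keep
    the discretisation error well under 1% for protein-sized atoms.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    pts = _sphere_points(n_points)
    coords = structure.coords
    radii = structure.radius + probe
    tree = cKDTree(coords)
    rmax = radii.max()
    atom_sasa = np.empty(len(structure))
    for i in range(len(structure)):
        ri = radii[i]
        nb = tree.query_ball_point(coords[i], ri + rmax)
        nb = [j for j in nb if j != i]
        test = coords[i] + ri * pts
        if nb:
            nb = np.array(nb)
            d2 = np.sum((coords[nb] - coords[i]) ** 2, axis=1)
            nb = nb[d2 < (ri + radii[nb]) ** 2]
        if len(nb):
            diff = test[:, None, :] - coords[nb][None, :, :]
            occluded = np.any(np.einsum("ijk,ijk->ij", diff, diff)
                              < radii[nb][None, :] ** 2, axis=1)
            frac = 1.0 - occluded.mean()
        else:
            frac = 1.0
        atom_sasa[i] = 4.0 * np.pi * ri * ri * frac

    keys = structure.residue_keys()
    order = pd.unique(keys)
    df = pd.DataFrame({
        "key": keys, "chain": structure.chain, "res_id": structure.res_id,
        "icode": structure.icode, "res_name": structure.res_name,
        "sasa": atom_sasa,
    })
    res = (df.groupby("key", sort=False)
             .agg(chain=("chain", "first"), res_id=("res_id", "first"),
                  icode=("icode", "first"), res_name=("res_name", "first"),
                  sasa=("sasa", "sum"))
             .loc[order]
             .reset_index(drop=True))
    return atom_sasa, res


def classify_polarity(residue_name: str) -> str:
    """'apolar' or 'polar' for a standard 3-letter residue name."""
    name = residue_name.upper()
    if name not in _STANDARD_RESIDUES:
        raise ValueError(f"unknown residue name {residue_name!r}")
    return "apolar" if name in APOLAR_RESIDUES else "polar"


@dataclass(frozen=True)
class HydrogenBond:
    donor_chain: str
    donor_res_id: int
    donor_res_name: str
    donor_atom: str
    acceptor_chain: str
    acceptor_res_id: int
    acceptor_res_name: str
    acceptor_atom: str
    distance: float      # A, heavy-atom donor-acceptor


@dataclass(frozen=True)
class InterfaceResidue:
    chain: str
    res_id: int
    icode: str
    res_name: str
    sasa_monomer: float       # A^2, isolated chain
    sasa_complex: float       # A^2, in the dimer
    buried: float             # A^2
    relative_buried: float    # %
    polarity: str
    hbond_partner: str | None = None    # "chain:res_id" on the other chain


@dataclass
class InterfaceReport:
    """Interface inventory of a two-chain complex."""

    residues: list[InterfaceResidue]
    total_buried: float               # A^2, both chains
    total_buried_per_monomer: float   # A^2, mean over the two chains
    n_residues: int
    pct_apolar: float
    hbonds: list[HydrogenBond] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.residues])


def detect_hbonds(dimer: Structure, chain_a: str, chain_b: str,
                  max_da: float = 3.5) -> list[HydrogenBond]:
    """Inter-chain hydrogen bonds by heavy-atom donor-acceptor distance.

    Donor and acceptor capability comes from residue templates (backbone
    N donates except in Pro; backbone O always accepts; sidechain N/O/S
    per standard chemistry).  Every (donor, acceptor) pair within
    ``max_da`` is reported; symmetry mates of a C2 dimer therefore appear
    as separate entries, and hydroxyls that can both donate and accept
    may pair in both directions.
    """
    a, b = dimer.select_chain(chain_a), dimer.select_chain(chain_b)

    def capability(st: Structure) -> tuple[np.ndarray, np.ndarray]:
        donor = np.zeros(len(st), dtype=bool)
        acceptor = np.zeros(len(st), dtype=bool)
        for i in range(len(st)):
            rn, an = st.res_name[i], st.atom_name[i]
            if an == "N" and rn != "PRO":
                donor[i] = True
            if an in ("O", "OXT"):
                acceptor[i] = True
            if an in _SIDECHAIN_DONORS.get(rn, ()):
                donor[i] = True
            if an in _SIDECHAIN_ACCEPTORS.get(rn, ()):
                acceptor[i] = True
        return donor, acceptor

    bonds: list[HydrogenBond] = []
    for don_st, acc_st in ((a, b), (b, a)):
        don_mask, _ = capability(don_st)
        _, acc_mask = capability(acc_st)
        di = np.flatnonzero(don_mask)
        ai = np.flatnonzero(acc_mask)
        if not len(di) or not len(ai):
            continue
        d = np.linalg.norm(don_st.coords[di][:, None, :] -
                           acc_st.coords[ai][None, :, :], axis=2)
        for p, q in zip(*np.nonzero(d <= max_da)):
            i, j = di[p], ai[q]
            bonds.append(HydrogenBond(
                donor_chain=str(don_st.chain[i]), donor_res_id=int(don_st.res_id[i]),
                donor_res_name=str(don_st.res_name[i]), donor_atom=str(don_st.atom_name[i]),
                acceptor_chain=str(acc_st.chain[j]), acceptor_res_id=int(acc_st.res_id[j]),
                acceptor_res_name=str(acc_st.res_name[j]),
                acceptor_atom=str(acc_st.atom_name[j]),
                distance=float(d[p, q])))
    bonds.sort(key=lambda h: (h.donor_chain, h.donor_res_id, h.acceptor_res_id))
    return bonds


def interface_residues(dimer: Structure, chain_a: str, chain_b: str,
                       min_buried: float = 0.1, probe: float = 1.4,
                       n_points: int = 960,
                       max_da: float = 3.5) -> InterfaceReport:
    """Inventory of interface residues by SASA differencing.

    SASA is computed for each isolated chain and for the complex; any
    residue burying more than ``min_buried`` A^2 is an interface
    residue.  Relative burial is buried / SASA in the free monomer.
    H-bond partners are annotated from `detect_hbonds`.
    """
    a, b = dimer.select_chain(chain_a), dimer.select_chain(chain_b)
    _, res_a = shrake_rupley_sasa(a, probe=probe, n_points=n_points)
    _, res_b = shrake_rupley_sasa(b, probe=probe, n_points=n_points)
    _, res_ab = shrake_rupley_sasa(dimer, probe=probe, n_points=n_points)

    mono = pd.concat([res_a, res_b], ignore_index=True)
    key = lambda f: f["chain"].astype(str) + ":" + f["res_id"].astype(str) \
        + ":" + f["icode"].astype(str)
    mono = mono.set_index(key(mono))
    comp = res_ab.set_index(key(res_ab))

    hbonds = detect_hbonds(dimer, chain_a, chain_b, max_da=max_da)
    partner: dict[tuple[str, int], str] = {}
    for h in hbonds:
        partner.setdefault((h.donor_chain, h.donor_res_id),
                           f"{h.acceptor_chain}:{h.acceptor_res_id}")
        partner.setdefault((h.acceptor_chain, h.acceptor_res_id),
                           f"{h.donor_chain}:{h.donor_res_id}")

    residues: list[InterfaceResidue] = []
    per_chain_buried = {chain_a: 0.0, chain_b: 0.0}
    for k, row in mono.iterrows():
        sasa_c = float(comp.loc[k, "sasa"]) if k in comp.index else 0.0
        buried = float(row["sasa"]) - sasa_c
        if buried <= min_buried:
            continue
        rel = 100.0 * buried / row["sasa"] if row["sasa"] > 0 else 0.0
        try:
            pol = classify_polarity(row["res_name"])
        except ValueError:
            pol = "polar"   # non-standard residues counted as polar
        residues.append(InterfaceResidue(
            chain=str(row["chain"]), res_id=int(row["res_id"]),
            icode=str(row["icode"]), res_name=str(row["res_name"]),
            sasa_monomer=float(row["sasa"]), sasa_complex=sasa_c,
            buried=buried, relative_buried=min(rel, 100.0), polarity=pol,
            hbond_partner=partner.get((str(row["chain"]), int(row["res_id"])))))
        per_chain_buried[str(row["chain"])] += buried

    total = sum(per_chain_buried.values())
    n = len(residues)
    pct_apolar = 100.0 * sum(r.polarity == "apolar" for r in residues) / n if n else 0.0
    return InterfaceReport(
        residues=residues, total_buried=total,
        total_buried_per_monomer=total / 2.0, n_residues=n,
        pct_apolar=pct_apolar, hbonds=hbonds)
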