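"""Feature-table to SMILES conversion (RDKit-backed).

The writer materializes the per-position feature table as a molecular graph:
backbone carbons in numbering order, carbonyl/hydroxyl oxidation states,
olefins with cis/trans geometry, branch methyls, the macrolactone ester, the
glycine amide and starter fragment, and hydroxyl decorations (carbamate,
sulfate, glycosyl as O-methyl placeholder).

Stereochemistry: l/d hydroxyl labels are emitted as fixed tetrahedral parity
tags (l → counter-clockwise, d → clockwise, with neighbors enumerated in
graph-construction order).  This is a stable, documented convention for
round-tripping the labels — it is not a CIP assignment.
"""

from __future__ import annotations

from rdkit import Chem

from .bgc_model import AMINO_ACID_CONTRIBUTIONS
from .errors import StructureError


def to_smiles(structure) -> str:
    """Render an :class:`AssembledStructure` as a canonical SMILES string."""
    mol = Chem.RWMol()
    idx: dict[int, int] = {}
    positions = sorted(structure.features)
    if not positions:
        raise StructureError("empty feature table")
    for p in positions:
        idx[p] = mol.AddAtom(Chem.Atom(6))

    aa_end = None
    if structure.amino_acids and not structure.hydrolyzed:
        aa_end = 2 * structure.n_post_nrps + sum(
            AMINO_ACID_CONTRIBUTIONS[a]["backbone_carbons"]
            for a in structure.amino_acids)

    olefins = structure.olefins
    stereo_bonds = []
    for p, q in zip(positions, positions[1:]):
        if q != p + 1:
            raise StructureError(f"backbone gap between C{p} and C{q}")
        if structure.tail_extension and p == aa_end:
            continue  # the amide nitrogen bridges this junction
        if p in olefins:
            bond_idx = mol.AddBond(idx[p], idx[q], Chem.BondType.DOUBLE) - 1
            if olefins[p] in ("cis", "trans"):
                stereo_bonds.append((bond_idx, p, olefins[p]))
        else:
            mol.AddBond(idx[p], idx[q], Chem.BondType.SINGLE)

    ring_target = structure.ring_closure[1] if structure.ring_closure else None
    hydroxyl_oxygens: dict[int, int] = {}
    for p in positions:
        f = structure.features[p]
        if f.state in ("carboxyl", "ester_carbonyl", "ketone", "carbonyl"):
            o = mol.AddAtom(Chem.Atom(8))
            mol.AddBond(idx[p], o, Chem.BondType.DOUBLE)
            if f.state == "carboxyl":
                oh = mol.AddAtom(Chem.Atom(8))
                mol.AddBond(idx[p], oh, Chem.BondType.SINGLE)
        elif f.state == "hydroxyl":
            o = mol.AddAtom(Chem.Atom(8))
            mol.AddBond(idx[p], o, Chem.BondType.SINGLE)
            hydroxyl_oxygens[p] = o
            if f.stereo == "L":
                mol.GetAtomWithIdx(idx[p]).SetChiralTag(
                    Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
            elif f.stereo == "D":
                mol.GetAtomWithIdx(idx[p]).SetChiralTag(
                    Chem.ChiralType.CHI_TETRAHEDRAL_CW)
        for _ in f.branch_methyls:
            c = mol.AddAtom(Chem.Atom(6))
            mol.AddBond(idx[p], c, Chem.BondType.SINGLE)
        if f.branch_mode == "exo":
            c = mol.AddAtom(Chem.Atom(6))
            mol.AddBond(idx[p], c, Chem.BondType.DOUBLE)

    # Macrolactone: C1(=O)-O-C(target); the target's hydroxyl oxygen is the
    # ester oxygen.
    if ring_target is not None:
        o_ester = hydroxyl_oxygens.get(ring_target)
        if o_ester is None:
            raise StructureError("ring-closure target bears no hydroxyl oxygen")
        mol.AddBond(o_ester, idx[1], Chem.BondType.SINGLE)

    # Amine/amide nitrogen and starter fragment.
    n_atom = None
    if aa_end is not None:
        n_atom = mol.AddAtom(Chem.Atom(7))
        mol.AddBond(idx[aa_end], n_atom, Chem.BondType.SINGLE)
        if structure.tail_extension:
            mol.AddBond(n_atom, idx[aa_end + 1], Chem.BondType.SINGLE)
    if structure.starter is not None:
        if structure.amino_acids:
            if structure.tail_extension:
                # starter acylates the end of the tail extension, not the N
                _attach_starter(mol, idx[positions[-1]], structure.starter)
            elif n_atom is not None:
                _attach_starter(mol, n_atom, structure.starter)
        else:
            # The starter's carbonyl/α pair is already the primer at the end
            # of the numbered backbone; append its remaining carbons linearly.
            prev = idx[positions[-1]]
            for _ in range(max(structure.starter.carbon_count - 2, 0)):
                c = mol.AddAtom(Chem.Atom(6))
                mol.AddBond(prev, c, Chem.BondType.SINGLE)
                prev = c

    # Decorations on hydroxyl oxygens.
    for p, f in structure.features.items():
        for deco in f.decorations:
            if deco == "macrolactone":
                continue
            o = hydroxyl_oxygens.get(p)
            if o is None:
                raise StructureError(f"decoration {deco!r} at C{p} without hydroxyl")
            if deco == "carbamate":
                c = mol.AddAtom(Chem.Atom(6))
                mol.AddBond(o, c, Chem.BondType.SINGLE)
                o2 = mol.AddAtom(Chem.Atom(8))
                mol.AddBond(c, o2, Chem.BondType.DOUBLE)
                n = mol.AddAtom(Chem.Atom(7))
                mol.AddBond(c, n, Chem.BondType.SINGLE)
            elif deco == "sulfate":
                s = mol.AddAtom(Chem.Atom(16))
                mol.AddBond(o, s, Chem.BondType.SINGLE)
                for _ in range(2):
                    ox = mol.AddAtom(Chem.Atom(8))
                    mol.AddBond(s, ox, Chem.BondType.DOUBLE)
                oh = mol.AddAtom(Chem.Atom(8))
                mol.AddBond(s, oh, Chem.BondType.SINGLE)
            elif deco == "glycosyl":
                c = mol.AddAtom(Chem.Atom(6))
                mol.AddBond(o, c, Chem.BondType.SINGLE)

    m = mol.GetMol()
    Chem.SanitizeMol(m)
    for bond_idx, lower, geometry in stereo_bonds:
        bond = m.GetBondWithIdx(bond_idx)
        a, b = idx[lower], idx[lower + 1]
        left = _backbone_neighbor(m, a, exclude=b)
        right = _backbone_neighbor(m, b, exclude=a)
        if left is None or right is None:
            continue
        bond.SetStereoAtoms(left, right)
        bond.SetStereo(Chem.BondStereo.STEREOZ if geometry == "cis"
                       else Chem.BondStereo.STEREOE)
    return Chem.MolToSmiles(m)


def _backbone_neighbor(mol, atom_idx: int, exclude: int):
    for nb in mol.GetAtomWithIdx(atom_idx).GetNeighbors():
        if nb.GetIdx() != exclude and nb.GetAtomicNum() == 6:
            return nb.GetIdx()
    for nb in mol.GetAtomWithIdx(atom_idx).GetNeighbors():
        if nb.GetIdx() != exclude:
            return nb.GetIdx()
    return None


def _attach_starter(mol: Chem.RWMol, n_atom: int, starter) -> None:
    """Acylate the chain nitrogen with the starter fragment.

    3-methylcrotonate: N-C(=O)-CH=C(CH3)2; the 3-methyl-3-butenoate isomer:
    N-C(=O)-CH2-C(CH3)=CH2 (terminal olefin); generic starters fall back to
    a linear acyl chain of the right carbon count.
    """
    c1 = mol.AddAtom(Chem.Atom(6))
    mol.AddBond(n_atom, c1, Chem.BondType.SINGLE)
    o = mol.AddAtom(Chem.Atom(8))
    mol.AddBond(c1, o, Chem.BondType.DOUBLE)
    remaining = starter.carbon_count - 1
    if starter.monomer_id == "3-methylcrotonic acid":
        c2 = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(c1, c2, Chem.BondType.SINGLE)
        c3 = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(c2, c3, Chem.BondType.DOUBLE)
        for _ in range(2):
            c = mol.AddAtom(Chem.Atom(6))
            mol.AddBond(c3, c, Chem.BondType.SINGLE)
    elif starter.monomer_id == "3-methyl-3-butenoic acid":
        c2 = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(c1, c2, Chem.BondType.SINGLE)
        c3 = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(c2, c3, Chem.BondType.SINGLE)
        cme = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(c3, cme, Chem.BondType.SINGLE)
        cterm = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(c3, cterm, Chem.BondType.DOUBLE)
    else:
        prev = c1
        for _ in range(remaining):
            c = mol.AddAtom(Chem.Atom(6))
            mol.AddBond(prev, c, Chem.BondType.SINGLE)
            prev = c
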