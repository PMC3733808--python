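import pytest

from edqc.model_io import Atom, Residue, ResidueKey, StructureModel


def pdb_record(
    rec,
    serial,
    name,
    comp,
    chain,
    seq,
    x,
    y,
    z,
    occ=1.0,
    b=20.0,
    alt="",
    icode="",
    element=None,
):
    """Format one fixed-column ATOM/HETATM record."""
    element = (element or name[0]).upper()
    nm = f"{name:<4}" if len(name) == 4 or len(element) == 2 else f" {name:<3}"
    return (
        f"{rec:<6}{serial:>5} {nm}{alt:1}{comp:>3} {chain:1}{seq:>4}{icode:1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2}"
    )


def make_residue(comp, chain, seq, positions, hetero=True, occ=1.0, b=20.0, element="C"):
    key = ResidueKey(chain_id=chain, res_seq=seq, insertion_code="", comp_id=comp)
    atoms = [
        Atom(
            serial=i + 1,
            name=f"{element}{i + 1}"[:4],
            element=element,
            alt_loc="",
            position=tuple(float(v) for v in p),
            occupancy=occ,
            b_factor=b,
            is_hetero=hetero,
        )
        for i, p in enumerate(positions)
    ]
    from edqc.model_io import WATER_CODES

    return Residue(key=key, atoms=atoms, is_polymer=not hetero, is_water=comp in WATER_CODES)


def make_model(residues, model_id="TEST"):
    return StructureModel(model_id=model_id, residues=list(residues))


@pytest.fixture
def tiny_pdb_text():
    lines = [
        pdb_record("ATOM", 1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_record("ATOM", 2, "CA", "GLY", "A", 1, 1.5, 0.0, 0.0),
        pdb_record("ATOM", 3, "C", "GLY", "A", 2, 3.0, 0.0, 0.0),
        "TER",
        pdb_record("HETATM", 4, "C1", "LIG", "B", 100, 0.0, 6.0, 0.0),
        pdb_record("HETATM", 5, "O1", "HOH", "B", 200, 9.0, 9.0, 9.0, element="O"),
        "END",
    ]
    return "\n".join(lines) + "\n"
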