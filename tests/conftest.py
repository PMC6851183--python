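from __future__ import annotations

import pytest

from ndpdesign import EIIPTable


@pytest.fixture(scope="session")
def table() -> EIIPTable:
    return EIIPTable.default()


def pdb_line(serial: int, name: str, resname: str, chain: str, resseq: int,
             x: float, y: float, z: float, element: str,
             record: str = "ATOM") -> str:
    """One well-formed PDB coordinate line."""
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:5d} {nm} {resname:>3s} {chain}{resseq:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


def make_pdb(atoms: list[tuple], multi_model: bool = False) -> str:
    """Minimal PDB text from (name, resname, chain, resseq, x, y, z, element)
    tuples; ``multi_model`` wraps the same atoms in two MODEL blocks with the
    second model shifted, to exercise first-model loading."""
    lines = []
    if multi_model:
        lines.append("MODEL        1")
    for i, (name, resname, chain, resseq, x, y, z, element) in \
            enumerate(atoms, 1):
        lines.append(pdb_line(i, name, resname, chain, resseq, x, y, z,
                              element))
    if multi_model:
        lines.append("ENDMDL")
        lines.append("MODEL        2")
        for i, (name, resname, chain, resseq, x, y, z, element) in \
                enumerate(atoms, 1):
            lines.append(pdb_line(i, name, resname, chain, resseq,
                                  x + 100.0, y, z, element))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
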