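"""Shared fixtures: synthetic PDB builders and small planted alignments."""

from __future__ import annotations

import numpy as np
import pytest

from chapdock.synthetic import PlantedPottsSpec, generate_paired_msa

_PDB_ATOM = ("ATOM  {serial:>5d} {name:^4s}{alt:1s}{res:>3s} {chain:1s}"
             "{resseq:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}"
             "{occ:>6.2f}{b:>6.2f}          {elem:>2s}")


def pdb_atom_line(serial, name, res, chain, resseq, xyz, alt=" ", icode=" ",
                  occ=1.0, b=0.0, elem=None) -> str:
    if elem is None:
        elem = name.strip()[0]
    return _PDB_ATOM.format(serial=serial, name=name, alt=alt, res=res,
                            chain=chain, resseq=resseq, icode=icode,
                            x=xyz[0], y=xyz[1], z=xyz[2], occ=occ, b=b,
                            elem=elem)


def make_ca_pdb(residues, chain="A") -> str:
    """PDB text with one Cα per residue.

    ``residues`` is a list of (resseq, three-letter name, (x, y, z)).
    """
    lines = []
    for i, (resseq, res, xyz) in enumerate(residues, start=1):
        lines.append(pdb_atom_line(i, " CA ", res, chain, resseq, xyz))
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_fullatom_residue_pdb(extra_shell=False) -> str:
    """A single full-atom alanine, optionally surrounded by a burying shell
    of dummy alanine Cβ atoms (as a second residue ring)."""
    # idealized alanine heavy-atom geometry (Å)
    atoms = [
        (" N  ", (-0.525, 1.363, 0.000)),
        (" CA ", (0.000, 0.000, 0.000)),
        (" C  ", (1.526, 0.000, 0.000)),
        (" O  ", (2.153, -1.062, 0.000)),
        (" CB ", (-0.507, -0.785, -1.207)),
    ]
    lines = []
    serial = 1
    for name, xyz in atoms:
        lines.append(pdb_atom_line(serial, name, "ALA", "A", 1, xyz))
        serial += 1
    if extra_shell:
        # bury residue 1 under densely packed concentric layers of carbon
        # atoms (a hollow shell would leave an internal cavity the probe can
        # still roll over)
        rng = np.random.default_rng(0)
        resseq = 2
        for radius, n in ((3.2, 60), (4.8, 140), (6.4, 260), (8.0, 400)):
            pts = rng.normal(size=(n, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            for p in pts:
                lines.append(pdb_atom_line(serial, " CB ", "ALA", "A", resseq,
                                           tuple(0.5 + radius * p)))
                serial += 1
                resseq += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def planted_families():
    """Small planted-coupling families shared by the slower DCA tests."""
    spec = PlantedPottsSpec(
        n_a=12, n_b=12,
        planted_pairs=[(3, 5), (8, 10)],
        coupling=3.0,
        n_organisms=150,
        paralog_distribution=(1.0,),       # single copy: deterministic match
        burn_in=300,
        seed=21,
    )
    fam_a, fam_b, truth = generate_paired_msa(spec)
    return fam_a, fam_b, truth
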