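"""Reading structures and alignments into the package data model, and writing
analysis products.

Structures are reduced to one bead per residue at the Cα position, the
resolution at which the rigid-body docking model operates.  Alignments are
kept as integer-encoded arrays over the 21-letter alphabet (20 amino acids
plus gap) used by the Potts-model machinery.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.PDB import PDBParser

__all__ = [
    "AA_ALPHABET",
    "GAP",
    "DEFAULT_CHARGES",
    "RigidBodyStructure",
    "FamilyMSA",
    "PairedMSA",
    "read_structure",
    "read_family_msa",
    "ContactPrediction",
    "write_contact_table",
    "read_contact_table",
    "encode_sequences",
    "decode_sequences",
]

#: Canonical ordering of the 21-state alphabet: gap first, then the 20 amino acids.
AA_ALPHABET = "-ACDEFGHIKLMNPQRSTVWY"
GAP = 0

_AA_TO_INT = {a: i for i, a in enumerate(AA_ALPHABET)}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Per-residue charges (elementary charges) for the screened electrostatics.
#: Aspartate/glutamate carry -1, lysine/arginine +1 and histidine +0.5; the
#: table is configurable because the protonation state of histidine at neutral
#: pH is genuinely ambiguous.
DEFAULT_CHARGES = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}


@dataclass
class RigidBodyStructure:
    """One rigid binding partner: Cα bead coordinates plus residue metadata.

    Residue identifiers keep the author numbering of the source PDB so that
    reported contacts can be read directly in the reference (e.g. *E. coli*
    DnaK/DnaJ) numbering.
    """

    residue_ids: np.ndarray          # (n,) int, strictly increasing
    residue_types: np.ndarray        # (n,) unicode, one-letter codes
    coords: np.ndarray               # (n, 3) float, Å
    charges: np.ndarray              # (n,) float, elementary charges
    label: str = ""

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.residue_types = np.asarray(self.residue_types, dtype="U1")
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.residue_ids)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} residues"
            )
        if len(self.residue_types) != n or len(self.charges) != n:
            raise ValueError("residue_types/charges length mismatch")
        if n > 1 and not np.all(np.diff(self.residue_ids) > 0):
            raise ValueError("residue_ids must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_ids)

    @property
    def center_of_mass(self) -> np.ndarray:
        """Equal-mass centroid of the Cα beads."""
        return self.coords.mean(axis=0)

    def index_of(self, residue_id: int) -> int:
        idx = np.searchsorted(self.residue_ids, residue_id)
        if idx >= len(self) or self.residue_ids[idx] != residue_id:
            raise KeyError(f"residue {residue_id} not in structure {self.label!r}")
        return int(idx)


def read_structure(
    pdb_text: str,
    chain: str,
    residue_range: tuple[int, int],
    charge_table: dict[str, float] | None = None,
    model: int = 0,
    label: str | None = None,
) -> RigidBodyStructure:
    """Extract a Cα-bead rigid body from PDB coordinate records.

    Parameters
    ----------
    pdb_text:
        Full text of a PDB file (coordinate records are sufficient).
    chain:
        Chain identifier to read.
    residue_range:
        Inclusive ``(first, last)`` interval in author numbering.  Every
        residue in the interval must be present with a Cα atom; gaps are a
        hard error listing the missing residues.
    charge_table:
        Mapping one-letter code -> charge; defaults to ``DEFAULT_CHARGES``.
    model:
        Model index for multi-model (NMR) files.

    Returns
    -------
    RigidBodyStructure with one bead per residue of the requested range, in
    increasing residue order.
    """
    if charge_table is None:
        charge_table = DEFAULT_CHARGES
    lo, hi = residue_range
    if lo > hi:
        raise ValueError(f"empty residue range {lo}-{hi}")

    parser = PDBParser(QUIET=True)
    struct = parser.get_structure("s", io.StringIO(pdb_text))
    models = list(struct)
    if model >= len(models):
        raise ValueError(f"model {model} not present ({len(models)} models)")
    mdl = models[model]
    if chain not in [c.id for c in mdl]:
        raise ValueError(f"chain {chain!r} not found in PDB")
    ch = mdl[chain]

    found: dict[int, tuple[str, np.ndarray]] = {}
    for res in ch:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue
        if not (lo <= resseq <= hi):
            continue
        if icode.strip():
            warnings.warn(
                f"residue {resseq}{icode} has an insertion code; skipped"
            )
            continue
        if "CA" not in res:
            continue
        ca = res["CA"]
        if ca.is_disordered():
            # pick the altloc with highest occupancy
            ca = max(ca.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
        one = _THREE_TO_ONE.get(res.get_resname())
        if one is None:
            warnings.warn(f"nonstandard residue {res.get_resname()} {resseq}; skipped")
            continue
        found[resseq] = (one, np.asarray(ca.get_coord(), dtype=float))

    missing = [i for i in range(lo, hi + 1) if i not in found]
    if missing:
        raise ValueError(
            f"missing residues in chain {chain} range {lo}-{hi}: "
            + ", ".join(map(str, missing))
        )

    ids = np.arange(lo, hi + 1)
    types = np.array([found[i][0] for i in ids], dtype="U1")
    coords = np.array([found[i][1] for i in ids])
    charges = np.array([charge_table.get(t, 0.0) for t in types])
    return RigidBodyStructure(ids, types, coords, charges,
                              label=label or f"chain {chain} {lo}-{hi}")


def encode_sequences(rows: list[str]) -> np.ndarray:
    """Integer-encode aligned rows over ``AA_ALPHABET``.

    Nonstandard letters (B, Z, X, U, O, ...) and '.' are mapped to the gap
    state with a warning, matching how the Potts machinery treats uninformative
    symbols.
    """
    n_bad = 0
    out = np.zeros((len(rows), len(rows[0]) if rows else 0), dtype=np.int8)
    for i, row in enumerate(rows):
        for j, c in enumerate(row.upper()):
            v = _AA_TO_INT.get(c)
            if v is None:
                if c not in ".-":
                    n_bad += 1
                v = GAP
            out[i, j] = v
    if n_bad:
        warnings.warn(f"{n_bad} nonstandard letters mapped to gap")
    return out


def decode_sequences(seqs: np.ndarray) -> list[str]:
    return ["".join(AA_ALPHABET[v] for v in row) for row in np.asarray(seqs)]


@dataclass
class FamilyMSA:
    """One protein family's alignment with per-row organism labels."""

    sequences: np.ndarray            # (M, N) int8 over the 21-state alphabet
    organism_ids: np.ndarray         # (M,) organism identifier per row
    labels: np.ndarray               # (M,) row identifiers
    n_removed: int = 0               # rows dropped by the gap filter

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        self.organism_ids = np.asarray(self.organism_ids)
        self.labels = np.asarray(self.labels)
        if self.sequences.ndim != 2:
            raise ValueError("sequences must be a 2-D array")
        m = self.sequences.shape[0]
        if len(self.organism_ids) != m or len(self.labels) != m:
            raise ValueError("organism_ids/labels length mismatch")
        if self.sequences.size and (
            self.sequences.min() < 0 or self.sequences.max() >= len(AA_ALPHABET)
        ):
            raise ValueError("sequence states outside the 21-letter alphabet")

    @property
    def n_rows(self) -> int:
        return self.sequences.shape[0]

    @property
    def width(self) -> int:
        return self.sequences.shape[1]


@dataclass
class PairedMSA:
    """Concatenated two-family alignment with a segment boundary.

    ``boundary`` is the first column of segment B, so segment A occupies
    columns ``[0, boundary)`` and segment B ``[boundary, N)``.  Weights are
    attached lazily by :func:`chapdock.coevolution.sequence_weights`.
    """

    sequences: np.ndarray            # (M, N_A + N_B) int8
    boundary: int
    organism_ids: np.ndarray
    labels_a: np.ndarray = None
    labels_b: np.ndarray = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        if not (0 < self.boundary < self.sequences.shape[1]):
            raise ValueError("boundary must split the alignment into two segments")
        if self.labels_a is None:
            self.labels_a = np.arange(self.sequences.shape[0])
        if self.labels_b is None:
            self.labels_b = np.arange(self.sequences.shape[0])

    @property
    def n_rows(self) -> int:
        return self.sequences.shape[0]

    @property
    def width(self) -> int:
        return self.sequences.shape[1]

    @property
    def neff(self) -> float:
        if self.weights is None:
            raise ValueError("weights not computed; call sequence_weights first")
        return float(self.weights.sum())


def read_family_msa(
    msa_text: str,
    taxonomy_table: dict[str, str] | str,
    fmt: str = "fasta",
    max_gap_fraction: float = 0.10,
    on_missing_organism: str = "error",
) -> FamilyMSA:
    """Read one family alignment and attach organism identifiers.

    Rows with a gap fraction strictly above ``max_gap_fraction`` are removed
    (the removal count is kept on the returned object).  ``taxonomy_table``
    maps row identifier -> organism id, either as a dict or as two-column TSV
    text.  ``on_missing_organism`` is ``"error"`` or ``"skip"`` (skip with a
    warning).
    """
    if isinstance(taxonomy_table, str):
        tax: dict[str, str] = {}
        for line in taxonomy_table.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed taxonomy line: {line!r}")
            tax[parts[0]] = parts[1]
    else:
        tax = dict(taxonomy_table)

    aln = AlignIO.read(io.StringIO(msa_text), fmt)
    rows, ids = [], []
    for rec in aln:
        rows.append(str(rec.seq))
        ids.append(rec.id)
    if not rows:
        raise ValueError("empty alignment")

    seqs = encode_sequences(rows)
    keep_ids, keep_rows, orgs = [], [], []
    n_removed = 0
    width = seqs.shape[1]
    for i, rid in enumerate(ids):
        gap_frac = np.count_nonzero(seqs[i] == GAP) / width
        # the raw gap characters, not the remapped nonstandard letters, decide
        # the filter; recompute from text to keep the rule exact
        gap_frac = (rows[i].count("-") + rows[i].count(".")) / width
        if gap_frac > max_gap_fraction:
            n_removed += 1
            continue
        if rid not in tax:
            if on_missing_organism == "skip":
                warnings.warn(f"no organism for row {rid!r}; skipped")
                continue
            raise KeyError(f"no organism for row {rid!r}")
        keep_ids.append(rid)
        keep_rows.append(seqs[i])
        orgs.append(tax[rid])

    if not keep_rows:
        raise ValueError("no rows retained after filtering")
    return FamilyMSA(
        sequences=np.array(keep_rows, dtype=np.int8),
        organism_ids=np.array(orgs),
        labels=np.array(keep_ids),
        n_removed=n_removed,
    )


@dataclass
class ContactPrediction:
    """One predicted inter-protein residue pair with its selection frequency."""

    column_a: int
    column_b: int
    residue_a: int | None = None     # author numbering in family A's reference
    residue_b: int | None = None
    frequency: float = 0.0
    sasa_a: float = np.nan
    sasa_b: float = np.nan
    retained: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError("frequency must be in [0, 1]")


_CONTACT_COLUMNS = [
    "residue_A", "residue_B", "selection_frequency", "SASA_A", "SASA_B",
    "retained_flag",
]


def write_contact_table(predictions: list[ContactPrediction], path) -> None:
    """Write predictions to TSV, ordered by frequency descending with
    lexicographic ``(residue_A, residue_B)`` tie-break."""
    rows = sorted(
        predictions,
        key=lambda p: (
            -p.frequency,
            p.residue_a if p.residue_a is not None else p.column_a,
            p.residue_b if p.residue_b is not None else p.column_b,
        ),
    )
    df = pd.DataFrame(
        [
            {
                "residue_A": p.residue_a if p.residue_a is not None else p.column_a,
                "residue_B": p.residue_b if p.residue_b is not None else p.column_b,
                "selection_frequency": p.frequency,
                "SASA_A": p.sasa_a,
                "SASA_B": p.sasa_b,
                "retained_flag": int(p.retained),
            }
            for p in rows
        ],
        columns=_CONTACT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_contact_table(path) -> list[ContactPrediction]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            ContactPrediction(
                column_a=int(r["residue_A"]),
                column_b=int(r["residue_B"]),
                residue_a=int(r["residue_A"]),
                residue_b=int(r["residue_B"]),
                frequency=float(r["selection_frequency"]),
                sasa_a=float(r["SASA_A"]),
                sasa_b=float(r["SASA_B"]),
                retained=bool(r["retained_flag"]),
            )
        )
    return out
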