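"""Contact maps, protein structures and the standard filtering rules.

A contact map is a binary, square, symmetric matrix over residue pairs;
two residues are in contact when their C-alpha or C-beta atoms lie within
a distance threshold, conventionally 8 Angstrom.  Maps are stored sparsely
as canonical ``i < j`` pairs (1-based residue numbering) with a contact
likelihood in [0, 1].

Predicted maps are cleaned with the two standard filters before any
evaluation or threading use: pairs with likelihood below 0.5 are dropped
(both boundaries inclusive: p >= 0.5 survives) and pairs closer than 6
residues in sequence are dropped (j - i >= 6 survives).
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ContactMap",
    "ProteinStructure",
    "FeatureTrack",
    "RRParseError",
    "read_rr",
    "write_rr",
    "read_structure",
    "write_structure",
    "native_contact_map",
    "filter_map",
    "normalize_likelihoods",
]

#: Kyte-Doolittle hydropathy scale, range [-4.5, 4.5].
KYTE_DOOLITTLE: Mapping[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

AA1 = "ACDEFGHIKLMNPQRSTVWY"

_AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}
_AA_3TO1 = {v: k for k, v in _AA_1TO3.items()}


class RRParseError(ValueError):
    """Raised for malformed RR contact rows; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class FeatureTrack:
    """Per-residue structural/sequence feature channels used for threading.

    ss: 3-state secondary structure codes in {H, E, C}.
    sa: relative solvent accessibility in [0, 1].
    phi, psi: backbone (virtual) torsion angles in degrees, (-180, 180].
    seq_profile, struct_profile: L x 20 row-stochastic matrices.
    hydro: Kyte-Doolittle hydropathy per residue.
    """

    ss: np.ndarray
    sa: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    seq_profile: np.ndarray
    struct_profile: np.ndarray
    hydro: np.ndarray

    def __post_init__(self):
        L = len(self.ss)
        for name in ("sa", "phi", "psi", "hydro"):
            if len(getattr(self, name)) != L:
                raise ValueError(f"feature channel {name} length mismatch")
        for name in ("seq_profile", "struct_profile"):
            prof = getattr(self, name)
            if prof.shape != (L, 20):
                raise ValueError(f"{name} must be L x 20")
            if not np.allclose(prof.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if prof.min() < -1e-12 or prof.max() > 1 + 1e-12:
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if self.sa.min() < -1e-12 or self.sa.max() > 1 + 1e-12:
            raise ValueError("sa must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ss)

    def to_dict(self) -> dict:
        return {
            "ss": "".join(self.ss.tolist()),
            "sa": self.sa.tolist(),
            "phi": self.phi.tolist(),
            "psi": self.psi.tolist(),
            "seq_profile": self.seq_profile.tolist(),
            "struct_profile": self.struct_profile.tolist(),
            "hydro": self.hydro.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureTrack":
        return cls(
            ss=np.array(list(d["ss"])),
            sa=np.asarray(d["sa"], dtype=float),
            phi=np.asarray(d["phi"], dtype=float),
            psi=np.asarray(d["psi"], dtype=float),
            seq_profile=np.asarray(d["seq_profile"], dtype=float),
            struct_profile=np.asarray(d["struct_profile"], dtype=float),
            hydro=np.asarray(d["hydro"], dtype=float),
        )


@dataclass(frozen=True)
class ProteinStructure:
    """Single-chain C-alpha (and optional C-beta) trace with sequence.

    Models built by coordinate copying mark unplaced residues with NaN
    coordinate rows; ``placed_mask`` exposes which residues carry
    coordinates.
    """

    id: str
    sequence: str
    ca: np.ndarray
    cb: np.ndarray | None = None
    features: FeatureTrack | None = None

    def __post_init__(self):
        ca = np.asarray(self.ca, dtype=float)
        object.__setattr__(self, "ca", ca)
        if ca.shape != (len(self.sequence), 3):
            raise ValueError("ca coordinate rows must match sequence length")
        if self.cb is not None:
            cb = np.asarray(self.cb, dtype=float)
            if cb.shape != ca.shape:
                raise ValueError("cb coordinate rows must match sequence length")
            object.__setattr__(self, "cb", cb)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def placed_mask(self) -> np.ndarray:
        return np.isfinite(self.ca).all(axis=1)

    def coords(self, atom_mode: str = "CB") -> np.ndarray:
        if atom_mode.upper() == "CB" and self.cb is not None:
            return self.cb
        return self.ca


@dataclass(frozen=True)
class ContactMap:
    """Sparse symmetric contact map over canonical 1-based ``i < j`` pairs."""

    length: int
    contacts: dict[tuple[int, int], float]
    atom_mode: str = "CB"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for (i, j), p in self.contacts.items():
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) outside canonical range for L={self.length}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"likelihood {p} outside [0,1] for pair ({i},{j})")

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return set(self.contacts)

    def to_matrix(self, binary: bool = True) -> np.ndarray:
        """Dense symmetric matrix (L x L, 0-based indexing)."""
        A = np.zeros((self.length, self.length))
        for (i, j), p in self.contacts.items():
            v = 1.0 if binary else p
            A[i - 1, j - 1] = v
            A[j - 1, i - 1] = v
        return A

    @classmethod
    def from_pairs(
        cls,
        length: int,
        pairs: Iterable[tuple[int, int, float]],
        atom_mode: str = "CB",
        meta: dict | None = None,
    ) -> "ContactMap":
        """Canonicalize arbitrary (i, j, p) triples: orient i < j, merge
        symmetric duplicates keeping the maximum likelihood."""
        contacts: dict[tuple[int, int], float] = {}
        for i, j, p in pairs:
            if i == j:
                raise ValueError(f"self-contact ({i},{i}) is not allowed")
            key = (i, j) if i < j else (j, i)
            if not (1 <= key[0] and key[1] <= length):
                raise ValueError(f"pair ({i},{j}) out of range for length {length}")
            prev = contacts.get(key)
            if prev is None or p > prev:
                contacts[key] = float(p)
        return cls(length=length, contacts=contacts, atom_mode=atom_mode,
                   meta=meta or {})


def read_rr(path: str | Path, length: int, atom_mode: str = "CB",
            raw_likelihood: bool = False) -> ContactMap:
    """Read a CASP RR-style contact file.

    Rows are ``i j [d_low d_high] p`` with 1-based indices; header lines
    (PFRMAT/TARGET/MODEL/END and ``#`` comments) and bare sequence lines
    are skipped.  Symmetric duplicates merge keeping the larger likelihood.

    With ``raw_likelihood=True`` scores outside [0, 1] are accepted
    (un-normalised coupling strengths); ``normalize_likelihoods`` must then
    be applied before evaluation.
    """
    triples: list[tuple[int, int, float]] = []
    raw_max = 0.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            head = line.split()[0].upper()
            if head in {"PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL",
                        "REMARK", "END"}:
                continue
            fields = line.split()
            if len(fields) == 1 and fields[0].isalpha():
                continue  # sequence line
            if len(fields) not in (3, 5):
                raise RRParseError(lineno, f"expected 3 or 5 fields, got {len(fields)}")
            try:
                i = int(fields[0])
                j = int(fields[1])
                p = float(fields[-1])
            except ValueError as exc:
                raise RRParseError(lineno, str(exc)) from None
            if i == j:
                raise RRParseError(lineno, f"self-contact ({i},{i})")
            if not (1 <= min(i, j) and max(i, j) <= length):
                raise RRParseError(lineno, f"pair ({i},{j}) out of range for length {length}")
            if p < 0 or (p > 1 and not raw_likelihood):
                raise RRParseError(
                    lineno,
                    f"likelihood {p} outside [0,1] (pass raw_likelihood=True "
                    "for un-normalised scores)")
            raw_max = max(raw_max, p)
            triples.append((i, j, p))
    if raw_likelihood and raw_max > 1.0:
        # store on a provisional [0,1] scale; caller must normalise before use
        triples = [(i, j, p / raw_max) for i, j, p in triples]
        meta = {"raw_likelihood_max": raw_max}
    else:
        meta = {}
    return ContactMap.from_pairs(length, triples, atom_mode=atom_mode, meta=meta)


def write_rr(cmap: ContactMap, path: str | Path) -> None:
    """Write a 5-column RR file; full float precision so reads round-trip."""
    with open(path, "w") as fh:
        for (i, j) in sorted(cmap.contacts):
            p = cmap.contacts[(i, j)]
            fh.write(f"{i} {j} 0 8 {p!r}\n")


def read_structure(path: str | Path, chain: str | None = None,
                   first_chain_only: bool = False) -> ProteinStructure:
    """Read a single-chain PDB coordinate file into a C-alpha/C-beta trace.

    Residues are ordered by residue number.  Missing C-beta atoms fall back
    to the C-alpha coordinate (the glycine convention).  A file with several
    chains raises unless ``chain`` or ``first_chain_only`` selects one.
    Chain breaks (non-consecutive residue numbers) emit a warning; residue
    indexing stays sequential.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    chains = sorted(set(atoms.chain_id))
    if chain is not None:
        if chain not in chains:
            raise ValueError(f"chain {chain!r} not present (have {chains})")
        sel_chain = chain
    elif len(chains) > 1:
        if not first_chain_only:
            raise ValueError(
                f"file has {len(chains)} chains {chains}; pass chain= or "
                "first_chain_only=True")
        sel_chain = chains[0]
    else:
        sel_chain = chains[0]
    atoms = atoms[atoms.chain_id == sel_chain]
    ca_atoms = atoms[atoms.atom_name == "CA"]
    if len(ca_atoms) == 0:
        raise ValueError(f"no CA atoms in {path}")
    order = np.argsort(ca_atoms.res_id, kind="stable")
    ca_atoms = ca_atoms[order]
    res_ids = ca_atoms.res_id
    if np.any(np.diff(res_ids) != 1):
        warnings.warn(f"chain breaks in {path}; residues renumbered sequentially")
    ca = np.asarray(ca_atoms.coord, dtype=float)
    seq = "".join(_AA_3TO1.get(rn, "X") for rn in ca_atoms.res_name)
    cb = ca.copy()
    cb_atoms = atoms[atoms.atom_name == "CB"]
    pos_of = {int(r): k for k, r in enumerate(res_ids)}
    for atom_i in range(len(cb_atoms)):
        k = pos_of.get(int(cb_atoms.res_id[atom_i]))
        if k is not None:
            cb[k] = cb_atoms.coord[atom_i]
    return ProteinStructure(id=Path(path).stem, sequence=seq, ca=ca, cb=cb)


def write_structure(s: ProteinStructure, path: str | Path) -> None:
    """Write the trace as PDB ATOM records (CA, plus CB where distinct).

    Unplaced residues (NaN coordinates) are omitted, so models keep their
    query residue numbering with gaps.
    """
    placed = s.placed_mask
    n_cb = 0
    if s.cb is not None:
        distinct = ~np.all(np.isclose(s.ca, s.cb, atol=1e-6), axis=1)
        distinct &= placed
        n_cb = int(distinct.sum())
    n_atoms = int(placed.sum()) + n_cb
    arr = AtomArray(n_atoms)
    k = 0
    for idx in np.flatnonzero(placed):
        res3 = _AA_1TO3.get(s.sequence[idx], "UNK")
        arr.chain_id[k] = "A"
        arr.res_id[k] = idx + 1
        arr.res_name[k] = res3
        arr.atom_name[k] = "CA"
        arr.element[k] = "C"
        arr.coord[k] = s.ca[idx]
        k += 1
        if s.cb is not None and not np.allclose(s.ca[idx], s.cb[idx], atol=1e-6):
            arr.chain_id[k] = "A"
            arr.res_id[k] = idx + 1
            arr.res_name[k] = res3
            arr.atom_name[k] = "CB"
            arr.element[k] = "C"
            arr.coord[k] = s.cb[idx]
            k += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def native_contact_map(s: ProteinStructure, threshold: float = 8.0,
                       sep_min: int = 6, atom_mode: str = "CB") -> ContactMap:
    """Native contact map: pairs within ``threshold`` Angstrom at sequence
    separation ``j - i >= sep_min``, likelihood 1."""
    coords = s.coords(atom_mode)
    L = len(s)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    ii, jj = np.triu_indices(L, k=sep_min)
    sel = dist[ii, jj] <= threshold
    contacts = {(int(i) + 1, int(j) + 1): 1.0
                for i, j in zip(ii[sel], jj[sel])}
    return ContactMap(length=L, contacts=contacts, atom_mode=atom_mode.upper())


def filter_map(m: ContactMap, p_min: float = 0.5, sep_min: int = 6) -> ContactMap:
    """Keep contacts with ``p >= p_min`` and ``j - i >= sep_min``.

    Both boundaries are inclusive; the operation is idempotent and its
    output is always a subset of its input.
    """
    contacts = {
        (i, j): p for (i, j), p in m.contacts.items()
        if p >= p_min and (j - i) >= sep_min
    }
    return replace(m, contacts=contacts)


def normalize_likelihoods(m: ContactMap) -> ContactMap:
    """Divide every likelihood by the map's maximum likelihood.

    Used for raw coupling-strength scores (e.g. direct coupling analysis)
    that do not live on a probability scale; afterwards the maximum is
    exactly 1.
    """
    if not m.contacts:
        raise ValueError("cannot normalize an empty contact map")
    pmax = max(m.contacts.values())
    if pmax <= 0:
        raise ValueError("cannot normalize a map whose likelihoods are all 0")
    contacts = {k: p / pmax for k, p in m.contacts.items()}
    return replace(m, contacts=contacts)


def hydropathy(sequence: str) -> np.ndarray:
    """Kyte-Doolittle hydropathy profile of a sequence (unknown -> 0)."""
    return np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in sequence])
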