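"""Backbone ingestion, dihedral geometry, sliding-window segments and superposition.

Protein chains are reduced to their N/CA/C backbone trace.  Local structure
is described by the (phi, psi) dihedral pair of each residue; fixed-length
windows of consecutive residues with fully defined angles become
:class:`DihedralSegment` objects, the raw material for structural clustering.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

#: CA-CA distance (Angstrom) beyond which two consecutive residues are
#: treated as a chain break; generous bound on trans-peptide geometry (~3.8 A).
CHAIN_BREAK_CA_CA = 4.5

_BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class Residue:
    """One residue of a backbone trace.

    ``complete`` is False when any of N/CA/C is missing; incomplete residues
    never contribute dihedral angles.
    """

    resnum: int
    aa: str
    n: np.ndarray | None
    ca: np.ndarray | None
    c: np.ndarray | None

    @property
    def complete(self) -> bool:
        return self.n is not None and self.ca is not None and self.c is not None


@dataclass
class BackboneChain:
    """Ordered backbone residues of one chain, with a structure label."""

    structure_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class DihedralSegment:
    """L consecutive residues described by their (phi, psi) angles.

    ``start`` is the 1-based index into the source chain's residue list;
    ``resnum_start``/``resnum_end`` carry author numbering for provenance.
    Angles are degrees in (-180, 180].
    """

    source: str
    chain_id: str
    start: int
    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    resnum_start: int = 0
    resnum_end: int = 0

    @property
    def L(self) -> int:
        return len(self.sequence)

    @property
    def angles(self) -> np.ndarray:
        """Interleaved (phi_1, psi_1, ..., phi_L, psi_L), shape (2L,)."""
        out = np.empty(2 * self.L)
        out[0::2] = self.phi
        out[1::2] = self.psi
        return out

    def residue_range(self) -> "ResidueRange":
        return ResidueRange(self.source, self.chain_id, self.resnum_start, self.resnum_end)


@dataclass(frozen=True)
class ResidueRange:
    """Author-numbered residue interval rendered as e.g. ``1jnrA:614-629``."""

    structure_id: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    def render(self) -> str:
        return f"{self.structure_id}{self.chain_id}:{self.start}-{self.end}"

    __str__ = render

    _RX = re.compile(r"^(?P<sid>.+?)(?P<chain>[A-Za-z0-9]):(?P<start>-?\d+)-(?P<end>-?\d+)$")

    @classmethod
    def parse(cls, text: str) -> "ResidueRange":
        m = cls._RX.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse residue range {text!r}")
        return cls(m["sid"], m["chain"], int(m["start"]), int(m["end"]))


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() and code in "ACDEFGHIKLMNPQRSTVWY" else "X"


def read_backbone(pdb_text: str, chain_id: str, structure_id: str = "") -> BackboneChain:
    """Parse N/CA/C coordinates of one chain from PDB-format text.

    HETATM residues are skipped; for alternate locations the highest-occupancy
    conformer wins (first on ties).  Residues missing any backbone atom are
    kept but flagged incomplete.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0 or all(len(model) == 0 for model in structure):
        raise ValueError("empty structure")
    model = structure[0]
    n_atoms = sum(len(res) for chain in model for res in chain)
    if n_atoms == 0:
        raise ValueError("empty structure")
    chain = model.find_chain(chain_id)
    if chain is None:
        raise KeyError(f"chain not found: {chain_id!r}")
    if not structure_id:
        structure_id = structure.name.lower() if structure.name else "unk"

    out = BackboneChain(structure_id=structure_id, chain_id=chain_id)
    for res in chain:
        if res.het_flag == "H":
            continue
        coords: dict[str, np.ndarray] = {}
        for name in _BACKBONE_ATOMS:
            best = None
            for atom in res:
                if atom.name != name:
                    continue
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is not None:
                coords[name] = np.array([best.pos.x, best.pos.y, best.pos.z])
        out.residues.append(
            Residue(
                resnum=res.seqid.num,
                aa=_one_letter(res.name),
                n=coords.get("N"),
                ca=coords.get("CA"),
                c=coords.get("C"),
            )
        )
    if not out.residues:
        raise ValueError("empty structure")
    return out


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion of p0-p1-p2-p3 in degrees, IUPAC sign, range (-180, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def compute_dihedrals(chain: BackboneChain) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue (phi, psi) with defined-flags.

    phi_k uses C(k-1)-N(k)-CA(k)-C(k); psi_k uses N(k)-CA(k)-C(k)-N(k+1).
    A dihedral touching an incomplete residue, a chain terminus, or a chain
    break (CA-CA distance > 4.5 A) is undefined.
    """
    n = len(chain)
    if n < 2:
        raise ValueError("chain length must be >= 2")
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)

    def _linked(k: int) -> bool:
        a, b = chain.residues[k], chain.residues[k + 1]
        if not (a.complete and b.complete):
            return False
        return float(np.linalg.norm(a.ca - b.ca)) <= CHAIN_BREAK_CA_CA

    for k in range(n):
        res = chain.residues[k]
        if not res.complete:
            continue
        if k > 0 and _linked(k - 1):
            prev = chain.residues[k - 1]
            phi[k] = dihedral_angle(prev.c, res.n, res.ca, res.c)
        if k < n - 1 and _linked(k):
            nxt = chain.residues[k + 1]
            psi[k] = dihedral_angle(res.n, res.ca, res.c, nxt.n)
    return phi, psi, ~np.isnan(phi), ~np.isnan(psi)


def extract_segments(chain: BackboneChain, L: int = 15) -> list[DihedralSegment]:
    """Harvest all L-residue sliding windows whose 2L angles are all defined.

    Windows step by one residue and overlap by L-1; the terminal phi/psi of a
    window come from the flanking residues, so a window lacking a defined
    flank angle (chain end, break, incomplete residue) is dropped.  A chain
    shorter than L yields an empty list.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    n = len(chain)
    if n < max(L, 2):
        return []
    phi, psi, _, _ = compute_dihedrals(chain)
    segments: list[DihedralSegment] = []
    for s in range(0, n - L + 1):
        wphi = phi[s : s + L]
        wpsi = psi[s : s + L]
        if np.isnan(wphi).any() or np.isnan(wpsi).any():
            continue
        residues = chain.residues[s : s + L]
        segments.append(
            DihedralSegment(
                source=chain.structure_id,
                chain_id=chain.chain_id,
                start=s + 1,
                sequence="".join(r.aa for r in residues),
                phi=wphi.copy(),
                psi=wpsi.copy(),
                resnum_start=residues[0].resnum,
                resnum_end=residues[-1].resnum,
            )
        )
    return segments


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Least-squares RMSD after optimal rigid superposition (proper rotation).

    Raises ``ValueError`` on mismatched point counts or n < 3.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("length mismatch: coordinate arrays must share shape (n, 3)")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite coordinates")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    # align_vectors returns the proper rotation minimising the RSSD;
    # degenerate (collinear) sets still yield an optimum, so silence the
    # non-uniqueness warning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / math.sqrt(a.shape[0]))


def segments_to_tsv(segments: list[DihedralSegment]) -> str:
    """Serialise segments as TSV: provenance, sequence, then phi/psi columns."""
    if not segments:
        return "source\tchain\tstart\tend\tsequence\n"
    L = segments[0].L
    cols = ["source", "chain", "start", "end", "sequence"]
    cols += [f"phi_{i+1}" for i in range(L)] + [f"psi_{i+1}" for i in range(L)]
    lines = ["\t".join(cols)]
    for seg in segments:
        row = [seg.source, seg.chain_id, str(seg.resnum_start), str(seg.resnum_end), seg.sequence]
        row += [f"{v:.6f}" for v in seg.phi] + [f"{v:.6f}" for v in seg.psi]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
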