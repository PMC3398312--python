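"""Seeded generators for every input the analysis pipeline consumes.

Three generators cover the pipeline end to end with no external downloads:

* :func:`backbone_from_dihedrals` builds ideal-geometry N/CA/C coordinates
  from (phi, psi) lists, giving an exact round-trip oracle for the dihedral
  code and PDB-format fixtures for the parser.
* :func:`generate_segment_population` plants well-separated dihedral
  clusters with known labels, the ground truth for single-pass clustering.
* :func:`generate_family_library` mutates a consensus sequence into a
  family, converts it to a log-odds PSSM, embeds it in a decoy-flanked
  target and surrounds it with random decoy PSSMs — a miniature stand-in
  for a PSI-BLAST-derived sequence-profile library with one planted motif.

Every generator is a pure function of its arguments (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import BackboneChain, DihedralSegment, Residue

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Ideal trans-peptide internal coordinates (Engh-Huber-style averages)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 0
    L: int = 15
    k_clusters: int = 3
    members_per_cluster: int = 50
    angular_noise_deg: float = 3.0
    family_size: int = 50
    per_site_mutation_rate: float = 0.1
    n_decoys: int = 200
    decoy_length_range: tuple[int, int] = (30, 120)

    def __post_init__(self) -> None:
        if min(self.L, self.k_clusters, self.members_per_cluster,
               self.family_size, self.n_decoys) < 1:
            raise ValueError("counts must be >= 1")
        if self.angular_noise_deg < 0:
            raise ValueError("noise must be >= 0")
        if not 0.0 <= self.per_site_mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position the atom bonded to c with given internal coordinates
    relative to the a-b-c frame."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def backbone_from_dihedrals(phi, psi, sequence: str,
                            structure_id: str = "synt", chain_id: str = "A") -> BackboneChain:
    """Build an ideal-geometry backbone realising the given dihedrals.

    phi[0] and psi[-1] are geometrically inert (no flanking atom exists) and
    may be NaN; all other angles must lie in (-180, 180].  Recomputing
    dihedrals from the result recovers the inputs to ~1e-6 degrees.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(sequence)
    if len(phi) != n or len(psi) != n:
        raise ValueError("phi, psi and sequence must share length")
    used = np.concatenate([phi[1:], psi[:-1]])
    if np.isnan(used).any() or (np.abs(used) > 180.0).any():
        raise ValueError("angles must be defined and in (-180, 180]")

    ang = math.radians(ANGLE_N_CA_C)
    atoms = [
        np.zeros(3),                                   # N1
        np.array([BOND_N_CA, 0.0, 0.0]),               # CA1
        np.array([BOND_N_CA - BOND_CA_C * math.cos(ang),
                  BOND_CA_C * math.sin(ang), 0.0]),    # C1
    ]
    for k in range(n - 1):
        n_k, ca_k, c_k = atoms[3 * k], atoms[3 * k + 1], atoms[3 * k + 2]
        n_next = _place_atom(n_k, ca_k, c_k, BOND_C_N, ANGLE_CA_C_N, psi[k])
        ca_next = _place_atom(ca_k, c_k, n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_next = _place_atom(c_k, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi[k + 1])
        atoms.extend([n_next, ca_next, c_next])

    chain = BackboneChain(structure_id=structure_id, chain_id=chain_id)
    for k, aa in enumerate(sequence):
        chain.residues.append(Residue(
            resnum=k + 1, aa=aa,
            n=atoms[3 * k], ca=atoms[3 * k + 1], c=atoms[3 * k + 2],
        ))
    return chain


def chain_to_pdb(chain: BackboneChain) -> str:
    """Render a backbone trace as minimal PDB-format ATOM records."""
    lines = []
    serial = 1
    for res in chain.residues:
        resname = _THREE.get(res.aa, "UNK")
        for name, pos in (("N", res.n), ("CA", res.ca), ("C", res.c)):
            if pos is None:
                continue
            # fixed PDB columns: serial 7-11, name 13-16, resname 18-20,
            # chain 22, resnum 23-26, xyz 31-54
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} {chain.chain_id}"
                f"{res.resnum:4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}           {name[0]:>1s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _wrap(deg: np.ndarray) -> np.ndarray:
    out = (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(out == -180.0, 180.0, out)


def generate_segment_population(spec: FixtureSpec, d_th: float = 30.0):
    """Plant ``k_clusters`` well-separated dihedral clusters with Gaussian
    angular noise; returns (segments, labels).

    Centroids are placed on a per-coordinate 360/k grid (random base, random
    per-coordinate cluster permutation), making every pairwise distance
    exactly 360/k degrees — 120 degrees for the default three clusters, far
    beyond any reasonable clustering threshold.  (Larger pairwise separations
    are impossible: under the RMS wrapped-angle metric the best attainable
    min pairwise distance for three points is below 150 degrees.)  Each
    cluster also gets a residue bias (one preferred amino acid per position,
    70% occupancy) so its sequence profile is informative.
    """
    rng = np.random.default_rng(spec.seed)

    k = spec.k_clusters
    sep = 360.0 / k if k > 1 else 360.0
    if k > 1 and sep < 2.0 * d_th:
        raise RuntimeError(
            f"cannot separate {k} clusters by more than twice d_th={d_th}")
    base = rng.uniform(-180.0, 180.0, size=2 * spec.L)
    offsets = np.empty((k, 2 * spec.L))
    for c in range(2 * spec.L):
        offsets[rng.permutation(k), c] = np.arange(k) * sep
    centroids = [_wrap(base + offsets[ci]) for ci in range(k)]

    aa = np.array(list(ALPHABET))
    segments: list[DihedralSegment] = []
    labels: list[int] = []
    order = []
    for ci in range(spec.k_clusters):
        preferred = rng.integers(0, 20, size=spec.L)
        for mi in range(spec.members_per_cluster):
            noise = rng.normal(0.0, spec.angular_noise_deg, size=2 * spec.L)
            ang = _wrap(centroids[ci] + noise)
            take_pref = rng.random(spec.L) < 0.7
            letters = np.where(take_pref, aa[preferred], aa[rng.integers(0, 20, size=spec.L)])
            order.append((ci, mi))
            segments.append(DihedralSegment(
                source=f"syn{ci}", chain_id="A", start=mi + 1,
                sequence="".join(letters),
                phi=ang[0::2].copy(), psi=ang[1::2].copy(),
                resnum_start=mi + 1, resnum_end=mi + spec.L,
            ))
            labels.append(ci)
    perm = rng.permutation(len(segments))
    return [segments[i] for i in perm], [labels[i] for i in perm]


def generate_family_library(consensus: str, spec: FixtureSpec):
    """Mutated family PSSM planted in a decoy library; returns
    (library, truth) where truth records the planted target id and offset.

    The family PSSM uses one pseudo-count per residue type over a uniform
    background — a crude stand-in for PSI-BLAST's estimation machinery,
    confined to fixture generation (propensity profiles never use
    pseudo-counts).  Decoy columns are symmetric-Dirichlet(0.5) frequencies
    converted to log-odds, giving realistic column sparsity.
    """
    from .profile_builder import SequenceProfile

    if any(c not in ALPHABET for c in consensus):
        raise ValueError("consensus must use the canonical alphabet")
    rng = np.random.default_rng(spec.seed)
    L = len(consensus)
    idx = {a: i for i, a in enumerate(ALPHABET)}

    # mutated family -> per-position counts
    counts = np.zeros((L, 20))
    family = []
    cons_idx = np.array([idx[c] for c in consensus])
    for _ in range(spec.family_size):
        res = cons_idx.copy()
        mutate = rng.random(L) < spec.per_site_mutation_rate
        if mutate.any():
            shifts = rng.integers(1, 20, size=int(mutate.sum()))
            res[mutate] = (res[mutate] + shifts) % 20
        family.append("".join(ALPHABET[i] for i in res))
        counts[np.arange(L), res] += 1.0

    freqs = (counts + 1.0) / (spec.family_size + 20.0)   # one pseudo-count
    family_scores = np.log(freqs / 0.05)

    def dirichlet_block(n_rows: int) -> np.ndarray:
        f = rng.dirichlet(np.full(20, 0.5), size=n_rows)
        return np.log(np.maximum(f, 1e-4) / 0.05)

    lo, hi = spec.decoy_length_range
    library: list[SequenceProfile] = []
    target_len = int(rng.integers(max(lo, L + 2), hi + 1))
    offset = int(rng.integers(0, target_len - L + 1))
    target_scores = dirichlet_block(target_len)
    target_scores[offset : offset + L] = family_scores
    target_seq_arr = [ALPHABET[int(j)] for j in np.argmax(target_scores, axis=1)]
    target_seq_arr[offset : offset + L] = list(consensus)
    library.append(SequenceProfile(
        identifier="planted_target",
        sequence="".join(target_seq_arr),
        scores=target_scores,
    ))
    for d in range(spec.n_decoys):
        n_len = int(rng.integers(lo, hi + 1))
        sc = dirichlet_block(n_len)
        library.append(SequenceProfile(
            identifier=f"decoy_{d:04d}",
            sequence="".join(ALPHABET[int(j)] for j in np.argmax(sc, axis=1)),
            scores=sc,
        ))
    truth = {
        "planted_id": "planted_target",
        "offset": offset,
        "family": family,
        "family_scores": family_scores,
    }
    return library, truth
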