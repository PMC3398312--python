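"""Compatibility of sequences with a structure-based profile.

The compatibility score of an L-symbol region threaded onto a structure
profile is

    S = sum_i ln pro_i(j_i)

with a fixed penalty of -9.21 (= ln 1e-4) whenever position i carries a
gap, an unknown residue, or a residue never observed at that position
(propensity 0).  High S means the sequence fits the amino-acid preferences
of the structural motif.

For a family alignment with a designated ancestral sequence, the score
difference

    dS = S_existing - S_ancestral

measures the direction of sequence evolution relative to the motif:
negative dS means the existing sequence is less compatible with the
structural profile than its ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile_builder import ALPHABET, _AA_INDEX, StructureProfile

#: ln(1e-4) at the 2-decimal precision used for reporting; the gap / zero
#: propensity / unknown-residue penalty
GAP_PENALTY = -9.21


@dataclass
class CompatibilityResult:
    identifier: str
    S: float
    terms: np.ndarray          # L per-position contributions
    n_gap_positions: int


@dataclass
class FamilyDeltaSet:
    ancestral_id: str
    ancestral_S: float
    members: list[tuple[str, float, float]]          # (id, S, deltaS)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


def score_sequence(profile: StructureProfile, region: str,
                   identifier: str = "") -> CompatibilityResult:
    """Score an L-symbol aligned region (may contain '-') against a profile."""
    if len(region) != profile.L:
        raise ValueError(f"region length {len(region)} != profile length {profile.L}")
    terms = np.empty(profile.L)
    n_gap = 0
    for i, sym in enumerate(region):
        j = _AA_INDEX.get(sym)
        if j is None:                       # gap or unknown residue
            terms[i] = GAP_PENALTY
            n_gap += 1
            continue
        pro = profile.propensities[i, j]
        terms[i] = np.log(pro) if pro > 0 else GAP_PENALTY
    return CompatibilityResult(identifier=identifier, S=float(terms.sum()),
                               terms=terms, n_gap_positions=n_gap)


def consensus_sequence(profile: StructureProfile) -> str:
    """Per-position argmax of the propensities; the gapless sequence with
    maximal S (terms are independent).  Ties break alphabetically; a
    position with no nonzero propensity is an error."""
    letters = []
    for i in range(profile.L):
        row = profile.propensities[i]
        if row.max() <= 0:
            raise ValueError(f"position {i+1} has no nonzero propensity")
        letters.append(ALPHABET[int(np.argmax(row))])  # argmax: first max = alphabetical
    return "".join(letters)


def _window(row: str, start: int, L: int) -> str:
    """L alignment columns (1-based inclusive start) of one alignment row."""
    return row[start - 1 : start - 1 + L]


def family_delta_scores(profile: StructureProfile,
                        family_alignment: dict[str, str],
                        ancestral_id: str,
                        window_start: int,
                        ancestral_sequence: str | None = None) -> FamilyDeltaSet:
    """Score every family member's window against the profile and take
    dS = S_member - S_ancestral.

    ``family_alignment`` maps identifiers to gapped rows of equal length;
    the window is the L alignment columns starting at ``window_start``
    (1-based).  Members whose window contains no amino acids are excluded
    with reason "empty region".  ``ancestral_sequence`` supplies an
    alternate (e.g. next-root) ancestor row not present in the alignment.
    """
    L = profile.L
    rows = list(family_alignment.values())
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment")
    if not 1 <= window_start <= width - L + 1:
        raise ValueError("window outside alignment")

    if ancestral_sequence is not None:
        anc_row = ancestral_sequence
        if len(anc_row) != width:
            raise ValueError("ancestral row length mismatch")
    else:
        if ancestral_id not in family_alignment:
            raise KeyError(f"ancestral id {ancestral_id!r} not in alignment")
        anc_row = family_alignment[ancestral_id]

    def has_residue(win: str) -> bool:
        return any(c in _AA_INDEX for c in win)

    anc_win = _window(anc_row, window_start, L)
    if not has_residue(anc_win):
        raise ValueError("ancestral lacks region; supply a next-root ancestor")
    s_r = score_sequence(profile, anc_win, ancestral_id).S

    members: list[tuple[str, float, float]] = []
    excluded: list[tuple[str, str]] = []
    for mid, row in family_alignment.items():
        if mid == ancestral_id and ancestral_sequence is None:
            continue
        win = _window(row, window_start, L)
        if not has_residue(win):
            excluded.append((mid, "empty region"))
            continue
        s_l = score_sequence(profile, win, mid).S
        members.append((mid, s_l, s_l - s_r))
    return FamilyDeltaSet(ancestral_id=ancestral_id, ancestral_S=s_r,
                          members=members, excluded=excluded)


def delta_set_to_tsv(ds: FamilyDeltaSet) -> str:
    """Per-member TSV: [id, S, excluded, reason, deltaS]."""
    lines = ["id\tS\texcluded\treason\tdeltaS"]
    lines.append(f"{ds.ancestral_id}\t{ds.ancestral_S:.6f}\t0\tancestral\t0.0")
    for mid, s, d in ds.members:
        lines.append(f"{mid}\t{s:.6f}\t0\t-\t{d:.6f}")
    for mid, reason in ds.excluded:
        lines.append(f"{mid}\tnan\t1\t{reason}\tnan")
    return "\n".join(lines) + "\n"


def delta_histogram(ds: FamilyDeltaSet, bin_width: float = 2.0) -> str:
    """Binned dS distribution as TSV."""
    d = np.array([x[2] for x in ds.members])
    if d.size == 0:
        return "d_low\td_high\tcount\n"
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    lines = ["d_low\td_high\tcount"]
    for k in range(len(counts)):
        lines.append(f"{edges[k]:.3f}\t{edges[k+1]:.3f}\t{counts[k]}")
    return "\n".join(lines) + "\n"
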