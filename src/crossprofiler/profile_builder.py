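"""Position-specific profiles: structure-based propensities and sequence PSSMs.

A *structure-based profile* summarises the member sequences of one
structural segment cluster as per-position amino-acid propensities

    pro_i(j) = p_i(j) / p(j)

where p_i(j) is the frequency of residue j at window position i over the
cluster members and p(j) the overall composition.  Counts are raw: no
sequence weighting and no pseudo-counts, so an amino acid absent at a
position has propensity exactly 0 (handled downstream by the log floor).

A *sequence profile* is a position x 20 log-odds matrix, typically read
from a PSI-BLAST ASCII PSSM; it encodes the evolutionary substitution
pattern of one protein family.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .structure_io import DihedralSegment

#: canonical internal residue order; all I/O re-maps at the boundary
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: the column order PSI-BLAST prints in its ASCII PSSM ("-Q" / makemat layout)
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class StructureProfile:
    cluster_id: int
    counts: np.ndarray              # L x 20 integers
    frequencies: np.ndarray         # L x 20, rows sum to 1 over counted residues
    background: np.ndarray          # 20, sums to 1
    propensities: np.ndarray        # L x 20, p_i(j)/p(j); 0 where residue absent

    @property
    def L(self) -> int:
        return self.counts.shape[0]


@dataclass
class SequenceProfile:
    identifier: str
    sequence: str
    scores: np.ndarray              # n x 20 log-odds, canonical order
    frequencies: np.ndarray | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def compute_background(segments: list[DihedralSegment]) -> np.ndarray:
    """Amino-acid composition p(j) over all residues of all segments.

    Non-canonical symbols ('X') are excluded; raises if nothing is countable.
    """
    counts = np.zeros(20)
    for seg in segments:
        for c in seg.sequence:
            i = _AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable residues")
    return counts / total


def build_structure_profile(members: list[str], background: np.ndarray,
                            cluster_id: int = 0) -> StructureProfile:
    """Raw-count propensity profile from equal-length member sequences.

    'X' is excluded per position from both numerator and denominator.
    Where the background of residue j is 0 (j never observed anywhere)
    the propensity is set to 0 by convention.
    """
    if not members:
        raise ValueError("no member sequences")
    L = len(members[0])
    if any(len(m) != L for m in members):
        raise ValueError(f"member length != {L}")
    background = np.asarray(background, dtype=float)
    counts = np.zeros((L, 20))
    for m in members:
        for i, c in enumerate(m):
            j = _AA_INDEX.get(c)
            if j is not None:
                counts[i, j] += 1
    row_tot = counts.sum(axis=1, keepdims=True)
    freqs = np.divide(counts, row_tot, out=np.zeros_like(counts), where=row_tot > 0)
    pro = np.divide(freqs, background[None, :],
                    out=np.zeros_like(freqs), where=background[None, :] > 0)
    return StructureProfile(cluster_id=cluster_id, counts=counts,
                            frequencies=freqs, background=background,
                            propensities=pro)


def logo_data(profile: StructureProfile) -> str:
    """Per-position frequency and information content (bits) as TSV.

    Information content is log2(20) minus the Shannon entropy of p_i; letter
    height is frequency times column information, the usual logo convention.
    """
    lines = ["position\tresidue\tfrequency\tinformation_bits"]
    max_bits = np.log2(20.0)
    for i in range(profile.L):
        p = profile.frequencies[i]
        nz = p[p > 0]
        info = max_bits + float(np.sum(nz * np.log2(nz)))
        for j, aa in enumerate(ALPHABET):
            if p[j] > 0:
                lines.append(f"{i+1}\t{aa}\t{p[j]:.6g}\t{p[j] * info:.6g}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM ingestion


def read_pssm(text: str, identifier: str = "pssm") -> SequenceProfile:
    """Parse a PSI-BLAST ASCII PSSM ("-Q" / makemat layout).

    Expects a header row of 20 one-letter codes followed by one row per
    position: index, residue, 20 integer log-odds and optionally 20
    percentage columns.  Columns are re-mapped from PSI-BLAST order to the
    canonical alphabet.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header_idx = None
    header_order = None
    for k, ln in enumerate(lines):
        toks = ln.split()
        letters = [t for t in toks if len(t) == 1 and t.isalpha()]
        if len(letters) >= 20 and set(letters[:20]) == set(ALPHABET):
            header_idx = k
            header_order = "".join(letters[:20])
            break
    if header_idx is None:
        raise ValueError("no PSSM header row of 20 residue letters found")

    perm = [header_order.index(a) for a in ALPHABET]
    scores_rows: list[list[float]] = []
    freq_rows: list[list[float]] = []
    seq_chars: list[str] = []
    for k, ln in enumerate(lines[header_idx + 1 :], start=1):
        toks = ln.split()
        if len(toks) < 2 or not toks[0].lstrip("-").isdigit():
            break  # footer (lambda/K lines etc.)
        res = toks[1]
        fields = toks[2:]
        try:
            vals = [float(v) for v in fields]
        except ValueError as exc:
            raise ValueError(f"malformed PSSM row {k}") from exc
        if len(vals) not in (20, 40, 42):
            raise ValueError(f"malformed PSSM row {k}")
        seq_chars.append(res if res in ALPHABET else "X")
        scores_rows.append([vals[p] for p in perm])
        if len(vals) >= 40:
            freq_rows.append([vals[20 + p] / 100.0 for p in perm])
    if not scores_rows:
        raise ValueError("empty PSSM body")
    return SequenceProfile(
        identifier=identifier,
        sequence="".join(seq_chars),
        scores=np.array(scores_rows),
        frequencies=np.array(freq_rows) if freq_rows else None,
    )


def write_pssm(profile: SequenceProfile) -> str:
    """Render a sequence profile in the PSI-BLAST ASCII layout (scores only)."""
    perm = [_AA_INDEX[a] for a in PSIBLAST_ORDER]
    out = io.StringIO()
    out.write("\nLast position-specific scoring matrix computed\n")
    out.write("            " + "   ".join(PSIBLAST_ORDER) + "\n")
    for i in range(profile.length):
        row = profile.scores[i][perm]
        cells = " ".join(f"{v:6.2f}" for v in row)
        out.write(f"{i+1:5d} {profile.sequence[i]} {cells}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# native profile TSV dialect (lossless round-trip, 6 significant digits)

_FMT = "{:.6g}"


def profile_to_tsv(profile: StructureProfile | SequenceProfile) -> str:
    """Serialise either profile type; numeric fields at 6 significant digits."""
    out = io.StringIO()
    if isinstance(profile, StructureProfile):
        out.write(f"#type\tstructure\n#id\t{profile.cluster_id}\n")
        out.write(f"#L\t{profile.L}\n#alphabet\t{ALPHABET}\n")
        out.write("#background\t" + "\t".join(_FMT.format(v) for v in profile.background) + "\n")
        out.write("position\tkind\t" + "\t".join(ALPHABET) + "\n")
        for i in range(profile.L):
            out.write(f"{i+1}\tcount\t" + "\t".join(_FMT.format(v) for v in profile.counts[i]) + "\n")
            out.write(f"{i+1}\tpro\t" + "\t".join(_FMT.format(v) for v in profile.propensities[i]) + "\n")
    else:
        out.write(f"#type\tsequence\n#id\t{profile.identifier}\n")
        out.write(f"#L\t{profile.length}\n#alphabet\t{ALPHABET}\n")
        out.write(f"#sequence\t{profile.sequence}\n")
        out.write("position\tkind\t" + "\t".join(ALPHABET) + "\n")
        for i in range(profile.length):
            out.write(f"{i+1}\tscore\t" + "\t".join(_FMT.format(v) for v in profile.scores[i]) + "\n")
    return out.getvalue()


def profile_from_tsv(text: str) -> StructureProfile | SequenceProfile:
    """Read the native profile TSV; alphabet headers in any order are
    re-mapped onto the canonical order."""
    meta: dict[str, str] = {}
    rows: list[tuple[int, str, list[float]]] = []
    col_order: str | None = None
    for ln in text.splitlines():
        if not ln.strip():
            continue
        if ln.startswith("#"):
            toks = ln[1:].split("\t")
            meta[toks[0]] = "\t".join(toks[1:])
            continue
        toks = ln.split("\t")
        if toks[0] == "position":
            col_order = "".join(toks[2:])
            if sorted(col_order) != sorted(ALPHABET):
                raise ValueError("alphabet mismatch in profile header")
            continue
        rows.append((int(toks[0]), toks[1], [float(v) for v in toks[2:]]))
    if "type" not in meta or col_order is None or not rows:
        raise ValueError("malformed profile TSV")
    perm = [col_order.index(a) for a in ALPHABET]

    def remap(vals: list[float]) -> list[float]:
        return [vals[p] for p in perm]

    L = int(meta["L"])
    if meta["type"] == "structure":
        counts = np.zeros((L, 20))
        pro = np.zeros((L, 20))
        for pos, kind, vals in rows:
            if kind == "count":
                counts[pos - 1] = remap(vals)
            elif kind == "pro":
                pro[pos - 1] = remap(vals)
        bg_raw = [float(v) for v in meta["background"].split("\t")]
        background = np.array(remap(bg_raw))
        row_tot = counts.sum(axis=1, keepdims=True)
        freqs = np.divide(counts, row_tot, out=np.zeros_like(counts), where=row_tot > 0)
        return StructureProfile(cluster_id=int(meta["id"]), counts=counts,
                                frequencies=freqs, background=background,
                                propensities=pro)
    if meta["type"] == "sequence":
        scores = np.zeros((L, 20))
        for pos, kind, vals in rows:
            if kind == "score":
                scores[pos - 1] = remap(vals)
        return SequenceProfile(identifier=meta["id"], sequence=meta.get("sequence", ""),
                               scores=scores)
    raise ValueError(f"unknown profile type {meta['type']!r}")
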