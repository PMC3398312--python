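"""Correlation-scored profile-profile search with library Z-scores.

The similarity of two profile columns is their Pearson correlation over the
20 amino-acid dimensions, which lets profiles of different provenance
(structure-based propensities vs. sequence-based log-odds) be compared
directly.  Structure-profile columns enter the correlation as
ln(propensity) floored at -9.21 (= ln 1e-4) so that both column types live
in log-odds-like space; sequence-profile columns are used as-is.

Alignment is global with free terminal gaps: any unaligned run at either
end of either profile costs nothing, while internal gaps pay an affine
open + k*extend penalty.  Significance of a query against a library is a
Z-score of the alignment score after removing the expected growth with
target length via a least-squares fit on ln(length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile_builder import SequenceProfile, StructureProfile

LOG_FLOOR = -9.21   # ln(1e-4) rounded to the 2 decimals used throughout

_DIAG, _QGAP, _TGAP = 0, 1, 2


@dataclass
class SearchConfig:
    gap_open: float = 0.6         # correlation units
    gap_extend: float = 0.06
    column_transform: str = "log"  # "log" | "raw" for structure profiles
    z_threshold: float = 8.0
    log_floor: float = LOG_FLOOR

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.column_transform not in ("log", "raw"):
            raise ValueError("column_transform must be 'log' or 'raw'")


@dataclass
class AlignmentResult:
    pairs: list[tuple[int, int]]          # 1-based (query_pos, target_pos)
    raw_score: float
    column_scores: list[float] = field(default_factory=list)

    def cigar(self) -> str:
        """Compact run-length trace of aligned/gapped columns (M/I/D)."""
        if not self.pairs:
            return ""
        ops: list[str] = []
        pq, pt = self.pairs[0]
        ops.append("M")
        for q, t in self.pairs[1:]:
            dq, dt = q - pq - 1, t - pt - 1
            if dq:
                ops.extend("I" * dq)
            if dt:
                ops.extend("D" * dt)
            ops.append("M")
            pq, pt = q, t
        out = []
        run, ch = 1, ops[0]
        for o in ops[1:]:
            if o == ch:
                run += 1
            else:
                out.append(f"{run}{ch}")
                run, ch = 1, o
        out.append(f"{run}{ch}")
        return "".join(out)


@dataclass
class SearchHit:
    target_id: str
    raw_score: float
    corrected: float
    z: float
    alignment: AlignmentResult
    significant: bool = False


def transform_columns(profile: StructureProfile | SequenceProfile,
                      config: SearchConfig | None = None) -> np.ndarray:
    """Columns as they enter the correlation kernel.

    Structure profiles: ln(pro) floored at ``log_floor`` (or raw propensities
    in raw mode).  Sequence profiles: log-odds scores unchanged.
    """
    config = config or SearchConfig()
    if isinstance(profile, StructureProfile):
        if config.column_transform == "raw":
            return profile.propensities.astype(float)
        with np.errstate(divide="ignore"):
            logp = np.log(profile.propensities)
        return np.maximum(logp, config.log_floor)
    return profile.scores.astype(float)


def column_similarity(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Pearson correlation of two 20-vectors; 0 if either has zero variance."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        return 0.0
    return float(da @ db / np.sqrt(va * vb))


def similarity_matrix(qcols: np.ndarray, tcols: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlations between rows of two column matrices;
    zero-variance rows yield zero similarity."""
    def standardise(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(c, axis=1, keepdims=True)
        return np.divide(c, norm, out=np.zeros_like(c), where=norm > 0)
    return standardise(np.asarray(qcols, float)) @ standardise(np.asarray(tcols, float)).T


def align_global_local(qcols: np.ndarray, tcols: np.ndarray,
                       config: SearchConfig | None = None,
                       sim: np.ndarray | None = None) -> AlignmentResult:
    """Affine-gap DP over column similarities with free terminal gaps.

    Terminal unaligned runs in either profile cost 0 (an empty alignment
    scores 0); an internal gap of length k costs open + k*extend.  Traceback
    ties prefer diagonal, then query-gap, then target-gap.
    """
    config = config or SearchConfig()
    qcols = np.asarray(qcols, dtype=float)
    tcols = np.asarray(tcols, dtype=float)
    if qcols.size == 0 or tcols.size == 0:
        raise ValueError("empty profile")
    if sim is None:
        sim = similarity_matrix(qcols, tcols)
    n, m = sim.shape
    open_k = config.gap_open + config.gap_extend   # cost of the first gapped column
    ext = config.gap_extend
    NEG = -np.inf

    # M[i,j]: best score of an alignment whose last pair is (i,j)
    # QG/TG:  best ending in an internal gap consuming query/target columns
    M = np.full((n + 1, m + 1), NEG)
    QG = np.full((n + 1, m + 1), NEG)
    TG = np.full((n + 1, m + 1), NEG)
    # traceback: which predecessor state fed each cell (-1 = fresh start)
    fromM = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        srow = sim[i - 1]
        for j in range(1, m + 1):
            # start fresh (leading overhangs free) or extend a previous state
            best_prev, state = 0.0, -1
            if M[i - 1, j - 1] > best_prev:
                best_prev, state = M[i - 1, j - 1], _DIAG
            if QG[i - 1, j - 1] > best_prev:
                best_prev, state = QG[i - 1, j - 1], _QGAP
            if TG[i - 1, j - 1] > best_prev:
                best_prev, state = TG[i - 1, j - 1], _TGAP
            M[i, j] = best_prev + srow[j - 1]
            fromM[i, j] = state
            # gap states may chain (a simultaneous internal gap in both
            # profiles pays both open penalties)
            QG[i, j] = max(M[i - 1, j] - open_k, QG[i - 1, j] - ext,
                           TG[i - 1, j] - open_k)
            TG[i, j] = max(M[i, j - 1] - open_k, TG[i, j - 1] - ext,
                           QG[i, j - 1] - open_k)

    end = np.unravel_index(int(np.argmax(M[1:, 1:])), (n, m))
    best = float(M[end[0] + 1, end[1] + 1])
    if best <= 0.0:
        return AlignmentResult(pairs=[], raw_score=0.0)

    # traceback from the best-scoring last pair
    pairs: list[tuple[int, int]] = []
    cols: list[float] = []
    i, j = end[0] + 1, end[1] + 1
    state = _DIAG
    while True:
        if state == _DIAG:
            pairs.append((i, j))
            cols.append(float(sim[i - 1, j - 1]))
            prev = fromM[i, j]
            if prev == -1:
                break
            state = int(prev)
            i, j = i - 1, j - 1
        elif state == _QGAP:
            # gap consuming query rows; prefer closing it (diagonal source)
            cand = (
                (M[i - 1, j] - open_k, _DIAG),
                (QG[i - 1, j] - ext, _QGAP),
                (TG[i - 1, j] - open_k, _TGAP),
            )
            state = max(cand, key=lambda c: c[0])[1]
            i -= 1
        else:  # _TGAP
            cand = (
                (M[i, j - 1] - open_k, _DIAG),
                (TG[i, j - 1] - ext, _TGAP),
                (QG[i, j - 1] - open_k, _QGAP),
            )
            state = max(cand, key=lambda c: c[0])[1]
            j -= 1
    pairs.reverse()
    cols.reverse()
    return AlignmentResult(pairs=pairs, raw_score=best, column_scores=cols)


def zscore_library_search(query: StructureProfile | SequenceProfile,
                          library: list[SequenceProfile],
                          config: SearchConfig | None = None) -> list[SearchHit]:
    """Align the query against every library profile and standardise scores.

    The raw score grows with target length, so a least-squares fit
    s ~ a*ln(n) + b over the whole library is removed first; the residuals
    are standardised into Z-scores (population std).  Hits are returned
    sorted by Z descending; for libraries smaller than 10 raw scores are
    reported with Z = 0 (flagged by ``significant=False`` everywhere).
    """
    config = config or SearchConfig()
    if not library:
        raise ValueError("empty library")
    qcols = transform_columns(query, config)
    raws = np.empty(len(library))
    alis: list[AlignmentResult] = []
    for k, target in enumerate(library):
        ali = align_global_local(qcols, transform_columns(target, config), config)
        raws[k] = ali.raw_score
        alis.append(ali)

    lengths = np.array([t.length for t in library], dtype=float)
    if len(library) >= 10:
        if np.ptp(lengths) == 0:   # degenerate: all targets the same length
            resid = raws - raws.mean()
        else:
            coeffs = np.polyfit(np.log(lengths), raws, 1)
            resid = raws - np.polyval(coeffs, np.log(lengths))
        sd = resid.std()
        if sd == 0.0:
            z = np.zeros_like(resid)
        else:
            z = (resid - resid.mean()) / sd
    else:
        resid = raws.copy()
        z = np.zeros_like(raws)

    hits = [
        SearchHit(target_id=t.identifier, raw_score=float(raws[k]),
                  corrected=float(resid[k]), z=float(z[k]), alignment=alis[k],
                  significant=bool(z[k] >= config.z_threshold))
        for k, t in enumerate(library)
    ]
    hits.sort(key=lambda h: (-h.z, h.target_id))
    return hits


def hits_to_tsv(hits: list[SearchHit]) -> str:
    lines = ["rank\ttarget_id\traw\tcorrected\tZ\tsignificant\talignment_cigar"]
    for r, h in enumerate(hits, start=1):
        lines.append(f"{r}\t{h.target_id}\t{h.raw_score:.6f}\t{h.corrected:.6f}"
                     f"\t{h.z:.6f}\t{int(h.significant)}\t{h.alignment.cigar()}")
    return "\n".join(lines) + "\n"


def z_histogram(hits: list[SearchHit], bin_width: float = 0.5) -> str:
    """Binned Z distribution as TSV, for score-distribution plots."""
    z = np.array([h.z for h in hits])
    lo = np.floor(z.min() / bin_width) * bin_width
    hi = np.ceil(z.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(z, bins=edges)
    lines = ["z_low\tz_high\tcount"]
    for k in range(len(counts)):
        lines.append(f"{edges[k]:.3f}\t{edges[k+1]:.3f}\t{counts[k]}")
    return "\n".join(lines) + "\n"
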