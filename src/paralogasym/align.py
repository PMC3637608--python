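"""Pairwise alignment, duplication-termination detection, span and structure.

The duplication span of a paralog pair is the length (bp) of the homologous
tract shared by the two copies between their duplication termination points.
Termination points are found by extending outward from the ORFs and declaring
a side terminated once a continuous 1 kb stretch shows no homology to the
partner sequence. "No homology" is operationalized as: no sliding window of
``window_bp`` (default 100 bp) matches anywhere in the partner context with
at least ``min_identity`` (default 60%) gapless identity at its best offset.
(Gapless identity is the right yardstick here: with gap-tolerant alignment,
unrelated DNA reaches ~55–60% identity by chance, which would swamp a 60%
threshold; ungapped, random matches above 60% are vanishingly rare. An edlib
infix alignment, whose edit distance lower-bounds the mismatch count at any
offset, is used as a fast rejection screen.)

Structural classes of a duplicate pair:

* ``complete`` — both paralogs' exons lie within the shared homologous tract;
* ``heterogeneous_partial`` — exactly one paralog has exon(s) unique to it
  (outside the tract);
* ``heterogeneous_chimeric`` — both paralogs have unique exon(s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import edlib
import numpy as np
from numba import njit

from .seq_io import Alphabet, GeneAnnotation, SequenceRecord

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Scoring

_NT_ORDER = "ACGTN"
_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"


def _nt_matrix(match: float, mismatch: float) -> np.ndarray:
    m = np.full((5, 5), mismatch)
    np.fill_diagonal(m, match)
    m[4, :] = 0.0  # N scores neutrally against everything
    m[:, 4] = 0.0
    return m


def _blosum62() -> np.ndarray:
    from Bio.Align import substitution_matrices

    b = substitution_matrices.load("BLOSUM62")
    n = len(_AA_ORDER)
    m = np.zeros((n, n))
    for i, x in enumerate(_AA_ORDER):
        for j, y in enumerate(_AA_ORDER):
            m[i, j] = b[x, y]
    return m


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring; a gap of length k costs gap_open + (k-1)*gap_extend."""

    matrix: np.ndarray
    order: str
    gap_open: float
    gap_extend: float

    @classmethod
    def nucleotide(cls, match: float = 1.0, mismatch: float = -1.0,
                   gap_open: float = -4.0, gap_extend: float = -1.0) -> "AlignScoring":
        return cls(_nt_matrix(match, mismatch), _NT_ORDER, gap_open, gap_extend)

    @classmethod
    def amino_acid(cls, gap_open: float = -10.0, gap_extend: float = -1.0) -> "AlignScoring":
        return cls(_blosum62(), _AA_ORDER, gap_open, gap_extend)


def _default_scoring(alphabet: Alphabet) -> AlignScoring:
    if alphabet is Alphabet.NUCLEOTIDE:
        return AlignScoring.nucleotide()
    return AlignScoring.amino_acid()


def _encode(seq: str, order: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int8)
    for i, c in enumerate(order):
        lut[ord(c)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({c for c in seq if c not in order})
        raise ValueError(f"sequence contains unalignable character(s) {bad}")
    return arr


# ---------------------------------------------------------------------------
# Needleman–Wunsch / Gotoh

_NEG = -1e18

# traceback states
_M, _Y, _X = 0, 1, 2  # substitution, gap-in-A (consumes b), gap-in-B (consumes a)


@njit(cache=False)
def _gotoh(a, b, sub, go, ge):  # pragma: no cover - exercised via global_align
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # ends consuming a[i-1] over a gap
    Y = np.full((n + 1, m + 1), _NEG)  # ends consuming b[j-1] over a gap
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + go, Y[i - 1, j] + go, X[i - 1, j] + ge)
            Y[i, j] = max(M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)

    # traceback; ties resolved as substitution > gap-in-A > gap-in-B
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    if M[i, j] >= Y[i, j] and M[i, j] >= X[i, j]:
        state = _M
    elif Y[i, j] >= X[i, j]:
        state = _Y
    else:
        state = _X
    score = max(M[i, j], max(X[i, j], Y[i, j]))
    while i > 0 or j > 0:
        if state == _M:
            ops[k] = _M
            k += 1
            if M[i - 1, j - 1] + sub[a[i - 1], b[j - 1]] == M[i, j] and M[i - 1, j - 1] >= Y[i - 1, j - 1] and M[i - 1, j - 1] >= X[i - 1, j - 1]:
                state = _M
            elif Y[i - 1, j - 1] + sub[a[i - 1], b[j - 1]] == M[i, j] and Y[i - 1, j - 1] >= X[i - 1, j - 1]:
                state = _Y
            else:
                state = _X
            i -= 1
            j -= 1
        elif state == _Y:
            ops[k] = _Y
            k += 1
            if j == 1 and i == 0:
                state = _M  # sentinel; loop will end
                j -= 1
                continue
            if M[i, j - 1] + go == Y[i, j]:
                state = _M
            elif X[i, j - 1] + go == Y[i, j]:
                state = _X
            else:
                state = _Y
            j -= 1
        else:
            ops[k] = _X
            k += 1
            if i == 1 and j == 0:
                state = _M
                i -= 1
                continue
            if M[i - 1, j] + go == X[i, j]:
                state = _M
            elif Y[i - 1, j] + go == X[i, j]:
                state = _Y
            else:
                state = _X
            i -= 1
    return score, ops[:k][::-1].copy()


@dataclass(frozen=True)
class PairwiseAlignment:
    """Global alignment of two sequences; equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    def __len__(self) -> int:
        return len(self.aligned_a)

    def column_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Per column, the 0-based ungapped position in each input (-1 at gaps)."""
        out = []
        for s in (self.aligned_a, self.aligned_b):
            arr = np.frombuffer(s.encode(), dtype=np.uint8) != ord("-")
            pos = np.cumsum(arr) - 1
            pos[~arr] = -1
            out.append(pos)
        return out[0], out[1]

    @property
    def identity(self) -> float:
        same = sum(1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-")
        return same / len(self.aligned_a)


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: AlignScoring | None = None,
    alphabet: Alphabet = Alphabet.NUCLEOTIDE,
) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch) alignment with affine gaps.

    Deterministic: score ties are broken preferring substitution over a gap
    in ``a`` over a gap in ``b``.
    """
    if isinstance(a, SequenceRecord) and isinstance(b, SequenceRecord):
        if a.alphabet is not b.alphabet:
            raise ValueError(f"mixed alphabets: {a.alphabet.value} vs {b.alphabet.value}")
        alphabet = a.alphabet
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align empty sequence")
    if "-" in sa or "-" in sb:
        raise ValueError("inputs to global_align must be ungapped")
    scoring = scoring or _default_scoring(alphabet)
    ea, eb = _encode(sa, scoring.order), _encode(sb, scoring.order)
    score, ops = _gotoh(ea, eb, scoring.matrix, float(scoring.gap_open), float(scoring.gap_extend))
    ra, rb = [], []
    i = j = 0
    for op in ops:
        if op == _M:
            ra.append(sa[i]); rb.append(sb[j]); i += 1; j += 1
        elif op == _Y:  # gap in a
            ra.append("-"); rb.append(sb[j]); j += 1
        else:  # gap in b
            ra.append(sa[i]); rb.append("-"); i += 1
    assert i == len(sa) and j == len(sb)
    return PairwiseAlignment("".join(ra), "".join(rb), float(score))


# ---------------------------------------------------------------------------
# Homology region / duplication termination points


@dataclass(frozen=True)
class HomologyRegion:
    """Bounds of the homologous tract within each paralog's genomic context."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    terminated_5prime: bool
    terminated_3prime: bool

    def __post_init__(self) -> None:
        if not (self.a_end > self.a_start >= 0 and self.b_end > self.b_start >= 0):
            raise ValueError("degenerate homology region")


class PairNotHomologousError(ValueError):
    pass


def _window_match(query: str, target_arr: np.ndarray, min_matches: int) -> tuple[int, int] | None:
    """Best-offset gapless match of ``query`` in ``target``; None if below
    ``min_matches`` identities. Returns the [lo, hi) target envelope of all
    qualifying offsets."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    w = len(q)
    if len(target_arr) < w:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(target_arr, w)
    matches = (windows == q).sum(axis=1)
    ok = np.nonzero(matches >= min_matches)[0]
    if len(ok) == 0:
        return None
    return int(ok[0]), int(ok[-1]) + w


def find_homology_region(
    a_context: SequenceRecord | str,
    b_context: SequenceRecord | str,
    a_orf: tuple[int, int] | None = None,
    window_bp: int = 100,
    min_identity: float = 0.6,
    step_bp: int = 1000,
) -> HomologyRegion:
    """Locate the shared homologous tract around the ORF of paralog A.

    Windows of ``window_bp`` are slid along A's context (stride window/2) and
    matched against B's whole context; a window is homologous if its best
    gapless offset reaches ``min_identity``. Starting from the window nearest
    A's ORF, homologous windows are accreted outward on each side until a
    homology-free stretch of at least ``step_bp`` is found (termination) or
    sequence runs out (flank exhausted; flag left False and logged). Bounds
    are the tightest enclosing all accreted windows; B bounds come from the
    match locations of those windows.
    """
    sa = a_context.residues if isinstance(a_context, SequenceRecord) else a_context
    sb = b_context.residues if isinstance(b_context, SequenceRecord) else b_context
    w = min(window_bp, len(sa), len(sb))
    max_dist = w - int(np.ceil(w * min_identity))
    min_matches = int(np.ceil(w * min_identity))
    stride = max(1, w // 2)
    sb_arr = np.frombuffer(sb.encode(), dtype=np.uint8)

    starts = list(range(0, len(sa) - w + 1, stride))
    if starts and starts[-1] != len(sa) - w:
        starts.append(len(sa) - w)
    hits: dict[int, tuple[int, int]] = {}
    for s in starts:
        query = sa[s : s + w]
        # edit distance lower-bounds the best-offset mismatch count
        res = edlib.align(query, sb, mode="HW", task="distance", k=max_dist)
        if res["editDistance"] == -1:
            continue
        loc = _window_match(query, sb_arr, min_matches)
        if loc is not None:
            hits[s] = loc
    if not hits:
        raise PairNotHomologousError("pair not homologous")

    hit_starts = sorted(hits)
    if a_orf is None:
        center = len(sa) // 2
    else:
        center = (a_orf[0] + a_orf[1]) // 2
    seed_idx = int(np.argmin([abs(s + w // 2 - center) for s in hit_starts]))

    included = [hit_starts[seed_idx]]
    # extend 5'
    for idx in range(seed_idx - 1, -1, -1):
        gap = included[0] - (hit_starts[idx] + w)
        if gap >= step_bp:
            break
        included.insert(0, hit_starts[idx])
    # extend 3'
    for idx in range(seed_idx + 1, len(hit_starts)):
        gap = hit_starts[idx] - (included[-1] + w)
        if gap >= step_bp:
            break
        included.append(hit_starts[idx])

    a_start, a_end = included[0], included[-1] + w
    b_start = min(hits[s][0] for s in included)
    b_end = max(hits[s][1] for s in included)

    term5 = a_start >= step_bp
    term3 = len(sa) - a_end >= step_bp
    if not term5:
        log.info("5' flank exhausted before a %d bp homology-free stretch", step_bp)
    if not term3:
        log.info("3' flank exhausted before a %d bp homology-free stretch", step_bp)
    return HomologyRegion(a_start, a_end, b_start, b_end, term5, term3)


# ---------------------------------------------------------------------------
# Duplication span


@dataclass(frozen=True)
class SpanResult:
    """Duplication span: the reported value is the lower of the two
    per-paralog tract lengths (conservative when indels differ)."""

    span_a: int
    span_b: int
    span: int
    region: HomologyRegion


def duplication_span(region: HomologyRegion) -> SpanResult:
    span_a = region.a_end - region.a_start
    span_b = region.b_end - region.b_start
    if span_a < 1 or span_b < 1:
        raise ValueError("degenerate homology region")
    return SpanResult(span_a, span_b, min(span_a, span_b), region)


# ---------------------------------------------------------------------------
# Structural classification


class Structure(str, Enum):
    COMPLETE = "complete"
    PARTIAL = "heterogeneous_partial"
    CHIMERIC = "heterogeneous_chimeric"

    @property
    def collapsed(self) -> str:
        """Two-level coding used by the regression analysis."""
        return "homogeneous" if self is Structure.COMPLETE else "heterogeneous"


@dataclass(frozen=True)
class StructureClass:
    value: Structure
    unique_exons_a: int
    unique_exons_b: int


def _unique_exons(
    exons: tuple[tuple[int, int], ...],
    offset: int,
    lo: int,
    hi: int,
    overlap_fraction: float,
) -> int:
    n = 0
    for start, end in exons:
        s, e = start - offset, end - offset
        overlap = max(0, min(e, hi) - max(s, lo))
        if overlap < overlap_fraction * (e - s):
            n += 1
    return n


def classify_structure(
    annot_a: GeneAnnotation,
    annot_b: GeneAnnotation,
    region: HomologyRegion,
    a_offset: int = 0,
    b_offset: int = 0,
    overlap_fraction: float = 0.5,
) -> StructureClass:
    """Classify a pair from exon coverage of the homologous tract.

    An exon is unique to a paralog when less than ``overlap_fraction`` of its
    length lies inside that paralog's homology bounds. ``a_offset``/``b_offset``
    translate annotation (chromosome) coordinates into context coordinates:
    context position = chromosome position - offset.
    """
    if not annot_a.exons or not annot_b.exons:
        raise ValueError("empty exon list")
    ua = _unique_exons(annot_a.exons, a_offset, region.a_start, region.a_end, overlap_fraction)
    ub = _unique_exons(annot_b.exons, b_offset, region.b_start, region.b_end, overlap_fraction)
    if ua == 0 and ub == 0:
        value = Structure.COMPLETE
    elif ua > 0 and ub > 0:
        value = Structure.CHIMERIC
    else:
        value = Structure.PARTIAL
    return StructureClass(value, ua, ub)
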