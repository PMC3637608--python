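"""Relative-rate statistics on paralog/outgroup triplets.

Given two paralogs A and B and an outgroup O, a site (alignment column) is
*unique* to A when A's state differs from both B and O while B and O agree —
evidence of a substitution on A's branch since the duplication. The counts
m_A, m_B of unique sites feed:

* Tajima's relative-rate test, the χ² statistic (m_A − m_B)² / (m_A + m_B)
  with 1 df, testing the molecular-clock null of equal branch rates;
* the continuous *asymmetry/site* variable |m_A − m_B| / L, where L is the
  number of usable homologous sites — a per-length-standardized measure of
  rate asymmetry usable even where the χ² test has no power;
* the signed *standardized asymmetry* (m_ancestral − m_derived) / L for pairs
  whose ancestral/derived copies are identified (negative values mean the
  derived copy accumulated more unique sites).

Columns with a gap or an ambiguity code (N at the nucleotide level, X or *
at the amino-acid level) in any of the three sequences are excluded from all
counts, including L. Sites at which all three states differ are tallied
separately (``n_alldiff``), excluded from m_A/m_B by default, and kept in L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .align import AlignScoring, PairwiseAlignment, global_align
from .seq_io import Alphabet, SequenceRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Translation


def translate_cds(nt: SequenceRecord | str, record_id: str = "") -> SequenceRecord:
    """Translate a coding sequence with the standard genetic code.

    A trailing incomplete codon is trimmed (logged); a terminal stop codon is
    dropped; internal stops are rendered as 'X' with a warning (they occur in
    pseudogenized copies). Ambiguous codons translate to 'X'.
    """
    seq = nt.residues if isinstance(nt, SequenceRecord) else nt
    rid = nt.id if isinstance(nt, SequenceRecord) else record_id
    if len(seq) < 3:
        raise ValueError(f"{rid or 'CDS'}: too short to translate ({len(seq)} nt)")
    if len(seq) % 3:
        log.info("%s: trimming %d nt incomplete trailing codon", rid or "CDS", len(seq) % 3)
        seq = seq[: len(seq) - len(seq) % 3]
    aa = str(Seq(seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        log.warning("%s: internal stop codon(s) translated as X", rid or "CDS")
        aa = aa.replace("*", "X")
    if not aa:
        raise ValueError(f"{rid or 'CDS'}: nothing left after trimming the stop codon")
    return SequenceRecord(rid or "translated", aa, Alphabet.AMINO_ACID)


# ---------------------------------------------------------------------------
# Triplet alignment


@dataclass(frozen=True)
class TripletAlignment:
    """Three aligned homologous sequences plus a per-column homology mask."""

    aligned_a: str
    aligned_b: str
    aligned_out: str
    level: Alphabet
    homologous_mask: np.ndarray  # bool per column

    def __post_init__(self) -> None:
        n = len(self.aligned_a)
        if len(self.aligned_b) != n or len(self.aligned_out) != n:
            raise ValueError("triplet rows differ in length")
        if len(self.homologous_mask) != n:
            raise ValueError("mask length mismatch")

    def __len__(self) -> int:
        return len(self.aligned_a)


def _merge_on_a(pair_ab: PairwiseAlignment, pair_ao: PairwiseAlignment) -> tuple[str, str, str]:
    """Merge two pairwise alignments sharing sequence A into three rows.

    A profile shortcut: the outgroup is threaded onto the A/B alignment via
    its alignment to A alone. Insertions in B relative to A and insertions in
    O relative to A become separate columns (B's first).
    """
    out_a, out_b, out_o = [], [], []
    i = j = 0
    ab_a, ab_b = pair_ab.aligned_a, pair_ab.aligned_b
    ao_a, ao_o = pair_ao.aligned_a, pair_ao.aligned_b
    while i < len(ab_a) or j < len(ao_a):
        if i < len(ab_a) and ab_a[i] == "-":
            out_a.append("-"); out_b.append(ab_b[i]); out_o.append("-")
            i += 1
        elif j < len(ao_a) and ao_a[j] == "-":
            out_a.append("-"); out_b.append("-"); out_o.append(ao_o[j])
            j += 1
        else:
            out_a.append(ab_a[i]); out_b.append(ab_b[i]); out_o.append(ao_o[j])
            i += 1; j += 1
    return "".join(out_a), "".join(out_b), "".join(out_o)


def _thread_codons(aligned_aa: str, cds: str) -> str:
    """Expand an aligned protein row back to codons of its source CDS."""
    chunks = []
    k = 0
    for ch in aligned_aa:
        if ch == "-":
            chunks.append("---")
        else:
            chunks.append(cds[3 * k : 3 * k + 3])
            k += 1
    return "".join(chunks)


@dataclass(frozen=True)
class TripletBundle:
    """Protein- and nucleotide-level triplet alignments for one pair, plus
    the paralog-only codon alignment used for K_S estimation.
    ``pair_codon_mask`` marks codon columns of the pair alignment lying inside
    the pair's homologous region (all True when no mask was supplied)."""

    aa: TripletAlignment
    nt: TripletAlignment
    pair_codon_a: str
    pair_codon_b: str
    pair_codon_mask: np.ndarray


def align_triplet(
    cds_a: SequenceRecord,
    cds_b: SequenceRecord,
    cds_out: SequenceRecord,
    a_codon_mask: np.ndarray | None = None,
    scoring: AlignScoring | None = None,
) -> TripletBundle:
    """Align the triplet at the protein level and thread codons back.

    ``a_codon_mask`` optionally marks which codons of paralog A lie inside the
    pair's homologous region; columns outside it are masked from site counts.
    The nucleotide-level alignment is the codon expansion of the protein one,
    so both levels scan the same homologous coding region.
    """
    prot_a = translate_cds(cds_a)
    prot_b = translate_cds(cds_b)
    prot_o = translate_cds(cds_out)
    scoring = scoring or AlignScoring.amino_acid()
    pair_ab = global_align(prot_a.residues, prot_b.residues, scoring, Alphabet.AMINO_ACID)
    pair_ao = global_align(prot_a.residues, prot_o.residues, scoring, Alphabet.AMINO_ACID)
    row_a, row_b, row_o = _merge_on_a(pair_ab, pair_ao)

    if a_codon_mask is None:
        mask_aa = np.ones(len(row_a), dtype=bool)
    else:
        mask_aa = np.ones(len(row_a), dtype=bool)
        k = 0
        for col, ch in enumerate(row_a):
            if ch != "-":
                mask_aa[col] = bool(a_codon_mask[k]) if k < len(a_codon_mask) else False
                k += 1
    aa = TripletAlignment(row_a, row_b, row_o, Alphabet.AMINO_ACID, mask_aa)

    nt_a = _thread_codons(row_a, cds_a.residues)
    nt_b = _thread_codons(row_b, cds_b.residues)
    nt_o = _thread_codons(row_o, cds_out.residues)
    nt = TripletAlignment(nt_a, nt_b, nt_o, Alphabet.NUCLEOTIDE, np.repeat(mask_aa, 3))

    pair_mask = np.ones(len(pair_ab.aligned_a), dtype=bool)
    if a_codon_mask is not None:
        k = 0
        for col, ch in enumerate(pair_ab.aligned_a):
            if ch != "-":
                pair_mask[col] = bool(a_codon_mask[k]) if k < len(a_codon_mask) else False
                k += 1
            else:
                pair_mask[col] = False
    return TripletBundle(
        aa=aa,
        nt=nt,
        pair_codon_a=_thread_codons(pair_ab.aligned_a, cds_a.residues),
        pair_codon_b=_thread_codons(pair_ab.aligned_b, cds_b.residues),
        pair_codon_mask=pair_mask,
    )


# ---------------------------------------------------------------------------
# Unique-site counting


@dataclass(frozen=True)
class UniqueSiteCounts:
    m_a: int
    m_b: int
    n_alldiff: int
    L: int
    level: Alphabet

    def __post_init__(self) -> None:
        if min(self.m_a, self.m_b, self.n_alldiff, self.L) < 0:
            raise ValueError("negative count")
        if self.m_a + self.m_b + self.n_alldiff > self.L:
            raise ValueError("site categories exceed usable length")


_NT_GOOD = frozenset(b"ACGT")
_AA_GOOD = frozenset(b"ACDEFGHIKLMNPQRSTVWY")


def _usable(arr: np.ndarray, level: Alphabet) -> np.ndarray:
    good = _NT_GOOD if level is Alphabet.NUCLEOTIDE else _AA_GOOD
    out = np.zeros(arr.shape, dtype=bool)
    for ch in good:
        out |= arr == ch
    return out


def count_unique_sites(
    t: TripletAlignment, include_all_different: bool = False
) -> UniqueSiteCounts:
    """Count sites unique to each paralog relative to the outgroup.

    Only columns inside the homologous mask with an unambiguous, ungapped
    state in all three sequences are scanned; their number is L. With
    ``include_all_different`` the columns where all three states differ are
    added to both paralogs' unique counts instead of only being tallied
    separately (the default follows the classical construction of the test).
    """
    a = np.frombuffer(t.aligned_a.encode(), dtype=np.uint8)
    b = np.frombuffer(t.aligned_b.encode(), dtype=np.uint8)
    o = np.frombuffer(t.aligned_out.encode(), dtype=np.uint8)
    usable = (
        t.homologous_mask
        & _usable(a, t.level)
        & _usable(b, t.level)
        & _usable(o, t.level)
    )
    L = int(usable.sum())
    if L == 0:
        raise ValueError("no homologous sites")
    m_a = int((usable & (a != b) & (b == o)).sum())
    m_b = int((usable & (a != b) & (a == o)).sum())
    alldiff = int((usable & (a != b) & (a != o) & (b != o)).sum())
    if include_all_different:
        m_a += alldiff
        m_b += alldiff
    return UniqueSiteCounts(m_a, m_b, alldiff, L, t.level)


# ---------------------------------------------------------------------------
# Tests and asymmetry measures


@dataclass(frozen=True)
class RelRateResult:
    counts: UniqueSiteCounts
    chi_square: float
    p_value: float
    significant: bool
    alpha: float


def tajima_test(c: UniqueSiteCounts, alpha: float = 0.05) -> RelRateResult:
    """Tajima's relative-rate χ² test with 1 df (upper tail, no continuity
    correction); zero informative sites yield χ² = 0, p = 1."""
    total = c.m_a + c.m_b
    if total == 0:
        chi, p = 0.0, 1.0
    else:
        chi = (c.m_a - c.m_b) ** 2 / total
        p = float(stats.chi2.sf(chi, df=1))
    return RelRateResult(c, float(chi), p, p <= alpha, alpha)


def asymmetry_per_site(c: UniqueSiteCounts) -> float:
    """|m_A − m_B| / L — zero iff the unique-site counts are equal."""
    if c.L <= 0:
        raise ValueError("L must be positive")
    return abs(c.m_a - c.m_b) / c.L


def signed_standardized_asymmetry(c: UniqueSiteCounts, ancestral_is_a: bool | None) -> float:
    """(m_ancestral − m_derived) / L; negative means the derived copy is faster."""
    if ancestral_is_a is None:
        raise ValueError("ancestral/derived assignment unavailable")
    if c.L <= 0:
        raise ValueError("L must be positive")
    diff = (c.m_a - c.m_b) if ancestral_is_a else (c.m_b - c.m_a)
    return diff / c.L


@dataclass(frozen=True)
class AsymmetryMeasures:
    """Per-pair asymmetry summary at both sequence levels."""

    asym_per_site_nt: float
    asym_per_site_aa: float
    L_nt: int
    L_aa: int
    signed_standardized_nt: float | None = None
    signed_standardized_aa: float | None = None


def asymmetry_measures(
    counts_nt: UniqueSiteCounts,
    counts_aa: UniqueSiteCounts,
    ancestral_is_a: bool | None = None,
) -> AsymmetryMeasures:
    signed_nt = signed_aa = None
    if ancestral_is_a is not None:
        signed_nt = signed_standardized_asymmetry(counts_nt, ancestral_is_a)
        signed_aa = signed_standardized_asymmetry(counts_aa, ancestral_is_a)
    return AsymmetryMeasures(
        asym_per_site_nt=asymmetry_per_site(counts_nt),
        asym_per_site_aa=asymmetry_per_site(counts_aa),
        L_nt=counts_nt.L,
        L_aa=counts_aa.L,
        signed_standardized_nt=signed_nt,
        signed_standardized_aa=signed_aa,
    )
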