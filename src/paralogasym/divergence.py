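"""Synonymous divergence (K_S) between paralog coding regions.

K_S — synonymous substitutions per synonymous site — is the pipeline's proxy
for the evolutionary age of a duplicate pair. It is estimated with the
Nei–Gojobori (1986) counting method on the codon alignment induced by the
paralogs' protein alignment:

* per codon, each position contributes a synonymous-site fraction equal to
  the fraction of its three possible single-nucleotide changes that preserve
  the amino acid (changes to stop codons count as nonsynonymous); site totals
  are averaged over the two sequences;
* observed differences between a codon pair are resolved by averaging the
  synonymous/nonsynonymous split over all minimal mutational pathways,
  excluding pathways that traverse a stop codon (if every pathway does, all
  are used);
* proportions are corrected for multiple hits with the Jukes–Cantor formula
  d = -3/4 ln(1 - 4p/3); p_s >= 3/4 is flagged as saturated.

Codon pairs containing a gap, an ambiguity code, or a stop codon are skipped.
At the divergences this pipeline targets (K_S <= 0.14) the counting estimate
tracks likelihood-based estimates closely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Seq import Seq

_NT = "ACGT"
_IDX = {c: i for i, c in enumerate(_NT)}

# Lazily built 64-codon tables (codon id = 16*n1 + 4*n2 + n3, ACGT order).
_TABLES: dict[str, np.ndarray] | None = None


def _codon_str(cid: int) -> str:
    return _NT[(cid >> 4) & 3] + _NT[(cid >> 2) & 3] + _NT[cid & 3]


def _build_tables() -> dict[str, np.ndarray]:
    aa = np.array([str(Seq(_codon_str(c)).translate()) for c in range(64)])
    stop = aa == "*"

    syn_sites = np.zeros(64)
    for c in range(64):
        if stop[c]:
            continue
        s = 0.0
        codon = _codon_str(c)
        for pos in range(3):
            for nt in _NT:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                alt_id = 16 * _IDX[alt[0]] + 4 * _IDX[alt[1]] + _IDX[alt[2]]
                if not stop[alt_id] and aa[alt_id] == aa[c]:
                    s += 1.0 / 3.0
        syn_sites[c] = s

    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    valid = np.zeros((64, 64), dtype=bool)
    for c1 in range(64):
        for c2 in range(64):
            if stop[c1] or stop[c2]:
                continue
            valid[c1, c2] = True
            diff_pos = [p for p in range(3) if _codon_str(c1)[p] != _codon_str(c2)[p]]
            if not diff_pos:
                continue
            paths = []
            for order in permutations(diff_pos):
                s_cnt = n_cnt = 0.0
                cur = _codon_str(c1)
                through_stop = False
                for p in order:
                    nxt = cur[:p] + _codon_str(c2)[p] + cur[p + 1 :]
                    nxt_id = 16 * _IDX[nxt[0]] + 4 * _IDX[nxt[1]] + _IDX[nxt[2]]
                    cur_id = 16 * _IDX[cur[0]] + 4 * _IDX[cur[1]] + _IDX[cur[2]]
                    if stop[nxt_id]:
                        through_stop = True
                    if aa[nxt_id] == aa[cur_id] and not stop[nxt_id] and not stop[cur_id]:
                        s_cnt += 1
                    else:
                        n_cnt += 1
                    cur = nxt
                paths.append((s_cnt, n_cnt, through_stop))
            clean = [p for p in paths if not p[2]]
            use = clean if clean else paths
            sd[c1, c2] = sum(p[0] for p in use) / len(use)
            nd[c1, c2] = sum(p[1] for p in use) / len(use)
    return {"aa": aa, "stop": stop, "syn_sites": syn_sites, "sd": sd, "nd": nd, "valid": valid}


def codon_tables() -> dict[str, np.ndarray]:
    global _TABLES
    if _TABLES is None:
        _TABLES = _build_tables()
    return _TABLES


@dataclass(frozen=True)
class KsEstimate:
    ks: float  # NaN when saturated
    ka: float
    syn_sites: float
    nonsyn_sites: float
    n_codons: int
    saturated: bool


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def ng86_from_codon_ids(codons_a: np.ndarray, codons_b: np.ndarray) -> KsEstimate:
    """NG86 estimate from parallel arrays of codon ids (-1 = unusable codon)."""
    t = codon_tables()
    ca = np.asarray(codons_a)
    cb = np.asarray(codons_b)
    if ca.shape != cb.shape:
        raise ValueError("codon arrays differ in length")
    ok = (ca >= 0) & (cb >= 0)
    ca, cb = ca[ok], cb[ok]
    ok2 = t["valid"][ca, cb]
    ca, cb = ca[ok2], cb[ok2]
    n_codons = len(ca)
    if n_codons == 0:
        raise ValueError("no comparable codons")
    S = float((t["syn_sites"][ca] + t["syn_sites"][cb]).sum() / 2.0)
    N = 3.0 * n_codons - S
    Sd = float(t["sd"][ca, cb].sum())
    Nd = float(t["nd"][ca, cb].sum())
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks, sat_s = _jukes_cantor(ps)
    ka, sat_n = _jukes_cantor(pn)
    return KsEstimate(ks, ka, S, N, n_codons, sat_s or sat_n)


def codon_ids_from_aligned(aligned: str) -> np.ndarray:
    """Codon ids (-1 for codons containing a gap/ambiguity) per codon column."""
    ids = np.full(len(aligned) // 3, -1, dtype=np.int64)
    for k in range(len(ids)):
        codon = aligned[3 * k : 3 * k + 3]
        if all(c in _IDX for c in codon):
            ids[k] = 16 * _IDX[codon[0]] + 4 * _IDX[codon[1]] + _IDX[codon[2]]
    return ids


def ng86_divergence(
    aligned_cds_a: str, aligned_cds_b: str, codon_mask: np.ndarray | None = None
) -> KsEstimate:
    """NG86 K_S/K_A from a gapped, codon-framed pairwise alignment.

    The alignment must keep the ungapped codon frame (gaps in whole-codon
    triplets), as produced by threading codons through a protein alignment.
    Codons with a gap or ambiguity in either sequence are skipped; an optional
    per-codon-column ``codon_mask`` restricts the estimate to the paralogs'
    homologous region (essential for partial/chimeric pairs).
    """
    if len(aligned_cds_a) != len(aligned_cds_b):
        raise ValueError("aligned sequences differ in length")
    if len(aligned_cds_a) % 3:
        raise ValueError("alignment length not a multiple of 3")
    ids_a = codon_ids_from_aligned(aligned_cds_a)
    ids_b = codon_ids_from_aligned(aligned_cds_b)
    if codon_mask is not None:
        if len(codon_mask) != len(ids_a):
            raise ValueError("codon_mask length mismatch")
        ids_a = np.where(codon_mask, ids_a, -1)
    return ng86_from_codon_ids(ids_a, ids_b)


# ---------------------------------------------------------------------------
# Age cohorts

COHORT_EDGES: tuple[tuple[float, float], ...] = (
    (0.0, 0.01),
    (0.01, 0.03),
    (0.03, 0.05),
    (0.05, 0.08),
    (0.08, 0.14),
)

OUT_OF_RANGE = "K_S>=0.14"


@dataclass(frozen=True)
class AgeCohort:
    label: str
    lower: float
    upper: float

    @property
    def out_of_range(self) -> bool:
        return self.label == OUT_OF_RANGE


def assign_cohort(ks: float) -> AgeCohort:
    """Half-open K_S age bins; K_S >= 0.14 is flagged out of range (such
    pairs stay in the regressions but are excluded from cohort summaries)."""
    if not np.isfinite(ks) or ks < 0:
        raise ValueError(f"invalid K_S {ks!r}")
    for lo, hi in COHORT_EDGES:
        if lo <= ks < hi:
            return AgeCohort(f"[{lo:g},{hi:g})", lo, hi)
    return AgeCohort(OUT_OF_RANGE, 0.14, float("inf"))


def cohort_labels() -> list[str]:
    return [f"[{lo:g},{hi:g})" for lo, hi in COHORT_EDGES]
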