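"""Synthetic paralog-triplet datasets with known ground truth.

The generative model mirrors the assumptions the analysis itself makes:

* an ancestral coding sequence is duplicated; each copy then accumulates
  Poisson-distributed substitutions on its own branch under an equal-rates
  (Jukes–Cantor-like) model, with the *derived* copy's branch rate multiplied
  by an asymmetry factor >= 1;
* the outgroup diverged from the ancestor earlier, with a branch length a
  configurable multiple of the paralogs' pairwise divergence;
* the per-pair asymmetry factor is a log-linear function of the pair's K_S,
  its relocation status and its duplication span, so downstream regressions
  have a configured, recoverable signal;
* genomic context is realized explicitly: each paralog's gene (exons and
  introns, splice sites at codon boundaries) sits inside a duplicated tract
  of known span, flanked by unrelated random sequence, so termination-point
  detection, span measurement and structural classification can be scored
  against truth. Heterogeneous pairs arise from duplications that truncate
  the ORF (partial) or additionally recruit novel exonic sequence into the
  derived copy (chimeric).

Defaults emulate the kind of dataset the pipeline targets: 130 pairs,
K_S in [0, 0.1363] with young pairs over-represented, ~26% of pairs with one
copy relocated to a different chromosome, structure mix ~50% complete /
~19% partial / ~31% chimeric, a right-skewed span distribution (floor 128 bp),
~15% of pairs containing a pseudogene, and 2 kb of retrieved flank.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import divergence, relrate
from .seq_io import (
    Alphabet,
    GeneAnnotation,
    PairManifestEntry,
    SequenceRecord,
    write_annotations,
    write_fasta,
    write_manifest,
)

log = logging.getLogger(__name__)

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)

_STOP_IDS = frozenset((48, 50, 56))  # TAA, TGA, TAG with A=0 C=1 G=2 T=3


def _stop_ids() -> frozenset[int]:
    # derive rather than trust the constant
    ids = set()
    for codon in ("TAA", "TAG", "TGA"):
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        ids.add(16 * idx[codon[0]] + 4 * idx[codon[1]] + idx[codon[2]])
    return frozenset(ids)


assert _stop_ids() == _STOP_IDS


@dataclass(frozen=True)
class AsymmetryModel:
    """Log-linear map from pair features to the derived-branch rate multiplier:
    factor = max(1, exp(b0 + b_ks*K_S + b_reloc*relocated + b_span*span))."""

    beta_intercept: float = 1.0
    beta_ks: float = 4.0
    beta_relocation: float = 0.5
    beta_span: float = -1.0e-4

    def factor(self, ks: float, relocated: bool, span_bp: float) -> float:
        z = (
            self.beta_intercept
            + self.beta_ks * ks
            + self.beta_relocation * float(relocated)
            + self.beta_span * span_bp
        )
        return max(1.0, math.exp(z))


@dataclass
class SimulationConfig:
    n_pairs: int = 130
    seed: int = 0
    cds_length_codons: tuple[int, int] = (100, 400)
    outgroup_depth_multiplier: float = 3.0
    ks_max: float = 0.1363
    ks_scale: float = 0.05  # truncated-exponential scale: young pairs dominate
    asymmetry_model: AsymmetryModel = field(default_factory=AsymmetryModel)
    p_relocation: float = 34 / 130
    structure_probs: tuple[float, float, float] = (65 / 130, 25 / 130, 40 / 130)
    span_log_mean: float = math.log(1670.0)  # lognormal: right-skewed spans
    span_log_sd: float = 0.8
    span_min: int = 128
    span_max: int = 10646
    p_pseudogene: float = 20 / 130
    flank_bp: int = 2000

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        for name in ("p_relocation", "p_pseudogene"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.structure_probs) - 1.0) > 1e-9:
            raise ValueError("structure_probs must sum to 1")
        if min(self.structure_probs) < 0:
            raise ValueError("structure_probs must be nonnegative")
        if self.span_min < 1 or self.span_max <= self.span_min:
            raise ValueError("invalid span bounds")
        if not 0 < self.ks_max <= 0.5:
            raise ValueError("ks_max must be in (0, 0.5]")
        lo, hi = self.cds_length_codons
        if lo < 30 or hi < lo:
            raise ValueError("cds_length_codons must be a range with lower bound >= 30")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# Sequence-level machinery


def _seq_str(arr: np.ndarray) -> str:
    return _NT[arr].tobytes().decode()


def random_cds(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    """Uniform random sense codons (no internal stops), as 0–3 nt codes."""
    sense = np.array([c for c in range(64) if c not in _STOP_IDS])
    codons = rng.choice(sense, size=n_codons)
    out = np.empty(3 * n_codons, dtype=np.uint8)
    out[0::3] = codons >> 4
    out[1::3] = (codons >> 2) & 3
    out[2::3] = codons & 3
    return out


def _mutate_coding(seq: np.ndarray, n_subs: int, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Apply n random substitutions, redrawing any that create a stop codon."""
    out = seq.copy()
    L = len(out)
    applied = 0
    for _ in range(n_subs):
        for _try in range(50):
            pos = int(rng.integers(L))
            new = (out[pos] + int(rng.integers(1, 4))) % 4
            old = out[pos]
            out[pos] = new
            c = pos - pos % 3
            cid = 16 * out[c] + 4 * out[c + 1] + out[c + 2]
            if cid in _STOP_IDS:
                out[pos] = old
                continue
            applied += 1
            break
    return out, applied


def _mutate_noncoding(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(out)) < p
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


@dataclass
class TripletSim:
    """One simulated triplet: ancestral copy, derived copy, outgroup (nt codes)."""

    anc: np.ndarray
    der: np.ndarray
    out: np.ndarray
    root: np.ndarray
    truth: dict

    def records(self, id_anc: str, id_der: str, id_out: str) -> tuple[SequenceRecord, ...]:
        return (
            SequenceRecord(id_anc, _seq_str(self.anc), Alphabet.NUCLEOTIDE),
            SequenceRecord(id_der, _seq_str(self.der), Alphabet.NUCLEOTIDE),
            SequenceRecord(id_out, _seq_str(self.out), Alphabet.NUCLEOTIDE),
        )


def simulate_triplet(
    length_codons: int,
    ks_target: float,
    asymmetry_factor: float,
    outgroup_depth: float,
    rng: np.random.Generator,
) -> TripletSim:
    """Evolve a duplicate pair plus outgroup from a random ancestral CDS.

    The total expected substitution count separating the two copies is
    calibrated so that their expected pairwise synonymous divergence is
    ``ks_target`` (under uniform substitution, the synonymous fraction of
    random changes equals the synonymous fraction of sites, so total
    substitutions ≈ ks_target × length). The derived branch carries
    ``asymmetry_factor`` times the ancestral branch's expected count; the
    outgroup branch carries ``outgroup_depth`` × half the pairwise total.
    """
    if length_codons < 30:
        raise ValueError("need at least 30 codons")
    if asymmetry_factor < 1.0:
        raise ValueError("asymmetry_factor must be >= 1")
    L = 3 * length_codons
    t_pair = ks_target * L
    if t_pair > 0.5 * L:
        raise ValueError(f"ks_target {ks_target} too large to calibrate at {length_codons} codons")
    t_anc = t_pair / (1.0 + asymmetry_factor)
    t_der = asymmetry_factor * t_pair / (1.0 + asymmetry_factor)
    t_out = outgroup_depth * t_pair / 2.0

    root = random_cds(rng, length_codons)
    n_anc = int(rng.poisson(t_anc))
    n_der = int(rng.poisson(t_der))
    n_out = int(rng.poisson(t_out))
    anc, k_anc = _mutate_coding(root, n_anc, rng)
    der, k_der = _mutate_coding(root, n_der, rng)
    out, k_out = _mutate_coding(root, n_out, rng)
    return TripletSim(
        anc, der, out, root,
        truth={
            "ks_target": ks_target,
            "asymmetry_factor": asymmetry_factor,
            "n_subs_ancestral": k_anc,
            "n_subs_derived": k_der,
            "n_subs_outgroup": k_out,
            "length_codons": length_codons,
        },
    )


# --- fast statistics on gap-free triplets (positionally aligned by construction)


def _codon_ids(seq: np.ndarray) -> np.ndarray:
    return (16 * seq[0::3].astype(np.int64) + 4 * seq[1::3] + seq[2::3])


def triplet_site_counts(sim: TripletSim, level: Alphabet) -> relrate.UniqueSiteCounts:
    """Unique-site counts straight from a simulated (indel-free) triplet."""
    if level is Alphabet.NUCLEOTIDE:
        a, b, o = sim.anc, sim.der, sim.out
        usable = np.ones(len(a), dtype=bool)
    else:
        t = divergence.codon_tables()
        ca, cb, co = _codon_ids(sim.anc), _codon_ids(sim.der), _codon_ids(sim.out)
        a, b, o = t["aa"][ca], t["aa"][cb], t["aa"][co]
        usable = ~(t["stop"][ca] | t["stop"][cb] | t["stop"][co])
    m_a = int((usable & (a != b) & (b == o)).sum())
    m_b = int((usable & (a != b) & (a == o)).sum())
    alldiff = int((usable & (a != b) & (a != o) & (b != o)).sum())
    return relrate.UniqueSiteCounts(m_a, m_b, alldiff, int(usable.sum()), level)


def triplet_ks(sim: TripletSim) -> divergence.KsEstimate:
    return divergence.ng86_from_codon_ids(_codon_ids(sim.anc), _codon_ids(sim.der))


# ---------------------------------------------------------------------------
# Feature-level dataset (fast path: no genomic context realization)


def _draw_ks(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    # truncated exponential on [0, ks_max]
    u = rng.random()
    cdf_max = 1.0 - math.exp(-cfg.ks_max / cfg.ks_scale)
    return -cfg.ks_scale * math.log1p(-u * cdf_max)


def _draw_span(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    s = rng.lognormal(cfg.span_log_mean, cfg.span_log_sd)
    return int(min(max(s, cfg.span_min), cfg.span_max))


_STRUCTURES = ("complete", "heterogeneous_partial", "heterogeneous_chimeric")
_CHROMS = ("I", "II", "III", "IV", "V", "X")


def simulate_feature_table(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate per-pair features and sequence-derived statistics directly.

    Every statistic (unique-site counts, χ² significance, asymmetry/site at
    both levels, NG86 K_S) is computed from actually evolved triplet
    sequences; only the genomic-context realization (flanks, exon layout) is
    skipped, which is exact here because these triplets contain no indels and
    are therefore positionally aligned by construction. Suitable for power
    and recovery studies that iterate many datasets.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    alpha = 0.05
    rows = []
    for i in range(config.n_pairs):
        ks_true = _draw_ks(config, rng)
        span = _draw_span(config, rng)
        relocated = bool(rng.random() < config.p_relocation)
        structure = _STRUCTURES[int(rng.choice(3, p=config.structure_probs))]
        pseudo = bool(rng.random() < config.p_pseudogene)
        n_codons = int(rng.integers(config.cds_length_codons[0], config.cds_length_codons[1] + 1))
        factor = config.asymmetry_model.factor(ks_true, relocated, span)
        sim = simulate_triplet(n_codons, ks_true, factor, config.outgroup_depth_multiplier, rng)

        c_nt = triplet_site_counts(sim, Alphabet.NUCLEOTIDE)
        c_aa = triplet_site_counts(sim, Alphabet.AMINO_ACID)
        t_nt = relrate.tajima_test(c_nt, alpha)
        t_aa = relrate.tajima_test(c_aa, alpha)
        ks_est = triplet_ks(sim)
        ks_val = ks_est.ks if not ks_est.saturated else ks_true
        same_chrom = not relocated
        rows.append({
            "pair_id": f"pair{i:04d}",
            "structure3": structure,
            "structure": "homogeneous" if structure == "complete" else "heterogeneous",
            "chromosome_relation": "same" if same_chrom else "different",
            "orientation": ("same" if rng.random() < 0.5 else "opposite") if same_chrom else None,
            "genomic_distance_bp": int(10 ** rng.uniform(3.0, 6.5)) if same_chrom else None,
            "span_bp": span,
            "ks": ks_val,
            "cohort": divergence.assign_cohort(max(ks_val, 0.0)).label,
            "pseudogene_pair": pseudo,
            "m_a_nt": c_nt.m_a, "m_b_nt": c_nt.m_b, "L_nt": c_nt.L,
            "chi_square_nt": t_nt.chi_square, "p_nt": t_nt.p_value,
            "significant_nt": t_nt.significant,
            "m_a_aa": c_aa.m_a, "m_b_aa": c_aa.m_b, "L_aa": c_aa.L,
            "chi_square_aa": t_aa.chi_square, "p_aa": t_aa.p_value,
            "significant_aa": t_aa.significant,
            "asym_nt": relrate.asymmetry_per_site(c_nt),
            "asym_aa": relrate.asymmetry_per_site(c_aa),
            "signed_nt": relrate.signed_standardized_asymmetry(c_nt, True),
            "signed_aa": relrate.signed_standardized_asymmetry(c_aa, True),
            "true_ks": ks_true,
            "true_factor": factor,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full dataset realization (sequences + annotations + manifest + truth)


@dataclass
class SimulatedDataset:
    cds: dict[str, SequenceRecord]
    genomic: dict[str, SequenceRecord]
    annotations: dict[str, GeneAnnotation]
    manifest: list[PairManifestEntry]
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.cds.values(), out / "cds.fasta")
        write_fasta(self.genomic.values(), out / "genomic.fasta")
        write_annotations(self.annotations.values(), out / "annotations.tsv")
        write_manifest(self.manifest, out / "manifest.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        meta = {"seed": self.config.seed, "config": self.config.to_dict()}
        meta["config"]["asymmetry_model"] = dataclasses.asdict(self.config.asymmetry_model)
        (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _split_exon_lengths(
    cds_nt: int, n_exons: int, rng: np.random.Generator, min_len: int = 45
) -> list[int]:
    """Split a CDS into exon chunks at codon boundaries, each >= min_len nt."""
    min_codons = (min_len + 2) // 3
    codons = cds_nt // 3
    n_exons = max(1, min(n_exons, codons // min_codons))
    lengths = []
    remaining = codons
    for k in range(n_exons - 1, 0, -1):
        hi = remaining - min_codons * k
        take = int(rng.integers(min_codons, hi + 1))
        lengths.append(take)
        remaining -= take
    lengths.append(remaining)
    return [3 * x for x in lengths]


def simulate_dataset(
    config: SimulationConfig | None = None, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Realize a full synthetic dataset (FASTA + annotations + manifest + truth).

    Genomic-context FASTA descriptions carry ``ctx_start=<chromosomal
    position of context base 0>`` so exon annotations can be mapped into
    context coordinates.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    flank = config.flank_bp

    cds: dict[str, SequenceRecord] = {}
    genomic: dict[str, SequenceRecord] = {}
    annots: dict[str, GeneAnnotation] = {}
    manifest: list[PairManifestEntry] = []
    truth_rows = []

    for i in range(config.n_pairs):
        pid = f"pair{i:04d}"
        id_anc, id_der, id_out = pid + "anc", pid + "der", pid + "out"

        ks_true = _draw_ks(config, rng)
        relocated = bool(rng.random() < config.p_relocation)
        structure = _STRUCTURES[int(rng.choice(3, p=config.structure_probs))]
        pseudo = bool(rng.random() < config.p_pseudogene)

        n_codons = int(rng.integers(config.cds_length_codons[0], config.cds_length_codons[1] + 1))
        n_exons = int(rng.integers(2, 6))
        exon_lens = _split_exon_lengths(3 * n_codons, n_exons, rng)
        n_exons = len(exon_lens)
        intron_lens = [int(rng.integers(50, 91)) for _ in range(n_exons - 1)]
        gene_len = sum(exon_lens) + sum(intron_lens)

        pre = int(rng.integers(80, 201))  # shared tract upstream of the gene
        if structure == "complete":
            drawn = _draw_span(config, rng)
            post = int(min(max(drawn - gene_len - pre, 40), 1500))
            span_true = pre + gene_len + post
            cut_local = None
        else:
            m_keep = int(rng.integers(1, n_exons))  # exons retained by the derived copy
            intron_part = int(rng.integers(20, intron_lens[m_keep - 1] - 19))
            cut_local = sum(exon_lens[:m_keep]) + sum(intron_lens[: m_keep - 1]) + intron_part
            span_true = pre + cut_local
            post = 0

        factor = config.asymmetry_model.factor(ks_true, relocated, span_true)
        sim = simulate_triplet(n_codons, ks_true, factor, config.outgroup_depth_multiplier, rng)
        p_branch = ks_true / 2.0  # noncoding per-site substitution probability

        pre_anc = rng.integers(0, 4, size=pre).astype(np.uint8)
        introns_anc = [rng.integers(0, 4, size=l).astype(np.uint8) for l in intron_lens]
        post_anc = rng.integers(0, 4, size=post).astype(np.uint8)

        def build_gene(cds_arr, introns):
            pieces = []
            offset = 0
            exon_bounds = []
            pos = 0
            for k, elen in enumerate(exon_lens):
                pieces.append(cds_arr[offset : offset + elen])
                exon_bounds.append((pos, pos + elen))
                pos += elen
                offset += elen
                if k < len(introns):
                    pieces.append(introns[k])
                    pos += len(introns[k])
            return np.concatenate(pieces), exon_bounds

        # ancestral copy: full gene in its ancestral neighborhood
        introns_a = [_mutate_noncoding(x, p_branch, rng) for x in introns_anc]
        gene_a, exon_bounds = build_gene(sim.anc, introns_a)
        pre_a = _mutate_noncoding(pre_anc, p_branch, rng)
        post_a = _mutate_noncoding(post_anc, p_branch, rng)
        fill5_a = rng.integers(0, 4, size=flank - pre).astype(np.uint8)
        fill3_a = rng.integers(0, 4, size=flank - post).astype(np.uint8)
        ctx_a = np.concatenate([fill5_a, pre_a, gene_a, post_a, fill3_a])
        gene_start_a = flank  # == len(fill5_a) + pre

        # derived copy: duplicated tract (possibly truncated) in a new neighborhood
        introns_d = [_mutate_noncoding(x, p_branch, rng) for x in introns_anc]
        gene_d_full, _ = build_gene(sim.der, introns_d)
        pre_d = _mutate_noncoding(pre_anc, p_branch, rng)
        if structure == "complete":
            tract_d = np.concatenate([pre_d, gene_d_full, _mutate_noncoding(post_anc, p_branch, rng)])
            der_exon_bounds = exon_bounds
            der_cds_arr = sim.der
            tail = []
        else:
            tract_d = np.concatenate([pre_d, gene_d_full[:cut_local]])
            der_exon_bounds = exon_bounds[:m_keep]
            der_cds_arr = sim.der[: sum(exon_lens[:m_keep])]
            tail = []
            if structure == "heterogeneous_chimeric":
                gap = rng.integers(0, 4, size=int(rng.integers(40, 121))).astype(np.uint8)
                novel = random_cds(rng, int(rng.integers(30, 81)))
                tail = [gap, novel]
        fill5_d = rng.integers(0, 4, size=flank - pre).astype(np.uint8)
        fill3_d = rng.integers(0, 4, size=flank).astype(np.uint8)
        ctx_d = np.concatenate([fill5_d, tract_d] + tail + [fill3_d])
        gene_start_d = flank

        # derived-copy annotation exon layout (context-local, gene starts at flank)
        der_bounds_local = list(der_exon_bounds)
        der_cds_pieces = [der_cds_arr]
        if structure == "heterogeneous_chimeric":
            novel_start = len(fill5_d) + len(tract_d) + len(tail[0]) - gene_start_d
            der_bounds_local.append((novel_start, novel_start + len(tail[1])))
            der_cds_pieces.append(tail[1])
        der_cds_full = np.concatenate(der_cds_pieces)

        # chromosomal placement
        chrom_a = _CHROMS[int(rng.integers(len(_CHROMS)))]
        start_a = int(rng.integers(10_000, 5_000_000))
        if relocated:
            others = [c for c in _CHROMS if c != chrom_a]
            chrom_d = others[int(rng.integers(len(others)))]
            start_d = int(rng.integers(10_000, 5_000_000))
        else:
            chrom_d = chrom_a
            gap_bp = int(10 ** rng.uniform(3.0, 6.5))
            start_d = start_a + gene_len + gap_bp
        strand_a = "+" if rng.random() < 0.5 else "-"
        strand_d = "+" if rng.random() < 0.5 else "-"

        gene_end_a = start_a + gene_len
        der_gene_len = (der_bounds_local[-1][1] - der_bounds_local[0][0]) if der_bounds_local else 0
        gene_end_d = start_d + der_gene_len

        chrom_o = chrom_a  # outgroup ortholog retains the ancestral location
        start_o = int(rng.integers(10_000, 5_000_000))

        ann_a = GeneAnnotation(
            id_anc, chrom_a, strand_a, start_a, gene_end_a,
            tuple((start_a + s, start_a + e) for s, e in exon_bounds),
            pseudogene=False, ortholog_id=id_out, ortholog_chromosome=chrom_o,
        )
        ann_d = GeneAnnotation(
            id_der, chrom_d, strand_d, start_d, gene_end_d,
            tuple((start_d + s, start_d + e) for s, e in der_bounds_local),
            pseudogene=pseudo, ortholog_id=id_out, ortholog_chromosome=chrom_o,
        )
        ann_o = GeneAnnotation(
            id_out, chrom_o, "+", start_o, start_o + gene_len,
            tuple((start_o + s, start_o + e) for s, e in exon_bounds),
        )
        annots[id_anc], annots[id_der], annots[id_out] = ann_a, ann_d, ann_o

        cds[id_anc] = SequenceRecord(id_anc, _seq_str(sim.anc), Alphabet.NUCLEOTIDE)
        cds[id_der] = SequenceRecord(id_der, _seq_str(der_cds_full), Alphabet.NUCLEOTIDE)
        cds[id_out] = SequenceRecord(id_out, _seq_str(sim.out), Alphabet.NUCLEOTIDE)
        genomic[id_anc] = SequenceRecord(
            id_anc, _seq_str(ctx_a), Alphabet.NUCLEOTIDE,
            description=f"ctx_start={start_a - gene_start_a}",
        )
        genomic[id_der] = SequenceRecord(
            id_der, _seq_str(ctx_d), Alphabet.NUCLEOTIDE,
            description=f"ctx_start={start_d - gene_start_d}",
        )

        # manifest label order decoupled from ancestry
        anc_is_a = bool(rng.random() < 0.5)
        pa, pb = (id_anc, id_der) if anc_is_a else (id_der, id_anc)
        manifest.append(PairManifestEntry(pid, pa, pb, id_out, outgroup_source="Cbrig"))

        truth_rows.append({
            "pair_id": pid,
            "paralog_a": pa, "paralog_b": pb, "outgroup": id_out,
            "ancestral_id": id_anc,
            "true_ks": ks_true,
            "true_asymmetry_factor": factor,
            "true_span_bp": span_true,
            "true_structure": structure,
            "relocated": relocated,
            "pseudogene_pair": pseudo,
            "n_subs_ancestral": sim.truth["n_subs_ancestral"],
            "n_subs_derived": sim.truth["n_subs_derived"],
            "n_subs_outgroup": sim.truth["n_subs_outgroup"],
        })

    ds = SimulatedDataset(
        cds=cds, genomic=genomic, annotations=annots, manifest=manifest,
        truth=pd.DataFrame(truth_rows), config=config,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds
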