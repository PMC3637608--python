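"""End-to-end analysis: feature extraction, per-pair statistics, inference.

``run_full_analysis`` drives every stage for each triplet in the manifest —
homology-region / span / structure extraction from genomic contexts,
protein- and nucleotide-level relative-rate statistics, NG86 K_S — then runs
the inference battery over the resulting pair-features table and assembles an
:class:`AnalysisReport` with one block per analysis:

* cohort significance profile across the five K_S age bins,
* stepwise regressions of asymmetry/site on structure, chromosomal location,
  duplication span and K_S (nucleotide and amino-acid responses),
* the same-chromosome sub-model (genomic distance + transcriptional
  orientation, forced least squares),
* Kendall correlations of K_S with asymmetry,
* pseudogene comparisons (Williams-corrected G-test of pseudogene frequency
  across the three structural classes; rank-sum tests of asymmetry),
* duplication span across structural classes (Kruskal–Wallis),
* ancestral-vs-derived signed-rank tests on standardized asymmetry.

Blocks with insufficient data are marked ``skipped`` with a reason, never
silently absent. The report is deterministic given identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align, divergence, relrate, stats
from .seq_io import GeneAnnotation, PairManifestEntry, SequenceRecord

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    homology_window_bp: int = 100
    homology_min_identity: float = 0.6
    homology_step_bp: int = 1000
    alpha: float = 0.05
    exon_overlap_fraction: float = 0.5
    boundary_tolerance_bp: int = 6
    include_all_different: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                for sub, v in val.items():
                    flat[f"{key}_{sub}".replace("__", "_")] = v
            else:
                flat[key] = val
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**flat)


# ---------------------------------------------------------------------------
# Ancestral / derived assignment


def _splice_junctions(ann: GeneAnnotation) -> list[int]:
    """Internal exon boundaries in spliced (mRNA) coordinates."""
    out = []
    pos = 0
    for start, end in ann.exons[:-1]:
        pos += end - start
        out.append(pos)
    return out


def _junction_score(paralog: GeneAnnotation, outgroup: GeneAnnotation, tol: int) -> int:
    pj = _splice_junctions(paralog)
    oj = _splice_junctions(outgroup)
    return sum(1 for j in oj if any(abs(j - k) <= tol for k in pj))


def assign_ancestral(
    annot_a: GeneAnnotation,
    annot_b: GeneAnnotation,
    annot_out: GeneAnnotation | None,
    boundary_tolerance_bp: int = 6,
) -> tuple[str | None, str]:
    """Identify the ancestral copy of a pair from the outgroup ortholog.

    Synteny rule: if exactly one paralog shares the ortholog's chromosome
    label, it is the ancestral copy (parsimony: relocation happened to the
    other). Structure rule: the paralog sharing more internal exon boundaries
    (within ``boundary_tolerance_bp`` in spliced coordinates) with the
    ortholog is ancestral. When both rules apply they must agree; pairs where
    neither discriminates remain unassigned.
    """
    if annot_out is None:
        return None, "no_outgroup"
    synteny_pick: str | None = None
    a_shares = annot_a.chromosome == annot_out.chromosome
    b_shares = annot_b.chromosome == annot_out.chromosome
    if a_shares != b_shares:
        synteny_pick = annot_a.gene_id if a_shares else annot_b.gene_id

    structure_pick: str | None = None
    sa = _junction_score(annot_a, annot_out, boundary_tolerance_bp)
    sb = _junction_score(annot_b, annot_out, boundary_tolerance_bp)
    if sa != sb:
        structure_pick = annot_a.gene_id if sa > sb else annot_b.gene_id

    if synteny_pick and structure_pick:
        if synteny_pick == structure_pick:
            return synteny_pick, "synteny+structure"
        return None, "conflicting"
    if synteny_pick:
        return synteny_pick, "synteny"
    if structure_pick:
        return structure_pick, "structure"
    return None, "unassigned"


def genomic_distance(annot_a: GeneAnnotation, annot_b: GeneAnnotation) -> int | None:
    """Nearest-edge gap (bp) between gene spans on the same chromosome;
    0 for overlapping or nested genes."""
    if annot_a.chromosome != annot_b.chromosome:
        return None
    gap = max(annot_a.span_start, annot_b.span_start) - min(annot_a.span_end, annot_b.span_end)
    return max(0, gap)


# ---------------------------------------------------------------------------
# Per-pair analysis


def _cds_codon_mask(
    ann: GeneAnnotation, ctx_offset: int, region_lo: int, region_hi: int, cds_len: int
) -> np.ndarray:
    """Which codons of a spliced CDS lie inside the homologous tract.

    Maps each coding position through the exon structure into context
    coordinates (annotation exons are assumed to be coding exons); a codon is
    homologous only if all three of its positions fall inside the bounds.
    """
    pos: list[int] = []
    for start, end in ann.exons:
        pos.extend(range(start - ctx_offset, end - ctx_offset))
        if len(pos) >= cds_len:
            break
    arr = np.full(cds_len, -1, dtype=np.int64)
    take = min(cds_len, len(pos))
    arr[:take] = pos[:take]
    inside = (arr >= region_lo) & (arr < region_hi)
    n_codons = cds_len // 3
    return inside[: 3 * n_codons].reshape(-1, 3).all(axis=1)


def _ctx_start(rec: SequenceRecord) -> int:
    for token in rec.description.split():
        if token.startswith("ctx_start="):
            return int(token.split("=", 1)[1])
    raise ValueError(f"{rec.id}: genomic context lacks a ctx_start= tag")


def analyze_pair(
    pair: PairManifestEntry,
    cds: dict[str, SequenceRecord],
    genomic: dict[str, SequenceRecord],
    annotations: dict[str, GeneAnnotation],
    config: PipelineConfig,
) -> dict:
    """All per-pair quantities as one flat row (see PairFeatures columns)."""
    ann_a = annotations[pair.paralog_a]
    ann_b = annotations[pair.paralog_b]
    ann_out = annotations.get(pair.outgroup)
    ctx_a = genomic[pair.paralog_a]
    ctx_b = genomic[pair.paralog_b]
    off_a, off_b = _ctx_start(ctx_a), _ctx_start(ctx_b)

    region = align.find_homology_region(
        ctx_a, ctx_b,
        a_orf=(ann_a.span_start - off_a, ann_a.span_end - off_a),
        window_bp=config.homology_window_bp,
        min_identity=config.homology_min_identity,
        step_bp=config.homology_step_bp,
    )
    span = align.duplication_span(region)
    structure = align.classify_structure(
        ann_a, ann_b, region, off_a, off_b, config.exon_overlap_fraction
    )

    a_mask = _cds_codon_mask(
        ann_a, off_a, region.a_start, region.a_end, len(cds[pair.paralog_a].residues)
    )
    bundle = relrate.align_triplet(
        cds[pair.paralog_a], cds[pair.paralog_b], cds[pair.outgroup], a_codon_mask=a_mask
    )
    c_nt = relrate.count_unique_sites(bundle.nt, config.include_all_different)
    c_aa = relrate.count_unique_sites(bundle.aa, config.include_all_different)
    t_nt = relrate.tajima_test(c_nt, config.alpha)
    t_aa = relrate.tajima_test(c_aa, config.alpha)
    ks_est = divergence.ng86_divergence(
        bundle.pair_codon_a, bundle.pair_codon_b, bundle.pair_codon_mask
    )
    cohort = divergence.assign_cohort(ks_est.ks) if not ks_est.saturated else None

    ancestral_id, method = assign_ancestral(ann_a, ann_b, ann_out, config.boundary_tolerance_bp)
    signed_nt = signed_aa = None
    if ancestral_id is not None:
        anc_is_a = ancestral_id == pair.paralog_a
        signed_nt = relrate.signed_standardized_asymmetry(c_nt, anc_is_a)
        signed_aa = relrate.signed_standardized_asymmetry(c_aa, anc_is_a)

    same_chrom = ann_a.chromosome == ann_b.chromosome
    orientation = None
    if same_chrom:
        orientation = "same" if ann_a.strand == ann_b.strand else "opposite"

    return {
        "pair_id": pair.pair_id,
        "paralog_a": pair.paralog_a,
        "paralog_b": pair.paralog_b,
        "outgroup": pair.outgroup,
        "structure3": structure.value.value,
        "structure": structure.value.collapsed,
        "unique_exons_a": structure.unique_exons_a,
        "unique_exons_b": structure.unique_exons_b,
        "chromosome_relation": "same" if same_chrom else "different",
        "orientation": orientation,
        "genomic_distance_bp": genomic_distance(ann_a, ann_b),
        "span_a": span.span_a,
        "span_b": span.span_b,
        "span_bp": span.span,
        "terminated_5prime": region.terminated_5prime,
        "terminated_3prime": region.terminated_3prime,
        "ks": ks_est.ks,
        "ka": ks_est.ka,
        "ks_saturated": ks_est.saturated,
        "cohort": cohort.label if cohort is not None and not cohort.out_of_range else (
            divergence.OUT_OF_RANGE if cohort is not None else None
        ),
        "pseudogene_pair": bool(ann_a.pseudogene or ann_b.pseudogene),
        "ancestral_id": ancestral_id,
        "ancestry_method": method,
        "m_a_nt": c_nt.m_a, "m_b_nt": c_nt.m_b, "L_nt": c_nt.L,
        "chi_square_nt": t_nt.chi_square, "p_nt": t_nt.p_value,
        "significant_nt": t_nt.significant,
        "m_a_aa": c_aa.m_a, "m_b_aa": c_aa.m_b, "L_aa": c_aa.L,
        "chi_square_aa": t_aa.chi_square, "p_aa": t_aa.p_value,
        "significant_aa": t_aa.significant,
        "asym_nt": relrate.asymmetry_per_site(c_nt),
        "asym_aa": relrate.asymmetry_per_site(c_aa),
        "signed_nt": signed_nt,
        "signed_aa": signed_aa,
    }


# ---------------------------------------------------------------------------
# Inference battery over the features table


def regression_design(features: pd.DataFrame) -> pd.DataFrame:
    """0/1-coded predictor columns in the documented candidate order.

    Reference levels: structure = homogeneous, chromosomal location = same.
    """
    return pd.DataFrame({
        "structure(heterogeneous)": (features["structure"] == "heterogeneous").astype(float),
        "location(different)": (features["chromosome_relation"] == "different").astype(float),
        "span_bp": features["span_bp"].astype(float),
        "ks": features["ks"].astype(float),
    }, index=features.index)


def _model_block(model: stats.StepwiseModel) -> dict:
    return {
        "selected_terms": model.selected_terms,
        "selection_path": model.selection_path,
        "coefficients": {
            term: {k: float(v) for k, v in row.items()}
            for term, row in model.coefficients.iterrows()
        },
        "r_square": model.r_square,
        "r_square_adj": model.r_square_adj,
        "rmse": model.rmse,
        "mean_response": model.mean_response,
        "n": model.n_obs,
        "anova": {k: float(v) for k, v in model.anova.items()},
    }


def _test_block(res: stats.TestResult) -> dict:
    return {
        "statistic": res.statistic_name,
        "value": res.value,
        "df": res.df,
        "p_value": res.p_value,
        "n": list(res.n),
        "note": res.note,
    }


def _skipped(reason: str, n: int = 0) -> dict:
    return {"skipped": True, "reason": reason, "n": n}


@dataclass
class AnalysisReport:
    pairs: pd.DataFrame
    blocks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {"provenance": self.provenance, "blocks": self.blocks}
        return json.dumps(payload, indent=2, sort_keys=True, default=_json_default)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(out / "pair_features.tsv", sep="\t", index=False)
        nt_cols = ["pair_id", "m_a_nt", "m_b_nt", "L_nt", "chi_square_nt", "p_nt",
                   "significant_nt", "asym_nt"]
        aa_cols = ["pair_id", "m_a_aa", "m_b_aa", "L_aa", "chi_square_aa", "p_aa",
                   "significant_aa", "asym_aa"]
        self.pairs[[c for c in nt_cols if c in self.pairs]].to_csv(
            out / "relrate_nt.tsv", sep="\t", index=False)
        self.pairs[[c for c in aa_cols if c in self.pairs]].to_csv(
            out / "relrate_aa.tsv", sep="\t", index=False)
        (out / "report.json").write_text(self.to_json() + "\n")
        (out / "report.txt").write_text(self.render_text() + "\n")

    def render_text(self) -> str:
        lines = ["Paralog rate-asymmetry analysis report", "=" * 40]
        for name, block in self.blocks.items():
            lines.append("")
            lines.append(f"[{name}]")
            if block.get("skipped"):
                lines.append(f"  skipped: {block['reason']} (n = {block.get('n', 0)})")
                continue
            lines.append(json.dumps(block, indent=2, sort_keys=True, default=_json_default))
        lines.append("")
        lines.append(f"[provenance] {json.dumps(self.provenance, sort_keys=True, default=_json_default)}")
        return "\n".join(lines)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _safe(fn, *args, n: int = 0, **kwargs) -> dict:
    try:
        return fn(*args, **kwargs)
    except (ValueError, stats.CollinearityError) as exc:
        return {"skipped": True, "reason": str(exc), "n": n}


def run_inference(features: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """The full inference battery over a pair-features table; one block per
    analysis, skipped blocks carry a reason."""
    config = config or PipelineConfig()
    blocks: dict[str, dict] = {}
    feats = features.copy()
    usable = feats[np.isfinite(feats["ks"].astype(float))]
    excluded = len(feats) - len(usable)
    if excluded:
        log.info("excluding %d pair(s) with saturated/undefined K_S from inference", excluded)

    # cohort profile
    in_range = usable[usable["cohort"].isin(divergence.cohort_labels())]
    profile = stats.cohort_significance_profile(in_range, divergence.cohort_labels())
    blocks["cohort_profile"] = {
        "n": int(len(in_range)),
        "rows": profile.to_dict(orient="records"),
    }

    # stepwise regressions at both levels (identical predictor pipeline)
    X = regression_design(usable)
    for level, resp in (("nt", "asym_nt"), ("aa", "asym_aa")):
        name = f"regression_{level}"
        if len(usable) < 6:
            blocks[name] = _skipped("too few pairs for regression", len(usable))
            continue
        def _run(y=usable[resp], X=X):
            return _model_block(stats.stepwise_regression(y.astype(float), X))
        blocks[name] = _safe(_run, n=len(usable))

    # same-chromosome sub-model: distance + orientation, forced least squares
    same = usable[usable["chromosome_relation"] == "same"].dropna(
        subset=["genomic_distance_bp", "orientation"])
    for level, resp in (("nt", "asym_nt"), ("aa", "asym_aa")):
        name = f"same_chromosome_{level}"
        if len(same) < 4:
            blocks[name] = _skipped("too few same-chromosome pairs", len(same))
            continue
        Xs = pd.DataFrame({
            "genomic_distance_bp": same["genomic_distance_bp"].astype(float),
            "orientation(opposite)": (same["orientation"] == "opposite").astype(float),
        }, index=same.index)
        def _run(y=same[resp], Xs=Xs):
            return _model_block(stats.fit_least_squares(y.astype(float), Xs))
        blocks[name] = _safe(_run, n=len(same))

    # Kendall: K_S vs asymmetry/site
    for level, resp in (("nt", "asym_nt"), ("aa", "asym_aa")):
        blocks[f"kendall_ks_vs_asym_{level}"] = _safe(
            lambda r=resp: _test_block(stats.kendall_tau(usable["ks"], usable[r])) | {"n": int(len(usable))},
            n=len(usable),
        )

    # pseudogene comparisons
    pseudo = usable["pseudogene_pair"].astype(bool)
    order3 = ["complete", "heterogeneous_partial", "heterogeneous_chimeric"]
    table = np.array([
        [int(((usable["structure3"] == s) & ~pseudo).sum()) for s in order3],
        [int(((usable["structure3"] == s) & pseudo).sum()) for s in order3],
    ])
    blocks["pseudogene_structure_gtest"] = _safe(
        lambda: _test_block(stats.g_test_williams(table)) | {"table": table.tolist(), "classes": order3},
        n=int(table.sum()),
    )
    for level, resp in (("nt", "asym_nt"), ("aa", "asym_aa")):
        blocks[f"pseudogene_asymmetry_{level}"] = _safe(
            lambda r=resp: _test_block(
                stats.wilcoxon_rank_sum(usable.loc[pseudo, r], usable.loc[~pseudo, r])
            ),
            n=len(usable),
        )

    # duplication span by structural class
    groups = [usable.loc[usable["structure3"] == s, "span_bp"].to_numpy(float) for s in order3]
    if any(len(g) == 0 for g in groups):
        blocks["span_by_structure"] = _skipped("empty structural class", len(usable))
    else:
        blocks["span_by_structure"] = _safe(
            lambda: _test_block(stats.kruskal_wallis(groups)) | {
                "medians": {s: float(np.median(g)) for s, g in zip(order3, groups)}},
            n=len(usable),
        )

    # ancestral vs derived
    assigned = usable.dropna(subset=["ancestral_id"])
    for level, col in (("nt", "signed_nt"), ("aa", "signed_aa")):
        name = f"ancestral_derived_{level}"
        vals = assigned[col].dropna().to_numpy(float)
        blocks[name] = _safe(
            lambda v=vals: _test_block(stats.wilcoxon_signed_rank(v)) | {
                "n_assigned": int(len(vals)),
                "caveat": "synteny-based assignments assume no secondary translocations",
            },
            n=len(vals),
        )

    return blocks


def run_full_analysis(
    cds: dict[str, SequenceRecord],
    genomic: dict[str, SequenceRecord],
    annotations: dict[str, GeneAnnotation],
    manifest: list[PairManifestEntry],
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    config = config or PipelineConfig()
    rows = []
    failures = []
    for pair in manifest:
        try:
            rows.append(analyze_pair(pair, cds, genomic, annotations, config))
        except Exception as exc:  # a failing pair must not sink the rest
            log.warning("pair %s failed: %s", pair.pair_id, exc)
            failures.append({"pair_id": pair.pair_id, "error": str(exc)})
    features = pd.DataFrame(rows)
    if len(features) == 0:
        report = AnalysisReport(pairs=features)
        report.blocks = {"pairs": _skipped("no pair analyzed successfully", 0)}
        report.provenance = _provenance(config, len(manifest), failures)
        return report
    blocks = {"pairs": {"n": int(len(features)), "failed": failures}}
    blocks.update(run_inference(features, config))
    return AnalysisReport(
        pairs=features,
        blocks=blocks,
        provenance=_provenance(config, len(manifest), failures),
    )


def _provenance(config: PipelineConfig, n_manifest: int, failures: list) -> dict:
    return {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_manifest": n_manifest,
        "n_failed": len(failures),
    }
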