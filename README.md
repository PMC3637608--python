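# paralogasym

Asymmetric sequence divergence of evolutionarily young gene duplicates:
which copy speeds up, and which genomic features predict it.

After a gene duplication, the two paralogs often stop evolving at the same
rate — one copy keeps the ancestral job under purifying selection while the
other drifts or explores new function. `paralogasym` implements a complete,
testable pipeline for quantifying that asymmetry in young duplicate pairs
(synonymous divergence K_S ≤ 0.14) and relating it to the genomic anatomy of
the duplication event. It is aimed at molecular-evolution researchers who
have, for each duplicate pair, the two paralog sequences, an outgroup
ortholog, and gene annotations.

## What it computes

For each triplet (paralog A, paralog B, outgroup O), aligned at the protein
level with codons threaded back for the nucleotide level:

* **Unique-site counts** m_A, m_B — columns where one paralog differs from
  both its partner and the outgroup (a substitution on that paralog's branch).
* **Tajima's relative-rate test** — χ² = (m_A − m_B)² / (m_A + m_B), 1 df,
  testing the molecular-clock null of equal branch rates. At small counts the
  test is conservative: with m_A + m_B = 20, a difference of at least 9 is
  needed to reject at α = 0.05.
* **Asymmetry/site** — |m_A − m_B| / L with L the usable homologous length; a
  continuous per-length measure usable where the χ² test has no power.
* **K_S , K_A** — Nei–Gojobori (1986) counting with Jukes–Cantor correction,
  on the codon alignment of the paralogs' homologous coding region; K_S keys
  five age cohorts ([0,0.01), [0.01,0.03), [0.03,0.05), [0.05,0.08),
  [0.08,0.14)).
* **Duplication span** — the homologous tract length between duplication
  termination points, found by extending outward from the ORF until a
  continuous 1 kb stretch shows no homology (sliding 100 bp windows, ≥60%
  identity); the lower of the two per-paralog spans is reported.
* **Structural class** — complete (no unique exons), partial (one paralog
  has unique exons) or chimeric (both do).
* **Ancestral vs derived copy** — assigned by synteny (which paralog shares
  the outgroup ortholog's chromosome) and/or exon-structure similarity to the
  ortholog, giving a signed standardized asymmetry
  (m_ancestral − m_derived)/L.

The inference battery then runs: stepwise mixed-selection multiple regression
(entry p ≤ 0.15, stay p ≤ 0.10, final OLS refit) of asymmetry/site on
structure, chromosomal location, span and K_S at both sequence levels; the
same-chromosome sub-model (genomic distance + transcriptional orientation);
Kendall's τ-b; Wilcoxon two-sample and signed-rank tests; Kruskal–Wallis for
span by structure; and a Williams-corrected G-test for pseudogene frequencies.

A first-class synthetic-data generator (`paralogasym.simulate`) produces
complete datasets — FASTA, annotations, manifest — with known ground truth
(branch rates, true spans, true structure, ancestral copy), so every stage is
testable end to end without any external download.

## Worked example

```python
from paralogasym import SimulationConfig, simulate_dataset, run_full_analysis

ds = simulate_dataset(SimulationConfig(n_pairs=130, seed=1))
report = run_full_analysis(ds.cds, ds.genomic, ds.annotations, ds.manifest)

pairs = report.pairs
print(f"significant rate asymmetry (nt): {pairs.significant_nt.sum()}/{len(pairs)}")
reg = report.blocks["regression_nt"]
print("selected terms:", reg["selected_terms"])
for term, row in reg["coefficients"].items():
    print(f"  {term:<26} {row['estimate']:+.6f}  p={row['p_value']:.3g}")
print(f"R^2 = {reg['r_square']:.4f}, F = {reg['anova']['f_ratio']:.2f}")
```

prints (this exact seed):

```
significant rate asymmetry (nt): 67/130
selected terms: ['ks', 'span_bp']
  Intercept                  +0.008071  p=3.36e-05
  ks                         +0.332352  p=6.72e-31
  span_bp                    -0.000003  p=0.0272
R^2 = 0.6547, F = 120.42
```

Reading: on this simulated dataset, rate asymmetry per site grows with
evolutionary age (positive K_S coefficient) and shrinks with duplication span
(negative, microscopically small per-bp coefficient — spans are thousands of
bp). The chromosomal-relocation effect is configured into the generator too
but at n = 130 the stepwise procedure does not always retain it; at n = 500
all three effects are recovered with their configured signs in ≥ 90% of runs
(see below). The default generator is deliberately signal-rich, so the
fraction of significant pairs is higher than one would see in a comparable
biological dataset.

The same analysis is available from the shell:

```bash
paralogasym simulate --out data/ --seed 1 --n-pairs 130
paralogasym run --fasta data/cds.fasta --fasta-genomic data/genomic.fasta \
    --annot data/annotations.tsv --manifest data/manifest.tsv --out out/
paralogasym report --in out/
```

## Layout

```
src/paralogasym/
  seq_io.py       FASTA / annotation-TSV / manifest reading and validation
  align.py        Needleman–Wunsch (affine, fixed tie-break), homology
                  regions, duplication span, structural classification
  relrate.py      triplet alignment, unique-site counts, relative-rate test,
                  asymmetry measures
  divergence.py   NG86 K_S/K_A, age cohorts
  stats.py        stepwise regression and the nonparametric test battery
  simulate.py     synthetic-data generator with ground truth
  pipeline.py     orchestration and report assembly
  calibration.py  null-calibration and recovery experiments
  cli.py          `paralogasym` command group
```

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
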