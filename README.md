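# xtalk — organelle cross-talk screening in protein interaction networks

`xtalk` is a reusable, fully testable implementation of a network screen
for **cytosolic proteins that bridge the endoplasmic reticulum (ER) and
mitochondria**. Contact sites between the two organelles
(mitochondria-associated membranes, MAMs) depend on cytosolic relays, and
their disruption is implicated in neurodegeneration; the screen nominates
candidate relay proteins from a compartment-labeled protein–protein
interaction (PPI) graph together with case/control expression evidence.

The pipeline chains six stages, each usable on its own:

1. **Catalog harmonization** — merge multi-source organelle protein lists
   (ER / mitochondria / cytosol) into a symbol-unique catalog; assign each
   protein a *primary* compartment by an explicit policy
   (source majority with a configurable priority tie-break).
2. **Graph construction** — a simple undirected PPI graph restricted to
   catalog proteins, every node labeled with its primary compartment.
3. **Dense-complex extraction (MCODE)** — each vertex *v* is weighted by
   `w(v) = k_max(N[v]) · density(highest k-core of N[v])` over its closed
   neighborhood `N[v]`; complexes grow from high-weight seeds, admitting
   neighbors with `w ≥ (1 − VWP) · w(seed)`, with optional *haircut*
   (2-core) and *fluff* (dense-boundary inclusion) post-processing, and are
   ranked by `density × size`.
4. **Meta differential expression** — per study, a pooled-variance
   two-group *t* contrast per gene; across studies, Fisher's
   combined-probability statistic `X² = −2 Σ ln pᵢ ~ χ²(2k)`; genes with
   combined `p < α` are DEGs, and complexes containing DEGs become
   disease-associated ("PD") clusters.
5. **Linker scoring** — inside the top-ranked PD cluster containing all
   three compartments, every cytosolic member *c* gets a *bridge length*
   `min over (e ∈ ER, m ∈ mito) [d(e, c) + d(c, m)]` in hops, with ties
   broken by the number of minimal ER→c→mito witness paths, then degree.
   The rank-1 node is the nominated relay.
6. **Expression validation statistics** — comparative-Ct (ΔΔCt) fold
   changes from qPCR tables (`fold = 2^−ΔΔCt`), one-way ANOVA, and Tukey
   HSD post-hoc comparisons.

A first-class synthetic-data module generates seeded catalogs,
planted-partition networks (with ground truth), multi-study case/control
expression matrices, and Ct tables, so the whole screen runs and is tested
entirely offline.

## Worked example

The packaged end-to-end fixture emulates a published organelle screen: a
2941-protein catalog (243 ER / 1399 mitochondria / 1299 cytosol), three
dense complexes of 84, 66 and 44 members, three case/control expression
studies totalling 277 samples, and a 75-sample qPCR table. The 44-member
complex is tri-compartmental (37 mitochondrial, 6 cytosolic, 1 ER member)
and carries a planted relay: the cytosolic protein **DDO** touches the ER
protein **SEC61A1** only through the mitochondrial intermediates **IDE**
and **UBA52**.

```python
from xtalk.pipeline import run_pipeline

result = run_pipeline({
    "simulate": {"preset": "reference_screen"},
    "seed": 1,
    "outdir": "out",
})
print("\n".join(result["report"]))
```

prints (abridged):

```
[annotate] 2941 proteins (1399 mito / 1299 cytosol / 243 ER), policy=source_majority
[cluster] rank 1: 84 members / 3444 edges (score 82.988, seed P000249)
[cluster] rank 2: 66 members / 1848 edges (score 56.862, seed P000298)
[cluster] rank 3: 44 members / 728 edges (score 33.860, seed P001032)
[meta-de] 3 studies, 2941 genes, 573 DEGs at alpha 0.05 (adjust=none)
[map] PD clusters: ranks [1, 2, 3] (min_hits=1)
[linker] selected cluster rank 3: 44 members (37 mito / 6 cytosol / 1 ER)
[linker] rank 1: DDO bridge_length=3 n_paths=2 witness=SEC61A1>IDE>DDO|DDO>UBA52
[ddct] group istradefylline: mean fold 0.508 (SD 0.128, n=25)
[anova] F=28.71 df=(2,72) p=6.794e-10
[tukey] control vs istradefylline: p_adj=1.502e-08 *
```

Reading the output: the three densest complexes mirror the expected
84/66/44 shape; all three contain DEGs, but only the 44-member cluster
spans all three compartments, so it is selected. Within it, DDO is the
top-ranked cytosolic linker — two hops from the ER and one from a
mitochondrial hub (bridge length 3), with exactly two minimal witness
relays (via IDE and via UBA52). The validation stage recovers the planted
two-fold down-regulation in the istradefylline group (mean fold 0.508
against a planted 0.5) and Tukey flags both of its pairwise contrasts.

The same run is available from the shell:

```bash
xtalk run --config run.yaml          # full screen from a YAML config
xtalk simulate --preset reference_screen --seed 1 --outdir data/
xtalk cluster --edges data/edges.tsv --catalog data/catalog.tsv --out complexes.tsv
```

Every run writes per-stage TSVs, a line-oriented `report.txt`, a DOT
export with the witness relay highlighted, and a `manifest.json` with all
parameters, seeds and output hashes; two runs with the same config are
byte-identical.

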