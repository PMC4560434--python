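# isodiv

Classify the *regulatory origin* of divergent transcript isoform usage
between two inbred strains from allele-specific expression in their F1
hybrids, and the *structural differences* between the isoforms involved.

## The problem

Two mouse strains (e.g. C57BL/6J "BL6" and CAST/EiJ "CAST") can differ not
only in how much of a gene they express, but in *which isoforms* they
express — divergent isoform usage (DIU). Any such difference is caused by a
mutation acting either **in cis** (linked to the affected allele: a
promoter, splice site or polyadenylation signal variant) or **in trans** (a
diffusible factor: a transcription factor or splicing regulator). F1
hybrids separate the two: both parental alleles sit in the same nucleus, so
a trans change affects both alleles equally while a cis change remains
allele-specific.

`isodiv` takes transcript models (GTF), transcript-level expression
estimates with standard errors for F0 replicates and F1 allele-resolved
measurements (TSV), and a strain variant table (VCF/TSV), and produces for
each gene expressing exactly two overlapping isoforms:

* a **regulatory call** — conserved / cis / trans / cis&trans — by Bayesian
  model comparison,
* a **structural classification** of the isoform pair — alternative first
  exon (AFE), transcription start site (TSS), internal splicing (INT),
  alternative last exon (ALE), alternative polyadenylation (APA),
* cohort-level cross-tabulations (category-by-mechanism enrichment,
  INT-alone excess, DIU x DGE independence).

A bundled synthetic-data generator emulates the full study design
(6 replicates per F0 strain, 12 F1 replicates measured per allele) with
known ground truth, so every stage is testable without any data download.

## The model

For a gene with isoform expression estimates $(e_1, e_2)$, usage is
summarised as the natural log-odds $\ell = \log(e_1/e_2)$. Two statistics
are computed per gene:

* $d_1$: mean F0 BL6 log-odds minus mean F0 CAST log-odds,
* $d_2$: mean over F1 replicates of (BL6-allele minus CAST-allele)
  log-odds,

with plug-in variances $v_1, v_2$ combining replicate scatter and the
per-estimate standard errors (delta method). Four models put a
$N(0,\sigma_0^2)$ prior on each free effect:

| model     | $E[d_1]$  | $E[d_2]$  | marginal likelihood |
|-----------|-----------|-----------|---------------------|
| conserved | $0$       | $0$       | $N(d_1;0,v_1)\,N(d_2;0,v_2)$ |
| cis       | $\beta$   | $\beta$   | bivariate $N$, cov $\begin{bmatrix}v_1+\sigma_0^2&\sigma_0^2\\\sigma_0^2&v_2+\sigma_0^2\end{bmatrix}$ |
| trans     | $\beta$   | $0$       | $N(d_1;0,v_1+\sigma_0^2)\,N(d_2;0,v_2)$ |
| cis&trans | $\beta_1$ | $\beta_2$ | $N(d_1;0,v_1+\sigma_0^2)\,N(d_2;0,v_2+\sigma_0^2)$ |

With a uniform 1/4 model prior, posteriors are the normalised marginals.
A gene is labelled only when one model's posterior exceeds 0.5 — more
probable than the other three combined — otherwise it is left
unclassified.

## Worked example

```python
import json
from isodiv import RunConfig, SimulationConfig, run_pipeline

sim = SimulationConfig(n_genes=300, n_single_spikeins=10, n_multi_spikeins=10)
manifest = run_pipeline(RunConfig(out_dir="demo", seed=7, simulation=sim))
print("funnel:", json.dumps(manifest["funnel"]))
print("classes:", json.dumps(manifest["n_classified"]))
print("structural changes:", manifest["total_structural_changes"],
      "| per category:", json.dumps(manifest["flag_counts"]))
```

prints

```
funnel: {"total_genes": 320, "two_expressed_isoforms": 300, "two_expressed_overlapping": 300, "nonoverlapping_removed": 0, "final_with_variant": 300}
classes: {"conserved": 65, "cis": 74, "trans": 82, "cis_trans": 79, "unclassified": 0}
structural changes: 679 | per category: {"AFE": 141, "TSS": 109, "INT": 169, "ALE": 109, "APA": 151}
```

The cohort planted 300 analysable two-isoform genes plus 20 spike-ins
(single- and three-isoform genes without strain variants); the selection
funnel removes exactly the spike-ins. Each analysed gene then receives a
regulatory call — here the planted classes are uniform, and the calls
recover them — and a structural flag profile; the 300 pairs carry 679
discrete structural differences (about 2.3 per pair), i.e. most divergent
pairs differ through more than one regulatory system. `demo/` holds the
per-gene tables (`calls.tsv`, `flags.tsv`, `proportions.tsv`), the
cross-tabulations, and a `manifest.json` recording seed and configuration;
rerunning with the same seed reproduces every file byte for byte.

The same stages are available from the shell:

```bash
isodiv --seed 7 --out-dir demo report --n-genes 300
isodiv --out-dir out filter --gtf demo/annotation.gtf \
    --expression demo/expression.tsv --meta demo/samples.tsv \
    --variants demo/variants.vcf
```

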