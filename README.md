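# isoreg

Isobaric-reporter (iTRAQ four-plex) protein quantification with a
2-standard-deviation regulation statistic and treatment-contrast
classification.

## The problem

After experimental subarachnoid hemorrhage (SAH), the proteome of large
cerebral arteries remodels over the following days — the window in which
delayed cerebral ischemia develops. Inhibiting the MEK-ERK1/2 kinase cascade
(with the MEK1/2 inhibitor U0126) normalizes much of that remodeling. The
analysis implemented here quantifies that effect from tandem-MS data of
iTRAQ-labeled cerebral-artery pools in three groups — U0126-treated SAH
(reporter channel 114), vehicle-treated SAH (channel 115), and sham surgery
(channel 116, the reference) — run as duplicate labeling experiments, and
asks: which proteins change after SAH, and which of those changes disappear
under MEK1/2 inhibition?

The package is for proteomics analysts and methods developers who want the
full pipeline — PSM filtering, reporter quantification, normalization,
regulation calling, contrast classification, and downstream summaries — as
tested, composable library code, with a synthetic-data generator that makes
every stage verifiable against known ground truth (the original raw spectra
were never deposited).

## The method

Per peptide-spectrum match (PSM) with reporter intensities $I_c$, the log
ratio against the sham reference is $r_c = \log_2(I_c / I_{116})$ for
channels $c \in \{114, 115\}$. The pipeline:

1. **Filter.** Target-decoy q-values per labeling experiment,
   $\mathrm{FDR}(t) = \#\{\text{decoys} \ge t\} / \max(1, \#\{\text{targets}
   \ge t\})$, $q(s) = \min_{t \le s} \mathrm{FDR}(t)$; keep targets with
   $q \le 0.01$ and search score $\ge 18$.
2. **Quantify.** Protein ratio = median of its PSM ratios, per channel and
   experiment.
3. **Normalize.** Subtract each channel's median protein ratio within each
   labeling experiment (protein-median normalization), then average each
   protein across the duplicate experiments.
4. **Call regulation.** For each channel ("tag") with protein ratios $x_i$,
   center $m$ = median, spread $s$ = sample SD; protein $i$ is *up* if
   $(x_i - m)/s > 2$, *down* if $< -2$, else *unchanged*.
5. **Classify the contrast.** *Group 1*: up in vehicle-vs-sham and down or
   unchanged in U0126-vs-sham (SAH-induced increase abolished by MEK1/2
   inhibition). *Group 2*: the mirror image for decreases. Proteins
   regulated in both directions of the same sign are *persistent*.
6. **Summarize.** Molecular-function category breakdown against a
   user-supplied annotation table, and connected components of the induced
   interaction network from a scored edge list (score cutoff 0.4).

The published result tables (ten most up-/downregulated proteins; the
group-1 and group-2 lists with their log2 iTRAQ ratios) are packaged as
checksum-pinned TSV fixtures and can be replayed (`isoreg replay-paper`).

## Worked example

```python
from isoreg import GeneratorConfig, PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(generator=GeneratorConfig(seed=1)))
for group, m in report["recovery"].items():
    print(group, m)
```

prints (numbers produced by this exact run):

```
group1 {'true_members': 100, 'predicted': 96, 'sensitivity': 0.96, 'specificity': 1.0}
group2 {'true_members': 100, 'predicted': 96, 'sensitivity': 0.96, 'specificity': 1.0}
```

i.e. of 2,000 simulated proteins with 100 planted in each of group 1 and
group 2 (true |log2| effect 1.5, per-PSM reporter noise 0.3, effects
reversed by treatment), the pipeline recovers 96 of each hundred and admits
no false members. The same run reports each stage's counts: 17,948 PSMs in,
16,109 after the 1%-FDR + score-floor filter (all 1,839 decoys removed),
2,000 proteins quantified, 98 up / 100 down called in the vehicle contrast.

The `examples/` directory holds one short script per capability
(simulation and recovery, reference-table replay, FDR filtering, category
and network summaries); each prints what it computes and what the numbers
mean. The `isoreg` command exposes the same stages as shell subcommands.

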