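# tfcascade

Hierarchical classification of **primary vs secondary transcription-factor
target genes**, and inference of the regulatory cascade behind the secondary
response.

## The problem

When a ligand activates a nuclear receptor — the motivating case is the
vitamin D receptor (VDR) activated by 1,25(OH)₂D₃ in monocytic cells — the
differentially expressed genes (DEGs) measured over a time course mix two
populations: *primary* targets bound and regulated by the receptor itself,
and *secondary* targets regulated by intermediate transcription factors that
are themselves primary targets. Timing alone (early 2.5 h/4 h response vs
late 24 h response) is a poor classifier: many late DEGs carry direct
receptor binding evidence.

`tfcascade` implements the three-channel evidence model that resolves this:

1. **window_peak** — a root-TF ChIP-seq peak overlaps the ±25 kb window
   centred on a gene's TSS;
2. **rem_overlap** — a regulatory element (REM, as catalogued in
   EpiRegio-style region→gene link tables) linked to the gene overlaps a
   root-TF peak;
3. **motif_open_chromatin** — a root-TF motif in open chromatin (FAIRE/ATAC)
   inside the window, scored by the TRAP biophysical affinity model and
   thresholded against random sequences.

A DEG supported by at least *k* channels (default *k* = 1, *k* = 2 for a
stringent variant) is classified primary; the rest are secondary. Secondary
DEGs are then explained by a DYNAMITE-style sparse logistic regression: TF–gene
scores contrasted between treated and control open chromatin are features, the
up/down direction of each secondary DEG is the label, and the elastic-net
coefficient of each TF — normalized to [0, 1] — ranks candidate driver TFs.
Finally, a directed, root-centred TF network connects the root to every
primary-target TF and adds `predicted_binding` edges from early-responding TFs
to TFs whose gene locus they are predicted to bind above threshold.

## The model in brief

TRAP occupancy of a motif of width *m* on a sequence window with mismatch
energy *E* is

```
p = R₀·e⁻ᴱ / (1 + R₀·e⁻ᴱ),   E(b,i) = ln(p_max,i / p_b,i) / λ,
λ = 0.7,  ln R₀ = 0.584·m − 5.66
```

summed over both strands and all offsets. TF–gene scores follow the TEPIC
exponential-decay aggregation

```
score(g, tf) = Σ_regions  affinity(r, tf) · exp(−|center(r) − TSS(g)| / d₀),  d₀ = 5 kb
```

over open-chromatin regions in the ±25 kb TSS window.

## Worked example

No downloads are needed: the package ships a deterministic generator that
emulates the full input structure (genome FASTA, GTF annotation, ChIP-seq and
open-chromatin BED tracks, REM and DEG tables, JASPAR motifs) with planted
ground truth.

```python
from tfcascade import SimulationConfig, simulate_bundle, config_for_bundle, run_pipeline

bundle = simulate_bundle(SimulationConfig(seed=1), "demo_bundle")
result = run_pipeline(config_for_bundle(bundle, "demo_run"))

for timing in ("early", "late"):
    cls = result.classification
    n = (cls.timing == timing).sum()
    k = ((cls.timing == timing) & cls.is_primary).sum()
    print(f"{timing:5s} DEGs: {n:4d}   predicted primary: {k:4d} ({100 * k / n:.1f}%)")
print("top driver candidates:",
      ", ".join(f"{i.tf_name} ({i.normalized_coefficient:.3f})"
                for i in result.importances[:3]))
edges = [(u, v) for u, v, d in result.network.edges(data=True)
         if d["evidence"] == "predicted_binding"]
print("binding edges:", edges)
```

prints

```
early DEGs:   22   predicted primary:   22 (100.0%)
late  DEGs:  128   predicted primary:   69 (53.9%)
top driver candidates: TF_E2 (1.000), TF_E1 (0.822), VDR (0.236)
binding edges: [('TF_E1', 'TF_E2'), ('TF_E2', 'TF_E1'), ('TF_E2', 'TF_L2')]
```

All 22 early DEGs and 69 of the 128 late DEGs carry planted regulatory
evidence and are recovered as primary; the two early TFs that drive the
planted secondary response dominate the regression ranking; and the binding
edges equal the planted TF→TF pairs exactly. The same command sequence works
on real data — point the `PipelineConfig` path fields at your own GTF, BED,
FASTA, motif, REM and DEG files.

The CLI mirrors the library:

```bash
cascade simulate --config sim.yaml --out bundle/
cascade run --config run.yaml
cascade classify --peaks peaks.bed --genes genes.gtf --rems rems.tsv \
    --scores scores.tsv --deg 2.5h=deg_2.5h.tsv --deg 4h=deg_4h.tsv \
    --deg 24h=deg_24h.tsv --early 2.5h,4h --late 24h --k 1 --out cls.tsv
```

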