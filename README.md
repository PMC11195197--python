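# fbekit

Toolkit and analysis pipeline for **adjacent FBF-binding-element (FBE)
discovery** in CLIP peak sequences, with the accompanying quantitative
binding analyses and germline expression-profile quantitation.

## The problem

PUF-family RNA-binding proteins such as *C. elegans* FBF-2 maintain
germline stem cells by repressing differentiation mRNAs through short
single-stranded RNA elements (FBEs). The partner protein LST-1 carries
two PUF-interacting motifs and can bridge two FBF-2 molecules, so a
natural question is which target mRNAs carry *pairs* of closely spaced
FBEs that could anchor such a higher-order complex — and how partner
binding changes affinity at those sites. `fbekit` implements that
analysis end to end for anyone working with CLIP peak sets and
equilibrium binding data:

- **Motif model** — exact matching of four degenerate element classes
  over RNA/DNA sequence (R = A/G, Y = C/U, n = any base):
  canonical `UGURnnAUn` (9 nt), compact `UGURnAUn` (8 nt), and the
  a\*-like variants `UGUYRnAUn` (9 nt) and `UGUnRnnAUn` (10 nt).
- **Adjacency scan** — qualifying pairs require at least one canonical
  element and a spacing of 1–20 nt computed from element starts:
  `gap = start(3′ element) − start(5′ element) − length(5′ element)`.
- **Peak statistics** — FPKM height comparisons (unpaired equal-variance
  t-test) and Y479A partnership-dependence categories.
- **Binding models** — the one-set-of-sites ITC isotherm (simulate and
  fit N, K_d, ΔH; derive ΔG = RT ln K_d and −TΔS = ΔG − ΔH), EMSA
  fraction-bound fitting with `B_max·x/(K_d + x)`, relative FRET
  efficiency `I_668/(I_668 + I_564)`, and affinity fold changes.
- **Expression profiles** — per-gonad intensity vs distance along the
  germline distal–proximal axis: genotype means with 95% CIs,
  normalization to the wild-type distal maximum, pooled window t-tests.
- **Synthetic data** — seeded generators for every input above with
  serialized ground truth, so the whole pipeline runs and is validated
  at desk scale.

## Worked example

The 29-nt *gld-1* 3′UTR fragment `AUCAUGUGCCAUACAUCAUGUUGCCAUUU`
carries the canonical FBEa and the noncanonical FBEa\*:

```python
>>> from fbekit import scan_all, find_pairs, flank_inclusive_gap
>>> rna = "AUCAUGUGCCAUACAUCAUGUUGCCAUUU"
>>> [(m.pattern_name, m.start, m.matched_text) for m in scan_all(rna)]
[('FBE9', 4, 'UGUGCCAUA'), ('ASTAR10', 18, 'UGUUGCCAUU')]
>>> (pair,) = find_pairs(scan_all(rna))
>>> pair.gap                      # core-element spacing: 18 - 4 - 9
5
>>> flank_inclusive_gap(4, 9, 18) # spacing of the CA-flanked elements
3
```

The scanner finds exactly the two elements; the core-element convention
puts them 5 nt apart, while the flank-inclusive convention (elements
extended 5′ through the affinity-enhancing CA) gives the 3-nt spacing
usually quoted for this pair. Thermodynamics from a measured K_d:

```python
>>> from fbekit import delta_g, minus_t_delta_s
>>> round(delta_g(1.1e-6), 1)     # Kd = 1.1 uM at 293.15 K
-33.4
>>> round(minus_t_delta_s(-33.4, -61.9), 1)
28.5
```

## The analysis pipeline

Numbered drivers under `analysis/` run the full study at desk scale and
write TSV tables under `results/`:

```sh
python analysis/01_simulate_peaks.py      # synthetic peak set + ground truth
python analysis/02_scan_adjacent_fbes.py  # adjacent-element scan
python analysis/03_peak_height_stats.py   # FPKM height comparisons
python analysis/04_itc_fits.py            # ITC generate-and-refit table
python analysis/05_emsa_fret_fits.py      # EMSA Kd recovery + FRET
python analysis/06_germline_profiles.py   # profile normalization + windows
```

A typical run reports, e.g., `51/200 peaks carry adjacent FBEs`,
adjacent-peak heights ~2300 vs ~1200 FPKM for all peaks
(p = 1.6e-03), stoichiometries recovered exactly from noise-free
titrations, and `***` distal (0–10 µm) but `ns` proximal windows for a
repression-defective element mutant.

The same stages are available as a CLI (`fbekit scan|stats|fit-itc|
fit-emsa|fret|profiles|simulate`). To run the scan on a real peak set
(e.g. the deposited FBF-2 eCLIP peaks), supply a FASTA of peak
sequences plus a TSV with columns `peak_id, gene_id, region, height_wt`
(optional `height_mut`, `category`):

```sh
fbekit scan --fasta peaks.fasta --peaks peaks.tsv --out results/scan
```

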