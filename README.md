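# taucleave

Time-resolved degradomics of protease digestion time courses: from
peptide-level MS identification tables to per-site cleavage kinetics,
fragment maps, P1-site classes and P5–P5′ specificity profiles.

## The problem

Limited-proteolysis MS follows a protease digesting a substrate over time:
samples taken at fixed time points in replicate yield identified peptides
with intensities. Each proteolytic product is bounded by two cuts, so its
termini reveal cleavage sites — the residue N-terminal to a scissile bond
is the site's **P1** residue. The quantity of interest is the **relative
frequency of cuts**: for each P1 site and time point, the sum over all
peptides evidencing that site of their average-intensity ratio, where each
peptide's reference is its first positive average along the time course,
after a per-time-point significance gate against substrate-alone controls
(non-significant or undetected averages are set to zero). Sites are then
classified by their maximum frequency (class 1: ≥ 20, class 2: 10–19,
class 3: < 10, class 4: undetected), peptides aligning without gaps are
grouped into fragments, and amino-acid preferences are profiled five
residues either side of the scissile bond.

The bundled study substrate is 2N4R human tau (441 residues), whose
amyloid fibril core (residues 306–378) is shielded from proteolysis in the
fibrillar state. A ground-truthed synthetic-digest generator — exponential
bond-cutting hazards in four class tiers, a multiplicative core-protection
factor, a detectable-length window and lognormal intensity noise — makes
every stage testable without any external data. A small companion module
computes specific protease activity, ΔA405·V/(m·ε·t), and fold activation
from chromogenic pNA plate-reader traces.

This is an analysis project: computation lives in the `taucleave` package
under `src/`, and the numbered scripts under `analysis/` are thin drivers
that run the study and write tables under `results/`.

## Worked example

```
python analysis/01_simulate_digests.py --seed 1   # soluble, fibrillar, CN digests
python analysis/02_cut_frequencies.py             # frequency matrices + site counts
python analysis/03_fragments_and_classes.py       # fragments, classes, specificity
python analysis/04_compare_conditions.py          # soluble vs fibrillar, wt vs CN
python analysis/05_activity_assay.py --seed 1     # pNA specific activities and folds
```

which prints (seed 1):

```
soluble: 91 contributing peptides, 40 sites, final-time site count 40
fibrillar: 70 contributing peptides, 31 sites, final-time site count 31
soluble: final-time fragments=1 (Peps=91, Cls=40); class tally 1:10, 2:6, 3:24
soluble - fibrillar: 40 sites compared; core sites with positive delta_max: 14/14
soluble truth recovery: sensitivity 0.98, precision 1.00, spearman rho 0.82
A4 (fibrils 5.0 uM): rate 0.0104/min, specific activity 1.183e-04, fold 2.61
```

Reading: of 41 planted sites, 40 are detected in the soluble run and the
max-over-time frequency recovers the planted hazard ranking (ρ = 0.82);
the fibrillar run detects fewer sites and all 14 sites inside the
protected core show a positive soluble-minus-fibrillar Δmax — the
protection signature. By the final time point the accepted peptides cover
one contiguous fragment of the C-terminal half (the zero-hazard N-terminal
half stays uncovered, class 4 throughout). In the activity demo, a well
with a planted 2.6-fold activation is recovered as fold 2.61.

Library use is one import away:

```python
from taucleave import tau_2n4r, make_tau_like_truth, simulate_digest, SimConfig

tau = tau_2n4r()
sim = simulate_digest(tau, make_tau_like_truth(tau), SimConfig(seed=1))
result = sim.analyze()                      # score filter, gate, ratios, sums
result.matrix.frequencies                   # P1 × time DataFrame
```

Real MaxQuant-style tables enter through `read_peptide_table` with a
sample manifest (`TimeSeriesDesign.from_manifest`).

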